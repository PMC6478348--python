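"""Readers and writers for the pipeline's plain-text interchange formats.

Everything travels as TSV or GMT so that intermediate results can be
inspected, diffed and versioned.  Exon coordinates are 1-based inclusive
(Ensembl convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

META_COLUMNS = ["gene_id", "exon_id", "chrom", "start", "end", "strand"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExonCountTable:
    """Per-exon, per-sample raw counts with genomic coordinates.

    ``table`` holds the six metadata columns (gene_id, exon_id, chrom,
    start, end, strand) followed by one integer column per sample.
    ``conditions`` maps sample id -> condition label.
    """

    table: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLUMNS]

    @property
    def counts(self) -> pd.DataFrame:
        return self.table[self.samples]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"count table missing columns: {missing}")
        if not self.samples:
            raise DataError("count table has no sample columns")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, conditions: dict[str, str] | None = None) -> "ExonCountTable":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table, conditions=conditions or {})


def read_conditions(path: str | Path) -> dict[str, str]:
    """Two-column sample sheet: sample_id <TAB> condition."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError("condition sheet needs columns: sample_id, condition")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_conditions(conditions: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(conditions), "condition": list(conditions.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        terms[parts[0]] = set(g for g in parts[2:] if g)
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_meta_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV term_id -> meta_group; terms may repeat across groups."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for term, group in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        out.setdefault(term, [])
        if group not in out[term]:
            out[term].append(group)
    return out


def write_meta_map(meta_map: dict[str, list[str]], path: str | Path) -> None:
    rows = [(t, g) for t, groups in meta_map.items() for g in groups]
    pd.DataFrame(rows, columns=["term_id", "meta_group"]).to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV mirna_id -> gene_id, aggregated to sets."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for mir, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        out.setdefault(mir, set()).add(gene)
    return out
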