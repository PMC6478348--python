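"""Feature-matrix assembly, meta-KEGG labelling and miRNA host-exon rules.

The FeatureMatrix is the substrate of every unsupervised stage: rows are
observations (exons), columns are numeric variables (per-sample
normalized counts, per-condition usage coefficients, optionally fold
changes), plus an optional qualitative label used as a supplementary
variable in PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deu import DEUResult
from .simulate import AnnotationCatalog

logger = logging.getLogger(__name__)

SCALE_TOL = 1e-8
MAX_META_LABELS = 5
UNANNOTATED = "unannotated"

__all__ = [
    "FeatureMatrix",
    "MirnaExonSet",
    "build_feature_matrix",
    "scale_matrix",
    "assign_meta_kegg",
    "extract_mirna_exons",
    "split_composite_gene_id",
]


@dataclass
class FeatureMatrix:
    """Observations x numeric variables, with optional qualitative label."""

    data: pd.DataFrame
    qualitative_label: pd.Series | None = None
    scaled: bool = False
    center: pd.Series | None = field(default=None, repr=False)
    scale: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        if self.qualitative_label is not None:
            self.qualitative_label = self.qualitative_label.reindex(self.data.index)
        if self.scaled:
            means = self.data.mean(axis=0).to_numpy()
            stds = self.data.std(axis=0, ddof=0).to_numpy()
            if np.abs(means).max() > 1e-6 or np.abs(stds - 1).max() > 1e-6:
                raise ValueError("scaled flag set but columns are not standardized")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    @property
    def n_var(self) -> int:
        return self.data.shape[1]

    def unscale(self) -> "FeatureMatrix":
        """Invert standardization using the stored center/scale."""
        if not self.scaled:
            return self
        if self.center is None or self.scale is None:
            raise ValueError("no center/scale stored; cannot unscale")
        raw = self.data * self.scale + self.center
        return FeatureMatrix(data=raw, qualitative_label=self.qualitative_label, scaled=False)


def scale_matrix(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (population sd); constant columns are dropped
    with a warning."""
    data = fm.data
    stds = data.std(axis=0, ddof=0)
    constant = stds[stds == 0].index.tolist()
    if constant:
        if len(constant) == data.shape[1]:
            raise ValueError("all columns are constant; nothing to scale")
        logger.warning("dropping constant columns under scaling: %s", constant)
        data = data.drop(columns=constant)
        stds = stds.drop(constant)
    center = data.mean(axis=0)
    z = (data - center) / stds
    return FeatureMatrix(
        data=z,
        qualitative_label=fm.qualitative_label,
        scaled=True,
        center=center,
        scale=stds,
    )


def build_feature_matrix(
    results: list[DEUResult],
    scale: bool = False,
    include_log2fc: bool = False,
    labels: dict[str, str] | None = None,
) -> FeatureMatrix:
    """One row per exon; columns are per-sample normalized counts and
    per-condition usage coefficients (plus the log2 fold change when
    ``include_log2fc`` is set, as in the miRNA matrix)."""
    if not results:
        raise ValueError("no results to build a matrix from")
    samples = list(results[0].normalized_counts)
    conds = list(results[0].usage_coefficient)
    rows, index = [], []
    for r in results:
        if list(r.normalized_counts) != samples or list(r.usage_coefficient) != conds:
            raise ValueError("results are not rectangular")
        row = [r.normalized_counts[s] for s in samples]
        row += [r.usage_coefficient[c] for c in conds]
        if include_log2fc:
            row.append(r.log2fc)
        rows.append(row)
        index.append(f"{r.gene_id}:{r.exon_id}")
    columns = [f"norm_{s}" for s in samples] + [f"usage_{c}" for c in conds]
    if include_log2fc:
        columns.append("log2fc")
    data = pd.DataFrame(rows, index=index, columns=columns)
    qual = pd.Series({i: labels.get(i, UNANNOTATED) for i in index}) if labels else None
    fm = FeatureMatrix(data=data, qualitative_label=qual)
    return scale_matrix(fm) if scale else fm


def split_composite_gene_id(exon_ref: str) -> tuple[list[str], str | None]:
    """Parse composite Ensembl references like
    ``ENSGALG...+ENSGALG...:E005`` into ([gene ids], exon id)."""
    if ":" in exon_ref:
        gene_part, exon_part = exon_ref.rsplit(":", 1)
    else:
        gene_part, exon_part = exon_ref, None
    return [g for g in gene_part.split("+") if g], exon_part


def assign_meta_kegg(
    results: list[DEUResult], catalog: AnnotationCatalog
) -> dict[str, list[str]]:
    """Map each exon to the meta-groups of the terms containing its gene.

    Collapsing terms to at most five functional meta-group labels averts
    the hyper-annotation that arises when every exon of a gene inherits
    every pathway of that gene.  Labels are ranked by how many of the
    gene's terms map to each group; ties break alphabetically.  Exons of
    unannotated genes get the single label ``"unannotated"``.
    """
    gene_terms: dict[str, list[str]] = {}
    for term, genes in catalog.terms.items():
        for g in genes:
            gene_terms.setdefault(g, []).append(term)
    out: dict[str, list[str]] = {}
    for r in results:
        key = f"{r.gene_id}:{r.exon_id}"
        genes, _ = split_composite_gene_id(r.gene_id)
        counts: dict[str, int] = {}
        for g in genes:
            for term in gene_terms.get(g, []):
                for group in catalog.meta_map.get(term, []):
                    counts[group] = counts.get(group, 0) + 1
        if not counts:
            out[key] = [UNANNOTATED]
        else:
            ranked = sorted(counts, key=lambda g: (-counts[g], g))
            out[key] = ranked[:MAX_META_LABELS]
    return out


@dataclass
class MirnaExonSet:
    """FDR-passing exons paired with the miRNAs they host and the locus
    rule that linked them: contained in a single exon, spanning two
    exons, or intronic with both flanking exons significant."""

    table: pd.DataFrame  # columns: mirna_id, gene_id, exon_id, rule

    RULES = ("single-exon", "spans-two-exons", "intron-flanking")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def extract_mirna_exons(
    results: list[DEUResult],
    mirna_annotation: pd.DataFrame,
    exon_coords: pd.DataFrame,
    fdr: float = 0.1,
) -> MirnaExonSet:
    """Apply the three host-locus rules to FDR-passing exons.

    ``mirna_annotation`` columns: mirna_id, gene_id, chrom, start, end,
    strand (1-based inclusive).  ``exon_coords`` columns: gene_id,
    exon_id, chrom, start, end, strand.  Overlap is evaluated on the
    matching strand only.  A miRNA fully inside one significant exon
    yields a single-exon row; one overlapping the boundary of two
    adjacent significant exons yields a row for each (which is why a
    miRNA id can repeat); an intronic miRNA is kept only when BOTH
    flanking exons are significant, contributing both flanks.
    """
    sig = {(r.gene_id, r.exon_id) for r in results if r.p_bh < fdr}
    coords = exon_coords.sort_values(["gene_id", "start"])
    by_gene = {g: sub.reset_index(drop=True) for g, sub in coords.groupby("gene_id")}

    rows = []
    for rec in mirna_annotation.itertuples(index=False):
        try:
            m_start, m_end = int(rec.start), int(rec.end)
            if m_start > m_end:
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("skipping malformed miRNA interval: %s", getattr(rec, "mirna_id", "?"))
            continue
        sub = by_gene.get(rec.gene_id)
        if sub is None:
            continue
        sub_strand = sub[sub["strand"] == rec.strand]
        hits = [
            e
            for e in sub_strand.itertuples(index=False)
            if e.chrom == rec.chrom and _overlaps(e.start, e.end, m_start, m_end)
        ]
        if len(hits) == 1 and hits[0].start <= m_start and m_end <= hits[0].end:
            e = hits[0]
            if (rec.gene_id, e.exon_id) in sig:
                rows.append((rec.mirna_id, rec.gene_id, e.exon_id, "single-exon"))
        elif len(hits) >= 2:
            if all((rec.gene_id, e.exon_id) in sig for e in hits[:2]):
                for e in hits[:2]:
                    rows.append((rec.mirna_id, rec.gene_id, e.exon_id, "spans-two-exons"))
        elif not hits:
            # intronic: find the exon pair bracketing the miRNA
            prev = nxt = None
            for e in sub_strand.itertuples(index=False):
                if e.chrom != rec.chrom:
                    continue
                if e.end < m_start and (prev is None or e.end > prev.end):
                    prev = e
                if e.start > m_end and (nxt is None or e.start < nxt.start):
                    nxt = e
            if prev is not None and nxt is not None:
                if (rec.gene_id, prev.exon_id) in sig and (rec.gene_id, nxt.exon_id) in sig:
                    rows.append((rec.mirna_id, rec.gene_id, prev.exon_id, "intron-flanking"))
                    rows.append((rec.mirna_id, rec.gene_id, nxt.exon_id, "intron-flanking"))
        # partial single-exon overlap without a second exon: treated as spanning
        elif len(hits) == 1:
            e = hits[0]
            if (rec.gene_id, e.exon_id) in sig:
                rows.append((rec.mirna_id, rec.gene_id, e.exon_id, "single-exon"))

    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "exon_id", "rule"])
    table = table.drop_duplicates().sort_values(["mirna_id", "gene_id", "exon_id"]).reset_index(drop=True)
    return MirnaExonSet(table=table)
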