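"""Synthetic data generators and the bundled miRNA exon fixture.

The generators emulate the shape of a two-condition pooled-replicate
exon-level RNA-seq experiment: negative-binomially distributed exon
counts for multi-exon genes, a planted fraction of differentially used
exons (with directions that may oppose one another within a gene, so
that the gene-level net change can cancel), miRNA-hosting exons, and a
KEGG-like annotation catalog with meta-group labels.  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import DataError, ExonCountTable

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "MirnaFixture",
    "AnnotationCatalog",
    "generate_exon_counts",
    "generate_random_matrix",
    "generate_annotation_catalog",
    "load_mirna_fixture",
    "FIXTURE_OUTLIER_EXON",
]

#: Exon excluded from the clustering reanalysis because its abundance
#: dominates all others (first PCA/k-means iteration outlier).
FIXTURE_OUTLIER_EXON = "ENSGALG00000003532+ENSGALG00000027517:E001"

_FIXTURE_SHA256 = "b14c2036a08dc5d90b3ae30e219b31a1f94d08a95b09d030b5d38ab87b08ae23"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic exon-count experiment.

    The defaults mirror the study design being emulated: two conditions
    ("alcohol" vs "control") with two pooled replicates each, NB counts
    with dispersion 0.01 (a biological coefficient of variation of 0.1,
    typical for pooled samples of a genetically uniform model organism),
    and a planted fraction of differentially used exons.
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 8)
    n_replicates_per_condition: int = 2
    nb_mean_range: tuple[float, float] = (50.0, 2000.0)
    nb_dispersion: float = 0.01
    frac_deu_exons: float = 0.1
    deu_log2_effect: float = 1.0
    frac_mirna_host: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_deu_exons", "frac_mirna_host"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("exons_per_gene", "nb_mean_range", "size_factor_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered low <= high, got ({lo}, {hi})")
        if self.nb_mean_range[0] <= 0:
            raise ConfigError("nb_mean_range must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.n_replicates_per_condition < 2:
            raise ConfigError("need at least 2 replicates per condition")
        if self.exons_per_gene[0] < 1:
            raise ConfigError("genes need at least one exon")
        if self.frac_deu_exons > 0 and self.deu_log2_effect == 0:
            raise ConfigError("frac_deu_exons > 0 requires a nonzero deu_log2_effect")


@dataclass
class AnnotationCatalog:
    """Gene-set catalog: term -> gene set over a background universe,
    plus a term -> meta-group mapping (1..5 groups per term)."""

    terms: dict[str, set[str]]
    universe: set[str]
    meta_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise DataError(f"term {term} contains genes outside the universe")
        for term in self.terms:
            if not self.meta_map.get(term):
                raise DataError(f"term {term} has no meta-group")


@dataclass
class MirnaFixture:
    """The 23 miRNA-hosting exon records printed in the source study:
    normalized counts for the four pooled samples, BH-adjusted p, and
    exon/gene-level log2 fold changes (control over alcohol)."""

    table: pd.DataFrame

    VARIABLES = ["alc1", "alc2", "cont1", "cont2", "exon_log2fc", "gene_log2fc"]

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def unique_mirnas(self) -> int:
        return self.table["mirbase_id"].nunique()

    def matrix(self, drop_outlier: bool = True) -> pd.DataFrame:
        """Observations x 6 numeric variables, indexed by exon id.

        With ``drop_outlier`` the high-abundance exon that skewed the
        first clustering iteration is removed, leaving the 22
        observations used for PCA/k-means.
        """
        t = self.table
        if drop_outlier:
            t = t[t["ensembl_exon_id"] != FIXTURE_OUTLIER_EXON]
        return t.set_index("ensembl_exon_id")[self.VARIABLES].astype(float)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # mean/dispersion parameterization: Var = mu + dispersion * mu^2
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_exon_counts(config: SimulationConfig) -> tuple[ExonCountTable, pd.DataFrame]:
    """Simulate an exon-level count experiment plus its ground truth.

    Returns the count table (gene/exon metadata + per-sample counts) and
    a truth table with one row per exon: ``is_deu``,
    ``true_log2_effect`` (alcohol over control; the analysis reports the
    control-over-alcohol convention, i.e. the negated value),
    ``is_mirna_host`` and ``mirna_id``.

    Planted exons shift the alcohol-condition mean by
    ``deu_log2_effect`` with a random sign, so a gene can carry exons
    moving in opposite directions and show no net gene-level change.
    """
    rng = _rng(config.seed)
    nrep = config.n_replicates_per_condition
    samples = [f"alc_{i+1}" for i in range(nrep)] + [f"cont_{i+1}" for i in range(nrep)]
    conditions = {s: ("alcohol" if s.startswith("alc") else "control") for s in samples}
    is_alc = np.array([conditions[s] == "alcohol" for s in samples])

    sf = rng.uniform(*config.size_factor_range, size=len(samples))
    sf = sf / np.exp(np.log(sf).mean())  # geometric mean 1

    rows = []
    truth = []
    mirna_counter = 0
    pos = 1
    for g in range(config.n_genes):
        gene_id = f"SIMG{g:05d}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{1 + g % 10}"
        base_mu = np.exp(rng.uniform(np.log(config.nb_mean_range[0]), np.log(config.nb_mean_range[1]), size=n_ex))
        for e in range(n_ex):
            exon_id = f"E{e+1:03d}"
            start, end = pos, pos + int(rng.integers(80, 500))
            pos = end + int(rng.integers(100, 2000))
            deu = rng.random() < config.frac_deu_exons
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effect = sign * config.deu_log2_effect if deu else 0.0
            mu = np.where(is_alc, base_mu[e] * 2.0 ** effect, base_mu[e]) * sf
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            host = rng.random() < config.frac_mirna_host
            mirna_id = None
            if host:
                mirna_counter += 1
                mirna_id = f"sim-mir-{mirna_counter:04d}"
            rows.append([gene_id, exon_id, chrom, start, end, strand, *counts])
            truth.append([gene_id, exon_id, deu, effect, host, mirna_id])

    table = pd.DataFrame(rows, columns=["gene_id", "exon_id", "chrom", "start", "end", "strand", *samples])
    truth_df = pd.DataFrame(
        truth, columns=["gene_id", "exon_id", "is_deu", "true_log2_effect", "is_mirna_host", "mirna_id"]
    )
    return ExonCountTable(table=table, conditions=conditions), truth_df


def generate_random_matrix(
    n_obs: int, column_ranges: dict[str, tuple[float, float]], seed: int = 0
) -> pd.DataFrame:
    """Uniform random feature matrix with the given per-column ranges.

    This is the spatial-randomness reference used by the Hopkins / VAT
    analyses: same number of observations and similar numeric ranges as
    the real matrix, entries i.i.d. uniform.
    """
    if n_obs < 2:
        raise ConfigError("need at least 2 observations")
    rng = _rng(seed)
    cols = {}
    for name, (lo, hi) in column_ranges.items():
        if not lo < hi:
            raise ConfigError(f"degenerate range for column {name!r}: [{lo}, {hi}]")
        cols[name] = rng.uniform(lo, hi, size=n_obs)
    return pd.DataFrame(cols, index=[f"obs_{i+1}" for i in range(n_obs)])


def generate_annotation_catalog(
    n_genes: int,
    n_terms: int,
    genes_per_term: tuple[int, int] = (5, 40),
    n_meta_groups: int = 20,
    seed: int = 0,
) -> AnnotationCatalog:
    """Random KEGG-like catalog over a synthetic gene universe.

    Each term samples its gene set from the universe and is assigned 1-5
    meta-groups (terms may appear in several groups, emulating pathway
    membership in multiple functional super-clusters).
    """
    if n_genes < 1:
        raise ConfigError("empty gene universe")
    if n_meta_groups > n_terms:
        raise ConfigError("n_meta_groups cannot exceed n_terms")
    rng = _rng(seed)
    universe = {f"SIMG{i:05d}" for i in range(n_genes)}
    ulist = sorted(universe)
    groups = [f"meta_{i+1:02d}" for i in range(n_meta_groups)]
    terms: dict[str, set[str]] = {}
    meta_map: dict[str, list[str]] = {}
    for t in range(n_terms):
        term = f"term_{t+1:03d}"
        k = int(rng.integers(genes_per_term[0], min(genes_per_term[1], n_genes) + 1))
        terms[term] = set(rng.choice(ulist, size=k, replace=False))
        n_g = int(rng.integers(1, 6))
        # round-robin base group guarantees every meta-group is populated
        chosen = {groups[t % n_meta_groups]}
        while len(chosen) < min(n_g, n_meta_groups):
            chosen.add(groups[int(rng.integers(n_meta_groups))])
        meta_map[term] = sorted(chosen)
    return AnnotationCatalog(terms=terms, universe=universe, meta_map=meta_map)


def load_mirna_fixture() -> MirnaFixture:
    """Load the bundled 23-row miRNA host-exon table.

    Raises ``DataError`` if the packaged file does not match its
    recorded checksum.
    """
    ref = resources.files("exonml.data") / "mirna_exon_table.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise DataError("miRNA fixture failed its integrity check")
    table = pd.read_csv(ref.open("r"), sep="\t")
    for col in ("alc1", "alc2", "cont1", "cont2"):
        table[col] = table[col].astype(float)
    return MirnaFixture(table=table)
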