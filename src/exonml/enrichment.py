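"""Gene-set enrichment with a size-matched permutation null.

A service-free reimplementation of the DAVID-style analysis: per-term
Fisher's exact (hypergeometric upper tail) enrichment of a gene list
against a background universe, plus a null ensemble built by drawing
many random gene lists of the same size from the universe and recording
each term's p-value distribution.  Terms whose null p-values are not
uniform — typically tiny gene sets whose discrete null piles up at low
p — are flagged as enrichment-prone so that their apparent enrichment
in the real list can be discounted as a likely false discovery.

The EASE variant (DAVID's conservative modification: the overlap is
decremented by one before the test) is available via ``ease=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, kstest

from .deu import adjust_bh
from .simulate import AnnotationCatalog

logger = logging.getLogger(__name__)

KS_UNIFORMITY_THRESHOLD = 0.1

__all__ = [
    "EnrichmentResult",
    "NullEnsemble",
    "fisher_enrichment",
    "random_null",
    "flag_terms",
    "mirna_pathway_profile",
]


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    list_size: int
    term_size: int
    universe_size: int
    fold_enrichment: float
    p: float
    p_bh: float


@dataclass
class NullEnsemble:
    """Per-term p-value vectors over random size-matched gene lists."""

    p_values: pd.DataFrame          # rows: replicates, columns: term ids
    list_size: int
    mid_p_values: pd.DataFrame | None = None

    @property
    def n_lists(self) -> int:
        return len(self.p_values)

    def uniformity(self) -> pd.DataFrame:
        """KS distance of each term's null p-vector from Uniform(0,1) and
        the resulting flag ('clean' or 'enrichment-prone').

        The distance is computed on mid-p values (P(X > k) + P(X = k)/2)
        when available: ordinary upper-tail p-values of a discrete test
        sit on conservative atoms and would register a spurious KS
        distance for every finite term, whereas mid-p is close to
        uniform unless the term's null really is degenerate (e.g. a
        handful of genes with only a few attainable overlaps)."""
        source = self.mid_p_values if self.mid_p_values is not None else self.p_values
        rows = []
        for term in self.p_values.columns:
            ks = kstest(source[term].to_numpy(), "uniform").statistic
            rows.append((term, float(ks), "clean" if ks < KS_UNIFORMITY_THRESHOLD else "enrichment-prone"))
        return pd.DataFrame(rows, columns=["term_id", "ks_distance", "flag"]).set_index("term_id")


def fisher_enrichment(
    gene_list: set[str], catalog: AnnotationCatalog, ease: bool = False
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of a gene list per catalog term.

    Genes outside the universe are dropped with a warning.  With
    ``ease`` the overlap is reduced by one before computing the tail
    (never below zero), giving DAVID's conservative EASE score.
    """
    if not catalog.terms:
        raise ValueError("catalog has no terms")
    in_universe = set(gene_list) & catalog.universe
    dropped = len(set(gene_list)) - len(in_universe)
    if dropped:
        logger.warning("dropped %d genes outside the universe", dropped)
    if not in_universe:
        raise ValueError("gene list is empty after restricting to the universe")
    N = len(catalog.universe)
    n = len(in_universe)
    results = []
    for term, genes in catalog.terms.items():
        K = len(genes)
        k = len(in_universe & genes)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        fe = (k / n) / (K / N) if K > 0 else 0.0
        results.append(
            EnrichmentResult(
                term_id=term, overlap=k, list_size=n, term_size=K,
                universe_size=N, fold_enrichment=float(fe), p=p, p_bh=np.nan,
            )
        )
    for r, pb in zip(results, adjust_bh([r.p for r in results])):
        r.p_bh = float(pb)
    return results


def random_null(
    catalog: AnnotationCatalog,
    list_size: int,
    reps: int = 1000,
    seed: int = 0,
    ease: bool = False,
) -> NullEnsemble:
    """Null ensemble from ``reps`` uniform random gene lists of the given
    size drawn without replacement from the universe."""
    universe = sorted(catalog.universe)
    if list_size > len(universe):
        raise ValueError("list_size exceeds the universe")
    if reps < 50:
        logger.warning("reps < 50 gives an unstable uniformity assessment")
    rng = np.random.default_rng(seed)
    terms = list(catalog.terms)
    N = len(universe)
    # vectorized: overlap counts via membership matrix product
    member = np.zeros((len(terms), N), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(universe)}
    for t_i, t in enumerate(terms):
        for g in catalog.terms[t]:
            member[t_i, gene_pos[g]] = True
    K = member.sum(axis=1)
    member_int = member.astype(np.int64)
    overlaps = np.empty((reps, len(terms)), dtype=int)
    for r in range(reps):
        pick = rng.choice(N, size=list_size, replace=False)
        sel = np.zeros(N, dtype=np.int64)
        sel[pick] = 1
        overlaps[r] = member_int @ sel
    k_eff = np.maximum(overlaps - 1, 0) if ease else overlaps
    p = np.where(
        k_eff > 0,
        hypergeom.sf(k_eff - 1, N, K[None, :], list_size),
        1.0,
    )
    mid_p = hypergeom.sf(k_eff, N, K[None, :], list_size) + 0.5 * hypergeom.pmf(
        k_eff, N, K[None, :], list_size
    )
    return NullEnsemble(
        p_values=pd.DataFrame(p, columns=terms),
        list_size=list_size,
        mid_p_values=pd.DataFrame(mid_p, columns=terms),
    )


def flag_terms(
    observed: list[EnrichmentResult],
    null: NullEnsemble,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term verdicts combining observed enrichment with the null.

    validated-enriched: observed p < alpha and the term's null p-vector
    is uniform (KS distance below threshold).  false-discovery-prone:
    observed p < alpha but the null is non-uniform AND concentrated low
    (null fraction below alpha exceeds 2 alpha).  Everything else is
    not-enriched.
    """
    uni = null.uniformity()
    rows = []
    for r in observed:
        if r.term_id not in null.p_values.columns:
            raise ValueError(f"term {r.term_id} missing from the null ensemble")
        ks = float(uni.loc[r.term_id, "ks_distance"])
        frac_low = float((null.p_values[r.term_id] < alpha).mean())
        if r.p < alpha:
            if ks < KS_UNIFORMITY_THRESHOLD:
                verdict = "validated-enriched"
            elif frac_low > 2 * alpha:
                verdict = "false-discovery-prone"
            else:
                verdict = "not-enriched"
        else:
            verdict = "not-enriched"
        rows.append((r.term_id, r.p, ks, frac_low, verdict))
    return pd.DataFrame(
        rows, columns=["term_id", "p", "ks_distance", "null_frac_low", "verdict"]
    ).set_index("term_id")


def mirna_pathway_profile(
    target_map: dict[str, set[str]],
    catalog: AnnotationCatalog,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-miRNA validated enrichment profiles.

    For each miRNA's predicted target list: Fisher enrichment, a
    size-matched random null, and verdict flagging.  miRNAs with no
    in-universe targets are skipped with a warning.  Null ensembles are
    cached by list size, since the null depends only on the size.
    """
    profiles: dict[str, pd.DataFrame] = {}
    null_cache: dict[int, NullEnsemble] = {}
    for i, (mirna, targets) in enumerate(sorted(target_map.items())):
        in_uni = targets & catalog.universe
        if not in_uni:
            logger.warning("miRNA %s has no targets in the universe; skipped", mirna)
            continue
        observed = fisher_enrichment(in_uni, catalog)
        size = len(in_uni)
        if size not in null_cache:
            null_cache[size] = random_null(catalog, size, reps=reps, seed=seed + size)
        verdicts = flag_terms(observed, null_cache[size], alpha=alpha)
        obs_df = pd.DataFrame(
            [
                (r.term_id, r.overlap, r.term_size, r.fold_enrichment, r.p, r.p_bh)
                for r in observed
            ],
            columns=["term_id", "overlap", "term_size", "fold_enrichment", "p", "p_bh"],
        ).set_index("term_id")
        profiles[mirna] = obs_df.join(verdicts[["ks_distance", "null_frac_low", "verdict"]])
    return profiles
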