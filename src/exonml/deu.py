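"""Differential exon usage testing.

A deliberately compact analogue of the negative-binomial GLM approach
used by exon-level tools: counts for each exon are compared against the
summed counts of the remaining exons of the same gene, and a full model
with a condition-by-exon interaction is tested against a reduced model
without it by a likelihood-ratio test on one degree of freedom.

Normalization follows the median-of-ratios scheme.  The dispersion is
estimated by method of moments on normalized counts per exon and pooled
(averaged) across all testable exons of the dataset before testing;
pooling is what keeps the chi-square reference calibrated at the
pooled-duplicate sample sizes this pipeline targets.

Sign convention: the reported ``log2fc`` is control over alcohol, so an
exon with higher normalized counts under alcohol has a NEGATIVE fold
change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import DataError, ExonCountTable

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5

__all__ = [
    "DEUResult",
    "estimate_size_factors",
    "test_differential_usage",
    "adjust_bh",
    "filter_significant",
    "results_to_frame",
]


@dataclass
class DEUResult:
    """Per-exon differential usage statistics."""

    exon_id: str
    gene_id: str
    base_mean: float
    normalized_counts: dict[str, float]
    usage_coefficient: dict[str, float]
    log2fc: float
    p_raw: float
    p_bh: float
    dispersion: float
    converged: bool = True


def estimate_size_factors(counts: ExonCountTable) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only exon rows with strictly positive counts in every sample enter
    the per-sample median of count / geometric-row-mean.
    """
    mat = counts.counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise DataError(
            "no exon has positive counts in all samples; supply a "
            "pseudo-reference or filter samples before normalizing"
        )
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.log(sf).mean())
    return pd.Series(sf, index=counts.samples, name="size_factor")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exon_mom_dispersion(norm_this: np.ndarray, norm_other: np.ndarray, is_alc: np.ndarray) -> float:
    """Clipped within-condition method-of-moments dispersion for one
    this-vs-rest pair (both response rows contribute estimates)."""
    ests = []
    for row in (norm_this, norm_other):
        for cond in (True, False):
            grp = row[is_alc == cond]
            if len(grp) < 2:
                continue
            m = grp.mean()
            if m > 0:
                ests.append(max((grp.var(ddof=1) - m) / m**2, 0.0))
    return float(np.mean(ests)) if ests else 0.0


def _fit_lrt(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray, offset: np.ndarray, alpha: float):
    """Full-vs-reduced NB GLM likelihood-ratio test; returns (p, beta_exon,
    beta_interaction, converged)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=200)
            mr = sm.GLM(y, X_red, family=fam, offset=offset).fit(maxiter=200)
        if not (np.isfinite(mf.llf) and np.isfinite(mr.llf)):
            return 1.0, 0.0, 0.0, False
        lr = max(2.0 * (mf.llf - mr.llf), 0.0)
        return float(chi2.sf(lr, 1)), float(mf.params[-2]), float(mf.params[-1]), True
    except Exception:
        return 1.0, 0.0, 0.0, False


def test_differential_usage(
    counts: ExonCountTable,
    conditions: dict[str, str] | None = None,
    size_factors: pd.Series | None = None,
) -> list[DEUResult]:
    """Test every exon of every multi-exon gene for differential usage.

    For exon *e* of gene *g* the response stacks, per sample, the counts
    of *e* and the summed counts of the other exons of *g*.  The full
    model ``~ condition + exon + condition:exon`` (with log size-factor
    offsets) is compared against the reduced model without the
    interaction; p-values come from the chi-square(1) likelihood-ratio
    statistic.  Single-exon genes are skipped with a warning; fits that
    do not converge are reported with p = 1 and flagged.
    """
    conditions = conditions or counts.conditions
    labels = sorted(set(conditions.values()))
    if len(labels) != 2:
        raise DataError(f"exactly 2 condition labels required, got {labels}")
    samples = counts.samples
    if any(s not in conditions for s in samples):
        raise DataError("every sample column needs a condition label")
    # 'alcohol'/'control' if present; otherwise first label alphabetically is treatment
    if "alcohol" in labels and "control" in labels:
        treat = "alcohol"
    else:
        treat = labels[0]
    is_alc = np.array([conditions[s] == treat for s in samples])
    if is_alc.sum() < 2 or (~is_alc).sum() < 2:
        raise DataError("need at least 2 samples per condition")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(samples).to_numpy(float)

    mat = counts.counts.to_numpy(float)
    norm = mat / sf
    meta = counts.table[["gene_id", "exon_id"]]

    gene_index: dict[str, list[int]] = {}
    for i, g in enumerate(meta["gene_id"]):
        gene_index.setdefault(g, []).append(i)

    ns = len(samples)
    cond_vec = np.concatenate([is_alc.astype(float)] * 2)
    exon_vec = np.concatenate([np.ones(ns), np.zeros(ns)])
    X_red = np.column_stack([np.ones(2 * ns), cond_vec, exon_vec])
    X_full = np.column_stack([np.ones(2 * ns), cond_vec, exon_vec, exon_vec * cond_vec])
    offset = np.log(np.concatenate([sf, sf]))

    testable: list[tuple[int, np.ndarray, np.ndarray]] = []
    n_skipped = 0
    for gene, idx in gene_index.items():
        if len(idx) < 2:
            n_skipped += 1
            continue
        block = mat[idx]
        total = block.sum(axis=0)
        for row_i in idx:
            testable.append((row_i, mat[row_i], total - mat[row_i]))
    if n_skipped:
        logger.warning("skipped %d single-exon genes", n_skipped)
    if not testable:
        raise DataError("no multi-exon genes to test")

    # pooled dispersion: mean of per-exon clipped MoM estimates
    per_exon_disp = np.array(
        [_exon_mom_dispersion(norm[i], y_other / sf, is_alc) for i, _, y_other in testable]
    )
    alpha = max(float(per_exon_disp.mean()), DISPERSION_FLOOR)

    results: list[DEUResult] = []
    p_raw_all = []
    for (row_i, y_this, y_other), disp_i in zip(testable, per_exon_disp):
        y = np.concatenate([y_this, y_other])
        if np.all(y_this == y_this[0]) and np.ptp(sf) == 0 and np.all(y_other == y_other[0]):
            p, b_exon, b_int, ok = 1.0, 0.0, 0.0, True
        else:
            p, b_exon, b_int, ok = _fit_lrt(y, X_full, X_red, offset, alpha)
        n_this = norm[row_i]
        mean_c = n_this[~is_alc].mean()
        mean_a = n_this[is_alc].mean()
        log2fc = float(np.log2((mean_c + LOG2FC_PSEUDOCOUNT) / (mean_a + LOG2FC_PSEUDOCOUNT)))
        results.append(
            DEUResult(
                exon_id=str(meta["exon_id"].iloc[row_i]),
                gene_id=str(meta["gene_id"].iloc[row_i]),
                base_mean=float(n_this.mean()),
                normalized_counts={s: float(v) for s, v in zip(samples, n_this)},
                usage_coefficient={"control": b_exon, treat: b_exon + b_int},
                log2fc=log2fc,
                p_raw=p,
                p_bh=np.nan,
                dispersion=float(max(disp_i, DISPERSION_FLOOR)),
                converged=ok,
            )
        )
        p_raw_all.append(p)

    for r, pb in zip(results, adjust_bh(p_raw_all)):
        r.p_bh = float(pb)
    return results


def filter_significant(results: list[DEUResult], fdr: float = 0.1) -> list[DEUResult]:
    """Exons with BH-adjusted p strictly below ``fdr``, input order kept."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError("fdr must be in [0, 1]")
    return [r for r in results if r.p_bh < fdr]


def results_to_frame(results: list[DEUResult]) -> pd.DataFrame:
    """Flatten DEU results into a TSV-ready table."""
    if not results:
        return pd.DataFrame()
    samples = list(results[0].normalized_counts)
    conds = list(results[0].usage_coefficient)
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "exon_id": r.exon_id,
                "base_mean": r.base_mean,
                **{f"norm_{s}": r.normalized_counts[s] for s in samples},
                **{f"usage_{c}": r.usage_coefficient[c] for c in conds},
                "log2fc": r.log2fc,
                "p_raw": r.p_raw,
                "p_bh": r.p_bh,
                "dispersion": r.dispersion,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
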