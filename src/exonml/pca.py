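"""Principal component analysis with observation diagnostics.

Follows the FactoMineR conventions for standardized PCA: columns are
centred and reduced with the population standard deviation, eigenvalues
are the variances of the factor scores (so they sum to the number of
variables), an observation's contribution to a component is its squared
factor score divided by n times the eigenvalue (as a percentage), and
its cos^2 is the share of its squared distance to the centroid captured
by the component.  Qualitative categories are projected as barycenters
of their members and play no part in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["PCAResult", "run_pca", "top_contributors"]


@dataclass
class PCAResult:
    eigenvalues: pd.Series            # component -> variance
    scores: pd.DataFrame              # observation x component
    loadings: pd.DataFrame            # variable x component (correlations)
    cos2: pd.DataFrame                # observation x component
    contributions: pd.DataFrame       # observation x component, percent
    supplementary_centroids: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def run_pca(fm: FeatureMatrix) -> PCAResult:
    """Eigendecomposition of the correlation structure of a scaled matrix."""
    if not fm.scaled:
        raise ValueError(
            "PCA expects a standardized matrix; build it with "
            "build_feature_matrix(..., scale=True) or scale_matrix()"
        )
    if fm.n_obs < 3 or fm.n_var < 2:
        raise ValueError("PCA needs at least 3 observations and 2 variables")
    Z = fm.values
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    ncomp = int((s > 1e-12 * s[0]).sum()) if s[0] > 0 else 0
    if ncomp == 0:
        raise ValueError("matrix has no variance")
    U, s, Vt = U[:, :ncomp], s[:ncomp], Vt[:ncomp]
    comps = [f"Dim.{i+1}" for i in range(ncomp)]

    eigenvalues = pd.Series(s**2 / n, index=comps, name="eigenvalue")
    scores = pd.DataFrame(U * s, index=fm.data.index, columns=comps)
    # variable coordinates = correlations between variables and components
    loadings = pd.DataFrame((Vt.T * np.sqrt(eigenvalues.to_numpy())), index=fm.data.columns, columns=comps)

    sq = scores.to_numpy() ** 2
    row_tot = sq.sum(axis=1, keepdims=True)
    row_tot[row_tot == 0] = 1.0
    cos2 = pd.DataFrame(sq / row_tot, index=scores.index, columns=comps)
    contributions = pd.DataFrame(
        100.0 * sq / (n * eigenvalues.to_numpy()[None, :]), index=scores.index, columns=comps
    )

    centroids = None
    if fm.qualitative_label is not None:
        centroids = scores.groupby(fm.qualitative_label).mean()
        centroids.index.name = "category"

    return PCAResult(
        eigenvalues=eigenvalues,
        scores=scores,
        loadings=loadings,
        cos2=cos2,
        contributions=contributions,
        supplementary_centroids=centroids,
    )


def top_contributors(
    pca: PCAResult, dims: tuple[str, ...] | tuple[int, ...] = (1, 2), n: int = 50
) -> pd.DataFrame:
    """Observations ranked by summed contribution over the given
    components, ties broken by observation id.

    Returns the per-dimension contribution columns alongside the total.
    If ``n`` exceeds the number of observations the full ranking is
    returned.
    """
    cols = [d if isinstance(d, str) else f"Dim.{d}" for d in dims]
    missing = [c for c in cols if c not in pca.contributions.columns]
    if missing:
        raise ValueError(f"components not computed: {missing}")
    contrib = pca.contributions[cols].copy()
    contrib["total_contribution"] = contrib.sum(axis=1)
    ranked = contrib.sort_values(
        ["total_contribution"], ascending=False, kind="mergesort"
    )
    # stable tie-break on observation id
    ranked = (
        ranked.reset_index()
        .sort_values(["total_contribution", "index"], ascending=[False, True], kind="mergesort")
        .set_index("index")
    )
    ranked.index.name = pca.contributions.index.name
    if n > len(ranked):
        return ranked
    return ranked.head(n)
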