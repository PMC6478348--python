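"""Self-organizing map with hierarchical partitioning of the codebook.

An online Kohonen network: a rectangular grid of codebook vectors is
trained by presenting one randomly chosen observation per step, moving
the best-matching unit (BMU) and its neighbours toward it under a
Gaussian neighbourhood whose radius decays linearly over training.  An
"epoch" is one such presentation step.  After training, the codebook
vectors are clustered with Ward linkage so that the map can be read as
a partition of the observations.

The map refuses datasets that cannot populate its nodes (fewer than
three observations per node on average, or fewer than three variables):
a sparsely populated map cannot reduce the observation-to-node mean
distance and learns nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

__all__ = ["SomResult", "InsufficientObservationsError", "som_fit"]


class InsufficientObservationsError(ValueError):
    """Raised when the dataset is too small for the requested map."""


@dataclass
class SomResult:
    codebook: pd.DataFrame          # node x variable
    grid: tuple[int, int]
    training_curve: pd.Series       # step -> mean distance of observations to BMU
    node_assignments: pd.Series     # observation -> node index
    partition: pd.Series | None     # observation -> cluster (Ward cut of codebook)


def _auto_grid(n: int) -> tuple[int, int]:
    nodes = max(4, int(round(5 * np.sqrt(n))))
    rows = max(2, int(round(np.sqrt(nodes))))
    cols = max(2, int(np.ceil(nodes / rows)))
    return rows, cols


def som_fit(
    X,
    grid: tuple[int, int] | None = None,
    learning_rate: float = 0.01,
    epochs: int = 15000,
    n_partitions: int | None = None,
    seed: int = 0,
) -> SomResult:
    """Train a SOM and hierarchically partition its codebook.

    ``epochs`` counts single-observation presentation steps.  The grid
    defaults to roughly 5 sqrt(n) nodes.  ``n_partitions`` requests a
    Ward cut of the trained codebook into that many clusters, mapped
    back to the observations through their BMUs.
    """
    M = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    idx = X.data.index if isinstance(X, FeatureMatrix) else pd.RangeIndex(len(M))
    n, p = M.shape
    rows, cols = grid if grid is not None else _auto_grid(n)
    n_nodes = rows * cols
    if n < n_nodes / 3 or p < 3:
        raise InsufficientObservationsError(
            f"insufficient observations for SOM: {n} observations, {p} variables "
            f"for a {rows}x{cols} map ({n_nodes} nodes); the map cannot be "
            "populated densely enough to learn the data"
        )
    rng = np.random.default_rng(seed)
    # node coordinates on the grid, for the neighbourhood kernel
    gy, gx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    node_pos = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
    # initialize codebook uniformly within the data's bounding box
    lo, hi = M.min(axis=0), M.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(n_nodes, p))

    radius0 = max(rows, cols) / 2.0
    curve_steps, curve_vals = [], []
    record_every = max(1, epochs // 10)
    for step in range(epochs):
        frac = step / max(epochs - 1, 1)
        radius = max(radius0 * (1.0 - frac), 0.5)
        lr = learning_rate * (1.0 - 0.9 * frac)
        x = M[rng.integers(n)]
        d2 = ((codebook - x) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))
        grid_d2 = ((node_pos - node_pos[bmu]) ** 2).sum(axis=1)
        h = np.exp(-grid_d2 / (2.0 * radius**2))
        codebook += lr * h[:, None] * (x - codebook)
        if step % record_every == 0 or step == epochs - 1:
            bmu_d = cdist(M, codebook).min(axis=1)
            curve_steps.append(step)
            curve_vals.append(float(bmu_d.mean()))

    assignments = cdist(M, codebook).argmin(axis=1)
    partition = None
    if n_partitions is not None:
        Zl = linkage(codebook, method="ward")
        node_part = fcluster(Zl, t=n_partitions, criterion="maxclust")
        partition = pd.Series(node_part[assignments], index=idx, name="cluster")

    return SomResult(
        codebook=pd.DataFrame(codebook, index=range(n_nodes)),
        grid=(rows, cols),
        training_curve=pd.Series(curve_vals, index=curve_steps, name="mean_bmu_distance"),
        node_assignments=pd.Series(assignments, index=idx, name="node"),
        partition=partition,
    )
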