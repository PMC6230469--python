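"""Mini-cluster approximation for large datasets.

Cells are grouped into many very small k-means clusters, separately within
each capture time, and the order sampler is run on the cluster centroids
instead of the cells.  The default number of clusters per capture time is
one eighth of the cells at that capture time (with a floor), shrinking the
permutation space from ``T!`` to ``k!`` while preserving the structure of
the posterior.  Each cell afterwards inherits the posterior pseudotime
summary of its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import InvalidInputError
from .model import ExpressionMatrix
from .postprocess import PosteriorSummary

__all__ = ["MiniClusterMap", "build_miniclusters", "expand_pseudotimes"]


@dataclass
class MiniClusterMap:
    """Centroid expression matrix plus the cell-to-centroid assignment."""

    centroids: ExpressionMatrix
    assignments: np.ndarray  # per original cell, index into centroids
    cell_ids: list
    clusters_per_capture: Dict[object, int]

    @property
    def n_clusters(self) -> int:
        return self.centroids.n_cells

    def to_frame(self) -> pd.DataFrame:
        ct = self.centroids.capture_times
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "capture_time": (
                    None if ct is None else ct[self.assignments]
                ),
                "centroid_id": [
                    self.centroids.cell_ids[a] for a in self.assignments
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_miniclusters(
    expr: ExpressionMatrix,
    fraction: float = 1.0 / 8.0,
    min_clusters: int = 5,
    seed: int = 0,
) -> MiniClusterMap:
    """k-means mini-clusters per capture-time block.

    The cluster count per block is ``max(min_clusters, round(n_t * fraction))``
    capped at the block size; when it equals the block size every cell is its
    own centroid (in block order), so the approximation degenerates to the
    exact method.  Without capture times all cells form a single block.
    k-means uses squared-Euclidean distance with 10 restarts and a fixed
    seed for reproducibility.
    """
    if not (0 < fraction <= 1):
        raise InvalidInputError("fraction must lie in (0, 1]")
    T = expr.n_cells
    if expr.capture_times is None:
        blocks = [(None, np.arange(T))]
    else:
        blocks = []
        for ct in np.unique(expr.capture_times):
            idx = np.flatnonzero(expr.capture_times == ct)
            if len(idx) == 0:
                raise InvalidInputError(f"empty capture-time block {ct!r}")
            blocks.append((ct, idx))
    centroid_cols = []
    centroid_ids = []
    centroid_ct = []
    assignments = np.full(T, -1, dtype=np.intp)
    clusters_per_capture: Dict[object, int] = {}
    offset = 0
    for ct, idx in blocks:
        n_t = len(idx)
        k = min(max(min_clusters, int(round(n_t * fraction))), n_t)
        clusters_per_capture[ct] = k
        x = expr.values[:, idx].T  # cells as samples
        if k == n_t:
            labels = np.arange(n_t)
            centers = x
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(x)
            centers = km.cluster_centers_
        assignments[idx] = offset + labels
        centroid_cols.append(centers.T)
        tag = "all" if ct is None else ct
        centroid_ids.extend(f"mc_{tag}_{j}" for j in range(k))
        centroid_ct.extend([ct] * k)
        offset += k
    centroids = ExpressionMatrix(
        np.concatenate(centroid_cols, axis=1),
        gene_ids=list(expr.gene_ids),
        cell_ids=centroid_ids,
        capture_times=None if expr.capture_times is None else np.asarray(centroid_ct),
    )
    return MiniClusterMap(
        centroids=centroids,
        assignments=assignments,
        cell_ids=list(expr.cell_ids),
        clusters_per_capture=clusters_per_capture,
    )


def expand_pseudotimes(
    mc_map: MiniClusterMap, centroid_summary: PosteriorSummary
) -> PosteriorSummary:
    """Assign each cell the posterior pseudotime summary of its centroid.

    The returned position-frequency matrix has one row per cell but keeps
    the centroid rank axis (cells in the same mini-cluster share a row).
    """
    a = mc_map.assignments
    if np.any(a < 0) or np.any(a >= mc_map.n_clusters):
        raise InvalidInputError("mini-cluster map contains unmapped cells")
    if len(centroid_summary.mean_pseudotime) != mc_map.n_clusters:
        raise InvalidInputError(
            "centroid summary size does not match the mini-cluster map"
        )
    mean_pt = centroid_summary.mean_pseudotime[a]
    return PosteriorSummary(
        cell_ids=list(mc_map.cell_ids),
        mean_pseudotime=mean_pt,
        sd_pseudotime=centroid_summary.sd_pseudotime[a],
        position_freq=centroid_summary.position_freq[a],
        modal_order=np.argsort(mean_pt, kind="stable"),
    )
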