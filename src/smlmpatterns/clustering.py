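"""Density-based nanocluster identification and size distributions.

DBSCAN with the field-standard parameters for receptor nanocluster sizing
(epsilon = 45 nm, minpts = 2) separates molecules into monomers, dimers
and clusters of three or more. With minpts = 2 — counting the point itself
in its neighborhood, so a single true neighbor suffices — clusters are
exactly the connected components of the epsilon-neighborhood graph with
at least two members, and isolated points are monomers.

Clustering is 2D (x, y): the axial coordinate is excluded even when
present, matching interface-plane analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.cluster import DBSCAN

__all__ = ["ClusterResult", "dbscan_clusters", "size_distribution"]

#: Recommended neighborhood radius (nm) for membrane-receptor nanoclusters.
DEFAULT_EPSILON = 45.0
#: Minimum neighborhood size for a core point, counting the point itself.
DEFAULT_MINPTS = 2

NOISE = -1  # label for monomers / noise points


@dataclass
class ClusterResult:
    """Cluster labels and derived size statistics.

    ``labels`` assigns each point a cluster id >= 0, or ``NOISE`` (-1) for
    monomers. ``sizes`` lists cluster cardinalities (each >= 2 at the
    default minpts).
    """

    labels: np.ndarray
    epsilon: float
    minpts: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_points(self) -> int:
        return len(self.labels)

    @property
    def n_monomers(self) -> int:
        return int(np.sum(self.labels == NOISE))

    @property
    def sizes(self) -> np.ndarray:
        """Cardinalities of the identified clusters (excluding monomers)."""
        if self.n_points == 0:
            return np.empty(0, dtype=int)
        in_cluster = self.labels[self.labels != NOISE]
        if not len(in_cluster):
            return np.empty(0, dtype=int)
        return np.bincount(in_cluster)[np.unique(in_cluster)]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def dbscan_clusters(
    points: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    minpts: int = DEFAULT_MINPTS,
    minpts_convention: Literal["inclusive", "exclusive"] = "inclusive",
) -> ClusterResult:
    """DBSCAN clustering of a single-channel 2D point pattern.

    ``minpts`` is the neighborhood size required of a core point. The
    default "inclusive" convention counts the point itself (minpts = 2
    means one true neighbor within epsilon makes a dimer); "exclusive"
    requires ``minpts`` true neighbors.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if minpts < 1:
        raise ValueError("minpts must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterResult(np.empty(0, dtype=int), epsilon, minpts)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("points must be an (n, 2) array")
    pts = pts[:, :2]
    min_samples = minpts if minpts_convention == "inclusive" else minpts + 1
    labels = DBSCAN(eps=epsilon, min_samples=min_samples).fit(pts).labels_
    return ClusterResult(labels, epsilon, minpts)


def size_distribution(result: ClusterResult) -> dict:
    """Monomer/dimer/3+ class fractions and the cumulative size curve.

    Two fraction bases are reported: ``molecule_fractions`` (fraction of
    molecules residing in each class, monomer-inclusive) and
    ``cluster_fractions`` (fraction of clusters of each size class,
    over clusters only). The cumulative distribution is over cluster
    sizes: fraction of clusters of size <= s.
    """
    sizes = result.sizes
    n = result.n_points
    n_mono = result.n_monomers
    n_clusters = len(sizes)

    n_in_dimers = int(sizes[sizes == 2].sum()) if n_clusters else 0
    n_in_multi = int(sizes[sizes >= 3].sum()) if n_clusters else 0
    molecule_fractions = {
        "monomer": n_mono / n if n else float("nan"),
        "dimer": n_in_dimers / n if n else float("nan"),
        "cluster_3plus": n_in_multi / n if n else float("nan"),
    }
    cluster_fractions = {
        "dimer": float(np.mean(sizes == 2)) if n_clusters else float("nan"),
        "cluster_3plus": float(np.mean(sizes >= 3)) if n_clusters else float("nan"),
    }

    if n_clusters:
        support = np.arange(2, sizes.max() + 1)
        cumulative = np.array([(sizes <= s).mean() for s in support])
    else:
        support = np.empty(0, dtype=int)
        cumulative = np.empty(0)

    return {
        "n_points": n,
        "n_monomers": n_mono,
        "n_clusters": n_clusters,
        "molecule_fractions": molecule_fractions,
        "cluster_fractions": cluster_fractions,
        "cumulative_sizes": support,
        "cumulative_distribution": cumulative,
        "degenerate": n_clusters == 0,
    }
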