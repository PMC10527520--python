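"""Independent brute-force oracles for the estimator tests.

Everything here is deliberately naive — O(n^2) distance matrices and
pure-Python breadth-first searches — and shares no code path with the
package's tree-based implementations.
"""

from __future__ import annotations

import math

import numpy as np


def toroidal_distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All pairwise distances under the minimum-image (toroidal) metric."""
    d = np.abs(a[:, None, :] - b[None, :, :])
    d = np.minimum(d, box[None, None, :] - d)
    return np.sqrt((d**2).sum(axis=2))


def pair_counts_toroidal(
    pts1: np.ndarray,
    pts2: np.ndarray | None,
    box: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Ordered pair counts per (e_k, e_{k+1}] annulus, brute force.

    With ``pts2 is None`` counts ordered self pairs (i != j).
    """
    if pts2 is None:
        d = toroidal_distance_matrix(pts1, pts1, box)
        np.fill_diagonal(d, np.inf)
    else:
        d = toroidal_distance_matrix(pts1, pts2, box)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for k in range(len(edges) - 1):
        counts[k] = int(np.sum((d > edges[k]) & (d <= edges[k + 1])))
    return counts


def pcf_brute(pts: np.ndarray, box: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Univariate toroidal PCF by exhaustive pair counting."""
    n = len(pts)
    counts = pair_counts_toroidal(pts, None, box, edges)
    area = box[0] * box[1]
    ann = math.pi * np.diff(np.asarray(edges, dtype=float) ** 2)
    return counts / (n * (n - 1) * ann / area)


def cross_pcf_brute(
    pts1: np.ndarray, pts2: np.ndarray, box: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    counts = pair_counts_toroidal(pts1, pts2, box, edges)
    area = box[0] * box[1]
    ann = math.pi * np.diff(np.asarray(edges, dtype=float) ** 2)
    return counts / (len(pts1) * len(pts2) * ann / area)


def _components(n: int, linked) -> np.ndarray:
    """Connected-component labels from a pairwise predicate, by BFS."""
    labels = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        queue = [start]
        labels[start] = current
        while queue:
            i = queue.pop()
            for j in range(n):
                if labels[j] == -1 and linked(i, j):
                    labels[j] = current
                    queue.append(j)
        current += 1
    return labels


def epsilon_graph_components(points: np.ndarray, eps: float) -> np.ndarray:
    """Labels of the epsilon-neighborhood graph's connected components."""
    pts = np.asarray(points, dtype=float)

    def linked(i: int, j: int) -> bool:
        return float(np.hypot(*(pts[i] - pts[j]))) <= eps

    return _components(len(pts), linked)


def spatiotemporal_components(
    xy: np.ndarray, frames: np.ndarray, dist: float, gap_frames: int
) -> np.ndarray:
    """Labels of the blinking-linkage graph (distance AND frame gap)."""
    xy = np.asarray(xy, dtype=float)
    frames = np.asarray(frames)

    def linked(i: int, j: int) -> bool:
        return (
            abs(int(frames[i]) - int(frames[j])) <= gap_frames
            and float(np.hypot(*(xy[i] - xy[j]))) <= dist
        )

    return _components(len(xy), linked)


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition up to label permutation (noise/-1 matched exactly)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if (x == -1) != (y == -1):
            return False
        if x == -1:
            continue
        if mapping.setdefault(int(x), int(y)) != y:
            return False
        if back.setdefault(int(y), int(x)) != x:
            return False
    return True


def pearson_hand(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw-sums formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x**2).sum() - sx**2) * math.sqrt(n * (y**2).sum() - sy**2)
    return num / den
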