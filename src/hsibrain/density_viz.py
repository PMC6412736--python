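"""Surgical-aid visualization: hierarchical k-means segmentation,
majority-voting merge, per-cluster probability cube, and RGB density maps.

The density map softens the hard class boundaries of the classification
map for the surgeon: an unsupervised segmentation (bisecting 2-means,
24 clusters by default) delineates spectrally homogeneous regions; each
cluster takes the modal class of the supervised map (majority voting) and
its class *frequencies* become per-pixel probabilities; the tumor, normal
and hypervascularized probabilities are rendered proportionally as the
red, green and blue channels.  The background class is never rendered
(always black), and everything outside the parenchymal mask is blacked
out by negative mask filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from hsibrain.hsio import (
    CLASS_BACKGROUND,
    CLASS_HYPERVASCULAR,
    CLASS_NORMAL,
    CLASS_TUMOR,
)
from hsibrain.preprocess import ProcessedCube

__all__ = [
    "SegmentationMap",
    "ThreeClassProbabilityCube",
    "hierarchical_kmeans",
    "majority_vote",
    "cluster_probability_cube",
    "render_density_map",
    "apply_thresholds",
    "CLASS_PRIORITY",
]

#: overlay/tie-break priority, highest first (mirrors the threshold sliders)
CLASS_PRIORITY = (CLASS_TUMOR, CLASS_NORMAL, CLASS_HYPERVASCULAR, CLASS_BACKGROUND)


@dataclass
class SegmentationMap:
    """Unsupervised cluster assignment, ids 1..K, every pixel assigned."""

    cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids)
        if self.cluster_ids.min() < 1:
            raise ValueError("cluster ids start at 1")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids.max())


@dataclass
class ThreeClassProbabilityCube:
    """(rows, cols, 3) probabilities for (tumor, normal, hypervascularized),
    constant within each cluster."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probability cube must be (rows, cols, 3)")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def hierarchical_kmeans(
    cube: ProcessedCube, k: int = 24, seed: int | None = 0
) -> SegmentationMap:
    """Bisecting 2-means over pixel spectra until ``k`` clusters.

    The cluster with the largest within-cluster sum of squared spectral
    distances is split by a seeded 2-means; splitting stops early when
    every remaining cluster is (numerically) homogeneous, so degenerate
    zero-noise cubes may yield fewer than ``k`` clusters.
    """
    rows, cols, bands = cube.shape
    n = rows * cols
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds pixel count {n}")
    x = cube.data.reshape(n, bands)
    assign = np.zeros(n, dtype=np.int64)

    def sse(idx: np.ndarray) -> float:
        pts = x[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    cluster_idx = {0: np.arange(n)}
    cluster_sse = {0: sse(cluster_idx[0])}
    rng = np.random.default_rng(seed)
    next_id = 1
    while len(cluster_idx) < k:
        cid = max(cluster_sse, key=cluster_sse.get)
        if cluster_sse[cid] <= 1e-9 or len(cluster_idx[cid]) < 2:
            break  # nothing left worth splitting
        idx = cluster_idx[cid]
        km = KMeans(n_clusters=2, n_init=3, random_state=int(rng.integers(2**31)))
        sub = km.fit_predict(x[idx])
        if len(np.unique(sub)) < 2:
            cluster_sse[cid] = 0.0
            continue
        a, b = idx[sub == 0], idx[sub == 1]
        cluster_idx[cid], cluster_sse[cid] = a, sse(a)
        cluster_idx[next_id], cluster_sse[next_id] = b, sse(b)
        next_id += 1

    ids = np.empty(n, dtype=np.int64)
    for new_id, cid in enumerate(sorted(cluster_idx), start=1):
        ids[cluster_idx[cid]] = new_id
    return SegmentationMap(ids.reshape(rows, cols))


def majority_vote(
    seg: SegmentationMap, class_map: np.ndarray
) -> tuple[np.ndarray, dict[int, dict[int, float]]]:
    """Assign every pixel of each cluster the cluster's modal class.

    Returns the voted map and, per cluster, the class frequency table
    (counts / cluster size over the four classes).  Ties break by the
    overlay priority tumor > normal > hypervascularized > background.
    """
    class_map = np.asarray(class_map)
    if class_map.shape != seg.cluster_ids.shape:
        raise ValueError("segmentation and classification shapes differ")
    voted = np.empty_like(class_map)
    freqs: dict[int, dict[int, float]] = {}
    for cid in np.unique(seg.cluster_ids):
        members = seg.cluster_ids == cid
        size = int(members.sum())
        table = {
            int(c): int((class_map[members] == c).sum()) / size
            for c in (CLASS_NORMAL, CLASS_TUMOR, CLASS_HYPERVASCULAR, CLASS_BACKGROUND)
        }
        freqs[int(cid)] = table
        best = max(CLASS_PRIORITY, key=lambda c: (table[c], -CLASS_PRIORITY.index(c)))
        voted[members] = best
    return voted, freqs


def cluster_probability_cube(
    seg: SegmentationMap, freqs: dict[int, dict[int, float]]
) -> ThreeClassProbabilityCube:
    """Spread per-cluster (tumor, normal, hypervascularized) frequencies
    over the cluster's pixels."""
    rows, cols = seg.cluster_ids.shape
    probs = np.zeros((rows, cols, 3))
    for cid, table in freqs.items():
        members = seg.cluster_ids == cid
        probs[members] = [
            table[CLASS_TUMOR],
            table[CLASS_NORMAL],
            table[CLASS_HYPERVASCULAR],
        ]
    return ThreeClassProbabilityCube(probs)


def render_density_map(
    pcube: ThreeClassProbabilityCube, parenchyma: np.ndarray
) -> np.ndarray:
    """8-bit RGB image: R=255*p_tumor, G=255*p_normal, B=255*p_hyper;
    pixels outside the parenchyma mask are black (negative fill)."""
    parenchyma = np.asarray(parenchyma, dtype=bool)
    if parenchyma.shape != pcube.probs.shape[:2]:
        raise ValueError("parenchyma mask shape differs from probability cube")
    rgb = np.rint(255.0 * pcube.probs).astype(np.uint8)
    rgb[~parenchyma] = 0
    return rgb


def apply_thresholds(
    prob_cube, thresholds: dict[int, float] | tuple[float, float, float]
) -> np.ndarray:
    """Re-classify from per-class probabilities with slider thresholds.

    A pixel takes the first class in priority order (tumor, normal,
    hypervascularized) whose probability meets its threshold; pixels that
    pass no threshold become background.  Raising a class's threshold can
    only shrink its area (monotone).
    """
    probs = prob_cube.probs if hasattr(prob_cube, "probs") else np.asarray(prob_cube)
    classes = getattr(prob_cube, "classes", None)
    if isinstance(thresholds, (tuple, list)):
        thresholds = dict(zip((CLASS_TUMOR, CLASS_NORMAL, CLASS_HYPERVASCULAR), thresholds))
    rows, cols = probs.shape[:2]
    out = np.full((rows, cols), CLASS_BACKGROUND, dtype=np.int64)
    assigned = np.zeros((rows, cols), dtype=bool)
    for c in (CLASS_TUMOR, CLASS_NORMAL, CLASS_HYPERVASCULAR):
        thr = thresholds.get(c)
        if thr is None:
            continue
        if classes is not None:
            matches = np.flatnonzero(np.asarray(classes) == c)
            if matches.size == 0:
                continue
            layer = probs[:, :, matches[0]]
        else:
            layer = probs[:, :, {CLASS_TUMOR: 0, CLASS_NORMAL: 1, CLASS_HYPERVASCULAR: 2}[c]]
        hit = (layer >= thr) & ~assigned
        out[hit] = c
        assigned |= hit
    return out
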