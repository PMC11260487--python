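"""Particle partitioning and conformational classification.

Two clustering stages mirror the heterogeneous-reconstruction workflow:

1. k-means on per-particle latent encodings (|Z| = 8 by default) partitions
   the particle set into K volumes (K = 500 in the study), each represented
   by the member closest to its centroid;
2. ward-linkage hierarchical clustering of the volumes' occupancy rows
   (Euclidean distance) groups the volumes into conformational classes.

The dendrogram cut is either a requested class count or "auto": the finest
cut whose relative merge-height gap is strongly supported, i.e. the deepest
level at which the tree still shows a sharp separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.cluster import KMeans

from .errors import ParameterError
from .occupancy import occupancy_values

__all__ = [
    "LatentEncodings",
    "VolumePartition",
    "ClassAssignment",
    "kmeans_partition",
    "select_representatives",
    "hierarchical_cluster",
    "order_heatmap",
    "class_mean_occupancy",
]


@dataclass
class LatentEncodings:
    """n_particles × d latent coordinates with stable particle ids."""

    values: np.ndarray
    particle_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        n, d = self.values.shape
        if d < 1 or n < d:
            raise ParameterError(f"need n >= d >= 1, got n={n}, d={d}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("latent encodings must be finite")
        if self.particle_ids is None:
            self.particle_ids = np.arange(n)
        else:
            self.particle_ids = np.asarray(self.particle_ids)
            if self.particle_ids.shape != (n,):
                raise ParameterError("particle_ids length must equal n_particles")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table(cls, path) -> "LatentEncodings":
        df = pd.read_csv(path, sep="\t")
        return cls(values=df.iloc[:, 1:].to_numpy(float), particle_ids=df.iloc[:, 0].to_numpy())

    def to_table(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"z{i}" for i in range(self.d)])
        df.insert(0, "particle_id", self.particle_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class VolumePartition:
    """Particle → volume assignment from k-means on latent encodings."""

    assignment: np.ndarray  # particle index -> cluster index in [0, K)
    centers: np.ndarray  # K × d
    representatives: np.ndarray  # per-cluster particle id (nearest centroid)
    counts: np.ndarray  # per-cluster particle totals
    K: int
    seed: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.assignment.size:
            raise ParameterError("partition counts do not sum to n_particles")


@dataclass
class ClassAssignment:
    """Ward-linkage classification of volumes into conformational classes."""

    labels: np.ndarray  # per-volume class label, contiguous 1..n_classes
    n_classes: int
    merge_tree: np.ndarray  # scipy linkage matrix
    linkage_name: str = "ward"
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.n_classes + 1)):
            raise ParameterError(
                f"class labels must be contiguous 1..{self.n_classes}, got {present}"
            )

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.merge_tree)


def kmeans_partition(
    latent: LatentEncodings, K: int, seed: int, n_init: int = 10
) -> VolumePartition:
    """Seeded k-means++ partition of particles into K volume clusters.

    ``n_init`` restarts guard against bad initializations on small problems;
    for large ensembles a single k-means++ init is the usual choice.
    """
    if K < 1 or K > latent.n:
        raise ParameterError(f"K={K} must satisfy 1 <= K <= n_particles={latent.n}")
    km = KMeans(n_clusters=K, random_state=seed, n_init=n_init)
    assignment = km.fit_predict(latent.values)
    counts = np.bincount(assignment, minlength=K)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        warnings.warn(f"{empty.size} empty k-means clusters: {empty.tolist()}")
    partition = VolumePartition(
        assignment=assignment,
        centers=km.cluster_centers_,
        representatives=np.full(K, -1),
        counts=counts,
        K=K,
        seed=seed,
    )
    partition.representatives = select_representatives(latent, partition)
    return partition


def select_representatives(
    latent: LatentEncodings, partition: VolumePartition
) -> np.ndarray:
    """Per cluster, the member particle id nearest the centroid (Euclidean).

    Distance ties are broken by the lowest particle id; empty clusters are
    skipped with a warning and keep a -1 sentinel.
    """
    reps = np.full(partition.K, -1, dtype=object)
    order = np.argsort(latent.particle_ids, kind="stable")
    for k in range(partition.K):
        members = np.flatnonzero(partition.assignment == k)
        if members.size == 0:
            warnings.warn(f"cluster {k} is empty; no representative")
            continue
        # scan in ascending particle-id order so strict '<' keeps the lowest id on ties
        members = order[np.isin(order, members)]
        d = np.linalg.norm(latent.values[members] - partition.centers[k], axis=1)
        best = members[0]
        best_d = d[0]
        for m, dist in zip(members[1:], d[1:]):
            if dist < best_d - 1e-12:
                best, best_d = m, dist
        reps[k] = latent.particle_ids[best]
    return np.array(list(reps), dtype=object)


def auto_cut(
    merge_tree: np.ndarray, max_classes: int = 50, margin: float = 0.5
) -> int:
    """Class count at the finest strongly supported merge-height gap.

    Merge heights h_1 <= ... <= h_{n-1}; cutting just below h_{n-k+1} yields
    k classes, and the support for that cut is the relative gap
    r(k) = h_{n-k+1} / h_{n-k}. A hierarchical ensemble shows large gaps at
    several granularities (e.g. both at the stage level and at the class
    level), so the rule picks the LARGEST k whose excess gap r(k) - 1
    reaches ``margin`` times the maximal excess gap — the finest cut the
    dendrogram still clearly supports. Zero lower heights (duplicate rows)
    are skipped; the search stops at ``max_classes``, past which a
    dendrogram cut stops being an interpretable class count.
    """
    heights = merge_tree[:, 2]
    n = heights.size + 1
    ratios: dict[int, float] = {}
    for k in range(2, min(max_classes, n - 1) + 1):
        hi = heights[n - k]  # first merge broken by the cut
        lo = heights[n - k - 1]  # last merge kept
        if lo <= 0:
            continue
        ratios[k] = hi / lo
    if not ratios:
        return 2
    best_excess = max(r - 1.0 for r in ratios.values())
    supported = [k for k, r in ratios.items() if r - 1.0 >= margin * best_excess]
    return max(supported)


def hierarchical_cluster(
    matrix: pd.DataFrame, n_classes: int | str = "auto"
) -> ClassAssignment:
    """Ward-linkage classification of occupancy rows.

    ``matrix`` is an occupancy DataFrame (volume_id, particle_count, blocks).
    ``n_classes`` is an integer cut or "auto" (largest relative merge-height
    gap). Class labels are renumbered 1..k in dendrogram leaf order, so class
    1 is the leftmost class on the ordered heatmap.
    """
    values = occupancy_values(matrix)
    if values.shape[0] < 2:
        raise ParameterError("need at least 2 volumes to cluster")
    if np.isnan(values).any():
        raise ParameterError("occupancy matrix contains missing values")
    tree = linkage(values, method="ward", metric="euclidean")
    if n_classes == "auto":
        k = auto_cut(tree)
    else:
        k = int(n_classes)
        if not 1 <= k <= values.shape[0]:
            raise ParameterError(
                f"n_classes={k} must be in 1..{values.shape[0]}"
            )
    raw = fcluster(tree, t=k, criterion="maxclust")
    # renumber labels by first appearance along the dendrogram leaf order
    order = leaves_list(tree)
    relabel: dict[int, int] = {}
    for leaf in order:
        relabel.setdefault(raw[leaf], len(relabel) + 1)
    labels = np.array([relabel[r] for r in raw])
    return ClassAssignment(labels=labels, n_classes=int(labels.max()), merge_tree=tree)


def order_heatmap(
    matrix: pd.DataFrame,
    classes: ClassAssignment,
    image_path=None,
) -> pd.DataFrame:
    """Rows permuted to dendrogram leaf order, with a class annotation column.

    Optionally renders the ordered matrix as a heatmap with class boundaries
    to ``image_path`` (PNG/SVG by extension).
    """
    order = classes.leaf_order
    ordered = matrix.iloc[order].copy()
    ordered.insert(2, "class", classes.labels[order])
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        values = occupancy_values(matrix)[order]
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(values, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        boundaries = np.flatnonzero(np.diff(classes.labels[order])) + 0.5
        for b in boundaries:
            ax.axhline(b, color="white", lw=0.8)
        ax.set_xlabel("block")
        ax.set_ylabel("volume (dendrogram leaf order)")
        fig.colorbar(im, ax=ax, label="occupancy")
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return ordered


def class_mean_occupancy(
    matrix: pd.DataFrame, classes: ClassAssignment
) -> pd.DataFrame:
    """Particle-count-weighted mean occupancy row per class.

    Returns one row per class label (index ``class``) with block columns in
    library order plus a ``particle_count`` column of summed member counts.
    """
    values = occupancy_values(matrix)
    counts = matrix["particle_count"].to_numpy(float)
    block_cols = [c for c in matrix.columns if c not in ("volume_id", "particle_count")]
    rows = []
    for label in range(1, classes.n_classes + 1):
        members = classes.labels == label
        w = counts[members]
        if w.sum() == 0:
            w = np.ones(members.sum())
        mean = np.average(values[members], axis=0, weights=w)
        rows.append([label, counts[members].sum(), *mean])
    out = pd.DataFrame(rows, columns=["class", "particle_count", *block_cols])
    return out.set_index("class")
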