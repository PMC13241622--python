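"""Per-cluster and per-cell quantification.

Channel counts follow the isotropic-packing rule (area divided by the single
channel footprint, unrounded).  "Edge-to-edge" distance between two clusters
is the minimum Euclidean distance between member pixel centres, scaled to nm;
this is computed on boundary pixels only, which is exact (see
``Cluster.boundary_pixels``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .segmentation import DEFAULT_CHANNEL_FOOTPRINT_NM2, ClusterSet

DEFAULT_SMALL_CLUSTER_CHANNELS = 6  # "small" cutoff for the cumulative fraction


def channels_per_cluster(
    area_nm2: float | np.ndarray,
    channel_footprint_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2,
) -> float | np.ndarray:
    """Convert cluster area to a (real-valued) channel count.

    channels = area_nm2 / channel_footprint_nm2, unrounded.
    """
    area = np.asarray(area_nm2, dtype=float)
    if not channel_footprint_nm2 > 0:
        raise ValidationError("channel_footprint_nm2 must be positive")
    if np.any(area <= 0):
        raise ValidationError("cluster area must be positive")
    out = area / channel_footprint_nm2
    return float(out) if np.isscalar(area_nm2) else out


def pairwise_edge_distances(cluster_set: ClusterSet) -> np.ndarray:
    """Symmetric matrix of edge-to-edge distances (nm) between all clusters.

    Entry (i, j) is the minimum pixel-centre distance between cluster i and
    cluster j times the pixel size; the diagonal is +inf.
    """
    clusters = cluster_set.clusters
    n = len(clusters)
    dist = np.full((n, n), np.inf)
    if n < 2:
        return dist
    boundaries = [c.boundary_pixels().astype(float) for c in clusters]
    trees = [cKDTree(b) for b in boundaries]
    for i in range(n):
        for j in range(i + 1, n):
            # query the smaller point set against the larger tree
            if len(boundaries[i]) >= len(boundaries[j]):
                d, _ = trees[i].query(boundaries[j])
            else:
                d, _ = trees[j].query(boundaries[i])
            dist[i, j] = dist[j, i] = d.min() * cluster_set.pixel_size_nm
    return dist


def edge_to_edge_nnd(
    cluster_set: ClusterSet,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cluster nearest-neighbour edge-to-edge distance in nm.

    With fewer than two clusters the NND is undefined and returned as NaN
    (missing, not zero).  A precomputed distance matrix may be passed to avoid
    recomputation.
    """
    n = len(cluster_set)
    if n < 2:
        return np.full(n, np.nan)
    if distances is None:
        distances = pairwise_edge_distances(cluster_set)
    return distances.min(axis=1)


@dataclass
class ClusterMetrics:
    """Per-cell aggregates over the retained clusters."""

    n_clusters: int
    mean_area_nm2: float
    mean_channels: float
    density_per_um2: float
    mean_nnd_nm: float  # NaN when fewer than two clusters
    fraction_small: float  # fraction of clusters with channels <= small cutoff
    small_cutoff_channels: float = DEFAULT_SMALL_CLUSTER_CHANNELS

    @property
    def is_empty(self) -> bool:
        return self.n_clusters == 0


def cell_summary(
    cluster_set: ClusterSet,
    channel_footprint_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2,
    small_cutoff_channels: float = DEFAULT_SMALL_CLUSTER_CHANNELS,
    distances: np.ndarray | None = None,
) -> ClusterMetrics:
    """Aggregate a cell's retained clusters into ClusterMetrics.

    Density divides the cluster count by the analyzed area (nucleus already
    excluded from ``analyzed_area_nm2``), reported per square micron.
    """
    n = len(cluster_set)
    if n == 0:
        return ClusterMetrics(
            n_clusters=0,
            mean_area_nm2=np.nan,
            mean_channels=np.nan,
            density_per_um2=0.0,
            mean_nnd_nm=np.nan,
            fraction_small=np.nan,
            small_cutoff_channels=small_cutoff_channels,
        )
    areas = cluster_set.areas_nm2()
    channels = channels_per_cluster(areas, channel_footprint_nm2)
    for c, ch in zip(cluster_set.clusters, channels):
        c.channels = float(ch)
    nnd = edge_to_edge_nnd(cluster_set, distances=distances)
    return ClusterMetrics(
        n_clusters=n,
        mean_area_nm2=float(areas.mean()),
        mean_channels=float(channels.mean()),
        density_per_um2=n / (cluster_set.analyzed_area_nm2 / 1e6),
        mean_nnd_nm=float(np.nanmean(nnd)) if np.isfinite(nnd).any() else np.nan,
        fraction_small=float((channels <= small_cutoff_channels).mean()),
        small_cutoff_channels=small_cutoff_channels,
    )
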