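"""Grouping of clusters into release units by single-linkage distance threshold.

Two eligible clusters belong to the same unit when a chain of pairwise
edge-to-edge distances strictly below the threshold connects them
(single-linkage transitivity).  Exactly-at-threshold pairs are NOT grouped.
Eligibility defaults to clusters holding at least two channels; whether
single-channel clusters may join as members is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cluster_metrics import channels_per_cluster, pairwise_edge_distances
from .segmentation import (
    DEFAULT_CHANNEL_FOOTPRINT_NM2,
    DEFAULT_GROUP_THRESHOLD_NM,
    ClusterSet,
)

DEFAULT_MIN_CHANNELS = 2.0


@dataclass
class CRU:
    """One release unit: a single-linkage group of clusters."""

    cru_id: int
    member_cluster_ids: list[int]
    total_channels: float

    @property
    def n_clusters(self) -> int:
        return len(self.member_cluster_ids)

    @property
    def is_isolated(self) -> bool:
        return self.n_clusters == 1


@dataclass
class CRUSummary:
    """Per-cell release-unit composition statistics.

    Two clusters-per-unit means are always reported because the literature
    value is ambiguous between all units and multi-cluster units only.
    """

    n_crus: int
    n_eligible_clusters: int
    mean_clusters_per_cru: float       # over all units
    mean_clusters_per_cru_multi: float  # over multi-cluster units (NaN if none)
    mean_channels_per_cru: float
    isolated_fraction: float           # singleton units / eligible clusters


def group_crus(
    cluster_set: ClusterSet,
    threshold_nm: float = DEFAULT_GROUP_THRESHOLD_NM,
    min_channels: float = DEFAULT_MIN_CHANNELS,
    channel_footprint_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2,
    distances: np.ndarray | None = None,
) -> list[CRU]:
    """Partition eligible clusters into release units.

    Units are the connected components of the graph on eligible clusters with
    an edge wherever the edge-to-edge distance is strictly below
    ``threshold_nm``.  Deterministic: units are ordered by their smallest
    member cluster id.

    Parameters
    ----------
    min_channels : float
        Eligibility cutoff; clusters with fewer channels are excluded from
        grouping entirely.
    distances : ndarray, optional
        Precomputed full pairwise edge-to-edge matrix for ``cluster_set``.
    """
    clusters = cluster_set.clusters
    n = len(clusters)
    channels = (
        channels_per_cluster(cluster_set.areas_nm2(), channel_footprint_nm2)
        if n
        else np.empty(0)
    )
    eligible = np.flatnonzero(channels >= min_channels)
    if eligible.size == 0:
        return []
    if distances is None:
        distances = pairwise_edge_distances(cluster_set)
    sub = distances[np.ix_(eligible, eligible)]
    adj = csr_matrix(sub < threshold_nm)
    n_comp, labels = connected_components(adj, directed=False)
    crus: list[CRU] = []
    order = {}
    for comp in range(n_comp):
        members = eligible[labels == comp]
        order[comp] = members.min()
    for new_id, comp in enumerate(sorted(order, key=order.get), start=1):
        members = eligible[labels == comp]
        crus.append(
            CRU(
                cru_id=new_id,
                member_cluster_ids=[clusters[m].cluster_id for m in members],
                total_channels=float(channels[members].sum()),
            )
        )
    return crus


def cru_summary(crus: list[CRU], n_eligible_clusters: int | None = None) -> CRUSummary:
    """Aggregate a cell's release units into composition statistics.

    ``n_eligible_clusters`` defaults to the total membership of the units,
    which equals the eligible-cluster count by the partition property.
    """
    sizes = np.array([c.n_clusters for c in crus], dtype=float)
    if n_eligible_clusters is None:
        n_eligible_clusters = int(sizes.sum())
    if not crus:
        return CRUSummary(0, n_eligible_clusters, np.nan, np.nan, np.nan, np.nan)
    multi = sizes[sizes > 1]
    n_isolated = int((sizes == 1).sum())
    return CRUSummary(
        n_crus=len(crus),
        n_eligible_clusters=n_eligible_clusters,
        mean_clusters_per_cru=float(sizes.mean()),
        mean_clusters_per_cru_multi=float(multi.mean()) if multi.size else np.nan,
        mean_channels_per_cru=float(np.mean([c.total_channels for c in crus])),
        isolated_fraction=n_isolated / n_eligible_clusters if n_eligible_clusters else np.nan,
    )
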