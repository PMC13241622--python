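"""Cluster segmentation of rendered images.

The pipeline is: intensity-fraction binary mask over the analyzed ROI,
connected-component labeling, then a minimum-area filter that removes regions
smaller than one channel footprint.

The fraction-threshold mask is defined so it is unique and tie-stable: sort
the analyzed-ROI intensities descending, take the shortest prefix whose
cumulative sum reaches ``fraction`` of the total, set the threshold to the
last included intensity, and include *all* pixels at or above that threshold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import EmptySignalError, ValidationError
from .io_formats import DEFAULT_PIXEL_SIZE_NM, ROIMask, RenderedImage

logger = logging.getLogger(__name__)

# single-channel membrane footprint in nm^2; regions below this are discarded
DEFAULT_CHANNEL_FOOTPRINT_NM2 = 900.0
DEFAULT_MASK_FRACTION = 0.75
DEFAULT_GROUP_THRESHOLD_NM = 150.0


@dataclass(frozen=True)
class AnalysisConfig:
    """All thresholds of the image-analysis stages, with their defaults."""

    mask_fraction: float = DEFAULT_MASK_FRACTION
    min_cluster_area_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2
    connectivity: int = 8
    cru_threshold_nm: float = DEFAULT_GROUP_THRESHOLD_NM
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel_footprint_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2

    def __post_init__(self) -> None:
        errors = []
        if not 0 < self.mask_fraction <= 1:
            errors.append(f"mask_fraction must be in (0, 1], got {self.mask_fraction}")
        if not self.min_cluster_area_nm2 > 0:
            errors.append(f"min_cluster_area_nm2 must be positive, got {self.min_cluster_area_nm2}")
        if self.connectivity not in (4, 8):
            errors.append(f"connectivity must be 4 or 8, got {self.connectivity}")
        if not self.cru_threshold_nm > 0:
            errors.append(f"cru_threshold_nm must be positive, got {self.cru_threshold_nm}")
        if not self.pixel_size_nm > 0:
            errors.append(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        if not self.channel_footprint_nm2 > 0:
            errors.append(f"channel_footprint_nm2 must be positive, got {self.channel_footprint_nm2}")
        if errors:
            raise ValidationError("; ".join(errors))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Cluster:
    """One labeled connected region of the binary mask.

    ``pixels`` is an (n, 2) array of (row, col) image indices.  ``channels``
    is filled by the metrics stage; ``boundary`` is computed lazily.
    """

    cluster_id: int
    pixels: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    channels: float | None = None
    _boundary: np.ndarray | None = field(default=None, repr=False)

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    @property
    def area_nm2(self) -> float:
        return self.pixel_count * self.pixel_size_nm**2

    @property
    def centroid_nm(self) -> tuple[float, float]:
        """World (x, y) of the mean pixel centre."""
        i_mean, j_mean = self.pixels.mean(axis=0)
        p = self.pixel_size_nm
        return (self.origin_nm[0] + (j_mean + 0.5) * p, self.origin_nm[1] + (i_mean + 0.5) * p)

    def boundary_pixels(self) -> np.ndarray:
        """Member pixels with at least one 8-neighbour outside the cluster.

        The minimum centre-to-centre distance between two disjoint pixel sets
        is always attained at such pixels, so they suffice for edge-to-edge
        distances.
        """
        if self._boundary is None:
            px = self.pixels
            i0, j0 = px.min(axis=0)
            local = np.zeros((px[:, 0].max() - i0 + 3, px[:, 1].max() - j0 + 3), dtype=bool)
            local[px[:, 0] - i0 + 1, px[:, 1] - j0 + 1] = True
            eroded = ndimage.binary_erosion(local, structure=np.ones((3, 3), dtype=bool))
            edge = local & ~eroded
            bi, bj = np.nonzero(edge)
            self._boundary = np.column_stack([bi + i0 - 1, bj + j0 - 1])
        return self._boundary


@dataclass
class ClusterSet:
    """A set of disjoint labeled clusters plus the analyzed-region area."""

    clusters: list[Cluster]
    analyzed_area_nm2: float
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.analyzed_area_nm2 > 0:
            raise ValidationError("analyzed_area_nm2 must be positive")

    def __len__(self) -> int:
        return len(self.clusters)

    def areas_nm2(self) -> np.ndarray:
        return np.array([c.area_nm2 for c in self.clusters], dtype=float)

    def label_image(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the clusters as a label image (0 = background)."""
        out = np.zeros(shape, dtype=np.uint16)
        for k, c in enumerate(self.clusters, start=1):
            out[c.pixels[:, 0], c.pixels[:, 1]] = k
        return out


def intensity_fraction_mask(
    image: RenderedImage,
    roi: ROIMask,
    fraction: float = DEFAULT_MASK_FRACTION,
) -> np.ndarray:
    """Binary mask holding at least ``fraction`` of the ROI labelling intensity.

    The mask is ``{analyzed pixels with intensity >= t*}`` where ``t*`` is the
    largest intensity threshold whose mask still reaches the fraction; all
    pixels tied at ``t*`` are included.  Minimal over threshold masks by
    construction.

    Raises
    ------
    EmptySignalError
        If the analyzed region holds zero total intensity.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if image.shape != roi.include.shape:
        raise ValidationError(
            f"image shape {image.shape} does not match ROI shape {roi.include.shape}"
        )
    analyzed = roi.analyzed
    vals = image.pixels[analyzed].astype(np.int64)
    total = vals.sum()
    if total == 0:
        raise EmptySignalError("analyzed region contains no intensity")
    vals_sorted = np.sort(vals)[::-1]
    csum = np.cumsum(vals_sorted)
    k = int(np.searchsorted(csum, fraction * total))  # first index reaching the fraction
    t_star = vals_sorted[k]
    return analyzed & (image.pixels >= t_star)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_clusters(
    mask: np.ndarray,
    config: AnalysisConfig,
    analyzed_area_nm2: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    provenance: dict | None = None,
) -> ClusterSet:
    """Connected-component labeling of the binary mask (unfiltered)."""
    labels, n = ndimage.label(mask, structure=_STRUCTURES[config.connectivity])
    clusters = []
    if n:
        objects = ndimage.find_objects(labels)
        for k in range(1, n + 1):
            sl = objects[k - 1]
            ii, jj = np.nonzero(labels[sl] == k)
            pixels = np.column_stack([ii + sl[0].start, jj + sl[1].start])
            clusters.append(
                Cluster(
                    cluster_id=k,
                    pixels=pixels,
                    pixel_size_nm=config.pixel_size_nm,
                    origin_nm=origin_nm,
                )
            )
    prov = dict(provenance or {})
    prov["config_hash"] = config.hash()
    return ClusterSet(
        clusters=clusters,
        analyzed_area_nm2=analyzed_area_nm2,
        pixel_size_nm=config.pixel_size_nm,
        origin_nm=origin_nm,
        provenance=prov,
    )


def filter_min_area(
    cluster_set: ClusterSet,
    min_cluster_area_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2,
) -> ClusterSet:
    """Drop clusters strictly smaller than the minimum area (boundary retained)."""
    kept = [c for c in cluster_set.clusters if c.area_nm2 >= min_cluster_area_nm2]
    n_removed = len(cluster_set.clusters) - len(kept)
    if n_removed:
        logger.info("filtered %d clusters below %g nm^2", n_removed, min_cluster_area_nm2)
    prov = dict(cluster_set.provenance)
    prov["n_filtered_min_area"] = n_removed
    return ClusterSet(
        clusters=kept,
        analyzed_area_nm2=cluster_set.analyzed_area_nm2,
        pixel_size_nm=cluster_set.pixel_size_nm,
        origin_nm=cluster_set.origin_nm,
        provenance=prov,
    )


def segment_image(
    image: RenderedImage,
    roi: ROIMask,
    config: AnalysisConfig,
    provenance: dict | None = None,
) -> ClusterSet:
    """Mask, label, and area-filter in one step."""
    mask = intensity_fraction_mask(image, roi, config.mask_fraction)
    unfiltered = label_clusters(
        mask,
        config,
        analyzed_area_nm2=roi.analyzed_area_nm2(config.pixel_size_nm),
        origin_nm=image.origin_nm,
        provenance=provenance,
    )
    return filter_min_area(unfiltered, config.min_cluster_area_nm2)
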