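"""Readers and writers for every external representation the pipeline touches.

Conventions
-----------
All geometry is in world nanometres, x to the right and y down.  Pixel
``(i, j)`` of an image with pixel size ``p`` and origin ``(x0, y0)`` covers the
half-open square ``[x0 + j*p, x0 + (j+1)*p) x [y0 + i*p, y0 + (i+1)*p)``; its
centre sits at ``(x0 + (j + 0.5)*p, y0 + (i + 0.5)*p)``.

Images are single-plane 16-bit greyscale TIFFs.  The nm/pixel scale is a
required parameter (default 5 nm) rather than being trusted from TIFF tags,
which are unreliable across renderers.  ROI masks are 8-bit TIFFs (nonzero =
inside) or polygon JSON files rasterized on pixel centres.  Localizations are
CSV with header ``x_nm,y_nm,frame,weight``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import SchemaError, UnsupportedFormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_NM = 5.0

LOCALIZATION_COLUMNS = ["x_nm", "y_nm", "frame", "weight"]


# ---------------------------------------------------------------------------
# Rendered images
# ---------------------------------------------------------------------------

@dataclass
class RenderedImage:
    """A rendered greyscale intensity grid with its physical scale.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative integer intensity grid.
    pixel_size_nm : float
        Edge length of one pixel in nm; must be positive.
    origin_nm : tuple of float
        World coordinates (x0, y0) of the corner of pixel (0, 0).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"image must be 2-D, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError(
                f"image intensities must be integers, got dtype {self.pixels.dtype}"
            )
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("image intensities must be non-negative")
        if not self.pixel_size_nm > 0:
            raise ValidationError(
                f"pixel_size_nm must be positive, got {self.pixel_size_nm}"
            )
        self.origin_nm = (float(self.origin_nm[0]), float(self.origin_nm[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def total_intensity(self) -> int:
        return int(self.pixels.astype(np.int64).sum())

    def pixel_centers_nm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) world coordinates of every pixel centre as 2-D grids."""
        h, w = self.pixels.shape
        p = self.pixel_size_nm
        x = self.origin_nm[0] + (np.arange(w) + 0.5) * p
        y = self.origin_nm[1] + (np.arange(h) + 0.5) * p
        return np.meshgrid(x, y)


def write_rendered_image(image: RenderedImage, path: str | Path) -> Path:
    """Write a RenderedImage as a single-plane 16-bit greyscale TIFF."""
    if image.pixels.size and image.pixels.max() > np.iinfo(np.uint16).max:
        raise ValidationError(
            "image intensities exceed 16-bit range; rescale before writing"
        )
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.uint16))
    return path


def read_rendered_image(
    path: str | Path,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> RenderedImage:
    """Read a single-plane greyscale integer TIFF.

    Raises
    ------
    UnsupportedFormatError
        If the file is multi-channel, multi-plane, or floating point.
    ValidationError
        If ``pixel_size_nm`` is not positive.
    """
    if not pixel_size_nm > 0:
        raise ValidationError(f"pixel_size_nm must be positive, got {pixel_size_nm}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: expected single-plane greyscale TIFF, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedFormatError(
            f"{path}: expected integer intensities, got dtype {arr.dtype}"
        )
    return RenderedImage(arr, pixel_size_nm=pixel_size_nm, origin_nm=origin_nm)


# ---------------------------------------------------------------------------
# Localization tables
# ---------------------------------------------------------------------------

@dataclass
class LocalizationTable:
    """Point events (x, y in nm, frame index, photon weight)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("x_nm", "y_nm") if c not in self.data.columns]
        if missing:
            raise SchemaError(f"localization table missing columns: {missing}")
        df = self.data.copy()
        if "frame" not in df.columns:
            df["frame"] = 0
        if "weight" not in df.columns:
            df["weight"] = 1.0
        df = df[LOCALIZATION_COLUMNS]
        if len(df) and (df["weight"] <= 0).any():
            raise ValidationError("localization weights must be positive")
        if len(df) and (df["frame"] < 0).any():
            raise ValidationError("frame indices must be non-negative")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_arrays(
        cls,
        x_nm: np.ndarray,
        y_nm: np.ndarray,
        frame: np.ndarray | int = 0,
        weight: np.ndarray | float = 1.0,
    ) -> "LocalizationTable":
        n = len(x_nm)
        return cls(
            pd.DataFrame(
                {
                    "x_nm": np.asarray(x_nm, dtype=float),
                    "y_nm": np.asarray(y_nm, dtype=float),
                    "frame": np.broadcast_to(np.asarray(frame), (n,)).astype(int),
                    "weight": np.broadcast_to(np.asarray(weight, dtype=float), (n,)),
                }
            )
        )

    def total_weight(self) -> float:
        return float(self.data["weight"].sum())


def write_localizations(table: LocalizationTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def read_localizations(path: str | Path) -> LocalizationTable:
    """Read a localization CSV, dropping rows with non-finite coordinates.

    The number of dropped rows is logged at WARNING level.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing coordinate columns {missing}")
    finite = np.isfinite(df["x_nm"]) & np.isfinite(df["y_nm"])
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite coordinates", path, n_dropped)
        df = df[finite]
    return LocalizationTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

@dataclass
class ROIMask:
    """Analysis region: an include mask (soma) minus an exclude mask (nucleus).

    Both grids must be congruent with the paired image.  The exclude mask is
    clipped to the include mask on construction.
    """

    include: np.ndarray
    exclude: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.exclude is None:
            self.exclude = np.zeros_like(self.include)
        self.exclude = np.asarray(self.exclude, dtype=bool)
        if self.include.shape != self.exclude.shape:
            raise ValidationError(
                f"include shape {self.include.shape} != exclude shape {self.exclude.shape}"
            )
        self.exclude = self.exclude & self.include
        if not (self.include & ~self.exclude).any():
            raise ValidationError("analyzed region (include AND NOT exclude) is empty")

    @property
    def analyzed(self) -> np.ndarray:
        return self.include & ~self.exclude

    @property
    def analyzed_pixel_count(self) -> int:
        return int(self.analyzed.sum())

    def analyzed_area_nm2(self, pixel_size_nm: float) -> float:
        return self.analyzed_pixel_count * pixel_size_nm**2


def rasterize_polygon(
    vertices_nm: np.ndarray,
    image_shape: tuple[int, int],
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize a polygon to a boolean grid: a pixel is inside iff its centre is.

    Vertices are (x, y) pairs in nm.  Uses shapely's point-in-polygon test on
    pixel centres, so the result matches a brute-force centre scan exactly.
    """
    poly = Polygon(np.asarray(vertices_nm, dtype=float))
    if not poly.is_valid:
        raise ValidationError("polygon is invalid (self-intersecting or degenerate)")
    h, w = image_shape
    x = origin_nm[0] + (np.arange(w) + 0.5) * pixel_size_nm
    y = origin_nm[1] + (np.arange(h) + 0.5) * pixel_size_nm
    xx, yy = np.meshgrid(x, y)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
    return inside.reshape(h, w)


def _load_mask_file(
    path: str | Path,
    image_shape: tuple[int, int],
    pixel_size_nm: float,
    origin_nm: tuple[float, float],
) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            vertices = json.load(fh)
        return rasterize_polygon(vertices, image_shape, pixel_size_nm, origin_nm)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: mask must be a single-plane image")
    if arr.shape != tuple(image_shape):
        raise ValidationError(
            f"{path}: mask shape {arr.shape} does not match image shape {tuple(image_shape)}"
        )
    return arr > 0


def read_roi_mask(
    path_include: str | Path,
    path_exclude: str | Path | None,
    image_shape: tuple[int, int],
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> ROIMask:
    """Load include/exclude masks (8-bit TIFF or polygon JSON) into an ROIMask.

    The analyzed-region pixel count is logged.  ``path_exclude`` may be None
    for an empty exclusion.
    """
    include = _load_mask_file(path_include, image_shape, pixel_size_nm, origin_nm)
    if path_exclude is None:
        exclude = np.zeros(image_shape, dtype=bool)
    else:
        exclude = _load_mask_file(path_exclude, image_shape, pixel_size_nm, origin_nm)
    roi = ROIMask(include=include, exclude=exclude)
    logger.info(
        "ROI loaded: %d analyzed pixels (%.1f nm^2 at %g nm/px)",
        roi.analyzed_pixel_count,
        roi.analyzed_area_nm2(pixel_size_nm),
        pixel_size_nm,
    )
    return roi


def write_roi_mask(roi: ROIMask, path_include: str | Path, path_exclude: str | Path) -> None:
    tifffile.imwrite(Path(path_include), roi.include.astype(np.uint8) * 255)
    tifffile.imwrite(Path(path_exclude), roi.exclude.astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# Tidy result tables
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = ["animal_id", "cell_id", "entity_id", "metric", "value", "units"]


@dataclass
class ResultsTable:
    """Tidy results: one row per (animal, cell, entity, metric), units required."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULTS_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in RESULTS_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"results table missing columns: {missing}")
        df = self.data[RESULTS_COLUMNS].reset_index(drop=True)
        if len(df) and df["units"].isna().any():
            raise ValidationError("every result row must carry units")
        key = ["animal_id", "cell_id", "entity_id", "metric"]
        if df.duplicated(key).any():
            raise ValidationError("duplicate (entity, metric) rows in results table")
        self.data = df

    def append_rows(self, rows: list[dict]) -> "ResultsTable":
        new = pd.concat([self.data, pd.DataFrame(rows)], ignore_index=True)
        return ResultsTable(new)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "ResultsTable":
        return cls(pd.read_csv(path))
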