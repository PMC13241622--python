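"""Synthetic SMLM scene generation, blinking simulation, and rendering.

The generative hierarchy is: ground-truth channel clusters (channels packed
isotropically on a jittered hexagonal lattice, footprint area = count x
single-channel footprint) -> labeled fluorophores -> blink events -> point
localizations with Gaussian precision error -> rendered greyscale image.
Every rate is configurable; identical seeds give bit-identical output.

Distribution laws are given as tuples so they round-trip through YAML:
``("constant", v)``, ``("geometric", mean)`` for cluster sizes and blink
counts, ``("constant", g)``, ``("exponential", scale, shift)`` for inter-
cluster edge gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from .errors import PlacementError, ValidationError
from .io_formats import LocalizationTable, ROIMask, RenderedImage
from .group_stats import CONTROL, DISEASE, CellRecord

DEFAULT_CHANNEL_FOOTPRINT_NM2 = 900.0


# ---------------------------------------------------------------------------
# Distribution laws
# ---------------------------------------------------------------------------

def sample_count_law(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n positive integers from a ("constant", k) or ("geometric", mean) law.

    The geometric law has support {1, 2, ...} and the given mean (>= 1), a
    discrete near-exponential size distribution.
    """
    kind = law[0]
    if kind == "constant":
        k = int(law[1])
        if k < 1:
            raise ValidationError("constant count law requires a value >= 1")
        return np.full(n, k, dtype=int)
    if kind == "geometric":
        mean = float(law[1])
        if mean < 1:
            raise ValidationError("geometric count law requires mean >= 1")
        return rng.geometric(1.0 / mean, size=n)
    if kind == "poisson":
        # shifted Poisson with support {1, 2, ...} and the given mean
        mean = float(law[1])
        if mean < 1:
            raise ValidationError("poisson count law requires mean >= 1")
        return 1 + rng.poisson(mean - 1.0, size=n)
    raise ValidationError(f"unknown count law kind {kind!r}")


def count_law_mean(law: tuple) -> float:
    if law[0] == "constant":
        return float(int(law[1]))
    if law[0] == "geometric":
        return float(law[1])
    raise ValidationError(f"unknown count law kind {law[0]!r}")


def scale_count_law(law: tuple, factor: float) -> tuple:
    """Scale a count law's mean by a multiplicative factor (floored at 1)."""
    if law[0] == "constant":
        return ("constant", max(1, round(int(law[1]) * factor)))
    if law[0] == "geometric":
        return ("geometric", max(1.0, float(law[1]) * factor))
    raise ValidationError(f"unknown count law kind {law[0]!r}")


def sample_gap_law(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n non-negative edge gaps (nm)."""
    kind = law[0]
    if kind == "constant":
        g = float(law[1])
        if g < 0:
            raise ValidationError("gap must be non-negative")
        return np.full(n, g)
    if kind == "exponential":
        scale = float(law[1])
        shift = float(law[2]) if len(law) > 2 else 0.0
        if scale < 0 or shift < 0:
            raise ValidationError("exponential gap law requires non-negative scale and shift")
        return shift + rng.exponential(scale, size=n)
    raise ValidationError(f"unknown gap law kind {kind!r}")


# ---------------------------------------------------------------------------
# Scene configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one ground-truth scene (one cell)."""

    frame_size_nm: tuple[float, float] = (3000.0, 3000.0)
    n_clusters: int = 36
    channel_footprint_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2
    cluster_size_law: tuple = ("geometric", 14.9)
    min_edge_gap_law: tuple = ("constant", 30.0)
    nucleus_radius_frac: float = 0.15  # nucleus exclusion disc, fraction of min frame edge / 2
    lattice_jitter_frac: float = 0.1  # channel jitter, fraction of lattice constant
    group_effect: float = 1.0  # multiplicative factor on mean cluster size for the disease group
    seed: int | None = None
    max_placement_tries: int = 2000

    def __post_init__(self) -> None:
        errors = []
        if not (self.frame_size_nm[0] > 0 and self.frame_size_nm[1] > 0):
            errors.append("frame_size_nm must be positive")
        if self.n_clusters < 0:
            errors.append("n_clusters must be >= 0")
        if not self.channel_footprint_nm2 > 0:
            errors.append("channel_footprint_nm2 must be positive")
        if not 0 < self.group_effect <= 2:
            errors.append(f"group_effect must be in (0, 2], got {self.group_effect}")
        if not 0 <= self.nucleus_radius_frac < 0.5:
            errors.append("nucleus_radius_frac must be in [0, 0.5)")
        if errors:
            raise ValidationError("; ".join(errors))

    @property
    def lattice_constant_nm(self) -> float:
        return math.sqrt(self.channel_footprint_nm2)


@dataclass
class TrueCluster:
    """Ground truth for one cluster: packed channel positions and true area."""

    cluster_id: int
    center_nm: tuple[float, float]
    channel_xy_nm: np.ndarray  # (k, 2) absolute world positions
    radius_nm: float  # circumradius used for placement

    @property
    def n_channels(self) -> int:
        return len(self.channel_xy_nm)

    def true_area_nm2(self, channel_footprint_nm2: float = DEFAULT_CHANNEL_FOOTPRINT_NM2) -> float:
        return self.n_channels * channel_footprint_nm2


@dataclass
class GroundTruthScene:
    """A realized scene: clusters inside the analyzed region of one frame."""

    config: SceneConfig
    clusters: list[TrueCluster]
    nucleus_center_nm: tuple[float, float]
    nucleus_radius_nm: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def channel_counts(self) -> np.ndarray:
        return np.array([c.n_channels for c in self.clusters], dtype=int)

    def true_areas_nm2(self) -> np.ndarray:
        return self.channel_counts() * self.config.channel_footprint_nm2

    def true_nnd_nm(self) -> np.ndarray:
        """Ground-truth edge-to-edge NND per cluster.

        Edge distance between two clusters is approximated as the minimum
        channel-centre pair distance minus one lattice constant (two half
        channel widths), clipped at zero.
        """
        n = self.n_clusters
        if n < 2:
            return np.full(n, np.nan)
        a = self.config.lattice_constant_nm
        pts = [c.channel_xy_nm for c in self.clusters]
        centers = np.array([c.center_nm for c in self.clusters])
        radii = np.array([c.radius_nm for c in self.clusters])
        d_centers = np.hypot(
            centers[:, 0, None] - centers[None, :, 0],
            centers[:, 1, None] - centers[None, :, 1],
        )
        # lower bound on the exact edge distance; prunes most pairs
        lower = d_centers - radii[:, None] - radii[None, :] - a
        np.fill_diagonal(lower, np.inf)
        exact: dict[tuple[int, int], float] = {}

        def pair(i: int, j: int) -> float:
            key = (i, j) if i < j else (j, i)
            if key not in exact:
                diff = pts[i][:, None, :] - pts[j][None, :, :]
                d = np.sqrt((diff**2).sum(axis=2)).min()
                exact[key] = max(d - a, 0.0)
            return exact[key]

        nnd = np.empty(n)
        for i in range(n):
            best = np.inf
            for j in np.argsort(lower[i], kind="stable"):
                if lower[i, j] >= best:
                    break
                best = min(best, pair(i, int(j)))
            nnd[i] = best
        return nnd

    def make_roi(self, pixel_size_nm: float, origin_nm: tuple[float, float] = (0.0, 0.0)) -> ROIMask:
        """Rasterize the scene's include/exclude geometry at the given scale."""
        w = int(round(self.config.frame_size_nm[0] / pixel_size_nm))
        h = int(round(self.config.frame_size_nm[1] / pixel_size_nm))
        include = np.ones((h, w), dtype=bool)
        exclude = np.zeros((h, w), dtype=bool)
        if self.nucleus_radius_nm > 0:
            x = origin_nm[0] + (np.arange(w) + 0.5) * pixel_size_nm
            y = origin_nm[1] + (np.arange(h) + 0.5) * pixel_size_nm
            xx, yy = np.meshgrid(x, y)
            exclude = (
                (xx - self.nucleus_center_nm[0]) ** 2 + (yy - self.nucleus_center_nm[1]) ** 2
            ) <= self.nucleus_radius_nm**2
        return ROIMask(include=include, exclude=exclude)


def _hex_channel_offsets(k: int, a: float, jitter_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Offsets of k channels packed on a jittered hexagonal lattice (nm).

    Lattice points are taken closest-first from a hex lattice with constant
    ``a`` (so each channel occupies ~a^2), randomly rotated per cluster.
    """
    if k == 1:
        pts = np.zeros((1, 2))
    else:
        rings = int(math.ceil(math.sqrt(k))) + 2
        qs, rs = np.meshgrid(np.arange(-rings, rings + 1), np.arange(-rings, rings + 1))
        x = a * (qs + rs / 2.0)
        y = a * rs * (math.sqrt(3) / 2.0)
        pts = np.column_stack([x.ravel(), y.ravel()])
        order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
        pts = pts[order[:k]]
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts = pts @ rot.T
    if jitter_frac > 0:
        pts = pts + rng.normal(0.0, jitter_frac * a, size=pts.shape)
    return pts


def simulate_scene(config: SceneConfig, rng: np.random.Generator | None = None) -> GroundTruthScene:
    """Realize a ground-truth scene from its configuration.

    Clusters are placed by rejection sampling: each new cluster must keep at
    least its sampled minimum edge gap (circumradius-based) from every
    existing cluster, stay inside the frame, and stay clear of the nucleus
    disc.

    Raises
    ------
    PlacementError
        If a cluster cannot be placed within ``max_placement_tries`` draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fw, fh = config.frame_size_nm
    nuc_center = (fw / 2.0, fh / 2.0)
    nuc_radius = config.nucleus_radius_frac * min(fw, fh)
    a = config.lattice_constant_nm

    sizes = sample_count_law(config.cluster_size_law, config.n_clusters, rng)
    gaps = sample_gap_law(config.min_edge_gap_law, config.n_clusters, rng)

    clusters: list[TrueCluster] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    for idx in range(config.n_clusters):
        offsets = _hex_channel_offsets(int(sizes[idx]), a, config.lattice_jitter_frac, rng)
        radius = float(np.hypot(offsets[:, 0], offsets[:, 1]).max() + a * math.sqrt(2) / 2)
        placed = False
        for _ in range(config.max_placement_tries):
            cx = rng.uniform(radius, fw - radius)
            cy = rng.uniform(radius, fh - radius)
            if nuc_radius > 0:
                if math.hypot(cx - nuc_center[0], cy - nuc_center[1]) < nuc_radius + radius:
                    continue
            if len(centers):
                d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy) - radii - radius
                if (d < gaps[idx]).any():
                    continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cluster {idx + 1}/{config.n_clusters} after "
                f"{config.max_placement_tries} tries; reduce density or gaps"
            )
        centers = np.vstack([centers, [cx, cy]])
        radii = np.append(radii, radius)
        clusters.append(
            TrueCluster(
                cluster_id=idx + 1,
                center_nm=(cx, cy),
                channel_xy_nm=offsets + np.array([cx, cy]),
                radius_nm=radius,
            )
        )
    return GroundTruthScene(
        config=config,
        clusters=clusters,
        nucleus_center_nm=nuc_center,
        nucleus_radius_nm=nuc_radius,
    )


# ---------------------------------------------------------------------------
# Blinking / localization simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionConfig:
    """Standard SMLM emission assumptions; every rate is configurable."""

    labeling_efficiency: float = 1.0
    blinks_per_fluorophore_law: tuple = ("poisson", 20.0)
    localization_precision_nm: float = 12.0
    background_rate_per_um2: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        errors = []
        if not 0 <= self.labeling_efficiency <= 1:
            errors.append("labeling_efficiency must be in [0, 1]")
        if self.localization_precision_nm < 0:
            errors.append("localization_precision_nm must be >= 0")
        if self.background_rate_per_um2 < 0:
            errors.append("background_rate_per_um2 must be >= 0")
        if errors:
            raise ValidationError("; ".join(errors))


def simulate_localizations(
    scene: GroundTruthScene,
    emission: EmissionConfig,
    rng: np.random.Generator | None = None,
) -> LocalizationTable:
    """Simulate blink localizations for a scene.

    Each channel is labeled with probability ``labeling_efficiency``; each
    labeled channel emits >= 1 blinks drawn from the blink-count law, each
    jittered by isotropic Gaussian noise of the localization precision.
    Background localizations are uniform over the frame with the configured
    area rate.
    """
    if rng is None:
        rng = np.random.default_rng(emission.seed)
    fw, fh = scene.config.frame_size_nm
    if scene.clusters:
        channels = np.vstack([c.channel_xy_nm for c in scene.clusters])
    else:
        channels = np.empty((0, 2))
    labeled = channels[rng.random(len(channels)) < emission.labeling_efficiency]
    xs, ys = [], []
    if len(labeled):
        blinks = sample_count_law(emission.blinks_per_fluorophore_law, len(labeled), rng)
        pos = np.repeat(labeled, blinks, axis=0)
        noise = rng.normal(0.0, emission.localization_precision_nm, size=pos.shape)
        pts = pos + noise
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
    n_bg = rng.poisson(emission.background_rate_per_um2 * fw * fh / 1e6)
    if n_bg:
        xs.append(rng.uniform(0, fw, n_bg))
        ys.append(rng.uniform(0, fh, n_bg))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        x = np.empty(0)
        y = np.empty(0)
    frames = rng.integers(0, 10_000, size=len(x)) if len(x) else np.empty(0, dtype=int)
    return LocalizationTable.from_arrays(x, y, frame=frames, weight=1.0)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_density(
    localizations: LocalizationTable,
    pixel_size_nm: float,
    frame_size_nm: tuple[float, float],
    origin_nm: tuple[float, float] = (0.0, 0.0),
    sigma_render_nm: float = 5.0,
) -> np.ndarray:
    """Deposit event weights into a float grid (pre-quantization).

    With ``sigma_render_nm == 0`` each event's full weight lands in the pixel
    containing it; otherwise the weight is spread with a symmetric Gaussian
    kernel integrated exactly per pixel, so total deposited intensity equals
    total event weight up to frame clipping.
    """
    if not pixel_size_nm > 0:
        raise ValidationError(f"pixel_size_nm must be positive, got {pixel_size_nm}")
    if sigma_render_nm < 0:
        raise ValidationError("sigma_render_nm must be >= 0")
    w = int(round(frame_size_nm[0] / pixel_size_nm))
    h = int(round(frame_size_nm[1] / pixel_size_nm))
    img = np.zeros((h, w))
    df = localizations.data
    if not len(df):
        return img
    u = (df["x_nm"].to_numpy() - origin_nm[0]) / pixel_size_nm
    v = (df["y_nm"].to_numpy() - origin_nm[1]) / pixel_size_nm
    wt = df["weight"].to_numpy()
    if sigma_render_nm == 0:
        j = np.floor(u).astype(int)
        i = np.floor(v).astype(int)
        ok = (i >= 0) & (i < h) & (j >= 0) & (j < w)
        np.add.at(img, (i[ok], j[ok]), wt[ok])
        return img
    s = sigma_render_nm / pixel_size_nm
    r = int(math.ceil(4 * s)) + 1
    offs = np.arange(-r, r + 1)
    jc = np.floor(u).astype(int)
    ic = np.floor(v).astype(int)
    # per-pixel Gaussian mass via erf differences, separable in x and y
    def cdf(z):
        return 0.5 * (1.0 + special.erf(z / math.sqrt(2)))

    jedges = jc[:, None] + offs[None, :]
    iedges = ic[:, None] + offs[None, :]
    fx = cdf((jedges + 1 - u[:, None]) / s) - cdf((jedges - u[:, None]) / s)
    fy = cdf((iedges + 1 - v[:, None]) / s) - cdf((iedges - v[:, None]) / s)
    contrib = wt[:, None, None] * fy[:, :, None] * fx[:, None, :]
    ii = np.broadcast_to(iedges[:, :, None], contrib.shape)
    jj = np.broadcast_to(jedges[:, None, :], contrib.shape)
    ok = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
    np.add.at(img, (ii[ok], jj[ok]), contrib[ok])
    return img


def render(
    localizations: LocalizationTable,
    pixel_size_nm: float,
    frame_size_nm: tuple[float, float],
    origin_nm: tuple[float, float] = (0.0, 0.0),
    sigma_render_nm: float = 5.0,
    gain: float = 100.0,
) -> RenderedImage:
    """Render localizations into a 16-bit-ready greyscale image.

    ``gain`` is the integer count deposited per unit event weight; it keeps
    Gaussian-spread mass above the quantization floor.  Intensities are
    clipped at the 16-bit maximum.
    """
    if not gain > 0:
        raise ValidationError("gain must be positive")
    dens = render_density(localizations, pixel_size_nm, frame_size_nm, origin_nm, sigma_render_nm)
    img = np.rint(dens * gain)
    np.clip(img, 0, np.iinfo(np.uint16).max, out=img)
    return RenderedImage(img.astype(np.uint16), pixel_size_nm=pixel_size_nm, origin_nm=origin_nm)


# ---------------------------------------------------------------------------
# Two-group nested dataset
# ---------------------------------------------------------------------------

@dataclass
class CellData:
    """One synthetic cell: ground truth plus (optionally) rendered artifacts."""

    animal_id: str
    group: str
    cell_id: str
    scene: GroundTruthScene
    localizations: LocalizationTable | None = None
    image: RenderedImage | None = None
    roi: ROIMask | None = None


@dataclass
class TwoGroupDataset:
    cells: list[CellData]
    scene_config: SceneConfig
    emission: EmissionConfig | None
    seed: int

    def ground_truth_records(self) -> list[CellRecord]:
        """Per-cell CellRecords computed from ground truth (no imaging)."""
        records = []
        for cell in self.cells:
            scene = cell.scene
            counts = scene.channel_counts()
            nnd = scene.true_nnd_nm()
            records.append(
                CellRecord(
                    animal_id=cell.animal_id,
                    group=cell.group,
                    cell_id=cell.cell_id,
                    metrics={
                        "mean_channels": float(counts.mean()) if len(counts) else np.nan,
                        "mean_area_nm2": float(scene.true_areas_nm2().mean()) if len(counts) else np.nan,
                        "mean_nnd_nm": float(np.nanmean(nnd)) if np.isfinite(nnd).any() else np.nan,
                    },
                )
            )
        return records


def make_two_group_dataset(
    scene_config: SceneConfig,
    emission: EmissionConfig | None = None,
    n_animals_per_group: int = 5,
    cells_per_animal: int = 30,
    group_effect: float | None = None,
    animal_rel_sd: float = 0.0,
    seed: int = 0,
    render_images: bool = False,
    pixel_size_nm: float = 5.0,
    sigma_render_nm: float = 16.0,
    gain: float = 100.0,
) -> TwoGroupDataset:
    """Generate a control/disease dataset of cells nested within animals.

    The disease group's mean cluster size is scaled by ``group_effect``
    (default: ``scene_config.group_effect``); inter-cluster spacing is shared
    between groups.  Each animal carries a multiplicative lognormal random
    effect on mean cluster size with log-scale SD ``animal_rel_sd``.  With
    ``render_images=True`` each cell also gets localizations, a rendered
    image, and an ROI mask.  Fully reproducible from ``seed``.
    """
    if n_animals_per_group < 1 or cells_per_animal < 1:
        raise ValidationError("need >= 1 animal per group and >= 1 cell per animal")
    if animal_rel_sd < 0:
        raise ValidationError("animal_rel_sd must be >= 0")
    if group_effect is None:
        group_effect = scene_config.group_effect
    if emission is None and render_images:
        emission = EmissionConfig()
    root = np.random.SeedSequence(seed)
    cells: list[CellData] = []
    for group, mult in ((CONTROL, 1.0), (DISEASE, group_effect)):
        for a in range(n_animals_per_group):
            animal_seq = root.spawn(1)[0]
            animal_rng = np.random.default_rng(animal_seq)
            animal_factor = float(np.exp(animal_rng.normal(0.0, animal_rel_sd))) if animal_rel_sd else 1.0
            animal_id = f"{group}_animal{a + 1}"
            law = scale_count_law(scene_config.cluster_size_law, mult * animal_factor)
            cell_config = replace(scene_config, cluster_size_law=law, seed=None)
            for c in range(cells_per_animal):
                cell_rng = np.random.default_rng(animal_seq.spawn(1)[0])
                scene = simulate_scene(cell_config, rng=cell_rng)
                cell = CellData(
                    animal_id=animal_id,
                    group=group,
                    cell_id=f"{animal_id}_cell{c + 1}",
                    scene=scene,
                )
                if render_images:
                    locs = simulate_localizations(scene, emission, rng=cell_rng)
                    cell.localizations = locs
                    cell.image = render(
                        locs,
                        pixel_size_nm,
                        scene_config.frame_size_nm,
                        sigma_render_nm=sigma_render_nm,
                        gain=gain,
                    )
                    cell.roi = scene.make_roi(pixel_size_nm)
                cells.append(cell)
    return TwoGroupDataset(cells=cells, scene_config=scene_config, emission=emission, seed=seed)


@dataclass
class SpacingCalibration:
    """Result of tuning the cluster count toward a target mean NND."""

    n_clusters: int
    achieved_mean_nnd_nm: float
    se_nm: float  # SE of the achieved mean over calibration scenes


def calibrate_n_clusters_for_nnd(
    scene_config: SceneConfig,
    target_mean_nnd_nm: float,
    n_scenes: int = 12,
    n_refine_scenes: int = 40,
    n_lo: int = 4,
    n_hi: int = 400,
    seed: int = 0,
    tol_nm: float = 2.0,
) -> SpacingCalibration:
    """Tune the cluster count so scenes hit a target mean ground-truth NND.

    Mean NND decreases monotonically with density, so integer bisection on
    ``n_clusters`` converges; the bisection winner and its neighbours are then
    re-evaluated on ``n_refine_scenes`` scenes and the closest is returned.
    The estimator is the mean of per-scene mean NNDs.
    """

    def evaluate(n: int, scenes: int) -> tuple[float, float]:
        root = np.random.SeedSequence((seed, n, scenes))
        means = []
        for s in root.spawn(scenes):
            scene = simulate_scene(replace(scene_config, n_clusters=n), rng=np.random.default_rng(s))
            means.append(float(np.nanmean(scene.true_nnd_nm())))
        means = np.array(means)
        return float(means.mean()), float(means.std(ddof=1) / math.sqrt(len(means)))

    lo, hi = n_lo, n_hi
    best_n, best_err = lo, math.inf
    while lo <= hi:
        mid = (lo + hi) // 2
        try:
            m, _ = evaluate(mid, n_scenes)
        except PlacementError:
            hi = mid - 1
            continue
        err = abs(m - target_mean_nnd_nm)
        if err < best_err:
            best_n, best_err = mid, err
        if err <= tol_nm:
            break
        if m > target_mean_nnd_nm:
            lo = mid + 1  # too sparse: more clusters
        else:
            hi = mid - 1

    best = None
    for n in range(max(n_lo, best_n - 2), best_n + 3):
        try:
            m, se = evaluate(n, n_refine_scenes)
        except PlacementError:
            continue
        if best is None or abs(m - target_mean_nnd_nm) < abs(best.achieved_mean_nnd_nm - target_mean_nnd_nm):
            best = SpacingCalibration(n_clusters=n, achieved_mean_nnd_nm=m, se_nm=se)
    assert best is not None
    return best
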