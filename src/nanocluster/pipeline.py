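"""End-to-end orchestration: simulate -> segment -> metrics -> group -> compare.

A single YAML config carries every stage's parameters; each analysis constant
(mask fraction 0.75, 900 nm^2 minimum area, 150 nm grouping threshold,
5 nm/pixel) is a named, defaulted key.  A RunManifest records the config
snapshot, seeds, software version, output inventory with content hashes, and
per-stage timings, so a run is identified by its manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_metrics import (
    ClusterMetrics,
    cell_summary,
    edge_to_edge_nnd,
    pairwise_edge_distances,
)
from .cru_analysis import CRU, CRUSummary, cru_summary, group_crus
from .errors import ValidationError
from .group_stats import CellRecord, GroupComparison, compare_all_metrics, records_to_frame
from .io_formats import ROIMask, RenderedImage, write_localizations, write_rendered_image, write_roi_mask
from .segmentation import AnalysisConfig, ClusterSet, segment_image
from .synthetic_data import (
    EmissionConfig,
    SceneConfig,
    TwoGroupDataset,
    make_two_group_dataset,
)

_CONFIG_SECTIONS = {"scene", "emission", "analysis", "render", "dataset", "compare"}


def _as_law(value) -> tuple:
    if isinstance(value, (list, tuple)):
        return tuple(value)
    raise ValidationError(f"distribution law must be a [kind, params...] list, got {value!r}")


def _build_section(cls, data: dict, problems: list[str], section: str, law_keys=()):
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in valid:
            problems.append(f"{section}: unknown key {key!r}")
            continue
        if key in law_keys:
            try:
                value = _as_law(value)
            except ValidationError as exc:
                problems.append(f"{section}.{key}: {exc}")
                continue
        if key.endswith("frame_size_nm") and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValidationError, TypeError) as exc:
        problems.append(f"{section}: {exc}")
        return None


@dataclass
class PipelineConfig:
    """Validated union of all per-stage configs."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    emission: EmissionConfig = field(default_factory=EmissionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    sigma_render_nm: float = 16.0
    gain: float = 100.0
    n_animals_per_group: int = 2
    cells_per_animal: int = 3
    animal_rel_sd: float = 0.05
    group_effect: float | None = None
    metrics: list[str] | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build and validate, reporting every problem at once."""
        problems: list[str] = []
        unknown = set(raw) - _CONFIG_SECTIONS
        for key in sorted(unknown):
            problems.append(f"unknown config section {key!r}")
        scene = _build_section(
            SceneConfig, raw.get("scene", {}), problems, "scene",
            law_keys=("cluster_size_law", "min_edge_gap_law"),
        )
        emission = _build_section(
            EmissionConfig, raw.get("emission", {}), problems, "emission",
            law_keys=("blinks_per_fluorophore_law",),
        )
        analysis = _build_section(AnalysisConfig, raw.get("analysis", {}), problems, "analysis")
        render_cfg = raw.get("render", {})
        dataset_cfg = raw.get("dataset", {})
        compare_cfg = raw.get("compare", {})
        for key in set(render_cfg) - {"sigma_render_nm", "gain"}:
            problems.append(f"render: unknown key {key!r}")
        for key in set(dataset_cfg) - {"n_animals_per_group", "cells_per_animal", "animal_rel_sd", "group_effect"}:
            problems.append(f"dataset: unknown key {key!r}")
        for key in set(compare_cfg) - {"metrics"}:
            problems.append(f"compare: unknown key {key!r}")
        if problems:
            raise ValidationError("invalid config: " + "; ".join(problems))
        return cls(
            scene=scene,
            emission=emission,
            analysis=analysis,
            sigma_render_nm=float(render_cfg.get("sigma_render_nm", 16.0)),
            gain=float(render_cfg.get("gain", 100.0)),
            n_animals_per_group=int(dataset_cfg.get("n_animals_per_group", 2)),
            cells_per_animal=int(dataset_cfg.get("cells_per_animal", 3)),
            animal_rel_sd=float(dataset_cfg.get("animal_rel_sd", 0.05)),
            group_effect=dataset_cfg.get("group_effect"),
            metrics=compare_cfg.get("metrics"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def snapshot(self) -> dict:
        return {
            "scene": dataclasses.asdict(self.scene),
            "emission": dataclasses.asdict(self.emission),
            "analysis": dataclasses.asdict(self.analysis),
            "render": {"sigma_render_nm": self.sigma_render_nm, "gain": self.gain},
            "dataset": {
                "n_animals_per_group": self.n_animals_per_group,
                "cells_per_animal": self.cells_per_animal,
                "animal_rel_sd": self.animal_rel_sd,
                "group_effect": self.group_effect,
            },
            "compare": {"metrics": self.metrics},
        }


@dataclass
class CellAnalysis:
    """All per-cell analysis products for one image."""

    cluster_set: ClusterSet
    metrics: ClusterMetrics
    crus: list[CRU]
    cru_stats: CRUSummary
    nnd_nm: np.ndarray


def analyze_cell(image: RenderedImage, roi: ROIMask, config: AnalysisConfig) -> CellAnalysis:
    """Segment one cell image and compute all cluster and grouping metrics.

    The pairwise edge-to-edge distance matrix is computed once and shared by
    the NND and grouping stages.
    """
    cluster_set = segment_image(image, roi, config)
    distances = pairwise_edge_distances(cluster_set)
    metrics = cell_summary(
        cluster_set,
        channel_footprint_nm2=config.channel_footprint_nm2,
        distances=distances,
    )
    crus = group_crus(
        cluster_set,
        threshold_nm=config.cru_threshold_nm,
        channel_footprint_nm2=config.channel_footprint_nm2,
        distances=distances,
    )
    cru_stats = cru_summary(crus)
    return CellAnalysis(
        cluster_set=cluster_set,
        metrics=metrics,
        crus=crus,
        cru_stats=cru_stats,
        nnd_nm=edge_to_edge_nnd(cluster_set, distances=distances),
    )


def cell_record_from_analysis(
    animal_id: str, group: str, cell_id: str, analysis: CellAnalysis
) -> CellRecord:
    m, cs = analysis.metrics, analysis.cru_stats
    return CellRecord(
        animal_id=animal_id,
        group=group,
        cell_id=cell_id,
        metrics={
            "n_clusters": m.n_clusters,
            "mean_area_nm2": m.mean_area_nm2,
            "mean_channels": m.mean_channels,
            "mean_nnd_nm": m.mean_nnd_nm,
            "density_per_um2": m.density_per_um2,
            "fraction_small": m.fraction_small,
            "n_crus": cs.n_crus,
            "mean_clusters_per_cru": cs.mean_clusters_per_cru,
            "mean_clusters_per_cru_multi": cs.mean_clusters_per_cru_multi,
            "mean_channels_per_cru": cs.mean_channels_per_cru,
            "isolated_fraction": cs.isolated_fraction,
        },
    )


def analyze_dataset(dataset: TwoGroupDataset, config: AnalysisConfig) -> list[CellRecord]:
    """Run the imaging analysis on every rendered cell of a synthetic dataset."""
    records = []
    for cell in dataset.cells:
        if cell.image is None or cell.roi is None:
            raise ValidationError(
                f"cell {cell.cell_id} has no rendered image; "
                "generate the dataset with render_images=True"
            )
        analysis = analyze_cell(cell.image, cell.roi, config)
        records.append(
            cell_record_from_analysis(cell.animal_id, cell.group, cell.cell_id, analysis)
        )
    return records


def per_cluster_table(analysis: CellAnalysis) -> pd.DataFrame:
    cs = analysis.cluster_set
    rows = []
    cru_of = {}
    for cru in analysis.crus:
        for cid in cru.member_cluster_ids:
            cru_of[cid] = cru.cru_id
    for k, c in enumerate(cs.clusters):
        cx, cy = c.centroid_nm
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "pixel_count": c.pixel_count,
                "area_nm2": c.area_nm2,
                "channels": c.channels,
                "centroid_x_nm": cx,
                "centroid_y_nm": cy,
                "nnd_nm": analysis.nnd_nm[k],
                "cru_id": cru_of.get(c.cluster_id),
            }
        )
    return pd.DataFrame(rows)


def per_cru_table(analysis: CellAnalysis) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cru_id": cru.cru_id,
                "n_clusters": cru.n_clusters,
                "total_channels": cru.total_channels,
                "member_cluster_ids": ";".join(map(str, cru.member_cluster_ids)),
            }
            for cru in analysis.crus
        ]
    )


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(
            {"config": self.config, "seed": self.seed, "outputs": self.outputs},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        body = dataclasses.asdict(self)
        body["manifest_hash"] = self.hash()
        path.write_text(json.dumps(body, indent=2, sort_keys=True))
        return path


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int = 0,
    write_images: bool = False,
) -> RunManifest:
    """Synthetic end-to-end run: generate, analyze, compare, and write tables.

    Writes per-cell records, per-cluster and per-CRU tables, the group
    comparison report, and a manifest with content hashes.  Byte-identical
    per-cluster and per-CRU tables across re-runs with the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), seed=seed, version=__version__)

    t0 = time.perf_counter()
    dataset = make_two_group_dataset(
        config.scene,
        config.emission,
        n_animals_per_group=config.n_animals_per_group,
        cells_per_animal=config.cells_per_animal,
        group_effect=config.group_effect,
        animal_rel_sd=config.animal_rel_sd,
        seed=seed,
        render_images=True,
        pixel_size_nm=config.analysis.pixel_size_nm,
        sigma_render_nm=config.sigma_render_nm,
        gain=config.gain,
    )
    manifest.timings_s["simulate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    records = []
    cluster_frames = []
    cru_frames = []
    for cell in dataset.cells:
        analysis = analyze_cell(cell.image, cell.roi, config.analysis)
        records.append(
            cell_record_from_analysis(cell.animal_id, cell.group, cell.cell_id, analysis)
        )
        ct = per_cluster_table(analysis)
        ct.insert(0, "cell_id", cell.cell_id)
        cluster_frames.append(ct)
        kt = per_cru_table(analysis)
        if len(kt):
            kt.insert(0, "cell_id", cell.cell_id)
            cru_frames.append(kt)
        if write_images:
            stem = out / cell.cell_id
            write_rendered_image(cell.image, stem.with_suffix(".tif"))
            write_roi_mask(cell.roi, f"{stem}_include.tif", f"{stem}_exclude.tif")
            write_localizations(cell.localizations, f"{stem}_localizations.csv")
    manifest.timings_s["analyze"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    frame = records_to_frame(records)
    comparisons = compare_all_metrics(frame, metrics=config.metrics)
    manifest.timings_s["compare"] = round(time.perf_counter() - t0, 3)

    tables = {
        "cell_records.csv": frame,
        "clusters.csv": pd.concat(cluster_frames, ignore_index=True),
        "crus.csv": (
            pd.concat(cru_frames, ignore_index=True) if cru_frames else pd.DataFrame()
        ),
        "comparisons.csv": comparisons_table(comparisons),
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        manifest.outputs[name] = _file_hash(path)
    manifest.write(out / "manifest.json")
    return manifest
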