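"""Nested two-group inference on per-cell metrics, plus densitometry.

Cells are the analysis unit but are nested within animals, so group
comparisons fit a linear mixed model with a fixed group effect and a random
intercept per animal (REML).  Densitometry uses an unpaired t-test on
per-sample means after collapsing technical replicates, which prevents
pseudo-replication.  Significance is two-sided at alpha = 0.05 with no
multiple-testing correction (per-metric reporting).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .errors import InferenceError, ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"

CELL_METRICS = [
    "mean_area_nm2",
    "mean_channels",
    "mean_nnd_nm",
    "density_per_um2",
    "mean_clusters_per_cru",
    "mean_channels_per_cru",
]


@dataclass
class CellRecord:
    """Per-cell metric values keyed by animal and group."""

    animal_id: str
    group: str
    cell_id: str
    metrics: dict[str, float] = field(default_factory=dict)


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"animal_id": r.animal_id, "group": r.group, "cell_id": r.cell_id}
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Result of one metric's two-group comparison."""

    metric: str
    control_mean: float
    control_sem: float
    disease_mean: float
    disease_sem: float
    difference: float  # disease - control
    percent_change: float  # (control - disease) / control * 100
    p_value: float
    model: str
    n_cells: dict[str, int] = field(default_factory=dict)
    n_animals: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False


def percent_change(control_mean: float, disease_mean: float) -> float:
    """Percent reduction of the disease mean relative to control.

    Returns (control_mean - disease_mean) / control_mean * 100; positive for
    a loss in the disease group.
    """
    if not control_mean > 0:
        raise ValidationError(f"control mean must be positive, got {control_mean}")
    return (control_mean - disease_mean) / control_mean * 100.0


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def compare_groups(
    records: list[CellRecord] | pd.DataFrame,
    metric: str,
    control_label: str = CONTROL,
) -> GroupComparison:
    """Mixed-model comparison of one per-cell metric between two groups.

    Fits ``metric ~ group`` with a random intercept per animal by REML and
    reports the Wald two-sided p-value of the fixed group effect.  Cells with
    a missing metric value are dropped.  A zero-variance metric is flagged as
    degenerate (difference per fit, p = 1) rather than crashing.

    Raises
    ------
    InferenceError
        If there are not exactly two groups, or fewer than two animals in
        either group.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if metric not in df.columns:
        raise ValidationError(f"metric {metric!r} not present in records")
    df = df[["animal_id", "group", "cell_id", metric]].dropna(subset=[metric]).copy()
    groups = sorted(df["group"].unique(), key=lambda g: g != control_label)
    if len(groups) != 2 or groups[0] != control_label:
        raise InferenceError(
            f"expected two groups including {control_label!r}, got {sorted(df['group'].unique())}"
        )
    control_label, disease_label = groups
    for g in groups:
        n_animals = df.loc[df["group"] == g, "animal_id"].nunique()
        if n_animals < 2:
            raise InferenceError(f"group {g!r} has {n_animals} animal(s); need >= 2")

    ctrl = df.loc[df["group"] == control_label, metric].to_numpy(dtype=float)
    dis = df.loc[df["group"] == disease_label, metric].to_numpy(dtype=float)
    diff = dis.mean() - ctrl.mean()

    one_cell_per_animal = df.groupby("animal_id")["cell_id"].count().max() == 1
    model_desc = "mixedlm: metric ~ group + (1 | animal), REML"
    degenerate = np.var(df[metric].to_numpy(dtype=float)) == 0.0
    if degenerate:
        logger.warning("metric %s has zero variance; comparison is degenerate", metric)
        p_value = 1.0
    elif one_cell_per_animal:
        # with a single cell per animal the animal and residual variances are
        # not separately identifiable; the nested model reduces to a
        # two-sample comparison of animals
        model_desc = "unpaired two-sided t-test (one cell per animal)"
        p_value = float(stats.ttest_ind(ctrl, dis).pvalue)
    else:
        df["is_disease"] = (df["group"] == disease_label).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(f"{metric} ~ is_disease", df, groups=df["animal_id"])
                fit = model.fit(reml=True)
            diff = float(fit.params["is_disease"])
            p_value = float(fit.pvalues["is_disease"])
        except np.linalg.LinAlgError:
            p_value = np.nan
        if not np.isfinite(p_value):
            # singular fits or variance components on a boundary can leave the
            # Wald p-value undefined; fall back to a cell-level t-test
            logger.warning("mixed model p-value undefined for %s; using t-test fallback", metric)
            model_desc = "t-test fallback (mixed model not identifiable)"
            p_value = float(stats.ttest_ind(ctrl, dis).pvalue)

    cm = float(ctrl.mean())
    dm = float(dis.mean())
    return GroupComparison(
        metric=metric,
        control_mean=cm,
        control_sem=_sem(ctrl),
        disease_mean=dm,
        disease_sem=_sem(dis),
        difference=float(diff),
        percent_change=percent_change(cm, dm) if cm > 0 else np.nan,
        p_value=p_value,
        model=model_desc,
        n_cells={control_label: len(ctrl), disease_label: len(dis)},
        n_animals={
            g: int(df.loc[df["group"] == g, "animal_id"].nunique()) for g in groups
        },
        degenerate=degenerate,
    )


def compare_all_metrics(
    records: list[CellRecord] | pd.DataFrame,
    metrics: list[str] | None = None,
    control_label: str = CONTROL,
) -> list[GroupComparison]:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if metrics is None:
        metrics = [m for m in CELL_METRICS if m in df.columns]
    return [compare_groups(df, m, control_label) for m in metrics]


# ---------------------------------------------------------------------------
# Densitometry
# ---------------------------------------------------------------------------

DENSITOMETRY_COLUMNS = [
    "sample_id",
    "group",
    "target_band_intensity",
    "loading_control_band_intensity",
    "replicate",
]


def densitometry_compare(
    table: pd.DataFrame,
    control_label: str = CONTROL,
) -> GroupComparison:
    """Unpaired t-test of loading-control-normalized band intensity.

    Each row is one technical replicate of one biological sample.  Normalized
    value = target / loading control; technical replicates are averaged per
    sample before testing so the biological sample is the unit of inference.
    """
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"densitometry table missing columns: {missing}")
    if (table["target_band_intensity"] <= 0).any() or (
        table["loading_control_band_intensity"] <= 0
    ).any():
        raise ValidationError("band intensities must be positive")
    t = table.copy()
    t["normalized"] = t["target_band_intensity"] / t["loading_control_band_intensity"]
    per_sample = t.groupby(["sample_id", "group"], as_index=False)["normalized"].mean()
    groups = sorted(per_sample["group"].unique(), key=lambda g: g != control_label)
    if len(groups) != 2 or groups[0] != control_label:
        raise InferenceError(f"expected two groups including {control_label!r}")
    disease_label = groups[1]
    ctrl = per_sample.loc[per_sample["group"] == control_label, "normalized"].to_numpy()
    dis = per_sample.loc[per_sample["group"] == disease_label, "normalized"].to_numpy()
    if len(ctrl) < 2 or len(dis) < 2:
        raise InferenceError("need at least two biological samples per group")
    if np.var(np.concatenate([ctrl, dis])) == 0.0:
        p_value = 1.0
    else:
        p_value = float(stats.ttest_ind(ctrl, dis).pvalue)
    cm, dm = float(ctrl.mean()), float(dis.mean())
    return GroupComparison(
        metric="normalized_expression",
        control_mean=cm,
        control_sem=_sem(ctrl),
        disease_mean=dm,
        disease_sem=_sem(dis),
        difference=dm - cm,
        percent_change=percent_change(cm, dm),
        p_value=p_value,
        model="unpaired two-sided t-test on per-sample means",
        n_cells={control_label: len(ctrl), disease_label: len(dis)},
        n_animals={control_label: len(ctrl), disease_label: len(dis)},
    )
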