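"""Calibration, recovery coefficients, threshold sweeps and volume estimation.

The sweep table is a pandas DataFrame with one row per
(sphere, method, threshold) combination — infeasible combinations are kept
as flagged rows, never dropped, so that detectability limits remain visible
in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SegmentationInfeasibleError
from .geometry import GridSpec, PhantomGeometry, VOIMask
from .segmentation import (
    DEFAULT_T_GRID,
    estimate_background,
    find_max,
    segment,
    sphere_search_region,
)
from .simulator import ActivityConfig, ImageVolume

__all__ = [
    "CalibrationResult",
    "QuantResult",
    "sensitivity_factor",
    "counts_to_concentration",
    "quantify",
    "recovery_coefficient",
    "sweep_thresholds",
    "max_in_voi_table",
    "select_best_threshold",
    "recovery_curve",
    "SWEEP_COLUMNS",
]

SWEEP_COLUMNS = [
    "sphere_id",
    "diameter_mm",
    "method",
    "threshold",
    "feasible",
    "reason",
    "ac_max",
    "ac_mean",
    "volume_cm3",
    "true_volume_cm3",
    "rc_max",
    "rc_mean",
    "rc_volume",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Sensitivity factor in cps per MBq per voxel, and its source image."""

    factor: float
    source: str = ""

    def __post_init__(self):
        if self.factor <= 0:
            raise InvalidArgumentError("sensitivity factor must be positive")


@dataclass(frozen=True)
class QuantResult:
    """Per-sphere measurements for one (method, threshold) combination."""

    sphere_id: str
    method: str
    threshold: float | None
    feasible: bool
    ac_max: float | None = None
    ac_mean: float | None = None
    volume_cm3: float | None = None
    rc_max: float | None = None
    rc_mean: float | None = None
    rc_volume: float | None = None
    reason: str = ""


def _central_cylinder_mask(grid: GridSpec, diameter_mm: float, length_mm: float) -> np.ndarray:
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    return (x**2 + y**2 <= (diameter_mm / 2.0) ** 2) & (np.abs(z) <= length_mm / 2.0)


def sensitivity_factor(
    uniform_image: ImageVolume,
    true_concentration_mbq_per_ml: float,
    duration_s: float,
    grid: GridSpec | None = None,
    roi_diameter_mm: float = 100.0,
    roi_length_mm: float = 60.0,
) -> CalibrationResult:
    """Camera calibration from a uniformly filled phantom acquisition.

    Mean counts per voxel are read in a central cylindrical ROI and divided
    by duration and by the activity contained in one voxel, yielding cps per
    MBq per voxel.
    """
    if uniform_image.value_unit != "counts":
        raise InvalidArgumentError("calibration image must be in counts")
    if true_concentration_mbq_per_ml <= 0:
        raise InvalidArgumentError("true concentration must be positive")
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    grid = grid or uniform_image.grid
    roi = _central_cylinder_mask(grid, roi_diameter_mm, roi_length_mm)
    if not roi.any():
        raise InvalidArgumentError("calibration ROI is empty on this grid")
    mean_counts = float(uniform_image.values[roi].mean())
    mbq_per_voxel = true_concentration_mbq_per_ml * grid.voxel_volume_ml
    factor = (mean_counts / duration_s) / mbq_per_voxel
    return CalibrationResult(
        factor=factor, source=str(uniform_image.provenance.get("seed", ""))
    )


def counts_to_concentration(
    image: ImageVolume, cal: CalibrationResult, duration_s: float
) -> ImageVolume:
    """Counts -> kBq/mL using the measured sensitivity factor."""
    if image.value_unit != "counts":
        raise InvalidArgumentError(f"expected a counts image, got {image.value_unit!r}")
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    mbq_per_ml = (image.values / duration_s) / (cal.factor * image.grid.voxel_volume_ml)
    out = image.with_values(mbq_per_ml * 1000.0, calibrated_with=cal.factor)
    out.value_unit = "kBq/mL"
    return out


def quantify(image: ImageVolume, mask: VOIMask, grid: GridSpec | None = None):
    """(AC_max, AC_mean, volume cm^3) over a VOI."""
    grid = grid or image.grid
    if mask.voxel_count == 0:
        raise SegmentationInfeasibleError("empty VOI")
    values = image.values[mask.mask]
    volume = mask.voxel_count * grid.voxel_volume_ml
    return float(values.max()), float(values.mean()), float(volume)


def recovery_coefficient(measured: float, true: float) -> float:
    """Measured-to-true ratio; units must match."""
    if true <= 0:
        raise InvalidArgumentError("true value must be positive")
    return measured / true


def _row(result: QuantResult, diameter: float, true_volume: float) -> dict:
    def num(v):
        return np.nan if v is None else float(v)

    return {
        "sphere_id": result.sphere_id,
        "diameter_mm": diameter,
        "method": result.method,
        "threshold": num(result.threshold),
        "feasible": result.feasible,
        "reason": result.reason,
        "ac_max": num(result.ac_max),
        "ac_mean": num(result.ac_mean),
        "volume_cm3": num(result.volume_cm3),
        "true_volume_cm3": true_volume,
        "rc_max": num(result.rc_max),
        "rc_mean": num(result.rc_mean),
        "rc_volume": num(result.rc_volume),
    }


def sweep_thresholds(
    image: ImageVolume,
    geometry: PhantomGeometry,
    method: str,
    activity: ActivityConfig | None = None,
    sphere_ids: list[str] | None = None,
    t_grid=DEFAULT_T_GRID,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """One QuantResult row per sphere x threshold (or per sphere for ct).

    Recovery coefficients are filled in when the true activity is supplied;
    infeasible combinations are flagged via ``feasible``/``reason``.
    """
    grid = grid or image.grid
    if method in ("ct", "ct3d"):
        t_values: list[float | None] = [None]
    else:
        t_values = [float(t) for t in t_grid]
        if any(not 0 < t < 1 for t in t_values):
            raise InvalidArgumentError("threshold grid must lie in (0, 1)")
    sphere_ids = sphere_ids or [s.id for s in geometry.spheres]
    true_conc = activity.sphere_concentration if activity is not None else None

    rows = []
    for sphere_id in sphere_ids:
        sphere = geometry.sphere(sphere_id)
        for t in t_values:
            try:
                mask = segment(image, geometry, sphere_id, method, T=t, grid=grid)
                ac_max, ac_mean, volume = quantify(image, mask, grid)
            except SegmentationInfeasibleError as exc:
                rows.append(
                    _row(
                        QuantResult(sphere_id, method, t, False, reason=exc.reason),
                        sphere.inner_diameter,
                        sphere.true_volume,
                    )
                )
                continue
            result = QuantResult(
                sphere_id,
                method,
                t,
                True,
                ac_max=ac_max,
                ac_mean=ac_mean,
                volume_cm3=volume,
                rc_max=recovery_coefficient(ac_max, true_conc) if true_conc else None,
                rc_mean=recovery_coefficient(ac_mean, true_conc) if true_conc else None,
                rc_volume=recovery_coefficient(volume, sphere.true_volume),
            )
            rows.append(_row(result, sphere.inner_diameter, sphere.true_volume))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def max_in_voi_table(
    image: ImageVolume,
    geometry: PhantomGeometry,
    activity: ActivityConfig | None = None,
    sphere_ids: list[str] | None = None,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Maximum-in-search-region quantification, one row per sphere.

    This is the "maximum value in the VOI" method: no mask is grown, only
    AC_max within the sphere search box is read off.
    """
    grid = grid or image.grid
    sphere_ids = sphere_ids or [s.id for s in geometry.spheres]
    true_conc = activity.sphere_concentration if activity is not None else None
    rows = []
    for sphere_id in sphere_ids:
        sphere = geometry.sphere(sphere_id)
        region = sphere_search_region(grid, geometry, sphere_id)
        est = find_max(image, region)
        result = QuantResult(
            sphere_id,
            "max",
            None,
            True,
            ac_max=est.value,
            rc_max=recovery_coefficient(est.value, true_conc) if true_conc else None,
        )
        rows.append(_row(result, sphere.inner_diameter, sphere.true_volume))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def select_best_threshold(table: pd.DataFrame, criterion: str = "concentration"):
    """Best threshold per the chosen criterion; ties go to the lower T.

    'concentration': one T per (method[, sbr]) minimizing the median of
    |RC_mean - 1| over feasible spheres — a robust reading of "best for the
    majority of the spheres".
    'volume': one T per sphere (and method[, sbr]) minimizing the absolute
    volume error against the true sphere volume.
    """
    if criterion not in ("concentration", "volume"):
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")
    t = table[table["threshold"].notna()]
    feasible = t[t["feasible"]]
    if feasible.empty:
        raise SegmentationInfeasibleError("no feasible rows in the sweep table")

    # seeds are replicates: pooled within each (method[, sbr]) group
    group_keys = [k for k in ("preset", "method", "sbr") if k in t.columns]
    if criterion == "volume":
        group_keys = group_keys + ["sphere_id", "diameter_mm"]

    records = []
    for keys, grp in feasible.groupby(group_keys, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        if criterion == "concentration":
            score = (
                grp.assign(err=(grp["rc_mean"] - 1.0).abs())
                .groupby("threshold")["err"]
                .median()
            )
        else:
            score = (
                grp.assign(err=(grp["volume_cm3"] - grp["true_volume_cm3"]).abs())
                .groupby("threshold")["err"]
                .mean()
            )
        best_t = score[score == score.min()].index.min()  # tie -> lower T
        records.append(
            dict(zip(group_keys, keys))
            | {"best_threshold": float(best_t), "score": float(score.min())}
        )
    return pd.DataFrame(records)


def recovery_curve(
    table: pd.DataFrame,
    method: str,
    statistic: str = "mean",
    threshold: float | None = None,
) -> pd.DataFrame:
    """(diameter, RC) series for one method, sorted by ascending diameter.

    For threshold methods, rows are taken at ``threshold`` when given,
    otherwise at the concentration-criterion best threshold.  ``statistic``
    selects RC_max or RC_mean.
    """
    if statistic not in ("max", "mean"):
        raise InvalidArgumentError("statistic must be 'max' or 'mean'")
    rc_col = f"rc_{statistic}"
    rows = table[table["method"] == method]
    if rows.empty:
        raise InvalidArgumentError(f"no rows for method {method!r}")
    if rows["threshold"].notna().any():
        if threshold is None:
            best = select_best_threshold(rows, "concentration")
            threshold = float(best["best_threshold"].iloc[0])
        rows = rows[np.isclose(rows["threshold"].astype(float), threshold)]
    out = rows[rows["feasible"]][["diameter_mm", "sphere_id", rc_col]]
    out = out.rename(columns={rc_col: "rc"}).sort_values("diameter_mm")
    out.insert(1, "threshold", threshold)
    return out.reset_index(drop=True)
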