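"""Line profiles, detectability scoring and the batch experiment driver."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CoverageError, InvalidArgumentError
from .geometry import PhantomGeometry, default_nema_geometry, uniform_geometry, voxelize
from .quantification import (
    counts_to_concentration,
    max_in_voi_table,
    select_best_threshold,
    sensitivity_factor,
    sweep_thresholds,
)
from .segmentation import DEFAULT_T_GRID, BackgroundEstimate, estimate_background
from .simulator import ActivityConfig, ImageVolume, preset, simulate

__all__ = [
    "LineProfile",
    "ExperimentPlan",
    "line_profile",
    "default_profile_endpoints",
    "peak_contrast",
    "sphere_profile_score",
    "run_experiment",
    "DEFAULT_SBR_LEVELS",
]

log = logging.getLogger(__name__)

DEFAULT_SBR_LEVELS = ("NB", "5:1", "2.5:1", "1.25:1")

#: Contrast-to-noise score above which a sphere is flagged detectable
#: (Rose-criterion-style convention; not a visual-reading equivalent).
DETECTABILITY_SCORE = 4.0


@dataclass(frozen=True)
class LineProfile:
    """Image samples along a straight segment, positions in mm from start."""

    positions: np.ndarray
    values: np.ndarray
    start: tuple[float, float, float]
    end: tuple[float, float, float]

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidArgumentError("profile positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("profile values must be finite")


def line_profile(image: ImageVolume, start, end, step: float = 1.0) -> LineProfile:
    """Trilinear interpolation of the image along a segment.

    Samples run from ``start`` to ``end`` inclusive at the given step (mm);
    both endpoints must lie inside the grid extent.
    """
    if step <= 0:
        raise InvalidArgumentError("step must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for p in (start, end):
        if not image.grid.contains_point(p):
            raise CoverageError(f"profile endpoint {tuple(p)} outside the grid")
    length = float(np.linalg.norm(end - start))
    n = max(int(np.floor(length / step + 1e-9)) + 1, 2)
    positions = np.linspace(0.0, length, n)
    points = start[None, :] + (positions / length)[:, None] * (end - start)[None, :]
    idx = np.stack([image.grid.world_to_index(p) for p in points], axis=1)
    values = ndimage.map_coordinates(image.values, idx, order=1, mode="nearest")
    return LineProfile(positions=positions, values=values, start=tuple(start), end=tuple(end))


def default_profile_endpoints(
    geometry: PhantomGeometry, margin_mm: float = 30.0
) -> tuple[tuple, tuple]:
    """Segment through the centres of the 37- and 17-mm spheres, extended
    by a margin on both sides (they are diametrically opposite by default)."""
    a = np.asarray(geometry.sphere("sphere_37mm").center, dtype=float)
    b = np.asarray(geometry.sphere("sphere_17mm").center, dtype=float)
    u = (b - a) / np.linalg.norm(b - a)
    return tuple(a - margin_mm * u), tuple(b + margin_mm * u)


def peak_contrast(profile_peak: float, background: float, noise_sd: float) -> float:
    """(peak - BG) / noise SD; the detectability flag uses score >= 4."""
    if noise_sd <= 0:
        raise InvalidArgumentError("noise_sd must be positive")
    return (profile_peak - background) / noise_sd


def sphere_profile_score(
    image: ImageVolume,
    geometry: PhantomGeometry,
    sphere_id: str,
    background: "BackgroundEstimate | None" = None,
    margin_mm: float = 25.0,
):
    """Line-profile contrast-to-noise score for one sphere.

    A radial profile (phantom centre through the sphere centre, in the
    sphere plane) is sampled at half the smallest voxel size; the peak is
    the profile maximum within the sphere extent, and the noise SD is the
    pooled background-ROI voxel SD.  Returns (score, peak, background).
    """
    sphere = geometry.sphere(sphere_id)
    c = np.asarray(sphere.center, dtype=float)
    u = c[:2] / np.linalg.norm(c[:2])
    direction = np.array([u[0], u[1], 0.0])
    start = c - (sphere.radius + margin_mm) * direction
    end = c + (sphere.radius + margin_mm) * direction
    prof = line_profile(image, start, end, step=min(image.grid.spacing) / 2.0)
    mid = float(np.linalg.norm(c - start))
    inside = np.abs(prof.positions - mid) <= sphere.radius
    peak = float(prof.values[inside].max())
    bg = background if background is not None else estimate_background(image, geometry)
    if bg.roi_std > 0:
        score = peak_contrast(peak, bg.value, bg.roi_std)
    else:
        score = np.inf if peak > bg.value else 0.0
    return score, peak, bg.value


@dataclass
class ExperimentPlan:
    """Cross of modality presets and SBR levels, replicated over seeds."""

    presets: tuple[str, ...] = ("spect-in111", "pet-ga68")
    sbr_levels: tuple[str, ...] = DEFAULT_SBR_LEVELS
    seeds: tuple[int, ...] = tuple(range(1, 11))
    sphere_concentration: float = 20.0  # kBq/mL
    t_grid: tuple[float, ...] = DEFAULT_T_GRID
    methods: tuple[str, ...] = ("threshold", "adapted", "ct")
    subsampling: int = 2
    out_dir: str = "results"

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [(p, s) for p in self.presets for s in self.sbr_levels]

    def to_dict(self) -> dict:
        return {
            "presets": list(self.presets),
            "sbr_levels": list(self.sbr_levels),
            "seeds": list(self.seeds),
            "sphere_concentration": self.sphere_concentration,
            "t_grid": list(self.t_grid),
            "methods": list(self.methods),
            "subsampling": self.subsampling,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        plan = cls()
        kwargs = {}
        for key in plan.to_dict():
            if key in d:
                value = d[key]
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)


def _calibration_for(preset_name: str, grid, acq, plan: ExperimentPlan, seed: int):
    """Sensitivity calibration from a uniformly filled phantom acquisition."""
    geom = uniform_geometry()
    fractions = voxelize(geom, grid, subsampling=plan.subsampling)
    conc = plan.sphere_concentration / 4.0  # arbitrary uniform fill level
    image = simulate(geom, grid, ActivityConfig(0.0, conc), acq, seed=seed, fractions=fractions)
    return sensitivity_factor(image, conc / 1000.0, acq.duration, grid)


def run_experiment(plan: ExperimentPlan, geometry: PhantomGeometry | None = None) -> dict:
    """Run the full matrix: simulate, segment, quantify, sweep, select.

    Writes per-cell sweep CSVs, per-cell line profiles, a combined summary
    CSV and a JSON manifest to ``plan.out_dir``; returns the manifest dict.
    Per-cell failures are logged and recorded, not fatal for the batch.
    """
    geometry = geometry or default_nema_geometry()
    out_dir = Path(plan.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_rows: list[pd.DataFrame] = []
    manifest: dict = {"plan": plan.to_dict(), "cells": [], "errors": []}

    for preset_name in plan.presets:
        grid, acq = preset(preset_name)
        fractions = voxelize(geometry, grid, subsampling=plan.subsampling)
        calibration = None
        if acq.modality == "spect-like":
            calibration = _calibration_for(preset_name, grid, acq, plan, seed=0)
            manifest[f"sensitivity_factor_{preset_name}"] = calibration.factor
        p_start, p_end = default_profile_endpoints(geometry)
        for sbr in plan.sbr_levels:
            activity = ActivityConfig.from_sbr(sbr, plan.sphere_concentration)
            cell_rows = []
            profiles = []
            detect_rows = []
            for seed in plan.seeds:
                try:
                    image = simulate(
                        geometry, grid, activity, acq, seed=seed, fractions=fractions
                    )
                    if calibration is not None:
                        image = counts_to_concentration(image, calibration, acq.duration)
                    tables = [
                        sweep_thresholds(
                            image, geometry, m, activity=activity, t_grid=plan.t_grid
                        )
                        for m in plan.methods
                    ]
                    tables.append(max_in_voi_table(image, geometry, activity=activity))
                    table = pd.concat(tables, ignore_index=True)
                    table.insert(0, "preset", preset_name)
                    table.insert(1, "sbr", sbr)
                    table.insert(2, "seed", seed)
                    cell_rows.append(table)
                    profiles.append(_profile_record(image, p_start, p_end, seed))
                    detect_rows.extend(_detectability(image, geometry, sbr, seed))
                except Exception as exc:  # per-cell robustness
                    log.exception("cell %s/%s seed %s failed", preset_name, sbr, seed)
                    manifest["errors"].append(
                        {"preset": preset_name, "sbr": sbr, "seed": seed, "error": str(exc)}
                    )
            if not cell_rows:
                continue
            cell = pd.concat(cell_rows, ignore_index=True)
            stem = f"{preset_name}_{sbr.replace(':', 'to').replace('.', 'p')}"
            sweep_path = out_dir / f"sweep_{stem}.csv"
            cell.to_csv(sweep_path, index=False, float_format="%.6g")
            prof_path = out_dir / f"profiles_{stem}.csv"
            pd.DataFrame(profiles).explode(["position_mm", "value"]).to_csv(
                prof_path, index=False, float_format="%.6g"
            )
            detect_path = out_dir / f"detectability_{stem}.csv"
            pd.DataFrame(detect_rows).to_csv(detect_path, index=False, float_format="%.6g")
            best = _best_thresholds(cell)
            cell_entry = {
                "preset": preset_name,
                "sbr": sbr,
                "sweep_csv": sweep_path.name,
                "profiles_csv": prof_path.name,
                "detectability_csv": detect_path.name,
                "best_thresholds": best,
            }
            manifest["cells"].append(cell_entry)
            all_rows.append(cell)

    if all_rows:
        combined = pd.concat(all_rows, ignore_index=True)
        combined.to_csv(out_dir / "sweep_all.csv", index=False, float_format="%.6g")
        manifest["combined_csv"] = "sweep_all.csv"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _profile_record(image, start, end, seed) -> dict:
    step = min(image.grid.spacing) / 2.0
    prof = line_profile(image, start, end, step=step)
    return {
        "seed": seed,
        "position_mm": list(np.round(prof.positions, 4)),
        "value": list(prof.values),
    }


def _detectability(image, geometry, sbr, seed) -> list[dict]:
    bg = estimate_background(image, geometry)
    rows = []
    for sphere in geometry.spheres:
        score, _, _ = sphere_profile_score(image, geometry, sphere.id, background=bg)
        rows.append(
            {
                "sbr": sbr,
                "seed": seed,
                "sphere_id": sphere.id,
                "diameter_mm": sphere.inner_diameter,
                "score": score,
                "detectable": bool(score >= DETECTABILITY_SCORE),
            }
        )
    return rows


def _best_thresholds(cell: pd.DataFrame) -> dict:
    out = {}
    try:
        conc = select_best_threshold(cell[cell["method"].isin(["threshold", "adapted"])], "concentration")
        out["concentration"] = conc.to_dict(orient="records")
    except Exception as exc:
        out["concentration"] = f"infeasible: {exc}"
    try:
        vol = select_best_threshold(cell[cell["method"] == "threshold"], "volume")
        out["volume"] = vol.to_dict(orient="records")
    except Exception as exc:
        out["volume"] = f"infeasible: {exc}"
    return out
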