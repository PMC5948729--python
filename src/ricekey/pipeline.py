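"""End-to-end workflows: calibration, key-period selection, stress mapping.

The functions here orchestrate the library modules behind a single
configuration object: calibrate the stress factor against field root
weights, pick the key assimilation period from the season's LAI curves,
select the nearest acquisitions, run the per-pixel LAI assimilation to
map the stress factor, and compare an all-images period against the
key-point period.  Every run writes a manifest (config hash, seed,
outputs) so it can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .assimilation import (AssimilationResult, ObservationSet, PSOConfig,
                           StressFactorSummary, estimate_stress_factor, mae,
                           r_squared, summarize_stress)
from .crop_model import (CropParameters, InputError, SimulationResult,
                         WeatherSeries, default_crop_parameters,
                         phenology_schedule, run_simulation,
                         simulate_from_schedule)
from .keyperiod import (DominantPointSet, find_dominant_points, growth_rate,
                        ratio_curve, screen_points, select_images,
                        fit_dominant_points)
from .retrieval import MultispectralScene, gbndvi, lai_from_gbndvi

__all__ = [
    "PipelineConfig",
    "StressMapSeries",
    "run_calibration",
    "run_keyperiod",
    "run_rs_assimilation",
    "compare_periods",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A workflow could not be completed (missing scenes, empty mask...)."""


@dataclass
class PipelineConfig:
    """Paths and settings driving the workflows.

    Any path may be None when the corresponding workflow is not used.
    ``keyperiod`` and ``pso`` hold the detector and optimizer settings;
    ``seed`` feeds every stochastic component.
    """

    weather_path: str | None = None
    params_path: str | None = None
    observations_path: str | None = None
    scene_paths: list = dc_field(default_factory=list)
    output_dir: str = "."
    start_doy: int | None = None
    n_days: int = 100
    keyperiod: dict = dc_field(default_factory=dict)
    pso: dict = dc_field(default_factory=dict)
    scene_match_window: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def load_weather(self) -> WeatherSeries:
        if not self.weather_path:
            raise InputError("config is missing weather_path")
        if not Path(self.weather_path).exists():
            raise InputError(f"weather file not found: {self.weather_path}")
        return WeatherSeries.from_csv(self.weather_path)

    def load_params(self) -> CropParameters:
        if not self.params_path:
            return default_crop_parameters()
        if not Path(self.params_path).exists():
            raise InputError(f"crop parameter file not found: {self.params_path}")
        return CropParameters.from_file(self.params_path)

    def load_observations(self) -> ObservationSet:
        if not self.observations_path:
            raise InputError("config is missing observations_path")
        if not Path(self.observations_path).exists():
            raise InputError(f"observations file not found: {self.observations_path}")
        return ObservationSet.from_csv(self.observations_path)

    def pso_config(self) -> PSOConfig:
        kwargs = dict(self.pso)
        kwargs.setdefault("seed", self.seed)
        if "bounds" in kwargs:
            kwargs["bounds"] = tuple(kwargs["bounds"])
        return PSOConfig(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StressMapSeries:
    """Per-pixel stress-factor map plus WRT rasters at requested DOYs."""

    f_map: np.ndarray
    mask: np.ndarray
    wrt_maps: dict  # doy -> g m^-2 raster
    summary: StressFactorSummary


def _write_manifest(config: PipelineConfig, workflow: str, outputs: list[str]) -> None:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"workflow": workflow, "config_sha256": config.digest(),
                "seed": config.seed, "outputs": outputs}
    with open(out_dir / f"manifest_{workflow}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def run_calibration(config: PipelineConfig
                    ) -> tuple[AssimilationResult, SimulationResult, dict]:
    """Estimate f from field WRT observations and rerun the model at f-hat.

    Writes the daily simulated series and a metrics report (R^2 and MAE of
    simulated vs measured WRT at the observation dates).
    """
    weather = config.load_weather()
    params = config.load_params()
    obs = config.load_observations()
    if obs.kind != "WRT":
        raise InputError("calibration requires WRT observations")
    start = config.start_doy if config.start_doy is not None else int(weather.doy[0])
    result = estimate_stress_factor(obs, weather, params, config.pso_config(),
                                    start_doy=start, n_days=config.n_days)
    sim = run_simulation(weather, params, result.f_hat, start, config.n_days)
    sim_at_obs = sim.series_at(obs.doy, "WRT")
    metrics = {"f_hat": result.f_hat.f, "cost": result.cost,
               "n_obs": result.n_obs,
               "r_squared": r_squared(sim_at_obs, obs.value),
               "mae": mae(sim_at_obs, obs.value)}
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim.to_csv(out_dir / "calibrated_simulation.csv")
    result.to_json(out_dir / "assimilation_result.json")
    with open(out_dir / "calibration_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    _write_manifest(config, "calibrate",
                    ["calibrated_simulation.csv", "assimilation_result.json",
                     "calibration_metrics.json"])
    return result, sim, metrics


def run_keyperiod(config: PipelineConfig, lai_reference: np.ndarray,
                  lai_stressed: np.ndarray,
                  start_doy: int) -> tuple[DominantPointSet, dict]:
    """Detect and screen dominant points on the stressed and ratio curves.

    Applies the rasterize-smooth-Harris-detect chain to the stressed LAI
    curve and to the stressed/reference ratio curve, merges the two point
    sets with the growth-rate screen, and reports the piecewise-linear fit
    R^2 of the merged points on the stressed curve.
    """
    kp = dict(config.keyperiod)
    detector = {key: kp[key] for key in
                ("y_step", "smooth_sigma", "k", "sigma_deriv", "sigma_window",
                 "window", "rel_threshold") if key in kp}
    pts_lai = find_dominant_points(lai_stressed, start_doy, source="LAI",
                                   **detector)
    ratio, offset = ratio_curve(lai_stressed, lai_reference,
                                epsilon=kp.get("ratio_epsilon", 0.05))
    pts_ratio = find_dominant_points(ratio, start_doy + offset, source="RATIO",
                                     **detector)
    logger.info("keyperiod: LAI curve points %s; ratio curve points %s",
                pts_lai.doys.tolist(), pts_ratio.doys.tolist())
    if len(pts_lai) == 0 or len(pts_ratio) == 0:
        raise PipelineError("no dominant points detected on one of the curves")
    gr = growth_rate(lai_stressed)
    merged = screen_points(pts_lai, pts_ratio, gr, start_doy + 1,
                           match_tol=kp.get("match_tol", 2),
                           compete_window=kp.get("compete_window", 30))
    _, fit_r2 = fit_dominant_points(lai_stressed, start_doy, merged)
    report = {"points_lai": pts_lai.doys.tolist(),
              "points_ratio": pts_ratio.doys.tolist(),
              "merged": merged.doys.tolist(), "fit_r_squared": fit_r2}
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged.to_csv(out_dir / "key_points.csv")
    with open(out_dir / "keyperiod_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(config, "keyperiod", ["key_points.csv", "keyperiod_report.json"])
    return merged, report


def _scene_lai_stack(scenes: list[MultispectralScene]) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Retrieve an LAI raster per scene; returns (stack, mask, doys)."""
    mask = scenes[0].mask
    stack = []
    for sc in scenes:
        if sc.mask.shape != mask.shape or not np.array_equal(sc.mask, mask):
            raise InputError("all scenes must share one rice mask")
        raster = lai_from_gbndvi(gbndvi(sc), doy=sc.doy, mask=sc.mask)
        stack.append(raster.lai)
    return np.stack(stack), mask, [sc.doy for sc in scenes]


def run_rs_assimilation(config: PipelineConfig,
                        scenes: list[MultispectralScene],
                        key_points, weather: WeatherSeries | None = None,
                        params: CropParameters | None = None,
                        output_doys=()) -> StressMapSeries:
    """Per-pixel stress-factor mapping from scene-retrieved LAI.

    For each key point the nearest scene within ``scene_match_window``
    days is selected; each unmasked pixel's LAI observations at those
    dates are assimilated independently (no spatial coupling) to estimate
    its f, and WRT rasters are produced at ``output_doys``.
    """
    if weather is None:
        weather = config.load_weather()
    if params is None:
        params = config.load_params()
    if not scenes:
        raise PipelineError("no scenes supplied")
    doys_avail = [sc.doy for sc in scenes]
    wanted = (key_points.doys if isinstance(key_points, DominantPointSet)
              else list(key_points))
    uncovered = [int(p) for p in wanted
                 if min(abs(d - int(p)) for d in doys_avail) > config.scene_match_window]
    if uncovered:
        raise PipelineError(
            f"no scene within +-{config.scene_match_window} days of key point(s) "
            f"{uncovered}")
    selected = select_images(doys_avail, wanted)
    use = [sc for sc in scenes if sc.doy in selected]
    logger.info("rs-assimilation: %d/%d scenes selected at DOYs %s",
                len(use), len(scenes), selected)

    lai_stack, mask, doys = _scene_lai_stack(use)
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise PipelineError("rice mask excludes every pixel")
    logger.info("rs-assimilation: assimilating %d masked-in pixels", n_pix)

    start = config.start_doy if config.start_doy is not None else int(weather.doy[0])
    schedule = phenology_schedule(weather, params, start, config.n_days)
    pso = config.pso_config()
    doy_arr = np.asarray(doys, int)

    from .assimilation import cost_lai, pso_minimize

    f_map = np.full(mask.shape, np.nan)
    rows, cols = np.nonzero(mask)
    for i, j in zip(rows, cols):
        obs = ObservationSet("LAI", doy_arr, lai_stack[:, i, j])

        def objective(f: float, _obs=obs) -> float:
            return cost_lai(_obs, simulate_from_schedule(schedule, f))

        res = pso_minimize(objective, pso)
        f_map[i, j] = res.f_hat.f

    summary = summarize_stress(f_map[mask])
    wrt_maps = {}
    f_values = np.unique(f_map[mask])
    wrt_by_f = {}
    for doy in output_doys:
        wrt_maps[int(doy)] = np.full(mask.shape, np.nan)
    if len(output_doys):
        for fv in f_values:
            sim = simulate_from_schedule(schedule, float(fv))
            wrt_by_f[fv] = sim.series_at(list(output_doys), "WRT")
        for i, j in zip(rows, cols):
            for d_i, doy in enumerate(output_doys):
                wrt_maps[int(doy)][i, j] = wrt_by_f[f_map[i, j]][d_i]
    return StressMapSeries(f_map, mask, wrt_maps, summary)


def compare_periods(config: PipelineConfig, scenes: list[MultispectralScene],
                    period_all, period_key,
                    true_wrt: dict | None = None,
                    weather: WeatherSeries | None = None,
                    params: CropParameters | None = None) -> dict:
    """Run the RS assimilation under two acquisition periods and compare.

    ``true_wrt`` optionally maps DOY -> ground-truth WRT raster (g m^-2);
    when given, per-period R^2 and MAE of the simulated WRT against it are
    reported over the masked-in pixels.
    """
    reports = {}
    eval_doys = sorted(true_wrt) if true_wrt else []
    for name, period in (("period_I", period_all), ("period_II", period_key)):
        result = run_rs_assimilation(config, scenes, period, weather=weather,
                                     params=params, output_doys=eval_doys)
        rep = {"n_scenes": len(select_images([sc.doy for sc in scenes], period)),
               "f_summary": result.summary.__dict__}
        if true_wrt:
            sim_vals = np.concatenate(
                [result.wrt_maps[d][result.mask] for d in eval_doys])
            true_vals = np.concatenate(
                [np.asarray(true_wrt[d])[result.mask] for d in eval_doys])
            rep["r_squared"] = r_squared(sim_vals, true_vals)
            rep["mae"] = mae(sim_vals, true_vals)
        reports[name] = rep
    return reports
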