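"""Synthetic study-condition generators: weather, observations, scenes.

Everything needed to exercise the toolkit without field or satellite
data: subtropical-monsoon daily weather, noisy root-weight or LAI
observation campaigns sampled from a known-stress crop run,
piecewise-linear curves with known corner positions, and small
multi-zone 4-band reflectance scenes whose GBNDVI encodes a prescribed
LAI field.  Every generator is a pure function of its arguments and
seed.

The default fixture mirrors a two-area field design: a near-clean
reference zone (f = 0.984) and a stressed zone (f = 0.850), a 100-day
season starting DOY 170, and observation campaigns on DOYs
184/211/241/260.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crop_model import (CropParameters, InputError, StressFactor,
                         WeatherSeries, default_crop_parameters, run_simulation)
from .assimilation import ObservationSet
from .retrieval import MultispectralScene, invert_lai_to_gbndvi

__all__ = [
    "SyntheticSceneSpec",
    "generate_weather",
    "generate_observations",
    "generate_breakpoint_curve",
    "generate_scene",
    "two_zone_map",
    "DEFAULT_START_DOY",
    "DEFAULT_SEASON_DAYS",
    "DEFAULT_OBS_DOYS",
    "REFERENCE_F",
    "STRESSED_F",
]

DEFAULT_START_DOY = 170
DEFAULT_SEASON_DAYS = 100
#: field campaign dates of the emulated study design
DEFAULT_OBS_DOYS = (184, 211, 241, 260)
#: average stress factors of the clean and polluted zones being emulated
REFERENCE_F = 0.984
STRESSED_F = 0.850

#: fixed scene brightness: NIR + G + B per pixel (mid-range vegetation albedo)
SCENE_BRIGHTNESS = 0.6
#: red band is unused by GBNDVI; filled with a vegetation-plausible constant
SCENE_RED = 0.05


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Recipe for a multi-zone synthetic scene stack.

    ``zone_map`` assigns each pixel its true stress factor; scenes are
    produced at each observation DOY with optional reflectance noise.
    """

    zone_map: np.ndarray
    obs_doys: tuple = DEFAULT_OBS_DOYS
    reflectance_sd: float = 0.0
    observation_rel_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        zm = np.asarray(self.zone_map, dtype=float)
        if zm.ndim != 2 or min(zm.shape) < 2:
            raise InputError("zone_map must be a 2-D grid of shape >= 2x2")
        if np.any((zm <= 0) | (zm > 1)):
            raise InputError("zone stress factors must lie in (0, 1]")
        object.__setattr__(self, "zone_map", zm)


def generate_weather(n_days: int = DEFAULT_SEASON_DAYS,
                     start_doy: int = DEFAULT_START_DOY,
                     seed: int = 0) -> WeatherSeries:
    """Subtropical-monsoon summer weather: warm, bright, mildly noisy.

    Mean temperature follows an annual sinusoid peaking near 29 degrees C
    in midsummer (annual mean ~17 degrees C scaled to the growing season),
    with seeded day-to-day variability; radiation is positive with summer
    values around 14-22 MJ m^-2 d^-1.
    """
    if n_days < 1:
        raise InputError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    doy = np.arange(start_doy, start_doy + n_days)
    tmean = (22.0 + 7.0 * np.sin(2 * np.pi * (doy - 110) / 365.0)
             + rng.normal(0.0, 1.5, n_days))
    trange = np.clip(8.0 + rng.normal(0.0, 1.0, n_days), 2.0, 14.0)
    radiation = np.clip(18.0 + 4.0 * np.sin(2 * np.pi * (doy - 172) / 365.0)
                        + rng.normal(0.0, 3.0, n_days), 2.0, None)
    return WeatherSeries(doy, tmean - trange / 2, tmean + trange / 2, radiation)


def generate_observations(weather: WeatherSeries, params: CropParameters,
                          f_true: float, doys=DEFAULT_OBS_DOYS,
                          rel_noise: float = 0.0, seed: int = 0,
                          kind: str = "WRT",
                          start_doy: int | None = None,
                          n_days: int = DEFAULT_SEASON_DAYS) -> ObservationSet:
    """Sample a known-stress crop run at the campaign dates, with noise.

    Noise is multiplicative lognormal with relative standard deviation
    ``rel_noise`` (0 returns exact model values), emulating destructive
    sampling scatter in root weights or canopy-analyzer LAI readings.
    """
    StressFactor(f_true)
    if start_doy is None:
        start_doy = int(weather.doy[0])
    sim = run_simulation(weather, params, f_true, start_doy, n_days)
    values = sim.series_at(doys, kind)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(rel_noise ** 2))
        values = values * rng.lognormal(-0.5 * sigma ** 2, sigma, len(values))
    return ObservationSet(kind, np.asarray(doys, int), values)


def generate_breakpoint_curve(breaks, n_days: int = 100, start_value: float = 0.0
                              ) -> tuple[np.ndarray, list[int]]:
    """Continuous piecewise-linear curve with prescribed slope changes.

    ``breaks`` is a list of (day, slope) pairs: each slope applies from its
    day onward; the first pair must start at day 0.  Returns the series and
    the interior corner days (ground truth for localization tests).
    """
    breaks = sorted(breaks, key=lambda p: p[0])
    if not breaks or breaks[0][0] != 0:
        raise InputError("breaks must start with a (0, slope) pair")
    days = np.arange(n_days, dtype=float)
    slope = np.zeros(n_days)
    for day, s in breaks:
        slope[int(day):] = s
    series = start_value + np.concatenate([[0.0], np.cumsum(slope[:-1])])
    corners = [int(d) for d, _ in breaks[1:] if 0 < d < n_days - 1]
    return series, corners


def _bands_for_gbndvi(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invertible band split realizing a target GBNDVI at fixed brightness.

    With s = NIR + (G + B) held at ``SCENE_BRIGHTNESS``:
    NIR = (1+g)/2 * s and G = B = (1-g)/4 * s, so the scene's GBNDVI is
    exactly g.  Synthetic-only decomposition; real canopies do not pin
    brightness.
    """
    s = SCENE_BRIGHTNESS
    nir = (1.0 + g) / 2.0 * s
    gb = (1.0 - g) / 4.0 * s
    return nir, gb, gb.copy()


def generate_scene(spec: SyntheticSceneSpec, weather: WeatherSeries,
                   params: CropParameters,
                   start_doy: int | None = None,
                   n_days: int = DEFAULT_SEASON_DAYS) -> list[MultispectralScene]:
    """Synthesize one 4-band scene per observation DOY from the zone map.

    Each pixel's LAI comes from the crop model at that pixel's zone stress
    factor; LAI maps to GBNDVI through the exact regression inverse and
    then to bands at fixed brightness.  Seeded Gaussian reflectance noise
    (sd ``spec.reflectance_sd``) is added per band and clipped to [0, 1].
    """
    if start_doy is None:
        start_doy = int(weather.doy[0])
    rng = np.random.default_rng(spec.seed)
    zones = np.unique(spec.zone_map)
    lai_by_zone = {}
    for f in zones:
        sim = run_simulation(weather, params, float(f), start_doy, n_days)
        lai_by_zone[float(f)] = sim.series_at(spec.obs_doys, "LAI")
    scenes = []
    mask = np.ones(spec.zone_map.shape, dtype=bool)
    for i, doy in enumerate(spec.obs_doys):
        lai = np.empty(spec.zone_map.shape)
        for f in zones:
            lai[spec.zone_map == f] = lai_by_zone[float(f)][i]
        g = invert_lai_to_gbndvi(np.maximum(lai, 1e-6))
        n_clip = int(np.sum((g <= -1) | (g >= 1)))
        if n_clip:
            import logging
            logging.getLogger(__name__).warning(
                "generate_scene: %d pixel(s) with GBNDVI outside (-1, 1) clipped",
                n_clip)
        g = np.clip(g, -0.999, 0.999)
        nir, green, blue = _bands_for_gbndvi(g)
        red = np.full(spec.zone_map.shape, SCENE_RED)
        if spec.reflectance_sd > 0:
            for band in (nir, green, blue, red):
                band += rng.normal(0.0, spec.reflectance_sd, band.shape)
        scenes.append(MultispectralScene(
            blue=np.clip(blue, 0, 1), green=np.clip(green, 0, 1),
            red=np.clip(red, 0, 1), nir=np.clip(nir, 0, 1),
            doy=int(doy), mask=mask))
    return scenes


def two_zone_map(shape: tuple[int, int] = (8, 8),
                 f_reference: float = REFERENCE_F,
                 f_stressed: float = STRESSED_F) -> np.ndarray:
    """Half-reference, half-stressed zone map (split along columns)."""
    zm = np.full(shape, f_reference)
    zm[:, shape[1] // 2:] = f_stressed
    return zm
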