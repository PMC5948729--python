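"""Stress-factor estimation by PSO assimilation of sparse observations.

The stress factor f is found by minimizing the mean squared misfit

    P(f) = (1/n) * sum_i (obs_i - sim_i(f))^2

between measured root dry weights (g m^-2) or LAI values at a few dates
and the corresponding simulated series, using a standard global-best
particle swarm.  The module also provides the squared-Pearson R^2 and
mean-absolute-error metrics used to evaluate the calibrated model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .crop_model import (CropParameters, InputError, ParameterError,
                         SimulationResult, StressFactor, WeatherSeries,
                         phenology_schedule, simulate_from_schedule)

__all__ = [
    "ObservationSet",
    "PSOConfig",
    "AssimilationResult",
    "StressFactorSummary",
    "cost_wrt",
    "cost_lai",
    "pso_minimize",
    "estimate_stress_factor",
    "r_squared",
    "mae",
    "summarize_stress",
]


class OptimizationError(RuntimeError):
    """The objective returned a non-finite value during optimization."""


class MetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""


@dataclass(frozen=True)
class ObservationSet:
    """Sparse dated observations of one variable (WRT in g m^-2, or LAI)."""

    kind: str
    doy: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("WRT", "LAI"):
            raise InputError(f"observation kind must be 'WRT' or 'LAI', got {self.kind!r}")
        doy = np.asarray(self.doy, dtype=int)
        val = np.asarray(self.value, dtype=float)
        if len(doy) != len(val) or len(doy) == 0:
            raise InputError("observations need >= 1 (doy, value) record")
        if np.any(np.diff(doy) <= 0):
            raise InputError("observation DOYs must increase strictly")
        if np.any(val < 0) or not np.all(np.isfinite(val)):
            raise InputError("observation values must be finite and non-negative")
        object.__setattr__(self, "doy", doy)
        object.__setattr__(self, "value", val)

    def __len__(self) -> int:
        return len(self.doy)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        df = pd.read_csv(path)
        required = {"doy", "value", "kind"}
        if not required.issubset(df.columns):
            raise InputError(f"observations CSV needs columns {sorted(required)}")
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise InputError("observations CSV must contain a single kind")
        return cls(str(kinds[0]), df["doy"].to_numpy(), df["value"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"doy": self.doy, "value": self.value,
                      "kind": self.kind}).to_csv(path, index=False)


@dataclass(frozen=True)
class PSOConfig:
    """Global-best PSO hyperparameters for the 1-D stress-factor search.

    Defaults are conventional swarm settings; the bounds cover the
    physically meaningful upper part of (0, 1] where field-calibrated
    stress factors fall.  Velocities are clamped to
    ``velocity_clamp * (upper - lower)``.
    """

    swarm_size: int = 20
    iterations: int = 50
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    bounds: tuple[float, float] = (0.5, 1.0)
    velocity_clamp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if self.swarm_size < 2:
            raise ParameterError("swarm_size must be >= 2")
        if not (0.0 < lo < hi <= 1.0):
            raise ParameterError("bounds must satisfy 0 < lower < upper <= 1")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ParameterError("inertia, cognitive and social weights must be > 0")


@dataclass
class AssimilationResult:
    """Optimum stress factor, its cost, and the per-iteration best-cost trace."""

    f_hat: StressFactor
    cost: float
    history: np.ndarray
    n_obs: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"f_hat": self.f_hat.f, "cost": self.cost,
                       "n_obs": self.n_obs,
                       "history": np.asarray(self.history).tolist()}, fh, indent=2)


@dataclass(frozen=True)
class StressFactorSummary:
    """Minimum / maximum / average stress factor over a set of pixels."""

    minimum: float
    maximum: float
    average: float


def _mean_squared_misfit(obs: ObservationSet, simulated: SimulationResult) -> float:
    sim_vals = simulated.series_at(obs.doy, obs.kind)
    d = obs.value - sim_vals
    return float(np.mean(d * d))


def cost_wrt(measured: ObservationSet, simulated: SimulationResult) -> float:
    """Mean squared WRT misfit at the observation DOYs (g m^-2 squared).

    The simulated root weight is converted from kg ha^-1 to g m^-2 before
    differencing so both series share the field unit.
    """
    if measured.kind != "WRT":
        raise InputError("cost_wrt requires WRT observations")
    return _mean_squared_misfit(measured, simulated)


def cost_lai(measured: ObservationSet, simulated: SimulationResult) -> float:
    """Mean squared LAI misfit at the observation DOYs (dimensionless)."""
    if measured.kind != "LAI":
        raise InputError("cost_lai requires LAI observations")
    return _mean_squared_misfit(measured, simulated)


def pso_minimize(objective: Callable[[float], float],
                 config: PSOConfig) -> AssimilationResult:
    """Minimize a scalar objective on ``config.bounds`` with global-best PSO.

    Reproducible for a fixed ``config.seed``; the returned history of best
    costs is non-increasing.  Positions are reflected into the bounds.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    width = hi - lo
    vmax = config.velocity_clamp * width
    x = rng.uniform(lo, hi, config.swarm_size)
    v = rng.uniform(-vmax, vmax, config.swarm_size)

    def evaluate(pos: float) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise OptimizationError(f"objective returned {val} at f={pos:.6f}")
        return val

    pbest_x = x.copy()
    pbest_c = np.array([evaluate(xi) for xi in x])
    g = int(np.argmin(pbest_c))
    gbest_x, gbest_c = pbest_x[g], pbest_c[g]
    history = np.empty(config.iterations + 1)
    history[0] = gbest_c
    for it in range(config.iterations):
        r1 = rng.random(config.swarm_size)
        r2 = rng.random(config.swarm_size)
        v = (config.inertia * v
             + config.cognitive * r1 * (pbest_x - x)
             + config.social * r2 * (gbest_x - x))
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        # reflect off the bounds
        over = x > hi
        under = x < lo
        x[over] = hi - (x[over] - hi) % width
        x[under] = lo + (lo - x[under]) % width
        for i in range(config.swarm_size):
            c = evaluate(x[i])
            if c < pbest_c[i]:
                pbest_c[i] = c
                pbest_x[i] = x[i]
                if c < gbest_c:
                    gbest_c, gbest_x = c, x[i]
        history[it + 1] = gbest_c
    return AssimilationResult(StressFactor(float(gbest_x)), float(gbest_c),
                              history, n_obs=0)


def estimate_stress_factor(obs: ObservationSet, weather: WeatherSeries,
                           params: CropParameters, config: PSOConfig,
                           start_doy: int | None = None,
                           n_days: int = 100) -> AssimilationResult:
    """Estimate f by assimilating WRT or LAI observations into the simulator.

    The crop model runs inside the PSO objective; phenology is precomputed
    once since it does not depend on f.
    """
    if start_doy is None:
        start_doy = int(weather.doy[0])
    schedule = phenology_schedule(weather, params, start_doy, n_days)
    cost_fn = cost_wrt if obs.kind == "WRT" else cost_lai

    def objective(f: float) -> float:
        return cost_fn(obs, simulate_from_schedule(schedule, f))

    result = pso_minimize(objective, config)
    result.n_obs = len(obs)
    return result


def r_squared(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Squared Pearson correlation between two series, in [0, 1]."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or len(p) < 2:
        raise InputError("r_squared needs two equal-length 1-D series, n >= 2")
    dp = p - p.mean()
    dm = m - m.mean()
    denom = np.sqrt((dp * dp).sum() * (dm * dm).sum())
    if denom == 0:
        raise MetricError("r_squared undefined: a series has zero variance")
    r = float((dp * dm).sum() / denom)
    return r * r


def mae(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Mean absolute error between two equal-length series."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or len(p) == 0:
        raise InputError("mae needs two equal-length 1-D series, n >= 1")
    return float(np.mean(np.abs(p - m)))


def summarize_stress(f_values: np.ndarray,
                     mask: np.ndarray | None = None) -> StressFactorSummary:
    """Min / max / mean stress factor over unmasked pixels."""
    f = np.asarray(f_values, dtype=float)
    if mask is not None:
        f = f[np.asarray(mask, dtype=bool)]
    if f.size == 0:
        raise InputError("summarize_stress needs at least one unmasked value")
    return StressFactorSummary(float(f.min()), float(f.max()), float(f.mean()))
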