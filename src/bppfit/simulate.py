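"""Synthetic measurement data with the statistical structure the analysis
assumes: forward-model T1(T) series on an 80-300 K grid with multiplicative
(lognormal) measurement noise of a given coefficient of variation, and
noisy single-exponential saturation-recovery curves.

The defaults emulate the acquisition conditions the fitting stages target:
a 25 MHz spectrometer, temperatures spanning 80-300 K, and +/-10%
measurement uncertainty on T1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bpp import RelaxationModel, t1 as model_t1
from .recovery import RecoveryCurve, T1Series

__all__ = [
    "SimulationSpec",
    "default_temperature_grid",
    "default_recovery_times",
    "simulate_t1_series",
    "simulate_recovery_curve",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for simulating a T1(T) series.

    Parameters
    ----------
    model : RelaxationModel
        Generating motion parameters and spectrometer context.
    t_min, t_max : float
        Temperature range, K (default 80-300).
    n_temps : int
        Number of temperatures (default 30).
    grid : str
        ``"reciprocal"`` (uniform in 1/T; natural for Arrhenius data, the
        default) or ``"uniform"``.
    noise_cv : float
        Coefficient of variation of the multiplicative measurement noise
        (default 0.10).
    noise_kind : str
        ``"lognormal"`` (default; preserves T1 > 0) or ``"gaussian"``
        (additive relative noise, may go non-positive at large CV).
    seed : int
        Seed for the noise stream.
    replicates : int
        Number of independent series drawn by callers that loop; carried
        here for provenance.
    """

    model: RelaxationModel
    t_min: float = 80.0
    t_max: float = 300.0
    n_temps: int = 30
    grid: str = "reciprocal"
    noise_cv: float = 0.10
    noise_kind: str = "lognormal"
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise ValueError("require 0 < t_min < t_max")
        if self.n_temps < 2:
            raise ValueError("n_temps must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.grid not in ("reciprocal", "uniform"):
            raise ValueError(f"unknown grid {self.grid!r}")
        if self.noise_kind not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")


def default_temperature_grid(spec: SimulationSpec) -> np.ndarray:
    """Measurement temperatures, ascending, endpoints included.

    The reciprocal grid is uniform in 1/T between 1/t_max and 1/t_min,
    mirroring how Arrhenius-activated data are naturally spaced.
    """
    if spec.grid == "uniform":
        return np.linspace(spec.t_min, spec.t_max, spec.n_temps)
    inv = np.linspace(1.0 / spec.t_max, 1.0 / spec.t_min, spec.n_temps)
    return np.sort(1.0 / inv)


def simulate_t1_series(spec: SimulationSpec) -> T1Series:
    """Draw one noisy T1(T) series from the forward model.

    True values t1(model, T_i) are multiplied by i.i.d. lognormal factors
    with unit mean and coefficient of variation ``noise_cv`` (so the sample
    CV of observed/true equals noise_cv); ``noise_cv=0`` reproduces the
    forward model exactly.  Fully determined by ``spec.seed``.
    """
    temps = default_temperature_grid(spec)
    true = np.asarray(model_t1(spec.model, temps))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv == 0:
        observed = true
    elif spec.noise_kind == "lognormal":
        sigma2 = math.log1p(spec.noise_cv**2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=len(temps))
        observed = true * factors
    else:
        observed = true * (1.0 + spec.noise_cv * rng.standard_normal(len(temps)))
        if np.any(observed <= 0):
            raise ValueError("gaussian noise drew a non-positive T1; lower noise_cv")
    return T1Series(temps, observed, true * spec.noise_cv if spec.noise_cv else None)


def default_recovery_times(t1: float, n_points: int = 16) -> np.ndarray:
    """Logarithmic delay grid from 0.05*T1 to 5*T1 (default 16 points)."""
    if not (t1 > 0):
        raise ValueError("t1 must be positive")
    return np.geomspace(0.05 * t1, 5.0 * t1, n_points)


def simulate_recovery_curve(
    m0: float,
    t1: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> RecoveryCurve:
    """Noisy saturation-recovery curve M0 (1 - exp(-t/T1)) + N(0, noise_sd)."""
    if not (t1 > 0):
        raise ValueError("t1 must be positive")
    times = np.asarray(times, dtype=float)
    clean = m0 * (-np.expm1(-times / t1))
    rng = np.random.default_rng(seed)
    noisy = clean + noise_sd * rng.standard_normal(times.shape)
    return RecoveryCurve(temperature=temperature, times=times, magnetization=noisy)
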