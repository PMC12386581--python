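"""T1 extraction from saturation-recovery curves.

A saturation-recovery experiment destroys the longitudinal magnetization
and samples its regrowth; the recovery follows the single-exponential law

    M(t) = M0 * (1 - exp(-t / T1)),

where M0 is the equilibrium magnetization.  This module fits that law to
tabulated (t, M) data by unweighted nonlinear least squares and assembles
per-temperature fits into a T1-vs-temperature series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RecoveryCurve",
    "T1Series",
    "RecoveryFit",
    "fit_saturation_recovery",
    "build_t1_series",
]


@dataclass(frozen=True)
class RecoveryCurve:
    """Magnetization samples at one temperature.

    ``times`` must be strictly increasing, non-negative, length >= 4
    (the minimum to constrain a 2-parameter fit with diagnostics), and all
    values finite.
    """

    temperature: float
    times: np.ndarray
    magnetization: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.magnetization, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "magnetization", m)
        if t.ndim != 1 or m.shape != t.shape:
            raise ValueError("times and magnetization must be 1-D and equal length")
        if len(t) < 4:
            raise ValueError(f"recovery curve needs >= 4 points, got {len(t)}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(m))):
            raise ValueError("recovery curve contains non-finite values")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature!r}")


@dataclass(frozen=True)
class T1Series:
    """(temperature, T1) pairs, ascending in temperature, with optional
    per-point uncertainties (1-sigma, seconds)."""

    temperatures: np.ndarray
    t1_values: np.ndarray
    t1_uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        vals = np.asarray(self.t1_values, dtype=float)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "t1_values", vals)
        if temps.shape != vals.shape or temps.ndim != 1:
            raise ValueError("temperatures and t1_values must be 1-D and equal length")
        if np.any(np.diff(temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(~(vals > 0)):
            raise ValueError("all T1 values must be positive")
        if self.t1_uncertainty is not None:
            unc = np.asarray(self.t1_uncertainty, dtype=float)
            if unc.shape != temps.shape:
                raise ValueError("t1_uncertainty length mismatch")
            object.__setattr__(self, "t1_uncertainty", unc)

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class RecoveryFit:
    """Result of a single-exponential recovery fit."""

    m0: float
    t1: float
    rms_residual: float
    converged: bool
    t1_stderr: float = math.nan


def _recovery_residuals(params: np.ndarray, t: np.ndarray, m: np.ndarray) -> np.ndarray:
    m0, t1 = params
    return m0 * (-np.expm1(-t / t1)) - m


def _initial_guess(t: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    # M0 from the plateau; T1 from the time M first crosses (1 - 1/e) * M0,
    # linearly interpolated -- robust and derivative-free.
    m0 = float(np.max(m))
    target = (1.0 - math.exp(-1.0)) * m0
    above = np.nonzero(m >= target)[0]
    if len(above) == 0 or above[0] == 0:
        t1 = float(t[len(t) // 2]) or float(t[-1]) / 2.0
    else:
        i = above[0]
        frac = (target - m[i - 1]) / (m[i] - m[i - 1])
        t1 = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    if not (t1 > 0):
        t1 = float(t[-1]) / 2.0
    return m0, t1


def _loglinear_guess(t: np.ndarray, m: np.ndarray) -> tuple[float, float] | None:
    # ln(M0 - M) is linear in t with slope -1/T1; use a slightly inflated
    # plateau so the log argument stays positive.
    m0 = 1.05 * float(np.max(m))
    mask = m0 - m > 0
    if mask.sum() < 3:
        return None
    slope, _ = np.polyfit(t[mask], np.log(m0 - m[mask]), 1)
    if slope >= 0:
        return None
    return m0, -1.0 / slope


def fit_saturation_recovery(curve: RecoveryCurve) -> RecoveryFit:
    """Least-squares estimates of (M0, T1) for M(t) = M0 (1 - exp(-t/T1)).

    Starts from a plateau/crossing heuristic; on failure retries from a
    log-linear regression start and then from five seeded random
    perturbations before giving up.  A negative fitted T1 signals data that
    are not recovery-shaped and is reported as an error.

    Raises
    ------
    ValueError
        For a constant (unidentifiable) curve, a negative fitted T1, or
        non-convergence after the retry ladder.
    """
    t, m = curve.times, curve.magnetization
    if np.ptp(m) == 0:
        raise ValueError("degenerate recovery curve: constant magnetization")

    starts: list[tuple[float, float]] = [_initial_guess(t, m)]
    ll = _loglinear_guess(t, m)
    if ll is not None:
        starts.append(ll)
    rng = np.random.default_rng(0)
    base = starts[0]
    starts.extend(
        (base[0] * float(f0), base[1] * float(f1))
        for f0, f1 in rng.lognormal(0.0, 0.5, size=(5, 2))
    )

    failures = []
    for m0_0, t1_0 in starts:
        try:
            res = least_squares(
                _recovery_residuals,
                x0=[m0_0, t1_0],
                args=(t, m),
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                max_nfev=10_000,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failures
            failures.append(str(exc))
            continue
        if not res.success:
            failures.append(res.message)
            continue
        m0_hat, t1_hat = res.x
        if t1_hat <= 0:
            raise ValueError(
                f"fitted T1 = {t1_hat:.4g} s is not positive: "
                "data are not recovery-shaped"
            )
        # T1 vastly beyond the sampled window means the solver collapsed to
        # the degenerate linear regime M ~ (M0/T1) t, where only the ratio
        # is identified -- the recovery was never actually sampled.
        if t1_hat > 50.0 * (t[-1] - t[0]):
            raise ValueError(
                f"fitted T1 = {t1_hat:.4g} s far exceeds the sampled time "
                f"window ({t[-1] - t[0]:.4g} s): recovery not sampled"
            )
        n, p = len(t), 2
        rms = float(np.sqrt(np.mean(res.fun**2)))
        # 1-sigma standard error of T1 from the Gauss-Newton covariance.
        stderr = math.nan
        if n > p:
            jtj = res.jac.T @ res.jac
            try:
                cov = np.linalg.inv(jtj) * (res.fun @ res.fun) / (n - p)
                stderr = float(np.sqrt(cov[1, 1]))
            except np.linalg.LinAlgError:
                pass
        return RecoveryFit(
            m0=float(m0_hat),
            t1=float(t1_hat),
            rms_residual=rms,
            converged=True,
            t1_stderr=stderr,
        )
    raise ValueError(
        "saturation-recovery fit did not converge after retry ladder: "
        + "; ".join(failures)
    )


def build_t1_series(curves: Sequence[RecoveryCurve]) -> T1Series:
    """Fit each curve and assemble a temperature-sorted T1 series.

    Per-curve fit failures are skipped (recorded, never imputed); if every
    curve fails the combined diagnostics are raised.  Duplicate temperatures
    are rejected.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 recovery curves")
    temps = [c.temperature for c in curves]
    if len(set(temps)) != len(temps):
        dupes = sorted({x for x in temps if temps.count(x) > 1})
        raise ValueError(f"duplicate temperature(s): {dupes}")

    rows: list[tuple[float, float, float]] = []
    diagnostics: list[str] = []
    for curve in curves:
        try:
            fit = fit_saturation_recovery(curve)
        except ValueError as exc:
            diagnostics.append(f"T={curve.temperature} K: {exc}")
            continue
        rows.append((curve.temperature, fit.t1, fit.t1_stderr))
    if not rows:
        raise ValueError("all recovery fits failed: " + "; ".join(diagnostics))
    rows.sort(key=lambda r: r[0])
    temps_arr, t1_arr, unc_arr = (np.array(col) for col in zip(*rows))
    return T1Series(temps_arr, t1_arr, unc_arr)
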