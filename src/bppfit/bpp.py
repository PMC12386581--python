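"""Forward evaluation of the BPP spin-lattice relaxation model.

The relaxation rate of a rigid multi-proton system modulated by K
thermally activated internal motions is

    1/T1 = (2/3) * gamma^2 * sum_k dM2_k * [ tau_k / (1 + w0^2 tau_k^2)
                                           + 4 tau_k / (1 + 4 w0^2 tau_k^2) ],

where ``gamma`` is the proton gyromagnetic ratio, ``dM2_k`` the portion of
the 1H second moment (Gauss^2) averaged out by motion k, ``w0`` the angular
Larmor frequency and ``tau_k`` the motion's correlation time, thermally
activated through the Arrhenius law

    tau_k(T) = tau0_k * exp(Ea_k / (R T)).

Per-motion contributions are additive.  Units are chosen so that
activation-parameter tables can be used verbatim: ``tau0`` in seconds,
``Ea`` in kJ/mol, ``dM2`` in Gauss^2, ``gamma`` in rad s^-1 G^-1; the rate
then comes out in s^-1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "GAS_CONSTANT",
    "Motion",
    "SpectrometerConfig",
    "RelaxationModel",
    "correlation_time",
    "motion_rate",
    "total_rate",
    "t1",
    "t1_minimum",
    "read_params",
    "write_params",
]

#: Proton gyromagnetic ratio, rad s^-1 Gauss^-1.
GAMMA_PROTON = 2.6752218744e4
#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314462618

#: Correlation times above this are far beyond any measurable regime and are
#: capped (with a flag) to keep the rate expression finite.
TAU_CAP_S = 1.0e3

#: Value of w0*tau at the single-motion T1 minimum of the two-term BPP
#: spectral density (root of d/dx [x/(1+x^2) + 4x/(1+4x^2)] = 0).
OMEGA_TAU_AT_MINIMUM = 0.6157951469617562


@dataclass(frozen=True)
class Motion:
    """One thermally activated internal motion.

    Parameters
    ----------
    tau0 : float
        Pre-exponential correlation time, seconds. Must be positive.
    ea : float
        Activation energy, kJ/mol. Must be non-negative.
    dm2 : float
        Second-moment reduction dM2 driven by this motion, Gauss^2.
        Must be non-negative.
    """

    tau0: float
    ea: float
    dm2: float

    def __post_init__(self) -> None:
        if not (self.tau0 > 0):
            raise ValueError(f"tau0 must be > 0, got {self.tau0!r}")
        if not (self.ea >= 0):
            raise ValueError(f"ea must be >= 0, got {self.ea!r}")
        if not (self.dm2 >= 0):
            raise ValueError(f"dm2 must be >= 0, got {self.dm2!r}")


@dataclass(frozen=True)
class SpectrometerConfig:
    """Larmor frequency and physical constants for the rate expression.

    ``omega0`` is derived from ``frequency`` (MHz) and must stay consistent
    with it; ``gamma`` and ``gas_constant`` are fixed physical constants but
    overridable for testing.
    """

    frequency: float = 25.0
    omega0: float = field(default=0.0)
    gamma: float = GAMMA_PROTON
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if not (self.frequency > 0):
            raise ValueError(f"frequency must be > 0 MHz, got {self.frequency!r}")
        expected = 2.0 * math.pi * self.frequency * 1.0e6
        if self.omega0 == 0.0:
            object.__setattr__(self, "omega0", expected)
        elif abs(self.omega0 - expected) > 1e-12 * expected:
            raise ValueError(
                f"omega0={self.omega0!r} inconsistent with frequency="
                f"{self.frequency!r} MHz (expected {expected!r})"
            )


@dataclass(frozen=True)
class RelaxationModel:
    """An ordered set of motions plus the spectrometer context."""

    motions: tuple[Motion, ...]
    config: SpectrometerConfig = SpectrometerConfig()

    def __post_init__(self) -> None:
        object.__setattr__(self, "motions", tuple(self.motions))

    @property
    def k(self) -> int:
        return len(self.motions)


def correlation_time(
    motion: Motion,
    temperature: float | np.ndarray,
    config: SpectrometerConfig = SpectrometerConfig(),
) -> float | np.ndarray:
    """Arrhenius correlation time tau0 * exp(Ea / (R T)), seconds.

    ``Ea`` is converted from kJ/mol to J/mol.  Evaluated in log space and
    capped at ``TAU_CAP_S`` to avoid overflow deep in the slow-motion limit.
    Strictly decreasing in temperature when ``Ea > 0``.

    Raises
    ------
    ValueError
        If any temperature is not strictly positive.
    """
    temp = np.asarray(temperature, dtype=float)
    if np.any(~(temp > 0)):
        bad = temp[~(temp > 0)]
        raise ValueError(f"temperature must be > 0 K, got {np.atleast_1d(bad)[0]!r}")
    log_tau = math.log(motion.tau0) + (motion.ea * 1e3) / (config.gas_constant * temp)
    tau = np.exp(np.minimum(log_tau, math.log(TAU_CAP_S)))
    if np.ndim(temperature) == 0:
        return float(tau)
    return tau


def _rate_from_tau(tau, dm2: float, config: SpectrometerConfig):
    """Eq. (1) integrand: (2/3) gamma^2 dM2 [J(w0) + 4 J(2 w0)] with
    J(w) = tau / (1 + w^2 tau^2)."""
    x = config.omega0 * np.asarray(tau, dtype=float)
    j = tau / (1.0 + x * x) + 4.0 * tau / (1.0 + 4.0 * x * x)
    return (2.0 / 3.0) * config.gamma**2 * dm2 * j


def motion_rate(
    motion: Motion,
    temperature: float | np.ndarray,
    config: SpectrometerConfig = SpectrometerConfig(),
) -> float | np.ndarray:
    """Relaxation-rate contribution of one motion at ``temperature``, s^-1.

    Always non-negative; identically zero when ``dm2 == 0``.
    """
    tau = correlation_time(motion, temperature, config)
    rate = _rate_from_tau(tau, motion.dm2, config)
    if np.ndim(temperature) == 0:
        return float(rate)
    return np.asarray(rate)


def total_rate(
    model: RelaxationModel, temperature: float | np.ndarray
) -> float | np.ndarray:
    """Total relaxation rate 1/T1: the sum of per-motion contributions."""
    if model.k == 0:
        raise ValueError("model has no motions")
    rates = [motion_rate(m, temperature, model.config) for m in model.motions]
    out = np.sum(rates, axis=0)
    if np.ndim(temperature) == 0:
        return float(out)
    return out


def t1(model: RelaxationModel, temperature: float | np.ndarray) -> float | np.ndarray:
    """Spin-lattice relaxation time T1 = 1 / total_rate, seconds."""
    rate = total_rate(model, temperature)
    out = 1.0 / np.asarray(rate, dtype=float)
    if np.ndim(temperature) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class T1Minimum:
    """Location of a single motion's T1 minimum."""

    temperature: float
    t1_min: float
    in_range: bool


def t1_minimum(
    motion: Motion, config: SpectrometerConfig = SpectrometerConfig()
) -> T1Minimum:
    """Temperature and value of the single-motion T1 minimum.

    The two-term BPP spectral density peaks where w0*tau = 0.6158...; the
    Arrhenius law is inverted to find the temperature at which the motion's
    correlation time crosses that value.  ``in_range`` is False (not an
    error) when that temperature falls outside (1 K, 1e4 K) or when the
    motion is too slow at any temperature (tau0 already above the optimum).
    """
    if not (motion.ea > 0):
        raise ValueError("t1_minimum requires ea > 0")
    if not (motion.dm2 > 0):
        raise ValueError("t1_minimum requires dm2 > 0")
    tau_star = OMEGA_TAU_AT_MINIMUM / config.omega0
    if tau_star <= motion.tau0:
        # tau(T) -> tau0 from above as T -> inf: the optimum is unreachable.
        return T1Minimum(temperature=math.inf, t1_min=math.nan, in_range=False)
    temp = (motion.ea * 1e3) / (config.gas_constant * math.log(tau_star / motion.tau0))
    model = RelaxationModel((motion,), config)
    value = t1(model, temp) if 0 < temp else math.nan
    in_range = bool(1.0 < temp < 1.0e4)
    return T1Minimum(temperature=temp, t1_min=value, in_range=in_range)


# ---------------------------------------------------------------------------
# Motion-parameter files


def read_params(path: str | Path) -> RelaxationModel:
    """Read a motion-parameter JSON file into a RelaxationModel.

    Expected document shape::

        {"frequency_MHz": 25,
         "motions": [{"tau0_s": ..., "ea_kJ_per_mol": ..., "dm2_G2": ...}, ...]}
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if "motions" not in doc:
        raise ValueError(f"{path}: missing required key 'motions'")
    freq = float(doc.get("frequency_MHz", 25.0))
    motions = []
    for i, entry in enumerate(doc["motions"]):
        missing = {"tau0_s", "ea_kJ_per_mol", "dm2_G2"} - set(entry)
        if missing:
            raise ValueError(f"{path}: motion {i} missing keys {sorted(missing)}")
        motions.append(
            Motion(
                tau0=float(entry["tau0_s"]),
                ea=float(entry["ea_kJ_per_mol"]),
                dm2=float(entry["dm2_G2"]),
            )
        )
    return RelaxationModel(tuple(motions), SpectrometerConfig(frequency=freq))


def write_params(model: RelaxationModel, path: str | Path) -> None:
    """Write a RelaxationModel to the motion-parameter JSON dialect at full
    precision (round-trips bit-exactly through ``read_params``)."""
    doc = {
        "frequency_MHz": model.config.frequency,
        "motions": [
            {"tau0_s": m.tau0, "ea_kJ_per_mol": m.ea, "dm2_G2": m.dm2}
            for m in model.motions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
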