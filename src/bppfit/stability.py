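"""Radiosterilization stability arithmetic.

Small, exact computations on tabulated stability data: encapsulation
efficiency of a drug in a nanoemulsion, percent decay of radiation-induced
EPR signal amplitudes over storage, drug content relative to a reference
(with delta-method error propagation for the ratio), and the fraction of
chromatographic peak area attributable to degradation products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

__all__ = [
    "AmplitudeRecord",
    "ContentRecord",
    "entrapment_efficiency",
    "epr_amplitude_decay",
    "content_percent",
    "degradation_area_fraction",
]


@dataclass(frozen=True)
class AmplitudeRecord:
    """EPR signal amplitude of one sample at irradiation time and after
    three months.  Growth over storage is allowed (reported as negative
    decay), so ``amplitude_3months <= amplitude_initial`` is not assumed."""

    compound: str
    dose: float
    amplitude_initial: float
    amplitude_3months: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0 kGy, got {self.dose!r}")
        if not (self.amplitude_initial > 0):
            raise ValueError(
                f"amplitude_initial must be > 0, got {self.amplitude_initial!r}"
            )
        if self.amplitude_3months < 0:
            raise ValueError(
                f"amplitude_3months must be >= 0, got {self.amplitude_3months!r}"
            )


@dataclass(frozen=True)
class ContentRecord:
    """Drug content at one dose: mean +/- SD in percent, referenced either
    to the theoretical content or to the unirradiated substance."""

    dose: float
    mean_percent: float
    sd_percent: float
    reference: str

    def __post_init__(self) -> None:
        if not (self.mean_percent > 0):
            raise ValueError(f"mean_percent must be > 0, got {self.mean_percent!r}")
        if self.sd_percent < 0:
            raise ValueError(f"sd_percent must be >= 0, got {self.sd_percent!r}")
        if self.reference not in ("theoretical", "unirradiated"):
            raise ValueError(f"unknown reference {self.reference!r}")


def entrapment_efficiency(entrapped_amount: float, total_added: float) -> float:
    """Encapsulation efficiency EE% = 100 * entrapped / total added.

    Values above 100% are passed through unmodified (they occur in practice
    from independent calibration of the two measurements).
    """
    if not (total_added > 0):
        raise ValueError(f"total_added must be > 0, got {total_added!r}")
    if entrapped_amount < 0:
        raise ValueError(f"entrapped_amount must be >= 0, got {entrapped_amount!r}")
    return 100.0 * entrapped_amount / total_added


def epr_amplitude_decay(
    records: Sequence[AmplitudeRecord], irradiated_only: bool = True
) -> tuple[list[float], float]:
    """Percent decay of EPR amplitudes over three months of storage.

    Per-record decay is 100 * (A0 - A3m) / A0.  The mean is taken over the
    irradiated records only by default (dose > 0): the decaying species are
    the radiation-induced paramagnetic centers, and native dose-0 signals
    would dilute the aggregate.

    Returns
    -------
    (per_record, mean) : list of per-record decays (in input order, all
    records) and the mean over the selected records.
    """
    if not records:
        raise ValueError("no amplitude records given")
    per_record = [
        100.0 * (r.amplitude_initial - r.amplitude_3months) / r.amplitude_initial
        for r in records
    ]
    selected = [
        d for d, r in zip(per_record, records) if (r.dose > 0 or not irradiated_only)
    ]
    if not selected:
        raise ValueError("no records selected (all doses are 0 kGy?)")
    return per_record, sum(selected) / len(selected)


def content_percent(
    measured_mean: float,
    measured_sd: float,
    reference_mean: float,
    reference_sd: float,
) -> tuple[float, float]:
    """Content as a percentage of a reference, with propagated SD.

    The mean is 100 * measured / reference; the SD follows the first-order
    delta method for a ratio of independent means:

        sd% = mean% * sqrt( (sd_m / m)^2 + (sd_r / r)^2 ).
    """
    if not (reference_mean > 0):
        raise ValueError(f"reference_mean must be > 0, got {reference_mean!r}")
    if measured_sd < 0 or reference_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    mean = 100.0 * measured_mean / reference_mean
    sd = abs(mean) * math.sqrt(
        (measured_sd / measured_mean) ** 2 + (reference_sd / reference_mean) ** 2
    )
    return mean, sd


def degradation_area_fraction(
    degradation_peak_areas: Sequence[float], all_peak_areas_total: float
) -> float:
    """Percent of total chromatographic peak area in degradation peaks."""
    if not (all_peak_areas_total > 0):
        raise ValueError(f"total peak area must be > 0, got {all_peak_areas_total!r}")
    if any(a < 0 for a in degradation_peak_areas):
        raise ValueError("peak areas must be >= 0")
    deg = sum(degradation_peak_areas)
    if deg > all_peak_areas_total:
        raise ValueError(
            f"degradation area {deg} exceeds total {all_peak_areas_total}: "
            "peaks are mislabeled"
        )
    return 100.0 * deg / all_peak_areas_total
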