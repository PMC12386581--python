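"""Bundled reference data: published activation-parameter sets for
magnolol (MAG) and honokiol (HON) before/after 400 kGy irradiation, and
small stability tables (EPR signal amplitudes per dose, HPLC drug content).

These are the worked-example inputs for the package; synthetic measurement
data are generated from them by :mod:`bppfit.simulate`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .bpp import RelaxationModel, read_params

#: Names of the bundled activation-parameter sets.
PARAMETER_SETS = ("mag_0kGy", "mag_400kGy", "hon_0kGy", "hon_400kGy")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bppfit").joinpath("data", name)))


def load_reference_model(name: str) -> RelaxationModel:
    """Load one of the bundled activation-parameter sets.

    Parameters
    ----------
    name : str
        One of ``mag_0kGy``, ``mag_400kGy``, ``hon_0kGy``, ``hon_400kGy``.
    """
    if name not in PARAMETER_SETS:
        raise KeyError(f"unknown parameter set {name!r}; choose from {PARAMETER_SETS}")
    return read_params(_data_path(f"{name}.json"))


def load_epr_amplitudes() -> pd.DataFrame:
    """EPR signal amplitudes per compound and dose, at irradiation time and
    after three months of storage (columns: compound, dose_kGy,
    amplitude_initial, amplitude_3m)."""
    return pd.read_csv(_data_path("epr_amplitudes.tsv"), sep="\t")


def load_drug_content() -> pd.DataFrame:
    """HPLC drug-content means and SDs per dose (percent of theoretical
    content at 0 kGy, percent of the unirradiated substance otherwise)."""
    return pd.read_csv(_data_path("drug_content.tsv"), sep="\t")
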