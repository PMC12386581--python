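"""Readers and writers for the package's tabular file dialects.

Series files: delimited text with header ``temperature_K`` / ``t1_s`` and
optional ``t1_err_s``.  Recovery-curve files: header ``time_s`` /
``magnetization`` with the temperature carried in a leading comment line
``# temperature_K=<value>``.  Tab and comma delimiters are auto-detected.
Writers emit full-precision values so write-then-read round-trips exactly;
readers reject malformed rows with their line numbers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .bpp import read_params, write_params  # re-exported  # noqa: F401
from .recovery import RecoveryCurve, T1Series

__all__ = [
    "read_series",
    "write_series",
    "read_curve",
    "write_curve",
    "read_params",
    "write_params",
]

_SERIES_REQUIRED = ("temperature_K", "t1_s")
_CURVE_REQUIRED = ("time_s", "magnetization")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def _parse_table(path: Path, required: tuple[str, ...]):
    """Parse a delimited file into {column: ndarray}, plus comment metadata."""
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if "=" in payload:
                key, _, value = payload.partition("=")
                meta[key.strip()] = value.strip()
            continue
        body.append((lineno, line))
    if not body:
        raise ValueError(f"{path}: no data rows")
    header_no, header_line = body[0]
    sep = _sniff_delimiter(header_line)
    columns = [c.strip() for c in header_line.split(sep)]
    missing = set(required) - set(columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    extra = set(columns) - set(required) - {"t1_err_s"}
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {sorted(extra)}")
    data: dict[str, list[float]] = {c: [] for c in columns}
    for lineno, line in body[1:]:
        cells = [c.strip() for c in line.split(sep)]
        if len(cells) != len(columns):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(columns)} fields, "
                f"got {len(cells)}"
            )
        for col, cell in zip(columns, cells):
            try:
                data[col].append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} "
                    f"in column {col!r}"
                ) from None
    return {c: np.array(v) for c, v in data.items()}, meta


def read_series(path: str | Path) -> T1Series:
    """Read a T1-vs-temperature series file."""
    path = Path(path)
    data, _ = _parse_table(path, _SERIES_REQUIRED)
    unc = data.get("t1_err_s")
    return T1Series(data["temperature_K"], data["t1_s"], unc)


def write_series(series: T1Series, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    cols = ["temperature_K", "t1_s"]
    arrays = [series.temperatures, series.t1_values]
    if series.t1_uncertainty is not None:
        cols.append("t1_err_s")
        arrays.append(series.t1_uncertainty)
    lines = [sep.join(cols)]
    for row in zip(*arrays):
        lines.append(sep.join(repr(float(x)) for x in row))
    path.write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path, temperature: float | None = None) -> RecoveryCurve:
    """Read a recovery-curve file.

    The temperature comes from the ``# temperature_K=...`` header comment
    unless overridden by the ``temperature`` argument (sidecar-manifest
    style).
    """
    path = Path(path)
    data, meta = _parse_table(path, _CURVE_REQUIRED)
    if temperature is None:
        if "temperature_K" not in meta:
            raise ValueError(
                f"{path}: no '# temperature_K=' header and no temperature given"
            )
        temperature = float(meta["temperature_K"])
    return RecoveryCurve(
        temperature=temperature, times=data["time_s"], magnetization=data["magnetization"]
    )


def write_curve(curve: RecoveryCurve, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    lines = [f"# temperature_K={curve.temperature!r}", sep.join(_CURVE_REQUIRED)]
    for t, m in zip(curve.times, curve.magnetization):
        lines.append(sep.join((repr(float(t)), repr(float(m)))))
    path.write_text("\n".join(lines) + "\n")
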