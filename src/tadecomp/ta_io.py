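"""Read/write TA maps, spectra and traces as plain TSV.

Format contract
---------------
* UTF-8, LF line endings, tab-separated, decimal *point* only — a decimal
  comma is an error, never a silent misparse.
* Values are serialized with ``repr(float)`` (shortest round-tripping
  decimal form), so a write→read cycle reproduces every bit.
* Leading ``# key=value`` comment lines carry provenance (tool version,
  seed of a synthetic map, the generating command); readers collect them
  into a metadata dict and otherwise ignore them.
* A TA map file has the literal corner cell ``delay_ps\\wavelength_nm``:
  row 0 holds the wavelengths (nm), column 0 the delays (ps), the body the
  ΔOD values in OD units.
* Spectra and traces are two-column files with headers
  ``wavelength_nm<TAB>od`` and ``delay_ps<TAB>dod``.

Units are fixed: nm, ps, OD.  Explicit converters are provided for data
recorded in mOD or fs; files never mix units.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import __version__
from .containers import DelayAxis, SpectralAxis, Spectrum, TAMap, Trace

__all__ = [
    "read_tamap",
    "write_tamap",
    "read_spectrum",
    "write_spectrum",
    "read_trace",
    "write_trace",
    "mod_to_od",
    "fs_to_ps",
]

TAMAP_CORNER = "delay_ps\\wavelength_nm"
SPECTRUM_HEADER = ("wavelength_nm", "od")
TRACE_HEADER = ("delay_ps", "dod")


def _fmt(x: float) -> str:
    return repr(float(x))


def _meta_lines(meta: dict | None) -> list[str]:
    lines = [f"# tadecomp={__version__}"]
    for key, value in (meta or {}).items():
        key = str(key)
        if any(ch in key for ch in "=\t\n"):
            raise ValueError(f"invalid metadata key {key!r}")
        value = str(value)
        if "\n" in value or "\t" in value:
            raise ValueError(f"invalid metadata value for {key!r}")
        lines.append(f"# {key}={value}")
    return lines


def _read_lines(path) -> tuple[list[str], dict]:
    """All non-comment lines plus the metadata collected from comments."""
    meta: dict[str, str] = {}
    rows: list[str] = []
    text = Path(path).read_text(encoding="utf-8")
    for raw in text.splitlines():
        if raw.startswith("#"):
            body = raw[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if raw.strip() == "":
            continue
        rows.append(raw)
    return rows, meta


def _parse_cell(token: str, where: str) -> float:
    token = token.strip()
    try:
        value = float(token)
    except ValueError:
        if "," in token:
            raise ValueError(
                f"{where}: {token!r} uses a decimal comma; "
                "files must use '.' as the decimal separator"
            ) from None
        raise ValueError(f"{where}: cannot parse {token!r} as a number") from None
    if not np.isfinite(value):
        raise ValueError(f"{where}: non-finite value {token!r}")
    return value


# ---------------------------------------------------------------------------
# TA maps

def write_tamap(tamap: TAMap, path, meta: dict | None = None) -> None:
    """Write a TA map to TSV; full-precision so the round trip is exact."""
    lines = _meta_lines(meta)
    lines.append(
        TAMAP_CORNER + "\t" + "\t".join(_fmt(w) for w in tamap.saxis.wavelengths)
    )
    for t, row in zip(tamap.taxis.delays, tamap.dod):
        lines.append(_fmt(t) + "\t" + "\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_tamap(path, return_meta: bool = False):
    """Read a TA map written by :func:`write_tamap`.

    Raises ``ValueError`` naming the offending axis, row or cell on
    non-monotone axes, ragged rows, or non-finite/NaN cells.
    """
    rows, meta = _read_lines(path)
    if len(rows) < 2:
        raise ValueError(f"{path}: not a TA map file (needs header plus data rows)")
    header = rows[0].split("\t")
    if header[0] != TAMAP_CORNER:
        raise ValueError(
            f"{path}: corner cell must be {TAMAP_CORNER!r}, got {header[0]!r}"
        )
    wavelengths = [
        _parse_cell(tok, f"{path}: wavelength header column {j + 1}")
        for j, tok in enumerate(header[1:])
    ]
    n_cols = len(wavelengths)
    if n_cols < 2:
        raise ValueError(f"{path}: wavelength header has {n_cols} entries; need >= 2")

    delays: list[float] = []
    body: list[list[float]] = []
    for i, line in enumerate(rows[1:]):
        tokens = line.split("\t")
        if len(tokens) != n_cols + 1:
            raise ValueError(
                f"{path}: ragged row {i} — expected {n_cols + 1} columns, "
                f"got {len(tokens)}"
            )
        delays.append(_parse_cell(tokens[0], f"{path}: delay column, row {i}"))
        body.append(
            [
                _parse_cell(tok, f"{path}: cell at row {i} (delay), column {j} (wavelength)")
                for j, tok in enumerate(tokens[1:])
            ]
        )

    tamap = TAMap(SpectralAxis(wavelengths), DelayAxis(delays), np.array(body))
    return (tamap, meta) if return_meta else tamap


# ---------------------------------------------------------------------------
# two-column files

def _write_columns(path, header: tuple[str, str], x, y, meta: dict | None) -> None:
    lines = _meta_lines(meta)
    lines.append("\t".join(header))
    for a, b in zip(x, y):
        lines.append(_fmt(a) + "\t" + _fmt(b))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _read_columns(path, header: tuple[str, str]):
    rows, meta = _read_lines(path)
    if not rows:
        raise ValueError(f"{path}: empty file")
    got = tuple(tok.strip() for tok in rows[0].split("\t"))
    if got != header:
        raise ValueError(f"{path}: expected header {header}, got {got}")
    x: list[float] = []
    y: list[float] = []
    for i, line in enumerate(rows[1:]):
        tokens = line.split("\t")
        if len(tokens) != 2:
            raise ValueError(
                f"{path}: ragged row {i} — expected 2 columns, got {len(tokens)}"
            )
        x.append(_parse_cell(tokens[0], f"{path}: row {i}, column {header[0]}"))
        y.append(_parse_cell(tokens[1], f"{path}: row {i}, column {header[1]}"))
    return x, y, meta


def write_spectrum(spectrum: Spectrum, path, meta: dict | None = None) -> None:
    _write_columns(path, SPECTRUM_HEADER, spectrum.saxis.wavelengths, spectrum.values, meta)


def read_spectrum(path, return_meta: bool = False):
    x, y, meta = _read_columns(path, SPECTRUM_HEADER)
    spectrum = Spectrum(SpectralAxis(x), y)
    return (spectrum, meta) if return_meta else spectrum


def write_trace(trace: Trace, path, meta: dict | None = None) -> None:
    combined = dict(trace.meta)
    combined.update(meta or {})
    _write_columns(path, TRACE_HEADER, trace.taxis.delays, trace.values, combined)


def read_trace(path, return_meta: bool = False):
    x, y, meta = _read_columns(path, TRACE_HEADER)
    # probe-window metadata written by write_trace comes back on the object
    trace_meta = {}
    for key in ("center_nm", "bandwidth_nm"):
        if key in meta:
            trace_meta[key] = float(meta[key])
    trace = Trace(DelayAxis(x), y, meta=trace_meta)
    return (trace, meta) if return_meta else trace


# ---------------------------------------------------------------------------
# explicit unit converters (mixed-unit files are refused by construction:
# the formats above only ever carry nm / ps / OD)

def mod_to_od(tamap: TAMap) -> TAMap:
    """Convert a map recorded in mOD to OD."""
    return TAMap(tamap.saxis, tamap.taxis, tamap.dod / 1000.0)


def fs_to_ps(tamap: TAMap) -> TAMap:
    """Convert a map whose delay axis was recorded in fs to ps."""
    return TAMap(tamap.saxis, DelayAxis(tamap.taxis.delays / 1000.0), tamap.dod)
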