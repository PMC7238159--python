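"""CSV/JSON/YAML input and output.

CSV dialect: comma-separated, "." decimal, mandatory header row.  Comment
lines starting with "#" carry block tags in ``key=value`` form
(``temperature_K=363``, ``elapsed_s=300``); a blank line separates
spectra blocks within one file.  JSON reports are written with a type tag
so any stage result round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import types as _types
from .exceptions import ParseError, ValidationError
from .types import DielectricSpectrum, StudyConfig, Thermogram

_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "min": 60.0, "minutes": 60.0,
                 "h": 3600.0, "hours": 3600.0}

#: Serializable result types, by class name.
_REGISTRY = {
    name: getattr(_types, name)
    for name in (
        "Thermogram", "DielectricSpectrum", "KineticCurve", "AvramovResult",
        "NucleationScales", "HNProcess", "HNFit", "MasterPlot", "KWWResult",
        "VFTResult", "ArrheniusResult", "ProcessSeries", "RelaxationMap",
        "CpPoint", "CapacityResult", "CapacityDifference", "KineticTruth",
        "SpectralTruth", "VFTParams", "ArrheniusParams", "StudyConfig",
    )
}


def read_thermogram(
    path: str | Path,
    column_map: dict | None = None,
    negate: bool = False,
) -> Thermogram:
    """Read an isothermal DSC thermogram from CSV.

    ``column_map`` may rename columns and declare the time unit, e.g.
    ``{"time": "t_min", "heat_flow": "hf", "time_unit": "min"}``; defaults
    are ``time_s`` and ``heat_flow_mw``.  ``negate=True`` flips an
    exothermic-negative instrument convention to the internal
    exothermic-positive one.  Header comment lines may carry a
    ``temperature_K`` tag.
    """
    path = Path(path)
    cmap = column_map or {}
    time_col = cmap.get("time", "time_s")
    heat_col = cmap.get("heat_flow", "heat_flow_mw")
    unit = cmap.get("time_unit", "s")
    if unit not in _TIME_FACTORS:
        raise ParseError(f"unknown time unit {unit!r}")
    tags = _read_tags(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    for col in (time_col, heat_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    time = df[time_col].to_numpy(dtype=float) * _TIME_FACTORS[unit]
    hf = df[heat_col].to_numpy(dtype=float)
    if negate:
        hf = -hf
    temperature = float(cmap.get("temperature", tags.get("temperature_K", 363.0)))
    try:
        return Thermogram(time=time, heat_flow=hf, temperature=temperature,
                          label=str(path.name))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_tags(path: Path, lines: list[str] | None = None) -> dict:
    """Parse ``# key=value`` comment tags from a file head or a block."""
    tags = {}
    if lines is None:
        with open(path) as fh:
            lines = []
            for line in fh:
                if not line.startswith("#"):
                    break
                lines.append(line)
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            tags[key.strip()] = value.strip()
    return tags


def _parse_spectrum_block(lines: list[str], origin: str) -> DielectricSpectrum:
    comments = [ln for ln in lines if ln.startswith("#")]
    data_lines = [ln for ln in lines if not ln.startswith("#")]
    tags = _read_tags(Path(origin), comments)
    if not data_lines:
        raise ParseError(f"{origin}: empty spectrum block")
    header = [c.strip() for c in data_lines[0].split(",")]
    required = ("frequency_hz", "eps_real", "eps_imag")
    for col in required:
        if col not in header:
            raise ParseError(f"{origin}: missing column {col!r}")
    idx = {col: header.index(col) for col in required}
    rows = []
    for ln in data_lines[1:]:
        parts = ln.split(",")
        try:
            rows.append([float(parts[idx[c]]) for c in required])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{origin}: malformed row {ln!r}") from exc
    if not rows:
        raise ParseError(f"{origin}: spectrum block has no data rows")
    arr = np.asarray(rows, dtype=float)
    kwargs = {}
    if "temperature_K" in tags:
        kwargs["temperature"] = float(tags["temperature_K"])
    if "elapsed_s" in tags:
        kwargs["elapsed_time"] = float(tags["elapsed_s"])
    try:
        return DielectricSpectrum(
            frequency=arr[:, 0], eps_real=arr[:, 1], eps_imag=arr[:, 2], **kwargs
        )
    except ValidationError as exc:
        raise ParseError(f"{origin}: {exc}") from exc


def read_spectra(
    path: str | Path, tag: str = "elapsed_time"
) -> list[DielectricSpectrum]:
    """Read dielectric spectra from a CSV file (blank-line-separated blocks)
    or a directory of single-spectrum CSV files, sorted ascending by ``tag``
    (``"temperature"`` or ``"elapsed_time"``)."""
    if tag not in ("temperature", "elapsed_time"):
        raise ParseError(f"unknown tag {tag!r}")
    path = Path(path)
    spectra = []
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise ParseError(f"{path}: no CSV files found")
    for fp in files:
        block: list[str] = []
        with open(fp) as fh:
            for raw in list(fh) + [""]:
                line = raw.strip()
                if not line:
                    if block:
                        spectra.append(_parse_spectrum_block(block, str(fp)))
                        block = []
                else:
                    block.append(line)
    if not spectra:
        raise ParseError(f"{path}: no spectra found")
    for sp in spectra:
        if tag == "elapsed_time" and sp.elapsed_time is None:
            raise ParseError(f"{path}: spectrum block lacks an elapsed_s tag")
    key = (lambda s: s.elapsed_time) if tag == "elapsed_time" else (lambda s: s.temperature)
    return sorted(spectra, key=key)


def write_spectra(spectra: list[DielectricSpectrum], path: str | Path) -> None:
    """Write spectra as blank-line-separated tagged CSV blocks."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write(f"# temperature_K={float(sp.temperature)!r}\n")
            if sp.elapsed_time is not None:
                fh.write(f"# elapsed_s={float(sp.elapsed_time)!r}\n")
            fh.write("frequency_hz,eps_real,eps_imag\n")
            for f, er, ei in zip(sp.frequency, sp.eps_real, sp.eps_imag):
                fh.write(f"{float(f)!r},{float(er)!r},{float(ei)!r}\n")
            fh.write("\n")


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    """Write a thermogram as tagged CSV."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={float(tg.temperature)!r}\n")
        fh.write("time_s,heat_flow_mw\n")
        for t, h in zip(tg.time, tg.heat_flow):
            fh.write(f"{float(t)!r},{float(h)!r}\n")


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            "data": {
                f.name: _encode(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        if all(isinstance(k, str) for k in obj):
            return {k: _encode(v) for k, v in obj.items()}
        return {"__dictitems__": [[_encode(k), _encode(v)] for k, v in obj.items()]}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return {"__float__": repr(obj)}
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__type__" in obj:
            cls = _REGISTRY.get(obj["__type__"])
            if cls is None:
                raise ParseError(f"unknown result type {obj['__type__']!r}")
            data = {k: _decode(v) for k, v in obj["data"].items()}
            return cls(**data)
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=float)
        if "__dictitems__" in obj:
            return {_decode(k): _decode(v) for k, v in obj["__dictitems__"]}
        if "__float__" in obj:
            return float(obj["__float__"])
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_report(result, path: str | Path) -> None:
    """Serialize any stage result (or a dict of results) to JSON.

    ``read_report(write_report(x)) == x`` field-by-field to full float
    precision.
    """
    payload = _encode(result)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path):
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return _decode(json.load(fh))


def load_config(path: str | Path | None) -> StudyConfig:
    """Load a :class:`StudyConfig` from a YAML file (None -> defaults)."""
    if path is None:
        return StudyConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return StudyConfig(**raw)
    except TypeError as exc:
        raise ParseError(f"bad config {path}: {exc}") from exc
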