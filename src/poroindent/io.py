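"""Delimited-text formats for curves, observation tables and fit reports.

Instrument exports vary wildly, so the package defines a minimal
comma-delimited dialect with ``#``-prefixed ``key = value`` metadata lines
and a ``columns`` declaration carrying per-column units, e.g.::

    # poroindent curve v1
    # R = 7.5 mm
    # delta_M = 3 mm
    # t_R = 100 s
    # columns = time[s], force[mN], depth[mm]
    0,0,0
    ...

Everything is converted to SI on read; floats are written with 17
significant digits so write -> read round-trips exactly.  Accepted unit
tokens: s, ms (time); N, mN, uN, nN (force; the micro sign is accepted as
an alias); m, mm, um, nm (length).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    ClampMode,
    DomainError,
    Geometry,
    RampObservation,
    RelaxationCurve,
)

__all__ = [
    "ParseError",
    "read_curve",
    "write_curve",
    "read_observations",
    "write_observations",
    "write_fit_report",
    "read_fit_report",
]

_TIME_UNITS = {"s": 1.0, "ms": 1e-3}
_FORCE_UNITS = {"N": 1.0, "mN": 1e-3, "uN": 1e-6, "µN": 1e-6, "nN": 1e-9}
_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_UNITS_BY_KIND = {"time": _TIME_UNITS, "force": _FORCE_UNITS, "length": _LENGTH_UNITS}
_COLUMN_KINDS = {"time": "time", "force": "force", "depth": "length"}
_SCALAR_KINDS = {
    "R": "length", "h": "length", "delta_M": "length",
    "t_R": "time", "F_M": "force", "F_inf": "force",
}


class ParseError(DomainError):
    """Malformed file; message carries the offending line number."""


def _unit_scale(kind: str, token: str, line_no: int) -> float:
    table = _UNITS_BY_KIND[kind]
    if token not in table:
        raise ParseError(
            f"line {line_no}: unknown {kind} unit {token!r}; "
            f"accepted: {', '.join(sorted(set(table)))}"
        )
    return table[token]


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _parse_header(lines) -> tuple[dict, list, int]:
    """Collect '# key = value' metadata; return (meta, columns, first data line#)."""
    meta: dict = {}
    columns: list = []
    i = 0
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        key, value = key.strip(), value.strip()
        if key == "columns":
            for spec in value.split(","):
                spec = spec.strip()
                if "[" in spec:
                    name, _, unit = spec.partition("[")
                    unit = unit.rstrip("]").strip()
                    columns.append((name.strip(), unit))
                else:
                    columns.append((spec, None))
        else:
            meta[key] = value
    return meta, columns, i


def _scalar_si(meta: dict, key: str) -> Optional[float]:
    if key not in meta:
        return None
    parts = meta[key].split()
    try:
        value = float(parts[0])
    except ValueError:
        raise ParseError(f"metadata {key} = {meta[key]!r} is not numeric") from None
    if len(parts) == 1:
        return value  # assumed SI
    kind = _SCALAR_KINDS[key]
    return value * _unit_scale(kind, parts[1], 0)


def read_curve(path: Union[str, Path]) -> RelaxationCurve:
    """Read a force-time curve file, converting all quantities to SI."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, columns, first = _parse_header(lines)
    if not columns:
        raise ParseError("missing '# columns = ...' declaration with units")
    names = [c[0] for c in columns]
    if names[:2] != ["time", "force"]:
        raise ParseError("column schema must start with time, force")
    scales = []
    for name, unit in columns:
        if name not in _COLUMN_KINDS:
            raise ParseError(f"unknown column {name!r}")
        if unit is None:
            raise ParseError(
                f"column {name!r} is missing a unit declaration, e.g. {name}[s]"
            )
        scales.append(_unit_scale(_COLUMN_KINDS[name], unit, 0))

    rows = []
    for line_no, raw in enumerate(lines[first - 1:], start=first):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != len(columns):
            raise ParseError(
                f"line {line_no}: expected {len(columns)} fields, got {len(parts)}"
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise ParseError(f"line {line_no}: non-numeric field") from None
        if any(np.isnan(v) for v in vals):
            raise ParseError(f"line {line_no}: NaN value")
        rows.append(vals)
    if not rows:
        raise ParseError("file contains no data rows")
    data = np.asarray(rows, dtype=float) * np.asarray(scales)
    t = data[:, 0]
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + first + 1
        raise ParseError(f"line ~{bad}: time samples must be strictly increasing")

    R = _scalar_si(meta, "R")
    geometry = None
    if R is not None:
        geometry = Geometry(R, h=_scalar_si(meta, "h"), label=meta.get("label", ""))
    return RelaxationCurve(
        t=t, F=data[:, 1],
        delta=data[:, 2] if data.shape[1] > 2 else None,
        geometry=geometry,
        t_R=_scalar_si(meta, "t_R"),
        F_M=_scalar_si(meta, "F_M"),
        F_inf=_scalar_si(meta, "F_inf"),
        delta_M=_scalar_si(meta, "delta_M"),
        label=meta.get("label", path.stem),
    )


def write_curve(curve: RelaxationCurve, path: Union[str, Path]) -> None:
    """Write a curve in the dialect above (SI units)."""
    path = Path(path)
    out = ["# poroindent curve v1"]
    if curve.label:
        out.append(f"# label = {curve.label}")
    if curve.geometry is not None:
        out.append(f"# R = {_fmt(curve.geometry.R)} m")
        if curve.geometry.h is not None:
            out.append(f"# h = {_fmt(curve.geometry.h)} m")
    for key in ("delta_M", "t_R", "F_M", "F_inf"):
        val = getattr(curve, key)
        if val is not None:
            unit = {"length": "m", "time": "s", "force": "N"}[_SCALAR_KINDS[key]]
            out.append(f"# {key} = {_fmt(val)} {unit}")
    cols = "time[s], force[N]" + (", depth[m]" if curve.delta is not None else "")
    out.append(f"# columns = {cols}")
    for i in range(len(curve)):
        row = [_fmt(curve.t[i]), _fmt(curve.F[i])]
        if curve.delta is not None:
            row.append(_fmt(curve.delta[i]))
        out.append(",".join(row))
    path.write_text("\n".join(out) + "\n")


def read_observations(path: Union[str, Path]) -> list:
    """Read an observation table (one ramp test per row) into SI records."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, columns, first = _parse_header(lines)
    if not columns:
        raise ParseError("missing '# columns = ...' declaration")
    names = [c[0] for c in columns]
    required = {"R", "t_R", "delta_M", "F_M"}
    if not required <= set(names):
        raise ParseError(f"observation table needs columns {sorted(required)}")
    scales = {}
    for name, unit in columns:
        if name in _SCALAR_KINDS:
            if unit is None:
                raise ParseError(f"column {name!r} is missing a unit declaration")
            scales[name] = _unit_scale(_SCALAR_KINDS[name], unit, 0)

    observations = []
    for line_no, raw in enumerate(lines[first - 1:], start=first):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != len(names):
            raise ParseError(
                f"line {line_no}: expected {len(names)} fields, got {len(parts)}"
            )
        row = dict(zip(names, parts))
        try:
            observations.append(RampObservation(
                geometry=Geometry(float(row["R"]) * scales["R"],
                                  label=row.get("label", "")),
                t_R=float(row["t_R"]) * scales["t_R"],
                delta_M=float(row["delta_M"]) * scales["delta_M"],
                F_M=float(row["F_M"]) * scales["F_M"],
                mode=ClampMode(row["mode"]) if "mode" in row
                else ClampMode.DISPLACEMENT,
                label=row.get("label", ""),
            ))
        except (ValueError, DomainError) as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
    if not observations:
        raise ParseError("observation table contains no rows")
    return observations


def write_observations(observations: Sequence[RampObservation],
                       path: Union[str, Path]) -> None:
    """Write ramp observations as a delimited table (SI units)."""
    path = Path(path)
    out = [
        "# poroindent observations v1",
        "# columns = label, R[m], t_R[s], delta_M[m], F_M[N], mode",
    ]
    for o in observations:
        out.append(",".join([
            o.label, _fmt(o.geometry.R), _fmt(o.t_R), _fmt(o.delta_M),
            _fmt(o.F_M), o.mode.value,
        ]))
    path.write_text("\n".join(out) + "\n")


def write_fit_report(result, path: Union[str, Path]) -> None:
    """Serialize a FitResult as JSON, echoing kPa / m^2 s^-1 alongside SI."""
    p = result.params
    payload = {
        "params_SI": {"E_Pa": p.E, "nu": p.nu, "D_m2_per_s": p.D},
        "params_customary": {"E_kPa": p.E / 1e3, "nu": p.nu, "D_m2_per_s": p.D},
        "derived": {
            "shear_modulus_Pa": p.shear_modulus,
            "permeability_m4_per_N_s": p.permeability,
        },
        "rms": result.rms,
        "n_obs": result.n_obs,
        "tau_R": [float(x) for x in result.tau_R],
        "F_star": [float(x) for x in result.F_star],
        "uncertainty": result.uncertainty,
        "flags": list(result.flags),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fit_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
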