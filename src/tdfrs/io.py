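"""File formats: heterodyne trace CSV dialect and condition tables.

Trace files are plain CSV with '#'-prefixed ``key=value`` header lines
carrying the experimental metadata, followed by a ``time_s,zeta[,zeta_sd]``
column header and data rows.  Condition tables are ordinary CSV.  Both are
hand-inspectable and diff-able.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .conditions import ConditionRecord
from .core import ContrastFactors, GratingGeometry
from .signals import HeterodyneTrace, TraceMetadata

__all__ = [
    "TraceFormatError",
    "MANDATORY_TRACE_KEYS",
    "read_trace",
    "write_trace",
    "read_conditions",
    "write_conditions",
]


class TraceFormatError(ValueError):
    """A trace file violates the expected dialect."""


# one of q_per_m / fringe_spacing_m satisfies the geometry requirement
MANDATORY_TRACE_KEYS = (
    "temperature_C",
    "pH",
    "buffer_label",
    "q_per_m",
    "dn_dT",
    "dn_dc",
    "c_weight_fraction",
    "t_excitation_off_s",
)

_FLOAT_KEYS = {
    "temperature_C",
    "pH",
    "q_per_m",
    "fringe_spacing_m",
    "dn_dT",
    "dn_dc",
    "c_weight_fraction",
    "t_excitation_off_s",
}


def _parse_header(path: Path) -> Dict[str, str]:
    header: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
    return header


def _metadata_from_header(
    header: Dict[str, str], strict: bool
) -> TraceMetadata:
    def get(key: str) -> Optional[str]:
        v = header.get(key)
        return None if v in (None, "") else v

    if strict:
        for key in MANDATORY_TRACE_KEYS:
            if key == "q_per_m":
                if get("q_per_m") is None and get("fringe_spacing_m") is None:
                    raise TraceFormatError(
                        "missing mandatory header key: q_per_m (or fringe_spacing_m)"
                    )
                continue
            if key == "buffer_label":
                if "buffer_label" not in header:
                    raise TraceFormatError("missing mandatory header key: buffer_label")
                continue
            if get(key) is None:
                raise TraceFormatError(f"missing mandatory header key: {key}")

    def fget(key: str) -> Optional[float]:
        v = get(key)
        if v is None:
            return None
        try:
            return float(v)
        except ValueError as exc:
            raise TraceFormatError(f"header key {key} is not a number: {v!r}") from exc

    geometry = None
    if fget("q_per_m") is not None:
        geometry = GratingGeometry(q=fget("q_per_m"))
    elif fget("fringe_spacing_m") is not None:
        geometry = GratingGeometry(fringe_spacing=fget("fringe_spacing_m"))
    contrast = None
    if fget("dn_dT") is not None and fget("dn_dc") is not None:
        contrast = ContrastFactors(dn_dT=fget("dn_dT"), dn_dc=fget("dn_dc"))
    return TraceMetadata(
        temperature_c=fget("temperature_C"),
        ph=fget("pH"),
        buffer_label=header.get("buffer_label", ""),
        geometry=geometry,
        contrast=contrast,
        c=fget("c_weight_fraction"),
        t_excitation_off_s=fget("t_excitation_off_s"),
    )


def read_trace(
    path,
    defaults: Optional[Dict[str, Union[str, float]]] = None,
    strict: bool = True,
) -> HeterodyneTrace:
    """Read a heterodyne trace file.

    ``defaults`` supplies header keys missing from the file (e.g. instrument
    constants from a run configuration).  With ``strict=True`` every
    mandatory key must be present after applying defaults.
    """
    path = Path(path)
    header: Dict[str, str] = {}
    if defaults:
        header.update({k: str(v) for k, v in defaults.items()})
    header.update(_parse_header(path))
    metadata = _metadata_from_header(header, strict)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceFormatError(f"cannot parse data columns of {path}: {exc}") from exc
    if df.shape[1] not in (2, 3):
        raise TraceFormatError(
            f"expected 2 or 3 data columns (time_s, zeta[, zeta_sd]), got {df.shape[1]}"
        )
    times = df.iloc[:, 0].to_numpy(dtype=float)
    values = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise TraceFormatError(f"{path}: times are not strictly increasing")
    sd = df.iloc[:, 2].to_numpy(dtype=float) if df.shape[1] == 3 else None
    return HeterodyneTrace(times, values, sd, metadata)


def write_trace(path, trace: HeterodyneTrace) -> None:
    """Write a trace in the '#'-header CSV dialect at full float precision."""
    m = trace.metadata
    lines = []

    def put(key: str, value) -> None:
        if value is not None:
            lines.append(f"# {key}={value:.17g}")

    put("temperature_C", m.temperature_c)
    put("pH", m.ph)
    lines.append(f"# buffer_label={m.buffer_label}")
    if m.geometry is not None:
        put("q_per_m", m.geometry.q)
    if m.contrast is not None:
        put("dn_dT", m.contrast.dn_dT)
        put("dn_dc", m.contrast.dn_dc)
    put("c_weight_fraction", m.c)
    put("t_excitation_off_s", m.t_excitation_off_s)
    cols = ["time_s", "zeta"] + (["zeta_sd"] if trace.per_point_sd is not None else [])
    lines.append(",".join(cols))
    data = [trace.times, trace.values]
    if trace.per_point_sd is not None:
        data.append(trace.per_point_sd)
    buf = _io.StringIO()
    np.savetxt(buf, np.column_stack(data), delimiter=",", fmt="%.17g")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


_CONDITION_COLUMNS = [
    "label",
    "pH",
    "buffer_label",
    "buffer_conc_mM",
    "helix_pct",
    "helix_sd",
    "delta_ST",
    "delta_ST_sd",
]


def read_conditions(path) -> List[ConditionRecord]:
    """Read a condition table CSV into records.

    Missing delta_ST entries load as None (e.g. the shipped helix-content
    fixture before thermodiffusion results are merged in).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CONDITION_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"conditions file missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        delta = row["delta_ST"]
        delta_sd = row["delta_ST_sd"]
        records.append(
            ConditionRecord(
                label=str(row["label"]),
                ph=float(row["pH"]),
                buffer_label="" if pd.isna(row["buffer_label"]) else str(row["buffer_label"]),
                buffer_conc_mm=0.0 if pd.isna(row["buffer_conc_mM"]) else float(row["buffer_conc_mM"]),
                helix_pct=float(row["helix_pct"]),
                helix_sd=0.0 if pd.isna(row["helix_sd"]) else float(row["helix_sd"]),
                delta_st=None if pd.isna(delta) else float(delta),
                delta_st_sd=None if pd.isna(delta_sd) else float(delta_sd),
            )
        )
    return records


def write_conditions(path, records: Sequence[ConditionRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "label": r.label,
                "pH": r.ph,
                "buffer_label": r.buffer_label,
                "buffer_conc_mM": r.buffer_conc_mm,
                "helix_pct": r.helix_pct,
                "helix_sd": r.helix_sd,
                "delta_ST": r.delta_st if r.delta_st is not None else math.nan,
                "delta_ST_sd": r.delta_st_sd if r.delta_st_sd is not None else math.nan,
            }
            for r in records
        ],
        columns=_CONDITION_COLUMNS,
    )
    df.to_csv(path, index=False)
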