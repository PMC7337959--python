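"""CSV readers/writers shared by all modules.

Dialect: comma-separated, header required, UTF-8, '.' decimal; units are
encoded in column names (time_s, extension_um, ...).  Schema violations
are reported with the offending column and row numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fret import EmissionSpectrum
from .kinetics import CleavageTimeCourse
from .rloopsize import RotationCurve
from .traces import BeadTrace, Phase, RotationProtocol

__all__ = [
    "read_time_courses",
    "write_time_courses",
    "read_bead_trace",
    "write_bead_trace",
    "read_rotation_curve",
    "write_rotation_curve",
    "read_spectrum",
    "write_spectrum",
    "read_events",
    "write_events",
    "protocol_from_dict",
]


def _load(path, required: list) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"{path}: file not found")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[coerced.isna() & df[col].notna()].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise SchemaError(f"{path}: non-numeric values in column {col!r} at row(s) {rows}")
    if coerced.isna().any():
        rows = ", ".join(str(i + 2) for i in df.index[coerced.isna()][:5])
        raise SchemaError(f"{path}: missing values in column {col!r} at row(s) {rows}")
    return coerced.to_numpy(dtype=float)


def read_time_courses(path, fractions: bool = False) -> list:
    """Cleavage time courses, one CleavageTimeCourse per replicate.

    Schema: replicate,time_s,sc,oc,lin.  With ``fractions`` the abundances
    are taken as normalised fractions, otherwise as raw counts.
    """
    df = _load(path, ["replicate", "time_s", "sc", "oc", "lin"])
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            CleavageTimeCourse(
                replicate_id=str(rep),
                times=_numeric(grp, "time_s", path),
                sc=_numeric(grp, "sc", path),
                oc=_numeric(grp, "oc", path),
                lin=_numeric(grp, "lin", path),
                is_fraction=fractions,
            )
        )
    if not out:
        raise SchemaError(f"{path}: no data rows")
    return out


def write_time_courses(tcs: list, path) -> None:
    frames = []
    for tc in tcs:
        frames.append(
            pd.DataFrame(
                {
                    "replicate": tc.replicate_id,
                    "time_s": tc.times,
                    "sc": tc.sc,
                    "oc": tc.oc,
                    "lin": tc.lin,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_bead_trace(path, trace_id: str | None = None, sample_rate: float | None = None) -> BeadTrace:
    """Bead trace from time_s,extension_um[,magnet_turns][,force_pN]."""
    df = _load(path, ["time_s", "extension_um"])
    time = _numeric(df, "time_s", path)
    rate = sample_rate
    if rate is None:
        if time.size < 2:
            raise SchemaError(f"{path}: cannot infer sample rate from < 2 samples")
        rate = 1.0 / float(np.median(np.diff(time)))
    return BeadTrace(
        trace_id=trace_id or Path(path).stem,
        time=time,
        extension=_numeric(df, "extension_um", path),
        magnet_turns=_numeric(df, "magnet_turns", path) if "magnet_turns" in df else None,
        sample_rate=rate,
        force_pn=float(df["force_pN"].iloc[0]) if "force_pN" in df else None,
    )


def write_bead_trace(trace: BeadTrace, path) -> None:
    cols = {"time_s": trace.time, "extension_um": trace.extension}
    if trace.magnet_turns is not None:
        cols["magnet_turns"] = trace.magnet_turns
    pd.DataFrame(cols).to_csv(path, index=False)


def read_rotation_curve(path, curve_id: str | None = None, condition: str = "reference") -> RotationCurve:
    """Rotation curve from turns,extension_um."""
    df = _load(path, ["turns", "extension_um"])
    return RotationCurve(
        curve_id=curve_id or Path(path).stem,
        magnet_turns=_numeric(df, "turns", path),
        extension=_numeric(df, "extension_um", path),
        condition=condition,
    )


def write_rotation_curve(curve: RotationCurve, path) -> None:
    pd.DataFrame(
        {"turns": curve.magnet_turns, "extension_um": curve.extension}
    ).to_csv(path, index=False)


def read_spectrum(path, excitation_nm: float) -> EmissionSpectrum:
    """Emission spectrum from wavelength_nm,intensity."""
    df = _load(path, ["wavelength_nm", "intensity"])
    return EmissionSpectrum(
        excitation_nm=excitation_nm,
        emission_nm=_numeric(df, "wavelength_nm", path),
        intensity=_numeric(df, "intensity", path),
    )


def write_spectrum(spec: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.emission_nm, "intensity": spec.intensity}
    ).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Dwell-event table written by the traces module."""
    return _load(path, ["trace_id", "kind", "dwell_s", "step_um", "complete", "censored"])


def write_events(events_frame: pd.DataFrame, path) -> None:
    events_frame.to_csv(path, index=False)


def protocol_from_dict(spec: dict) -> RotationProtocol:
    """Rotation protocol from a YAML/JSON-style mapping:
    {"initial_turns": 0, "phases": [{"start_time": ..., "end_time": ...,
    "target_turns": ..., "rotation_rate": 10}, ...]}."""
    try:
        phases = [
            Phase(
                start_time=float(p["start_time"]),
                end_time=float(p["end_time"]),
                target_turns=float(p["target_turns"]),
                rotation_rate=float(p.get("rotation_rate", 10.0)),
                sense=p.get("sense", ""),
            )
            for p in spec["phases"]
        ]
    except KeyError as exc:
        raise SchemaError(f"protocol phase is missing key {exc}")
    return RotationProtocol(phases=phases, initial_turns=float(spec.get("initial_turns", 0.0)))
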