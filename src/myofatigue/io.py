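"""File formats, schema validation, and EMG envelope preprocessing.

Formats (all plain text):

* model YAML — per-muscle blocks (name, role, F0M_N, l0M_m, lST_m,
  alpha0_deg, fiber_group, fatigue: {F_per_s, R_per_s, r_rest}) and a
  geometry block (phi_deg grid plus per-muscle lMT_m / moment_arm_m lists);
* protocol YAML — ordered segment list;
* motion CSV — t_s, phi_deg, phidot_deg_s, Q_Nm;
* trace CSV — t_s, force_N (optionally force_norm);
* session results — long-format CSV plus a summary JSON.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header.  All
angles on disk are degrees; radians appear only inside the library.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import pathlib
from typing import Dict, Union

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt

from .model import FatigueParameters, GeometryModel, MusculoskeletalModel, \
    MusculotendonParameters
from .session import Protocol, Segment, SessionResult

logger = logging.getLogger(__name__)

PathLike = Union[str, pathlib.Path]

_SEGMENT_FIELDS = {f.name for f in dataclasses.fields(Segment)}


# ---------------------------------------------------------------------------
# model YAML


def save_model_yaml(model: MusculoskeletalModel, path: PathLike) -> None:
    doc = {
        "variant": model.variant_tag,
        "muscles": [
            {
                "name": m.name,
                "role": m.role,
                "F0M_N": float(m.F0M),
                "l0M_m": float(m.l0M),
                "lST_m": float(m.lST),
                "alpha0_deg": float(math.degrees(m.alpha0)),
                "fiber_group": m.fiber_group,
                "fatigue": {
                    "F_per_s": float(m.fatigue.F),
                    "R_per_s": float(m.fatigue.R),
                    "r_rest": float(m.fatigue.r_rest),
                },
            }
            for m in model.muscles
        ],
        "geometry": {
            "phi_deg": [float(v) for v in model.geometry.phi_deg],
            "tables": {
                name: {
                    "lMT_m": [float(v) for v in model.geometry.lmt_tables[name]],
                    "moment_arm_m": [
                        float(v) for v in model.geometry.arm_tables[name]
                    ],
                }
                for name in model.geometry.muscle_names
            },
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_model_yaml(path: PathLike) -> MusculoskeletalModel:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    for key in ("muscles", "geometry"):
        if key not in doc:
            raise ValueError(f"model file {path}: missing required block {key!r}")
    known = {"variant", "muscles", "geometry"}
    for extra in set(doc) - known:
        logger.warning("model file %s: ignoring unknown top-level field %r", path, extra)
    muscles = []
    for block in doc["muscles"]:
        required = {"name", "role", "F0M_N", "l0M_m", "lST_m"}
        missing = required - set(block)
        if missing:
            raise ValueError(f"model file {path}: muscle block missing {sorted(missing)}")
        fatigue = block.get("fatigue", {})
        muscles.append(
            MusculotendonParameters(
                name=block["name"],
                role=block["role"],
                F0M=float(block["F0M_N"]),
                l0M=float(block["l0M_m"]),
                lST=float(block["lST_m"]),
                alpha0=math.radians(float(block.get("alpha0_deg", 0.0))),
                fiber_group=block.get("fiber_group", "undivided"),
                fatigue=FatigueParameters(
                    F=float(fatigue.get("F_per_s", 0.004)),
                    R=float(fatigue.get("R_per_s", 0.01)),
                    r_rest=float(fatigue.get("r_rest", 1.0)),
                ),
            )
        )
    geo = doc["geometry"]
    tables = geo["tables"]
    geometry = GeometryModel(
        geo["phi_deg"],
        {name: tab["lMT_m"] for name, tab in tables.items()},
        {name: tab["moment_arm_m"] for name, tab in tables.items()},
    )
    return MusculoskeletalModel(muscles, geometry, doc.get("variant", "7M"))


# ---------------------------------------------------------------------------
# protocol YAML


def save_protocol(protocol: Protocol, path: PathLike) -> None:
    doc = {
        "segments": [
            {k: v for k, v in dataclasses.asdict(seg).items() if v is not None}
            for seg in protocol.segments
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_protocol(path: PathLike) -> Protocol:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if "segments" not in doc:
        raise ValueError(f"protocol file {path}: missing 'segments'")
    segments = []
    for i, block in enumerate(doc["segments"]):
        if "kind" not in block:
            raise ValueError(f"protocol file {path}: segment {i} missing 'kind'")
        unknown = set(block) - _SEGMENT_FIELDS
        if unknown:
            logger.warning(
                "protocol file %s: segment %d: ignoring unknown fields %s",
                path, i, sorted(unknown),
            )
        segments.append(
            Segment(**{k: v for k, v in block.items() if k in _SEGMENT_FIELDS})
        )
    return Protocol(segments=segments)


# ---------------------------------------------------------------------------
# time-series CSV


def _check_timeseries(df: pd.DataFrame, path: PathLike, required: set) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    t = df["t_s"].to_numpy()
    if np.any(~np.isfinite(df[sorted(required)].to_numpy())):
        raise ValueError(f"{path}: non-finite values present")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: t_s must be strictly increasing")


def read_motion_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_timeseries(df, path, {"t_s", "phi_deg", "phidot_deg_s", "Q_Nm"})
    return df


def write_motion_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def read_trace_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_timeseries(df, path, {"t_s", "force_N"})
    return df


def write_trace_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# session results


def write_session_result(result: SessionResult, csv_path: PathLike,
                         summary_path: PathLike) -> None:
    result.muscle.to_csv(csv_path, index=False)
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(result.summary(), fh, indent=2)


def read_session_muscle_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"t_s", "muscle", "force_N", "activation", "Ma", "Mr", "Mf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# EMG preprocessing


def emg_envelope(
    raw: pd.DataFrame,
    mvc_reference_max: float,
    fs_hz: float = 1000.0,
    cutoff_hz: float = 6.0,
    order: int = 5,
) -> pd.DataFrame:
    """Rectified, zero-phase low-pass filtered, MVC-normalized EMG envelope.

    Full-wave rectification followed by a forward-and-reverse (zero lag)
    5th-order Butterworth low-pass at 6 Hz, then division by the maximal
    envelope value observed during the reference MVC.
    """
    if mvc_reference_max <= 0:
        raise ValueError("MVC reference maximum must be positive")
    if "t_s" not in raw.columns:
        raise ValueError("raw EMG table needs a t_s column")
    signal_cols = [c for c in raw.columns if c != "t_s"]
    if not signal_cols:
        raise ValueError("raw EMG table has no signal columns")
    b, a = butter(order, cutoff_hz, fs=fs_hz, btype="low")
    out = {"t_s": raw["t_s"].to_numpy()}
    for col in signal_cols:
        rectified = np.abs(raw[col].to_numpy(dtype=float))
        out[col] = filtfilt(b, a, rectified) / mvc_reference_max
    return pd.DataFrame(out)
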