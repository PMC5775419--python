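"""File round-trips: trace CSV, study CSV, calibration JSON, packaged data.

CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header; units
are embedded in the column names so files stay unambiguous on their own.
Lines starting with '#' are comments.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve, CalibrationPoint
from .comfort import SubjectSession, ThermalStatus
from .errors import FormatError, TraceValidationError
from .synth import CapacitanceTrace

TRACE_COLUMNS = ["time_s", "capacitance_pF"]
STUDY_COLUMNS = ["subject", "status", "reading_index", "sweat_rate_gm2h"]

_UNIFORMITY_TOL_S = 1e-6


def write_trace_csv(trace: CapacitanceTrace, path: str | Path) -> Path:
    """Write a trace as CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    frame = pd.DataFrame(
        {"time_s": trace.times_s, "capacitance_pF": trace.capacitances_pf}
    )
    frame.to_csv(path, index=False)
    meta = dict(trace.metadata, sampling_rate_hz=trace.sampling_rate_hz)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_trace_csv(path: str | Path) -> CapacitanceTrace:
    """Read a trace CSV, validating layout and uniform monotone sampling."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    if list(frame.columns) != TRACE_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {TRACE_COLUMNS}, found {list(frame.columns)}"
        )
    times = frame["time_s"].to_numpy(dtype=float)
    if times.size > 1:
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise TraceValidationError(f"{path}: time column is not strictly increasing")
        if np.any(np.abs(steps - steps[0]) > _UNIFORMITY_TOL_S):
            raise TraceValidationError(f"{path}: timestamps are not uniformly spaced")
        fs = 1.0 / steps[0]
    else:
        fs = float("nan")
    metadata = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        fs = metadata.pop("sampling_rate_hz", fs)
    return CapacitanceTrace(
        times_s=times,
        capacitances_pf=frame["capacitance_pF"].to_numpy(dtype=float),
        sampling_rate_hz=fs,
        metadata=metadata,
    )


def write_study_csv(sessions: list[SubjectSession], path: str | Path) -> Path:
    """Write study sessions as tidy CSV: subject,status,reading_index,sweat_rate_gm2h."""
    rows = []
    for session in sessions:
        for status, readings in session.records:
            for i, value in enumerate(readings):
                rows.append((session.subject_id, status.code, i, value))
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(Path(path), index=False)
    return Path(path)


def read_study_csv(path: str | Path) -> list[SubjectSession]:
    """Read a tidy study CSV back into per-subject sessions."""
    frame = pd.read_csv(path, comment="#")
    if list(frame.columns) != STUDY_COLUMNS:
        raise FormatError(f"{path}: expected columns {STUDY_COLUMNS}")
    sessions = []
    for subject, group in frame.groupby("subject", sort=True):
        records = []
        for code, sub in group.groupby("status", sort=True):
            readings = sub.sort_values("reading_index")["sweat_rate_gm2h"].tolist()
            records.append((ThermalStatus(int(code)), readings))
        sessions.append(SubjectSession(subject_id=str(subject), records=records))
    return sessions


def write_calibration_json(curve: CalibrationCurve, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(dataclasses.asdict(curve), indent=2))
    return Path(path)


def read_calibration_json(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve(**json.loads(Path(path).read_text()))


def write_points_csv(points: list[CalibrationPoint], path: str | Path) -> Path:
    pd.DataFrame(
        [(p.sweat_rate_gm2h, p.rising_rate_pf_per_s) for p in points],
        columns=["sweat_rate_gm2h", "slope_pF_per_s"],
    ).to_csv(Path(path), index=False)
    return Path(path)


def read_points_csv(path: str | Path) -> list[CalibrationPoint]:
    frame = pd.read_csv(path, comment="#")
    if list(frame.columns) != ["sweat_rate_gm2h", "slope_pF_per_s"]:
        raise FormatError(f"{path}: expected columns sweat_rate_gm2h,slope_pF_per_s")
    return [
        CalibrationPoint(float(r.sweat_rate_gm2h), float(r.slope_pF_per_s))
        for r in frame.itertuples()
    ]


def load_device_preset(name: str = "pf5060_watch") -> dict:
    """Load a packaged device-constant preset (YAML) by name."""
    text = resources.files("sweatwatch.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def load_human_fixture() -> tuple[dict[str, list[float]], dict[int, tuple[float, float]]]:
    """Packaged three-subject study summary numbers.

    Returns ``(per-subject adjacent-difference lists, per-status (mean, sd)
    moments)`` for the tabulated seated warm-up study.
    """
    with resources.files("sweatwatch.data").joinpath(
        "human_experiment_fixture.csv"
    ).open() as handle:
        frame = pd.read_csv(handle, comment="#")
    diffs: dict[str, list[float]] = {}
    part = frame[frame["table"] == "adjacent_diff"]
    for subject, group in part.groupby("subject", sort=True):
        diffs[str(subject)] = group.sort_values("status")["value"].tolist()
    moments: dict[int, tuple[float, float]] = {}
    part = frame[frame["table"] == "status_summary"]
    for code, group in part.groupby("status", sort=True):
        by_q = dict(zip(group["quantity"], group["value"]))
        moments[int(code)] = (by_q["mean_gm2h"], by_q["sd_gm2h"])
    return diffs, moments
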