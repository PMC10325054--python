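"""Readers and writers for the pipeline's table dialects.

All CSVs are comma-delimited UTF-8 with headers.  The pose-tracking
dialect follows the DeepLabCut convention: three header rows (scorer /
bodyparts / coords), a frame-index first column, and per-bodypart
x, y[, likelihood] triples.  Readers validate rather than coerce:
malformed headers and non-numeric cells raise with the offending
location.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import validate_trials
from .ephys import UnitSpikeTrain, WindEpochSeries
from .kinematics import WhiskerTrajectory
from .morphometrics import MorphometryRecord


def write_dlc_csv(
    trajectories: Sequence[WhiskerTrajectory],
    path,
    scorer: str = "synthetic",
    include_likelihood: bool = True,
) -> None:
    """Write trajectories in the DeepLabCut 3-header-row CSV dialect.

    A likelihood column of 1.0 is emitted for trajectories that carry
    none (synthetic data is perfectly 'tracked').
    """
    if not trajectories:
        raise ValueError("nothing to write")
    n = len(trajectories[0])
    if any(len(t) != n for t in trajectories):
        raise ValueError("trajectories must share a frame count")
    cols, data = [], []
    coords = ("x", "y", "likelihood") if include_likelihood else ("x", "y")
    for t in trajectories:
        for coord in coords:
            cols.append((scorer, t.whisker_id, coord))
            if coord == "x":
                data.append(t.x)
            elif coord == "y":
                data.append(t.y)
            else:
                lk = t.likelihood if t.likelihood is not None else np.ones(n)
                data.append(lk)
    frame = pd.DataFrame(
        np.column_stack(data),
        columns=pd.MultiIndex.from_tuples(cols, names=["scorer", "bodyparts", "coords"]),
    )
    frame.index.name = None
    frame.to_csv(path)


def read_dlc_csv(path, frame_rate: float = 100.0) -> list[WhiskerTrajectory]:
    """Read a DeepLabCut-dialect CSV into one trajectory per bodypart.

    The likelihood column is retained when present and absent otherwise.
    """
    try:
        frame = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, IndexError) as exc:
        raise ValueError(f"{path}: not a 3-header-row tracking CSV ({exc})") from exc
    names = [str(n).lower() if n is not None else "" for n in frame.columns.names]
    level_ok = len(frame.columns.levels) == 3 if hasattr(frame.columns, "levels") else False
    if not level_ok:
        raise ValueError(f"{path}: expected scorer/bodyparts/coords header rows")
    coords_level = frame.columns.get_level_values(-1)
    if not set(coords_level) <= {"x", "y", "likelihood"}:
        bad = sorted(set(coords_level) - {"x", "y", "likelihood"})
        raise ValueError(f"{path}: unknown coordinate columns {bad} in header row 3")
    out = []
    bodyparts = list(dict.fromkeys(frame.columns.get_level_values(1)))
    for bp in bodyparts:
        sub = frame.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y"):
            if coord not in sub.columns:
                raise ValueError(f"{path}: bodypart {bp!r} lacks {coord!r} column")
        x = _numeric(sub["x"], path, f"{bp}/x")
        y = _numeric(sub["y"], path, f"{bp}/y")
        lk = (
            _numeric(sub["likelihood"], path, f"{bp}/likelihood")
            if "likelihood" in sub.columns
            else None
        )
        out.append(
            WhiskerTrajectory(
                whisker_id=str(bp), x=x, y=y, frame_rate=frame_rate, likelihood=lk
            )
        )
    return out


def _numeric(series: pd.Series, path, where: str) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & series.notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"{path}: non-numeric value in column {where}, row {row}")
    return values.to_numpy(dtype=float)


# --- spike / epoch tables -------------------------------------------------

def write_spikes_csv(units: Sequence[UnitSpikeTrain], path) -> None:
    rows = [
        {"unit_id": u.unit_id, "region": u.region, "t_s": t}
        for u in units
        for t in u.spike_times
    ]
    # emit silent units too, so the roster round-trips
    roster = [
        {"unit_id": u.unit_id, "region": u.region, "t_s": np.nan}
        for u in units
        if u.spike_times.size == 0
    ]
    pd.DataFrame(rows + roster, columns=["unit_id", "region", "t_s"]).to_csv(
        path, index=False
    )


def read_spikes_csv(path) -> list[UnitSpikeTrain]:
    frame = pd.read_csv(path)
    for col in ("unit_id", "region", "t_s"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for (unit, region), grp in frame.groupby(["unit_id", "region"], sort=True):
        times = grp["t_s"].dropna().to_numpy(dtype=float)
        out.append(
            UnitSpikeTrain(unit_id=str(unit), region=str(region), spike_times=np.sort(times))
        )
    return out


def write_epochs_csv(epochs: WindEpochSeries, path) -> None:
    pd.DataFrame(
        {
            "onset_s": epochs.onsets,
            "speed_mps": epochs.speeds,
            "duration_s": epochs.duration,
        }
    ).to_csv(path, index=False)


def read_epochs_csv(path) -> WindEpochSeries:
    frame = pd.read_csv(path)
    for col in ("onset_s", "speed_mps", "duration_s"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    durations = frame["duration_s"].unique()
    if durations.size != 1:
        raise ValueError(f"{path}: epochs must share one duration")
    return WindEpochSeries(
        onsets=frame["onset_s"].to_numpy(dtype=float),
        speeds=frame["speed_mps"].to_numpy(dtype=float),
        duration=float(durations[0]),
    )


# --- morphometry / behavior ----------------------------------------------

def write_morphometry_csv(records: Sequence[MorphometryRecord], path) -> None:
    pd.DataFrame(
        {
            "whisker_id": [r.whisker_id for r in records],
            "length_mm": [r.length for r in records],
            "diameter_um": [r.base_diameter for r in records],
            "aperture_deg": [r.ring_wulst_aperture for r in records],
        }
    ).to_csv(path, index=False)


def read_morphometry_csv(path) -> list[MorphometryRecord]:
    frame = pd.read_csv(path)
    for col in ("whisker_id", "length_mm", "diameter_um"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    has_ap = "aperture_deg" in frame.columns
    out = []
    for _, row in frame.iterrows():
        ap = row["aperture_deg"] if has_ap and pd.notna(row.get("aperture_deg")) else None
        out.append(
            MorphometryRecord(
                whisker_id=str(row["whisker_id"]),
                length=float(row["length_mm"]),
                base_diameter=float(row["diameter_um"]),
                ring_wulst_aperture=float(ap) if ap is not None else None,
            )
        )
    return out


def write_behavior_csv(table: pd.DataFrame, path) -> None:
    validate_trials(table).to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path))
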