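"""Session containers and CSV round-trip for 90 Hz behavior + gaze logs.

A :class:`SessionLog` wraps one frame-level table (time, position, heading,
joystick speed, gaze ground point, gaze direction vector in the head frame,
pupil openness) plus the frame rate; a :class:`TrialRecord` carries per-trial
metadata and the epoch boundaries (search / pre-movement / movement).  Both
round-trip losslessly through plain CSV at microsecond/micrometer precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SessionLog", "TrialRecord", "write_session", "read_session",
           "SCHEMA_VERSION", "FRAME_COLUMNS"]

SCHEMA_VERSION = 1

FRAME_COLUMNS = [
    "t", "pos_x", "pos_y", "heading_deg", "joy_speed",
    "gaze_x", "gaze_y", "gdir_x", "gdir_y", "gdir_z", "pupil_open",
]

_TRIAL_FIELDS = [
    "trial_id", "start", "goal", "t_appear", "t_foveate", "t_onset",
    "t_offset", "t_press", "points", "skipped", "no_movement", "first_of_run",
]


@dataclass
class TrialRecord:
    """Per-trial metadata; times in seconds on the session clock.

    Epochs: search ``[t_appear, t_foveate)``, pre-movement
    ``[t_foveate, t_onset)``, movement ``[t_onset, t_offset]``.
    ``first_of_run`` flags trials affected by the run-start teleport artifact,
    excluded from path-length analyses.
    """

    trial_id: int
    start: int
    goal: int
    t_appear: float
    t_foveate: float
    t_onset: float = float("nan")
    t_offset: float = float("nan")
    t_press: float = float("nan")
    points: int = 0
    skipped: bool = False
    no_movement: bool = False
    first_of_run: bool = False


class SessionLog:
    """Frame-level behavior + gaze stream for one session."""

    def __init__(self, frames: pd.DataFrame, frame_rate: float = 90.0,
                 arena=None, trials: list[TrialRecord] | None = None):
        missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
        if missing:
            raise ValueError(f"frame table missing columns: {missing}")
        t = frames["t"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("frame timestamps must be strictly increasing")
        self.frames = frames.reset_index(drop=True)
        self.frame_rate = float(frame_rate)
        self.arena = arena
        self.trials: list[TrialRecord] = trials or []
        if "gaze_valid" not in self.frames.columns:
            self.frames["gaze_valid"] = True

    def __len__(self) -> int:
        return len(self.frames)

    def copy(self) -> "SessionLog":
        return SessionLog(self.frames.copy(), self.frame_rate, self.arena,
                          list(self.trials))

    def trial_frames(self, trial: TrialRecord,
                     epoch: str | None = None) -> pd.DataFrame:
        """Frames of one trial, optionally restricted to a single epoch."""
        t = self.frames["t"]
        t_end = trial.t_press if np.isfinite(trial.t_press) else t.iloc[-1]
        sel = (t >= trial.t_appear) & (t <= t_end)
        if epoch is not None:
            lo, hi = self._epoch_bounds(trial, epoch)
            sel &= (t >= lo) & (t < hi)
        return self.frames[sel]

    def _epoch_bounds(self, trial: TrialRecord, epoch: str) -> tuple[float, float]:
        if epoch == "search":
            return trial.t_appear, trial.t_foveate
        if epoch == "pre-movement":
            return trial.t_foveate, trial.t_onset
        if epoch == "movement":
            # movement includes its offset frame
            return trial.t_onset, np.nextafter(trial.t_offset, np.inf)
        raise ValueError(f"unknown epoch {epoch!r}")

    def epoch_labels(self, trial: TrialRecord, frames: pd.DataFrame) -> np.ndarray:
        """Label each frame of ``frames`` with its epoch for ``trial``."""
        t = frames["t"].to_numpy()
        lab = np.full(len(t), "post", dtype=object)
        lab[(t >= trial.t_appear) & (t < trial.t_foveate)] = "search"
        if np.isfinite(trial.t_onset):
            lab[(t >= trial.t_foveate) & (t < trial.t_onset)] = "pre-movement"
            lab[(t >= trial.t_onset) & (t <= trial.t_offset)] = "movement"
        else:
            lab[t >= trial.t_foveate] = "pre-movement"
        return lab


# ---------------------------------------------------------------------------
# CSV round-trip

def write_session(log: SessionLog, trials: list[TrialRecord], path) -> None:
    """Write ``<path>.frames.csv`` and ``<path>.trials.csv``.

    Each file starts with a ``#`` metadata line embedding the schema version
    and frame rate.  Floats are written with 6 decimals (1e-6 s / 1e-6 m),
    which round-trips all analysis-relevant precision.
    """
    path = Path(path)
    meta = json.dumps({"schema": "navgaze-session", "version": SCHEMA_VERSION,
                       "frame_rate": log.frame_rate})
    fpath = path.with_suffix(".frames.csv")
    tpath = path.with_suffix(".trials.csv")
    cols = FRAME_COLUMNS + (["gaze_valid"] if "gaze_valid" in log.frames else [])
    with open(fpath, "w") as f:
        f.write(f"# {meta}\n")
        log.frames[cols].to_csv(f, index=False, float_format="%.6f")
    tdf = pd.DataFrame([asdict(tr) for tr in trials], columns=_TRIAL_FIELDS)
    with open(tpath, "w") as f:
        f.write(f"# {meta}\n")
        tdf.to_csv(f, index=False, float_format="%.6f")


def read_session(path, arena=None) -> tuple[SessionLog, list[TrialRecord]]:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    fpath = path.with_suffix(".frames.csv")
    tpath = path.with_suffix(".trials.csv")
    meta = _read_meta(fpath)
    frames = _read_table(fpath, FRAME_COLUMNS)
    trials_df = _read_table(tpath, _TRIAL_FIELDS)
    trials = []
    for _, row in trials_df.iterrows():
        trials.append(TrialRecord(
            trial_id=int(row["trial_id"]), start=int(row["start"]),
            goal=int(row["goal"]), t_appear=float(row["t_appear"]),
            t_foveate=float(row["t_foveate"]), t_onset=float(row["t_onset"]),
            t_offset=float(row["t_offset"]), t_press=float(row["t_press"]),
            points=int(row["points"]), skipped=bool(row["skipped"]),
            no_movement=bool(row["no_movement"]),
            first_of_run=bool(row["first_of_run"]),
        ))
    log = SessionLog(frames, meta["frame_rate"], arena, trials)
    return log, trials


def _read_meta(path: Path) -> dict:
    with open(path) as f:
        first = f.readline().strip()
    if not first.startswith("# "):
        raise ValueError(f"{path}: missing metadata header line")
    meta = json.loads(first[2:])
    if meta.get("schema") != "navgaze-session":
        raise ValueError(f"{path}: unrecognized schema {meta.get('schema')!r}")
    if meta.get("version") != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {meta.get('version')} "
            f"(expected {SCHEMA_VERSION})"
        )
    return meta


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed CSV ({e})") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # NaN epoch times (t_*) are legitimate for no-movement trials
    bad = [c for c in required if not c.startswith("t_") and df[c].isna().any()]
    if bad:
        row = int(df.index[df[bad[0]].isna()][0]) + 2  # 1-based + header line
        raise ValueError(f"{path}: missing value in column {bad[0]!r}, row {row}")
    return df
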