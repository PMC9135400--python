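"""Detection of forward/backward gaze sweeps along the intended trajectory.

The gaze ground point of each frame is projected onto the trial's trajectory
and expressed as an arc-length fraction ``f(t)``.  Periods when the
median-filtered ``f`` consecutively ascends (descends) are *runs* with signed
length ``m`` (+frames ascending, -frames descending).  A permutation null for
``m`` is built by re-projecting the same gaze onto the participant's
trajectories from 20 other trials; runs whose signed length falls in the
tails of the null CDF (two-sided, alpha = 0.02) are classified as forward /
backward sweeps, then post-processed: same-direction sweeps separated by
fewer than 25 frames are merged; sweeps off-trajectory (> 2 m) on more than
30% of frames, shorter than 25 frames, with ``f`` variance below 0.001, or
covering less than 20% of the trajectory are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaze import project_gaze_on_trajectory, rolling_median
from .planning import Trajectory

__all__ = [
    "SweepNull",
    "Sweep",
    "monotone_runs",
    "build_sweep_null",
    "classify_sweeps",
    "sweep_statistics",
    "filtered_fraction",
]

MEDIAN_WINDOW = 20  # frames
ALPHA = 0.02
MERGE_GAP = 25  # frames
MIN_DURATION = 25  # frames
OFF_TRAJ_MAX = 0.30
MIN_F_VARIANCE = 0.001
MIN_COVERAGE = 0.20


@dataclass
class SweepNull:
    """Null distribution over signed run lengths m (frames)."""

    values: np.ndarray  # sorted pooled m values from shuffled projections
    n_trajectories: int
    alpha: float = ALPHA

    def pmf(self) -> dict[int, float]:
        vals, counts = np.unique(self.values, return_counts=True)
        return {int(v): float(c) / len(self.values)
                for v, c in zip(vals, counts)}

    def cdf(self, m: int) -> float:
        """P(M <= m) under the null."""
        return float(np.searchsorted(self.values, m, side="right")
                     / len(self.values))


@dataclass
class Sweep:
    trial_id: int
    direction: str  # "forward" | "backward"
    start: int  # frame index within the trial series (inclusive)
    end: int  # inclusive
    coverage: float  # |f_end - f_start|
    speed_mps: float  # along-trajectory speed
    saccade_count: int = 0
    epoch: str = ""

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def filtered_fraction(gaze_xy: np.ndarray, trajectory: Trajectory,
                      radius_m: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Median-filtered trajectory fraction series and its validity mask.

    The 20-frame median filter runs over the raw ``f`` with off-trajectory
    frames held as NaN (they split runs rather than bridging them).
    """
    f, valid = project_gaze_on_trajectory(gaze_xy, trajectory, radius_m)
    f_filt = rolling_median(f, MEDIAN_WINDOW)
    f_filt = np.where(valid, f_filt, np.nan)
    return f_filt, valid


def monotone_runs(f: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal non-reversing runs of a (filtered) fraction series.

    Returns ``(start, end, m)`` tuples with inclusive frame indices and
    signed length ``m`` (+frames for ascending, -frames for descending).
    Masked (NaN) frames split runs; plateaus (exact ties, which the median
    filter produces in abundance) terminate runs, so flats never inflate
    ``m``.  The null distribution is built from identically processed
    series, so the convention cannot bias the significance test.
    """
    x = np.asarray(f, dtype=float)
    n = len(x)
    runs = []
    i = 0
    while i < n - 1:
        if not (np.isfinite(x[i]) and np.isfinite(x[i + 1])):
            i += 1
            continue
        d = x[i + 1] - x[i]
        if d == 0.0:
            i += 1
            continue
        sign = 1 if d > 0 else -1
        j = i + 1
        while (j < n - 1 and np.isfinite(x[j + 1])
               and (x[j + 1] - x[j]) * sign > 0):
            j += 1
        runs.append((i, j, (j - i + 1) * sign))
        i = j
    return runs


def build_sweep_null(gaze_xy: np.ndarray, other_trajectories: list[Trajectory],
                     seed, n_draw: int = 20,
                     radius_m: float = 2.0) -> SweepNull:
    """Permutation null: project this trial's gaze onto other trials' paths.

    ``n_draw`` trajectories are drawn without replacement (seeded); if fewer
    are available they are drawn with replacement, with a warning.  The signed
    run lengths of all shuffled, median-filtered projections are pooled.
    """
    if not other_trajectories:
        raise ValueError("no other trajectories available for the null")
    rng = np.random.default_rng(seed)
    k = len(other_trajectories)
    if k >= n_draw:
        idx = rng.choice(k, size=n_draw, replace=False)
    else:
        warnings.warn(
            f"only {k} other trajectories; sampling {n_draw} with replacement",
            stacklevel=2)
        idx = rng.choice(k, size=n_draw, replace=True)
    ms = []
    for i in idx:
        f_filt, _ = filtered_fraction(gaze_xy, other_trajectories[int(i)],
                                      radius_m)
        ms.extend(m for _, _, m in monotone_runs(f_filt))
    if not ms:
        ms = [0]
    return SweepNull(np.sort(np.asarray(ms)), n_draw)


def classify_sweeps(gaze_xy: np.ndarray, trajectory: Trajectory,
                    null: SweepNull, trial_id: int = 0,
                    frame_rate: float = 90.0, alpha: float = ALPHA,
                    radius_m: float = 2.0,
                    epochs: np.ndarray | None = None,
                    saccade_onsets: np.ndarray | None = None) -> list[Sweep]:
    """Classify significant monotone gaze excursions along the trajectory.

    Runs in the lower tail of the null CDF (strictly below alpha/2) become
    backward sweeps; runs strictly above 1 - alpha/2 become forward sweeps.
    Post-processing applies, in order: merge same-direction sweeps separated
    by < 25 frames; drop sweeps off-trajectory on > 30% of frames; drop
    sweeps shorter than 25 frames; drop sweeps with f-variance < 0.001; drop
    sweeps covering < 20% of the trajectory.
    """
    f_filt, valid = filtered_fraction(gaze_xy, trajectory, radius_m)
    runs = monotone_runs(f_filt)
    cands = []
    for a, b, m in runs:
        c = null.cdf(m)
        if m < 0 and c < alpha / 2.0:
            cands.append([a, b, "backward"])
        elif m > 0 and c > 1.0 - alpha / 2.0:
            cands.append([a, b, "forward"])
    # 1) merge same-direction sweeps with gaps < MERGE_GAP
    merged = []
    for a, b, d in cands:
        if merged and merged[-1][2] == d and a - merged[-1][1] < MERGE_GAP:
            merged[-1][1] = b
        else:
            merged.append([a, b, d])
    out = []
    for a, b, d in merged:
        # 2) off-trajectory fraction
        off = 1.0 - valid[a:b + 1].mean()
        if off > OFF_TRAJ_MAX:
            continue
        # 3) minimum duration
        if b - a + 1 < MIN_DURATION:
            continue
        seg = f_filt[a:b + 1]
        seg = seg[np.isfinite(seg)]
        # 4) minimum variance (removes fixation periods)
        if len(seg) < 2 or seg.var() < MIN_F_VARIANCE:
            continue
        # 5) minimum coverage
        coverage = float(abs(seg[-1] - seg[0]))
        if coverage < MIN_COVERAGE:
            continue
        dur_s = (b - a + 1) / frame_rate
        speed = coverage * trajectory.length_m / dur_s
        sw = Sweep(trial_id, d, int(a), int(b), coverage, speed)
        if epochs is not None:
            ep, counts = np.unique(np.asarray(epochs)[a:b + 1],
                                   return_counts=True)
            sw.epoch = str(ep[counts.argmax()])
        if saccade_onsets is not None:
            so = np.asarray(saccade_onsets)
            sw.saccade_count = int(((so >= a) & (so <= b)).sum())
        out.append(sw)
    return out


def sweep_statistics(sweeps: list[Sweep], trajectory_length_m: float,
                     frame_rate: float = 90.0,
                     epoch_frame_counts: dict | None = None) -> pd.DataFrame:
    """Tidy per-sweep table plus per-epoch sweeping-time fractions.

    Returns a DataFrame with one row per sweep (direction, epoch, duration,
    coverage, speed, saccades).  ``epoch_frame_counts`` (epoch -> frames)
    enables ``attrs['epoch_fractions']``: fraction of each epoch's time spent
    sweeping in each direction.
    """
    rows = [
        {
            "trial_id": s.trial_id,
            "direction": s.direction,
            "epoch": s.epoch,
            "start": s.start,
            "end": s.end,
            "duration_s": s.n_frames / frame_rate,
            "coverage": s.coverage,
            "speed_mps": s.speed_mps,
            "saccades": s.saccade_count,
        }
        for s in sweeps
    ]
    df = pd.DataFrame(rows, columns=[
        "trial_id", "direction", "epoch", "start", "end", "duration_s",
        "coverage", "speed_mps", "saccades",
    ])
    if epoch_frame_counts:
        fracs = {}
        for ep, total in epoch_frame_counts.items():
            for d in ("forward", "backward"):
                frames = sum(
                    s.n_frames for s in sweeps
                    if s.epoch == ep and s.direction == d
                )
                fracs[(ep, d)] = frames / total if total else 0.0
        df.attrs["epoch_fractions"] = fracs
    return df
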