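"""Gaze pipeline: blink filtering, epoch segmentation, spread and goal
statistics, trajectory projection, saccade and turn (subgoal) detection,
common-timeline resampling, and alternative-trajectory analysis.

Conventions
-----------
* Blink frames (pupil openness < 0.8) are masked, never dropped: gaze columns
  become unusable while position/joystick streams stay intact.
* Movement onset/offset come from a 5-frame moving average of the absolute
  joystick speed crossing 0.2 m/s (about 10% of the 4.75 m/s cap).
* Smoothing filters use edge-truncated windows (no padding is invented).
* The gaze direction vector lives in a head frame with y forward, x right,
  z up; azimuth/elevation and angular speed follow from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import Arena
from .planning import Trajectory, value_iteration, optimal_path, move_graph
from .session import SessionLog, TrialRecord

__all__ = [
    "GazeAngles",
    "filter_blinks",
    "segment_epochs",
    "gaze_spread",
    "goal_gaze_stats",
    "project_gaze_on_trajectory",
    "detect_saccades",
    "detect_subgoals",
    "normalize_trial_time",
    "find_alternative_trajectories",
    "gaze_on_alternative_flags",
    "moving_average",
    "rolling_median",
]

BLINK_OPENNESS = 0.8
MOVE_THRESHOLD = 0.2  # m/s
MOVE_FILTER_FRAMES = 5
SACCADE_THRESHOLD = 50.0  # deg/s
TURN_THRESHOLD = 60.0  # deg/s
TURN_FILTER_FRAMES = 8
TRAJ_GAZE_RADIUS = 2.0  # m


@dataclass
class GazeAngles:
    azimuth: np.ndarray  # deg
    elevation: np.ndarray  # deg
    speed: np.ndarray  # deg/s
    valid: np.ndarray  # finite, non-zero-norm, blink-free frames


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-truncated windows."""
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with edge-truncated windows (NaNs ignored)."""
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# blink filtering and epoch segmentation

def filter_blinks(log: SessionLog) -> SessionLog:
    """Mask frames whose pupil openness dips below 0.8.

    Returns a copy with the ``gaze_valid`` column updated; position and
    joystick streams are untouched.
    """
    out = log.copy()
    valid = out.frames["pupil_open"].to_numpy() >= BLINK_OPENNESS
    out.frames["gaze_valid"] = valid
    if not valid.any():
        warnings.warn("all frames are blink-masked: no usable gaze", stacklevel=2)
    return out


def segment_epochs(log: SessionLog, trial: TrialRecord) -> TrialRecord:
    """Fill movement onset/offset from the smoothed joystick speed.

    Onset is the first up-crossing of 0.2 m/s after goal foveation; offset is
    the last frame at or above threshold before the button press.  If the
    speed never crosses threshold, the trial is flagged ``no_movement``.
    """
    frames = log.trial_frames(trial)
    t = frames["t"].to_numpy()
    speed = moving_average(np.abs(frames["joy_speed"].to_numpy()),
                           MOVE_FILTER_FRAMES)
    t_end = trial.t_press if np.isfinite(trial.t_press) else t[-1]
    win = (t >= trial.t_foveate) & (t <= t_end)
    above = win & (speed >= MOVE_THRESHOLD)
    if not above.any():
        trial.no_movement = True
        trial.t_onset = float("nan")
        trial.t_offset = float("nan")
        return trial
    idx = np.flatnonzero(above)
    trial.t_onset = float(t[idx[0]])
    trial.t_offset = float(t[idx[-1]])
    trial.no_movement = False
    return trial


# ---------------------------------------------------------------------------
# spatial statistics

def gaze_spread(log: SessionLog, trials: list[TrialRecord],
                epoch: str) -> dict:
    """Within-trial and across-trial gaze spread for one epoch, in meters.

    Within-trial spread is ``sqrt(E_n[Var_t[x] + Var_t[y]])``; across-trial
    spread is ``sqrt(Var_n[E_t[x]] + Var_n[E_t[y]])``.  Trials with fewer
    than two valid gaze frames in the epoch are dropped (count reported).
    """
    if len(trials) < 2:
        raise ValueError("gaze spread needs at least two trials")
    var_sums, means = [], []
    dropped = 0
    for tr in trials:
        fr = log.trial_frames(tr, epoch)
        fr = fr[fr["gaze_valid"]]
        if len(fr) < 2:
            dropped += 1
            continue
        gx = fr["gaze_x"].to_numpy()
        gy = fr["gaze_y"].to_numpy()
        var_sums.append(gx.var() + gy.var())
        means.append((gx.mean(), gy.mean()))
    if len(means) < 2:
        raise ValueError(f"too few usable trials in epoch {epoch!r} "
                         f"({dropped} dropped)")
    means = np.array(means)
    within_var = float(np.mean(var_sums))
    across_var = float(means[:, 0].var() + means[:, 1].var())
    return {
        "epoch": epoch,
        "within_m": float(np.sqrt(within_var)),
        "across_m": float(np.sqrt(across_var)),
        "within_var_m2": within_var,
        "across_var_m2": across_var,
        "n_trials": len(means),
        "n_dropped": dropped,
    }


def goal_gaze_stats(log: SessionLog, trial: TrialRecord, arena: Arena,
                    epoch: str, target_state: int | None = None,
                    radius_m: float = 2.0) -> dict:
    """Fraction of epoch time gazing within ``radius_m`` of the goal center,
    plus the mean gaze-goal distance.

    ``target_state`` overrides the trial goal (e.g. the stopping state).
    """
    g = trial.goal if target_state is None else target_state
    center = arena.centroids_m[g]
    fr = log.trial_frames(trial, epoch)
    fr = fr[fr["gaze_valid"]]
    if len(fr) == 0:
        return {"epoch": epoch, "fraction_near": float("nan"),
                "mean_distance_m": float("nan"), "n_frames": 0}
    d = np.linalg.norm(fr[["gaze_x", "gaze_y"]].to_numpy() - center, axis=1)
    return {
        "epoch": epoch,
        "fraction_near": float((d <= radius_m).mean()),
        "mean_distance_m": float(d.mean()),
        "n_frames": len(fr),
    }


# ---------------------------------------------------------------------------
# trajectory projection

def project_gaze_on_trajectory(gaze_xy: np.ndarray, trajectory: Trajectory,
                               radius_m: float = TRAJ_GAZE_RADIUS
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length fraction ``f in [0, 1]`` of each gaze point along a polyline.

    Each gaze point is perpendicularly projected onto the nearest point of
    the trajectory polyline; ``f`` is the arc length up to that point divided
    by the total length.  Frames whose gaze lies farther than ``radius_m``
    from the polyline are masked (``valid=False``, ``f=nan``).

    Returns ``(f, valid)``.
    """
    poly = np.asarray(trajectory.polyline, dtype=float)
    if len(poly) < 2 or trajectory.length_m <= 0:
        raise ValueError("degenerate (zero-length) trajectory")
    pts = np.atleast_2d(np.asarray(gaze_xy, dtype=float))
    a, b = poly[:-1], poly[1:]
    ab = b - a
    seglen = np.linalg.norm(ab, axis=1)
    keep = seglen > 0
    a, ab, seglen = a[keep], ab[keep], seglen[keep]
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    ap = pts[:, None, :] - a[None]
    t = np.clip((ap * ab[None]).sum(axis=2) / (seglen**2)[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - proj, axis=2)
    j = d.argmin(axis=1)
    rows = np.arange(len(pts))
    dist = d[rows, j]
    f = (cum[j] + t[rows, j] * seglen[j]) / total
    valid = dist <= radius_m
    f = np.where(valid, f, np.nan)
    return f, valid


# ---------------------------------------------------------------------------
# saccades

def detect_saccades(gdir: np.ndarray, frame_rate: float,
                    gaze_valid: np.ndarray | None = None
                    ) -> tuple[GazeAngles, np.ndarray]:
    """Azimuth/elevation angles, angular speed, and saccade onset frames.

    ``gdir`` is an (N, 3) array of gaze direction vectors (x right, y
    forward, z up).  Angular speed is the Euclidean norm of the consecutive-
    frame finite differences of azimuth and elevation, scaled by the frame
    rate; saccade onsets are up-crossings of 50 deg/s.
    """
    v = np.atleast_2d(np.asarray(gdir, dtype=float))
    norm = np.linalg.norm(v, axis=1)
    ok = np.isfinite(v).all(axis=1) & (norm > 0)
    if gaze_valid is not None:
        ok &= np.asarray(gaze_valid, dtype=bool)
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.degrees(np.arctan2(x, np.hypot(y, z)))
        el = np.degrees(np.arctan2(z, np.hypot(x, y)))
    az = np.where(ok, az, np.nan)
    el = np.where(ok, el, np.nan)
    speed = np.full(len(v), np.nan)
    if len(v) > 1:
        da = np.diff(az)
        de = np.diff(el)
        speed[1:] = np.hypot(da, de) * frame_rate
    below = speed < SACCADE_THRESHOLD
    above = speed >= SACCADE_THRESHOLD
    onsets = np.flatnonzero(above[1:] & below[:-1]) + 1
    return GazeAngles(az, el, speed, ok), onsets


# ---------------------------------------------------------------------------
# subgoals (turns) and common-timeline resampling

def detect_subgoals(heading_deg: np.ndarray, frame_rate: float,
                    positions: np.ndarray | None = None) -> list[dict]:
    """Turn intervals from thresholded, median-filtered heading velocity.

    A turn is a maximal interval where the smoothed absolute angular velocity
    exceeds 60 deg/s (median filter, 8-frame window).  Subgoals are numbered
    from the goal backwards: the stop is subgoal 0, the last turn subgoal 1,
    and so on.  Returns a list of dicts with ``start``, ``end`` (frame
    indices, inclusive), ``subgoal`` and optionally ``position``.
    """
    h = np.unwrap(np.asarray(heading_deg, dtype=float), period=360.0)
    if len(h) < 2:
        return []
    vel = np.gradient(h) * frame_rate
    smooth = rolling_median(np.abs(vel), TURN_FILTER_FRAMES)
    mask = smooth > TURN_THRESHOLD
    turns = _intervals(mask)
    n = len(turns)
    out = []
    for i, (a, b) in enumerate(turns):
        rec = {"start": int(a), "end": int(b), "subgoal": n - i}
        if positions is not None:
            mid = (a + b) // 2
            rec["position"] = tuple(np.asarray(positions)[mid])
        out.append(rec)
    return out


def _intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def normalize_trial_time(series: np.ndarray, turns: list[dict],
                         n_turn: int = 25, n_straight: int = 100
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Resample a per-frame series onto the common turn/straight timeline.

    Each turn maps to ``n_turn`` points and each straight segment to
    ``n_straight`` points.  Indices count back from the stop: the final
    straight segment occupies ``-n_straight .. -1``, the last turn the
    ``n_turn`` indices before it, and so on.  A trial with k turns always
    yields ``(k + 1) * n_straight + k * n_turn`` points.  Overlapping turn
    intervals are merged (with a warning) before resampling.

    Returns ``(indices, values)`` with indices ascending to -1.
    """
    x = np.asarray(series, dtype=float)
    N = len(x)
    ivs = sorted((t["start"], t["end"]) for t in turns)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if len(merged) < len(ivs):
        warnings.warn("overlapping turn intervals merged", stacklevel=2)
    pieces = []  # (start, end_inclusive, is_turn)
    cursor = 0
    for a, b in merged:
        pieces.append((cursor, a - 1, False))
        pieces.append((a, b, True))
        cursor = b + 1
    pieces.append((cursor, N - 1, False))
    vals = []
    for a, b, is_turn in pieces:
        m = n_turn if is_turn else n_straight
        if b < a:  # empty straight at a boundary turn
            anchor = x[min(max(a, 0), N - 1)]
            vals.append(np.full(m, anchor))
            continue
        seg = x[a:b + 1]
        src = np.linspace(0.0, 1.0, len(seg)) if len(seg) > 1 else np.array([0.0])
        dst = np.linspace(0.0, 1.0, m)
        vals.append(np.interp(dst, src, seg))
    values = np.concatenate(vals)
    indices = np.arange(-len(values), 0)
    return indices, values


# ---------------------------------------------------------------------------
# alternative trajectories

def find_alternative_trajectories(arena: Arena, s0: int, goal: int,
                                  length_factor: float = 1.25,
                                  max_overlap: float = 0.5,
                                  max_candidates: int = 200
                                  ) -> list[Trajectory]:
    """Near-optimal loopless paths, greedily deduplicated by state overlap.

    Enumerates loopless paths from ``s0`` to ``goal`` in increasing length
    (Yen's algorithm on the feasible-move graph) while their metric length is
    within ``length_factor`` of the optimal, capped at ``max_candidates``
    candidates (truncation warns).  A candidate is retained iff it shares at
    most ``max_overlap`` of its states with every previously retained path.
    The optimal path itself is the first retained trajectory.
    """
    import networkx as nx

    rows, cols, w = move_graph(arena)
    G = nx.Graph()
    G.add_nodes_from(range(arena.n_cells))
    for r, c, wt in zip(rows, cols, w):
        G.add_edge(int(r), int(c), weight=float(wt))
    vf = value_iteration(arena, goal)
    opt_len_units = -vf.values[s0]
    if not np.isfinite(opt_len_units) or (s0 != goal and opt_len_units <= 0):
        raise ValueError(f"goal {goal} unreachable from {s0}")
    limit = length_factor * opt_len_units
    retained: list[list[int]] = []
    count = 0
    for path in nx.shortest_simple_paths(G, s0, goal, weight="weight"):
        count += 1
        plen = sum(G[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))
        if plen > limit + 1e-9:
            break
        pset = set(path)
        ok = True
        for r in retained:
            shared = len(pset & set(r)) / min(len(pset), len(r))
            if shared > max_overlap:
                ok = False
                break
        if ok:
            retained.append(path)
        if count >= max_candidates:
            warnings.warn(
                f"alternative-path enumeration truncated at {max_candidates} "
                f"candidates", stacklevel=2)
            break
    out = []
    for states in retained:
        poly = arena.centroids_m[states]
        length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
        out.append(Trajectory(list(states), poly, length))
    return out


def gaze_on_alternative_flags(gaze_xy: np.ndarray, executed: Trajectory,
                              alternatives: list[Trajectory], arena: Arena,
                              radius_m: float = TRAJ_GAZE_RADIUS) -> np.ndarray:
    """Per-frame flag: gaze explores an alternative trajectory.

    A frame counts iff the gaze is within ``radius_m`` of a centroid of an
    alternative's states that are *not* on the executed trajectory, and
    farther than ``radius_m`` from the executed trajectory polyline.
    """
    pts = np.atleast_2d(np.asarray(gaze_xy, dtype=float))
    _, near_exec = project_gaze_on_trajectory(pts, executed, radius_m)
    exec_states = set(executed.states)
    alt_states = sorted(
        {s for alt in alternatives for s in alt.states} - exec_states
    )
    if not alt_states:
        return np.zeros(len(pts), dtype=bool)
    cents = arena.centroids_m[alt_states]
    d = np.linalg.norm(pts[:, None, :] - cents[None], axis=2).min(axis=1)
    return (~near_exec) & (d <= radius_m)
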