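"""Ground-truth-annotated synthetic sessions: trajectories, gaze, blinks.

The generator emulates the statistical structure the analyses assume: 90 Hz
frame logs, joystick speeds capped at 4.75 m/s, gaze measured as the
intersection of a noisy gaze ray (1.15 deg angular noise per axis, cast from
a 1.72 m vantage above the participant) with the ground plane, goal and
relevant-transition fixations, alternative-path glances, injected forward and
backward sweeps at 20-26 m/s along the trajectory, saccadic gaze shifts
between fixation targets, and blinks.

The gaze model is a seeded semi-Markov mixture over fixation targets with
geometric dwell times; movement follows the optimal trajectory with
acceleration-limited speed profiles and turn-in-place rotations at 120 deg/s.
The generator is a test harness with every frame annotated in
:class:`GroundTruth`, not a scientific claim about how people move their eyes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import Arena, OUTSIDE, build_arena, random_arena, centrality, \
    arena_complexity, states_of_points
from .planning import Trajectory, value_iteration, optimal_path, score_stop
from .relevance import RelevanceCalculator
from .session import SessionLog, TrialRecord, write_session, read_session

__all__ = [
    "SynthConfig",
    "TrialTruth",
    "GroundTruth",
    "generate_session",
    "generate_arena_suite",
    "write_session",
    "read_session",
]

DEFAULT_MIXTURE = {
    "goal": 0.45,
    "relevant": 0.20,
    "alternative": 0.10,
    "random": 0.20,
    "sweep": 0.05,
}


@dataclass
class SynthConfig:
    """Generator parameters; defaults mirror the study conditions."""

    arena: Arena
    n_trials: int = 50
    frame_rate: float = 90.0
    speed_cap: float = 4.75  # m/s
    move_speed: float = 2.0  # cruise speed, m/s
    accel: float = 4.0  # m/s^2
    turn_rate_dps: float = 120.0
    gaze_noise_deg: float = 1.15  # per-axis angular SD (slowly varying error)
    gaze_noise_tau_s: float = 30.0  # correlation time of the tracker bias
    gaze_jitter_deg: float = 0.1  # white frame-to-frame jitter
    vantage_m: float = 1.72
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    dwell_mean_s: float = 0.4
    sweep_speed_range: tuple = (20.0, 26.0)  # m/s along the trajectory
    sweep_coverage: tuple = (0.5, 0.9)
    n_backward_sweeps: int = 1  # scheduled per trial, pre-movement
    n_forward_sweeps: int = 1  # scheduled per trial, movement
    blink_rate_hz: float = 0.1
    blink_duration_s: float = 0.2
    search_duration_s: tuple = (1.0, 2.0)
    premove_duration_s: tuple = (1.5, 3.0)
    use_relevance_targets: bool = True
    seed: int = 0

    def __post_init__(self):
        w = np.array([self.mixture.get(k, 0.0) for k in DEFAULT_MIXTURE])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("mixture weights must be >= 0 with positive sum")
        total = w.sum()
        self.mixture = {k: float(v / total)
                        for k, v in zip(DEFAULT_MIXTURE, w)}


@dataclass
class TrialTruth:
    """Frame-exact annotations for one generated trial."""

    trial_id: int
    frame0: int  # index of the trial's first frame in the session table
    n_frames: int
    fixation: np.ndarray  # per-frame target label
    sweeps: list  # dicts: direction, start, end (trial-local), f0, f1, speed
    blink_frames: np.ndarray  # trial-local indices
    t_onset: float  # true movement onset (first frame speed > 0.2 m/s)
    t_offset: float  # true movement offset (last frame speed > 0.2 m/s)
    trajectory: Trajectory


@dataclass
class GroundTruth:
    trials: list


def generate_session(config: SynthConfig
                     ) -> tuple[SessionLog, list[TrialRecord], GroundTruth]:
    """Generate a full annotated session; deterministic under ``config.seed``."""
    arena = config.arena
    if not arena.is_connected():
        raise ValueError("synthetic sessions require a connected arena")
    rng = np.random.default_rng(config.seed)
    calc = RelevanceCalculator(arena) if config.use_relevance_targets else None
    fps = config.frame_rate
    dt = 1.0 / fps

    all_frames = []
    trials: list[TrialRecord] = []
    truths: list[TrialTruth] = []
    t_clock = 0.0
    frame0 = 0
    for trial_id in range(config.n_trials):
        start, goal = rng.choice(arena.n_cells, size=2, replace=False)
        start, goal = int(start), int(goal)
        vf = value_iteration(arena, goal)
        traj = optimal_path(arena, vf, start)
        tt = _generate_trial(config, rng, calc, trial_id, start, goal, traj,
                             t_clock, frame0)
        frames, record, truth = tt
        all_frames.append(frames)
        trials.append(record)
        truths.append(truth)
        t_clock = frames["t"].iloc[-1] + dt
        frame0 += len(frames)

    table = pd.concat(all_frames, ignore_index=True)
    log = SessionLog(table, fps, arena, trials)
    return log, trials, GroundTruth(truths)


# ---------------------------------------------------------------------------
# movement kinematics

def _movement_profile(config: SynthConfig, traj: Trajectory, rng):
    """Per-frame position, heading, and speed along the optimal polyline.

    Straight segments use acceleration-limited trapezoidal speed profiles
    (stopping at corners); corners are turn-in-place rotations at the
    configured angular rate, which keeps them above the 60 deg/s turn
    detection threshold.
    """
    dt = 1.0 / config.frame_rate
    poly = traj.polyline
    pos, heading, speed, arc = [], [], [], []
    segs = np.diff(poly, axis=0)
    seglen = np.linalg.norm(segs, axis=1)
    keep = seglen > 1e-12
    segs, seglen = segs[keep], seglen[keep]
    total = float(seglen.sum())
    dirs = np.degrees(np.arctan2(segs[:, 1], segs[:, 0]))
    anchors = np.concatenate([poly[:1], poly[:1] + np.cumsum(segs, axis=0)])
    cur_heading = dirs[0] if len(dirs) else 0.0
    done = 0.0  # arc length completed before the current segment
    for i in range(len(segs)):
        # rotate in place toward the segment direction
        delta = ((dirs[i] - cur_heading + 180.0) % 360.0) - 180.0
        n_rot = int(math.ceil(abs(delta) / (config.turn_rate_dps * dt)))
        for j in range(n_rot):
            cur_heading += delta / n_rot
            pos.append(anchors[i])
            heading.append(cur_heading)
            speed.append(0.0)
            arc.append(done / total)
        cur_heading = dirs[i]
        # accelerate / cruise / decelerate along the segment
        s, v = 0.0, 0.0
        vmax = min(config.move_speed, config.speed_cap)
        while s < seglen[i]:
            brake = math.sqrt(max(0.0, 2.0 * config.accel
                                  * (seglen[i] - s)))
            v = min(v + config.accel * dt, vmax, brake)
            v = max(v, 0.05)  # creep out of the corner
            s = min(s + v * dt, seglen[i])
            u = segs[i] / seglen[i]
            pos.append(anchors[i] + u * s)
            heading.append(cur_heading)
            speed.append(v)
            arc.append((done + s) / total)
        done += seglen[i]
    if not pos:  # start == goal
        pos = [poly[0]]
        heading = [0.0]
        speed = [0.0]
        arc = [0.0]
    return (np.asarray(pos), np.asarray(heading), np.asarray(speed),
            np.asarray(arc))


# ---------------------------------------------------------------------------
# gaze synthesis

def _random_point_in_hexagon(arena: Arena, rng, size: int = 1) -> np.ndarray:
    R = arena.n * arena.side_length
    out = np.empty((size, 2))
    got = 0
    while got < size:
        cand = rng.uniform(-R, R, size=(4 * (size - got), 2))
        ok = states_of_points(arena, cand) != OUTSIDE
        take = cand[ok][: size - got]
        out[got:got + len(take)] = take
        got += len(take)
    return out


def _arc_point(traj: Trajectory, f: np.ndarray) -> np.ndarray:
    """Point on the trajectory polyline at arc-length fraction ``f``."""
    poly = traj.polyline
    seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.clip(np.asarray(f, dtype=float), 0.0, 1.0) * cum[-1]
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.column_stack([x, y])


class _GazePlanner:
    """Fills per-frame gaze targets for one trial from the fixation mixture."""

    def __init__(self, config, rng, arena, calc, traj, goal, alternatives):
        self.cfg = config
        self.rng = rng
        self.arena = arena
        self.calc = calc
        self.traj = traj
        self.goal = goal
        self.alternatives = alternatives
        self.cats = list(DEFAULT_MIXTURE)
        self.weights = np.array([config.mixture[c] for c in self.cats])

    def fixation_point(self, cat: str, state: int) -> np.ndarray:
        arena, rng = self.arena, self.rng
        if cat == "goal":
            return arena.centroids_m[self.goal]
        if cat == "relevant":
            if self.calc is not None:
                om = self.calc.omega_matrix(self.goal)[:, state]
                if om.max() > 0:
                    return arena.edge_midpoints_m[int(np.argmax(om))]
            k = int(rng.integers(arena.n_interior_edges))
            return arena.edge_midpoints_m[k]
        if cat == "alternative":
            pool = [s for alt in self.alternatives for s in alt.states
                    if s not in set(self.traj.states)]
            if pool:
                return arena.centroids_m[pool[int(self.rng.integers(len(pool)))]]
            cat = "random"
        return _random_point_in_hexagon(arena, rng, 1)[0]

    def fill(self, targets, labels, lo, hi, states, epoch):
        """Fill frames [lo, hi) with mixture fixations; may inject sweeps."""
        cfg, rng = self.cfg, self.rng
        i = lo
        while i < hi:
            cat = self.cats[int(rng.choice(len(self.cats), p=self.weights))]
            dwell = max(3, int(rng.geometric(
                1.0 / max(1.0, cfg.dwell_mean_s * cfg.frame_rate))))
            j = min(i + dwell, hi)
            if cat == "sweep":
                direction = "backward" if epoch == "pre-movement" else "forward"
                f_start = (self.arc_of_frame(i)
                           if direction == "forward" else None)
                sw = _inject_sweep(cfg, rng, self.traj, targets, labels,
                                   i, hi, direction, f_start)
                if sw is not None:
                    i = sw["claim_end"] + 1
                    self.extra_sweeps.append(sw)
                    continue
                cat = "random"
            pt = self.fixation_point(cat, int(states[i]))
            targets[i:j] = pt
            labels[i:j] = cat
            i = j


def _inject_sweep(cfg, rng, traj, targets, labels, lo, hi, direction,
                  f_start=None):
    """Write one sweep into [lo, hi) if it fits; returns its record or None.

    Backward sweeps run from the goal (f = 1) toward the start; forward
    sweeps run from ``f_start`` (the participant's current trajectory
    fraction, when given) toward the goal.
    """
    speed = rng.uniform(*cfg.sweep_speed_range)
    coverage = rng.uniform(*cfg.sweep_coverage)
    if direction == "backward":
        f0, f1 = 1.0, 1.0 - coverage
    else:
        if f_start is None:
            f0 = rng.uniform(0.0, 1.0 - coverage)
        else:
            f0 = min(float(f_start), 0.99)
        f1 = min(1.0, f0 + coverage)
        coverage = f1 - f0
    n = int(round(coverage * traj.length_m / speed * cfg.frame_rate))
    # anchor fixations at the sweep endpoints (the subgoal/goal the sweep
    # departs from and arrives at), as sweeps are in the data
    n_anchor = int(round(0.2 * cfg.frame_rate))
    if n < 5 or lo + n_anchor + n + n_anchor > hi:
        return None
    a0 = lo
    s0_ = lo + n_anchor
    s1_ = s0_ + n - 1
    fr = np.linspace(f0, f1, n)
    targets[a0:s0_] = _arc_point(traj, np.array([f0]))[0]
    labels[a0:s0_] = "path"
    targets[s0_:s1_ + 1] = _arc_point(traj, fr)
    labels[s0_:s1_ + 1] = f"sweep_{direction}"
    targets[s1_ + 1:s1_ + 1 + n_anchor] = _arc_point(traj, np.array([f1]))[0]
    labels[s1_ + 1:s1_ + 1 + n_anchor] = "path"
    return {"direction": direction, "start": s0_, "end": s1_,
            "claim_start": a0, "claim_end": s1_ + n_anchor,
            "f0": f0, "f1": f1, "speed": speed, "coverage": coverage}


def _gaps(sweeps, lo, hi, epoch):
    """Sub-intervals of [lo, hi) not claimed by scheduled sweeps."""
    out = []
    cursor = lo
    for sw in sorted(sweeps, key=lambda s: s["start"]):
        a = sw.get("claim_start", sw["start"])
        b = sw.get("claim_end", sw["end"])
        if a >= hi or b < lo:
            continue
        if a > cursor:
            out.append((cursor, a, epoch))
        cursor = max(cursor, b + 1)
    if cursor < hi:
        out.append((cursor, hi, epoch))
    return out


def _generate_trial(config, rng, calc, trial_id, start, goal, traj,
                    t0, frame0):
    arena = config.arena
    fps = config.frame_rate
    dt = 1.0 / fps

    mv_pos, mv_head, mv_speed, mv_arc = _movement_profile(config, traj, rng)
    n_search = int(round(rng.uniform(*config.search_duration_s) * fps))
    n_pre = int(round(rng.uniform(*config.premove_duration_s) * fps))
    n_move = len(mv_pos)
    n_post = int(round(0.3 * fps))
    n = n_search + n_pre + n_move + n_post

    start_xy = arena.centroids_m[start]
    pos = np.empty((n, 2))
    pos[: n_search + n_pre] = start_xy
    pos[n_search + n_pre: n_search + n_pre + n_move] = mv_pos
    pos[n_search + n_pre + n_move:] = mv_pos[-1]
    heading = np.empty(n)
    heading[: n_search + n_pre] = mv_head[0]
    heading[n_search + n_pre: n_search + n_pre + n_move] = mv_head
    heading[n_search + n_pre + n_move:] = mv_head[-1]
    joy = np.zeros(n)
    joy[n_search + n_pre: n_search + n_pre + n_move] = mv_speed

    states = states_of_points(arena, pos)
    states = np.where(states == OUTSIDE, start, states)

    targets = np.empty((n, 2))
    labels = np.full(n, "random", dtype=object)

    alternatives = []  # alternative-path pool filled lazily (can be slow)
    if config.mixture["alternative"] > 0:
        from .gaze import find_alternative_trajectories
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                alternatives = find_alternative_trajectories(
                    arena, start, goal, max_candidates=50)
            except Exception:
                alternatives = []

    planner = _GazePlanner(config, rng, arena, calc, traj, goal, alternatives)
    planner.extra_sweeps = []

    def arc_of_frame(i):
        """Participant's trajectory fraction at trial frame ``i`` (movement)."""
        j = i - (n_search + n_pre)
        if 0 <= j < len(mv_arc):
            return float(mv_arc[j])
        return None

    planner.arc_of_frame = arc_of_frame

    # search: wide scatter, then foveate the goal for the final 0.25 s
    i = 0
    n_fove = min(n_search, int(0.25 * fps))
    while i < n_search - n_fove:
        dwell = max(3, int(rng.geometric(1.0 / (0.25 * fps))))
        j = min(i + dwell, n_search - n_fove)
        targets[i:j] = _random_point_in_hexagon(arena, rng, 1)[0]
        labels[i:j] = "search"
        i = j
    targets[n_search - n_fove: n_search] = arena.centroids_m[goal]
    labels[n_search - n_fove: n_search] = "goal"

    # scheduled sweeps claim their windows first; mixture fills the gaps
    sweeps = []
    cursor = n_search
    for _ in range(config.n_backward_sweeps):
        lo = cursor + int(rng.integers(0, max(1, n_pre // 4)))
        sw = _inject_sweep(config, rng, traj, targets, labels, lo,
                           n_search + n_pre, "backward")
        if sw is not None:
            sweeps.append(sw)
            cursor = sw["claim_end"] + 1
    m0, m1 = n_search + n_pre, n_search + n_pre + n_move
    cursor = m0
    for _ in range(config.n_forward_sweeps):
        lo = cursor + int(rng.integers(0, max(1, n_move // 2)))
        sw = _inject_sweep(config, rng, traj, targets, labels, lo, m1,
                           "forward", f_start=arc_of_frame(lo))
        if sw is not None:
            sweeps.append(sw)
            cursor = sw["claim_end"] + 1
    # mixture fixations in the gaps between scheduled sweeps
    for lo, hi, epoch in _gaps(sweeps, n_search, n_search + n_pre,
                               "pre-movement") + _gaps(sweeps, m0, m1,
                                                       "movement"):
        planner.fill(targets, labels, lo, hi, states, epoch)
    sweeps.extend(planner.extra_sweeps)
    sweeps.sort(key=lambda s: s["start"])

    # post-movement: stare near the stop
    targets[m1:] = pos[-1]
    labels[m1:] = "goal"

    # --- gaze ray with angular noise -> ground intersection + head frame
    eye = np.column_stack([pos, np.full(n, config.vantage_m)])
    gvec = np.column_stack([targets - pos, -np.full(n, config.vantage_m)])
    gvec /= np.linalg.norm(gvec, axis=1, keepdims=True)
    sigma = math.radians(config.gaze_noise_deg)
    jit = math.radians(config.gaze_jitter_deg)
    if sigma > 0 or jit > 0:
        # tracker error: slowly varying (OU) calibration drift with the
        # documented marginal spread, plus white frame-to-frame jitter
        xi = np.zeros((n, 2))
        if sigma > 0:
            a = math.exp(-dt / config.gaze_noise_tau_s)
            innov = rng.normal(0.0, sigma * math.sqrt(1.0 - a * a),
                               size=(n, 2))
            xi[0] = rng.normal(0.0, sigma, size=2)
            for i in range(1, n):
                xi[i] = a * xi[i - 1] + innov[i]
        if jit > 0:
            xi = xi + rng.normal(0.0, jit, size=(n, 2))
        # perturb within the plane orthogonal to the ray
        ref = np.zeros_like(gvec)
        ref[:, 2] = 1.0
        e1 = np.cross(gvec, ref)
        e1 /= np.maximum(np.linalg.norm(e1, axis=1, keepdims=True), 1e-12)
        e2 = np.cross(gvec, e1)
        gvec = gvec + xi[:, :1] * e1 + xi[:, 1:] * e2
        gvec /= np.linalg.norm(gvec, axis=1, keepdims=True)
    dz = np.minimum(gvec[:, 2], -1e-3)  # rays never point above horizon
    scale = config.vantage_m / -dz
    gaze_xy = eye[:, :2] + gvec[:, :2] * scale[:, None]

    # head frame: x right, y forward, z up
    phi = np.radians(heading)
    fwd_u = np.column_stack([np.cos(phi), np.sin(phi)])
    right_u = np.column_stack([np.sin(phi), -np.cos(phi)])
    gdir = np.column_stack([
        (gvec[:, :2] * right_u).sum(axis=1),
        (gvec[:, :2] * fwd_u).sum(axis=1),
        gvec[:, 2],
    ])

    # --- blinks
    pupil = rng.uniform(0.9, 1.0, size=n)
    blink_frames = []
    n_blinks = rng.poisson(config.blink_rate_hz * n * dt)
    bdur = max(1, int(round(config.blink_duration_s * fps)))
    for _ in range(n_blinks):
        b0 = int(rng.integers(0, max(1, n - bdur)))
        pupil[b0:b0 + bdur] = 0.2
        blink_frames.extend(range(b0, b0 + bdur))
    blink_frames = np.unique(np.asarray(blink_frames, dtype=int))

    t = t0 + np.arange(n) * dt
    frames = pd.DataFrame({
        "t": t,
        "pos_x": pos[:, 0], "pos_y": pos[:, 1],
        "heading_deg": heading % 360.0,
        "joy_speed": joy,
        "gaze_x": gaze_xy[:, 0], "gaze_y": gaze_xy[:, 1],
        "gdir_x": gdir[:, 0], "gdir_y": gdir[:, 1], "gdir_z": gdir[:, 2],
        "pupil_open": pupil,
    })

    moving = joy > 0.2
    if moving.any():
        on_idx = int(np.flatnonzero(moving)[0])
        off_idx = int(np.flatnonzero(moving)[-1])
        t_onset_true, t_offset_true = float(t[on_idx]), float(t[off_idx])
    else:
        t_onset_true = t_offset_true = float("nan")

    stop_state = int(states[-1])
    points, _ = score_stop(arena, stop_state, goal)
    record = TrialRecord(
        trial_id=trial_id, start=start, goal=goal,
        t_appear=float(t[0]), t_foveate=float(t[n_search]),
        t_onset=t_onset_true, t_offset=t_offset_true,
        t_press=float(t[-1]), points=points,
        first_of_run=(trial_id == 0),
    )
    truth = TrialTruth(
        trial_id=trial_id, frame0=frame0, n_frames=n,
        fixation=labels, sweeps=sweeps, blink_frames=blink_frames,
        t_onset=t_onset_true, t_offset=t_offset_true, trajectory=traj,
    )
    return frames, record, truth


# ---------------------------------------------------------------------------
# arena suite

def generate_arena_suite(seed, n: int = 5, side_length: float = 2.0,
                         obstacle_counts=(4, 16, 30, 44, 58),
                         max_retries: int = 50):
    """Five connected arenas spanning a strictly decreasing closeness gradient.

    Returns ``(arenas, complexities)`` ordered from most open (complexity 0)
    to most maze-like.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        arenas, cbars = [], []
        for count in obstacle_counts:
            sub = int(rng.integers(2**31))
            try:
                a = random_arena(n, count, sub, side_length)
            except RuntimeError:
                break
            arenas.append(a)
            cbars.append(centrality(a).mean_closeness)
        if len(arenas) == len(obstacle_counts) and all(
            cbars[i] > cbars[i + 1] for i in range(len(cbars) - 1)
        ):
            return arenas, arena_complexity(cbars)
    raise RuntimeError(
        "could not realize a strictly decreasing closeness gradient "
        f"within {max_retries} attempts"
    )
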