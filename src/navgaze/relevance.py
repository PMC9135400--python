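"""Transition relevance, per-frame gaze relevance, shuffled nulls, and ROC.

The relevance of transition ``k`` for navigating from state ``s0`` to goal
``sG`` is the squared change in the optimal value of ``s0`` induced by
toggling the passability of that transition::

    Omega_k(s0, sG) = [V(s0 | T_k = 1) - V(s0 | T_k = 0)] ** 2

Both values are computed by full value iteration on otherwise-identical
arenas.  Transitions with the highest relevance are typically bottlenecks
(graph bridges), obstacles precluding a straight path, and transitions on the
optimal trajectory.  A path-dependent variant sums squared value differences
over all states on the optimal path.

Per-frame gaze relevance pairs the transition nearest the point of gaze with
the participant's current state; a shuffled null re-scores the same frames
against the goal of a different, randomly drawn trial.  ROC curves compare the
cumulative distributions of true vs shuffled relevance; the area under the
curve equals the Mann-Whitney statistic ``U / (n1 * n2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import Arena, OUTSIDE, states_of_points
from .planning import value_iteration, optimal_path

__all__ = [
    "RelevanceMap",
    "RocResult",
    "RelevanceCalculator",
    "transition_relevance",
    "path_relevance",
    "relevance_map",
    "gaze_relevance_series",
    "shuffled_series",
    "roc_auc",
    "bottleneck_correlation",
    "nearest_interior_edge",
]


@dataclass
class RelevanceMap:
    s0: int
    goal: int
    omega: np.ndarray  # per-interior-edge Omega_k(s0, goal) >= 0
    omega_norm: np.ndarray  # omega / max(omega), in [0, 1]


@dataclass
class RocResult:
    auc: float
    n_true: int
    n_shuffled: int
    epoch: str = ""
    ci_low: float = float("nan")
    ci_high: float = float("nan")


class RelevanceCalculator:
    """Caches toggled-edge value functions per goal for one arena.

    For a fixed goal, toggling edge ``k`` changes the value of *every* state,
    so one pair of value functions per edge yields ``Omega_k(s0, goal)`` for
    all start states at once.  ``omega_matrix(goal)`` returns the
    ``(n_edges, n_states)`` table; per-frame relevance lookups then cost one
    indexing operation.
    """

    def __init__(self, arena: Arena, iterations: int = 100,
                 vertex_rule: str = "detour"):
        self.arena = arena
        self.iterations = iterations
        self.vertex_rule = vertex_rule
        self._cache: dict[int, np.ndarray] = {}

    def omega_matrix(self, goal: int) -> np.ndarray:
        if goal in self._cache:
            return self._cache[goal]
        arena = self.arena
        E = arena.n_interior_edges
        v_actual = value_iteration(
            arena, goal, self.iterations, vertex_rule=self.vertex_rule
        ).values
        omega = np.empty((E, arena.n_cells))
        for k in range(E):
            v_tog = value_iteration(
                arena.toggled(k), goal, self.iterations,
                vertex_rule=self.vertex_rule,
            ).values
            omega[k] = (v_actual - v_tog) ** 2
        self._cache[goal] = omega
        return omega


def transition_relevance(arena: Arena, k: int, s0: int, goal: int,
                         iterations: int = 100) -> float:
    """``Omega_k(s0, goal)``: squared value change at ``s0`` from toggling edge ``k``."""
    _check_edge(arena, k)
    v_open, v_closed = _toggle_values(arena, k, goal, iterations)
    return float((v_open[s0] - v_closed[s0]) ** 2)


def path_relevance(arena: Arena, k: int, s0: int, goal: int,
                   iterations: int = 100) -> float:
    """Path-dependent relevance: squared value changes summed along the optimal path.

    The optimal path is computed with edge ``k`` at its actual status.
    """
    _check_edge(arena, k)
    vf = value_iteration(arena, goal, iterations)
    path = optimal_path(arena, vf, s0).states
    v_open, v_closed = _toggle_values(arena, k, goal, iterations)
    diffs = v_open[path] - v_closed[path]
    return float((diffs**2).sum())


def _check_edge(arena: Arena, k: int) -> None:
    if not (0 <= k < arena.n_interior_edges):
        raise ValueError(
            f"edge {k} is not interior (0..{arena.n_interior_edges - 1})"
        )


def _toggle_values(arena, k, goal, iterations):
    open_arena = arena if arena.passable[k] else arena.toggled(k)
    closed_arena = arena.toggled(k) if arena.passable[k] else arena
    v_open = value_iteration(open_arena, goal, iterations).values
    v_closed = value_iteration(closed_arena, goal, iterations).values
    return v_open, v_closed


def relevance_map(arena: Arena, s0: int, goal: int,
                  calc: RelevanceCalculator | None = None,
                  exclude_radius_m: float | None = None) -> RelevanceMap:
    """All interior edges scored for (s0, goal), normalized by the arena max.

    ``exclude_radius_m`` zeroes edges whose midpoint lies within that distance
    of the goal centroid before normalization (used by the bottleneck
    analysis; off by default).
    """
    calc = calc or RelevanceCalculator(arena)
    omega = calc.omega_matrix(goal)[:, s0].copy()
    if exclude_radius_m is not None:
        d = np.linalg.norm(
            arena.edge_midpoints_m - arena.centroids_m[goal], axis=1
        )
        omega[d < exclude_radius_m] = 0.0
    top = omega.max()
    if top == 0.0:
        warnings.warn(
            f"all-zero relevance map for s0={s0}, goal={goal}", stacklevel=2
        )
        return RelevanceMap(s0, goal, omega, omega)
    return RelevanceMap(s0, goal, omega, omega / top)


# ---------------------------------------------------------------------------
# per-frame gaze relevance

def nearest_interior_edge(arena: Arena, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest interior edge (by point-to-segment distance) for each point.

    Returns ``(edge_ids, distances_m)`` for an ``(N, 2)`` array in meters.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    seg = arena.edge_endpoints_m  # (E, 2, 2)
    a, b = seg[:, 0], seg[:, 1]
    ab = b - a  # (E, 2)
    denom = (ab**2).sum(axis=1)  # (E,)
    ap = pts[:, None, :] - a[None, :, :]  # (N, E, 2)
    t = np.clip((ap * ab[None]).sum(axis=2) / denom[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - proj, axis=2)  # (N, E)
    ids = d.argmin(axis=1)
    return ids, d[np.arange(len(pts)), ids]


def gaze_relevance_series(session, trial, calc: RelevanceCalculator,
                          goal: int | None = None,
                          use_current_state: bool = True,
                          exclude_reward_zone: bool = False) -> pd.DataFrame:
    """Per-frame normalized gaze relevance for one trial.

    For every blink-valid frame between goal appearance and movement offset,
    finds the interior edge nearest the gaze ground point and returns
    ``omega = Omega_k(s(t), goal) / max_k Omega_k(s(t), goal)`` along with the
    edge id, participant state, and epoch label.  Frames whose gaze falls
    outside the arena are dropped.  ``goal`` defaults to the trial's goal;
    passing a different state yields a shuffled-goal series.
    ``use_current_state=False`` scores all frames against the trial start
    state instead of the participant's current state.
    """
    arena = calc.arena
    g = trial.goal if goal is None else goal
    frames = session.trial_frames(trial)
    frames = frames[frames["gaze_valid"]]
    if len(frames) == 0:
        warnings.warn(f"trial {trial.trial_id}: no valid gaze frames", stacklevel=2)
        return _empty_series()
    gaze = frames[["gaze_x", "gaze_y"]].to_numpy()
    pos = frames[["pos_x", "pos_y"]].to_numpy()
    gaze_state = states_of_points(arena, gaze)
    ok = gaze_state != OUTSIDE
    if exclude_reward_zone:
        from .planning import score_stop
        zone = {g} | {
            s for s in range(arena.n_cells) if score_stop(arena, s, g)[1]
        }
        ok &= ~np.isin(gaze_state, list(zone))
    frames, gaze, pos = frames[ok], gaze[ok], pos[ok]
    if len(frames) == 0:
        warnings.warn(f"trial {trial.trial_id}: no in-arena gaze frames",
                      stacklevel=2)
        return _empty_series()
    state = states_of_points(arena, pos)
    # participants can momentarily register outside near walls; snap to start
    state = np.where(state == OUTSIDE, trial.start, state)
    if not use_current_state:
        state = np.full(len(frames), trial.start)
    edge_ids, _ = nearest_interior_edge(arena, gaze)
    omega_all = calc.omega_matrix(g)  # (E, S)
    om = omega_all[edge_ids, state]
    top = omega_all[:, state].max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        om_norm = np.where(top > 0, om / top, 0.0)
    out = pd.DataFrame(
        {
            "t": frames["t"].to_numpy(),
            "edge": edge_ids,
            "state": state,
            "omega": om,
            "omega_norm": om_norm,
            "epoch": session.epoch_labels(trial, frames),
            "trial_id": trial.trial_id,
        }
    )
    return out


def _empty_series() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["t", "edge", "state", "omega", "omega_norm", "epoch", "trial_id"]
    )


def shuffled_series(session, trial, calc: RelevanceCalculator, seed,
                    trials=None, **kwargs) -> pd.DataFrame:
    """Relevance of this trial's gaze scored against another trial's goal.

    The surrogate goal is drawn uniformly from the other trials of the
    session (seeded); a single-trial session falls back to a uniform random
    goal state with a warning.
    """
    rng = np.random.default_rng(seed)
    trials = list(trials if trials is not None else session.trials)
    others = [t for t in trials if t.trial_id != trial.trial_id]
    if others:
        goal = others[int(rng.integers(len(others)))].goal
    else:
        warnings.warn("single-trial session: shuffling with a uniform random goal",
                      stacklevel=2)
        goal = int(rng.integers(calc.arena.n_cells))
    return gaze_relevance_series(session, trial, calc, goal=goal, **kwargs)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(true_samples, shuffled_samples, epoch: str = "",
            n_boot: int = 0, seed=0, ci: float = 0.95) -> RocResult:
    """AUC of the true-vs-shuffled ROC curve.

    The curve plots the cumulative probability of shuffled values against the
    cumulative probability of true values over the pooled thresholds; the
    trapezoidal area equals ``P(true > shuffled) + P(true == shuffled) / 2``,
    i.e. the Mann-Whitney ``U / (n1 n2)``.  AUC > 0.5 means the true samples
    are stochastically larger than the shuffled ones.  Optional bootstrap CI
    resamples both groups (seeded).
    """
    x = np.sort(np.asarray(true_samples, dtype=float))
    y = np.sort(np.asarray(shuffled_samples, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    auc = _auc_trapezoid(x, y)
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(len(x), size=len(x))]
            yb = y[rng.integers(len(y), size=len(y))]
            stats[b] = _auc_rank(xb, yb)
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return RocResult(auc, len(x), len(y), epoch, float(lo), float(hi))


def _auc_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    thr = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(x, thr, side="right") / len(x)  # CDF of true
    fy = np.searchsorted(y, thr, side="right") / len(y)  # CDF of shuffled
    fx = np.concatenate([[0.0], fx])
    fy = np.concatenate([[0.0], fy])
    return float(np.trapezoid(fy, fx))


def _auc_rank(x: np.ndarray, y: np.ndarray) -> float:
    # Mann-Whitney U via midranks; ties counted half
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    ranks[order] = np.arange(1, len(pooled) + 1)
    # midranks for ties
    i = 0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r1 = ranks[: len(x)].sum()
    u = r1 - len(x) * (len(x) + 1) / 2.0
    return float(u / (len(x) * len(y)))


# ---------------------------------------------------------------------------
# bottlenecks

def bottleneck_correlation(arena: Arena, calc: RelevanceCalculator | None = None,
                           goal_exclusion_m: float = 1.0) -> tuple[float, int]:
    """Pearson correlation of mean normalized relevance vs incident betweenness.

    For each goal, per-edge relevance is averaged over all start states and
    normalized by the arena-wide maximum for that goal; edges whose midpoint
    lies within ``goal_exclusion_m`` of the goal centroid are excluded for
    that goal.  The per-edge predictor is the mean betweenness centrality of
    the two incident states.  Returns ``(r, n_edges)``.
    """
    from scipy.stats import pearsonr
    from .arena import centrality

    calc = calc or RelevanceCalculator(arena)
    E = arena.n_interior_edges
    mids = arena.edge_midpoints_m
    cents = arena.centroids_m
    rel_sum = np.zeros(E)
    rel_cnt = np.zeros(E)
    for g in range(arena.n_cells):
        omega = calc.omega_matrix(g).mean(axis=1)  # mean over start states
        top = omega.max()
        if top == 0:
            continue
        keep = np.linalg.norm(mids - cents[g], axis=1) >= goal_exclusion_m
        rel_sum[keep] += omega[keep] / top
        rel_cnt[keep] += 1
    used = rel_cnt > 0
    mean_rel = rel_sum[used] / rel_cnt[used]
    bt = centrality(arena).betweenness
    ec = arena._geom.edge_cells_arr[:E][used]
    predictor = bt[ec].mean(axis=1)
    if np.ptp(mean_rel) == 0 or np.ptp(predictor) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    r, _ = pearsonr(mean_rel, predictor)
    return float(r), int(used.sum())


def relevance_map_to_frame(arena: Arena, rmap: RelevanceMap) -> pd.DataFrame:
    """Tidy per-edge export of a relevance map."""
    E = arena.n_interior_edges
    ec = arena._geom.edge_cells_arr[:E]
    return pd.DataFrame(
        {
            "edge": np.arange(E),
            "cell_a": ec[:, 0],
            "cell_b": ec[:, 1],
            "omega": rmap.omega,
            "omega_norm": rmap.omega_norm,
        }
    )
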