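"""Active-sensing agent simulations on corrupted world models.

Agents start each trial with a corrupted copy of the arena adjacency
(half of the blocked transitions believed open and an equal number of open
transitions believed blocked).  Before navigating they foveate ``k``
transitions under one of four policies — ``blind`` (no samples), ``random``
(uniform without replacement), ``goalward`` (von Mises around the goal
bearing, kappa = 5), ``directed`` (the k most task-relevant transitions under
the subjective model) — correcting the subjective model wherever a sample
disagrees with reality.  They then act greedily on the subjective value
function; bumping into a real wall (or discovering an unexpected opening)
corrects the touched transitions and triggers a value recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import Arena, random_arena
from .planning import value_iteration, _move_table, HEADINGS_DEG

__all__ = [
    "SubjectiveModel",
    "AgentSpec",
    "corrupt_model",
    "sample_gaze_targets",
    "simulate_trial",
    "run_experiment",
    "POLICIES",
]

POLICIES = ("blind", "random", "goalward", "directed")


@dataclass
class SubjectiveModel:
    """An agent's belief about the arena: same geometry, noisy passability."""

    true_arena: Arena
    passable: np.ndarray  # subjective belief per interior edge
    corrupted: np.ndarray = field(default=None)  # edges toggled at init

    @property
    def arena(self) -> Arena:
        """The believed arena (geometry shared with the true one)."""
        return self.true_arena.with_passable(self.passable)

    def observe(self, edges) -> bool:
        """Set the belief at ``edges`` to the true status; True if changed."""
        edges = np.asarray(list(edges), dtype=int)
        if len(edges) == 0:
            return False
        truth = self.true_arena.passable[edges]
        changed = bool((self.passable[edges] != truth).any())
        self.passable[edges] = truth
        return changed


@dataclass
class AgentSpec:
    policy: str
    k: int = 8
    kappa: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy == "blind":
            self.k = 0
        elif self.k < 1:
            raise ValueError("sighted agents need k >= 1 samples")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def corrupt_model(arena: Arena, fraction: float = 0.5, seed=0) -> SubjectiveModel:
    """Corrupt ``ceil(fraction * n_blocked)`` blocked edges open and as many
    open edges closed, uniformly at random; boundary edges never toggled."""
    blocked = np.flatnonzero(~arena.passable)
    open_ = np.flatnonzero(arena.passable)
    if fraction > 0 and (len(blocked) == 0 or len(open_) == 0):
        raise ValueError("corruption needs at least one blocked and one open edge")
    n_toggle = int(math.ceil(fraction * len(blocked)))
    if n_toggle > len(open_):
        raise ValueError(
            f"cannot close {n_toggle} edges: only {len(open_)} are open")
    rng = np.random.default_rng(seed)
    passable = arena.passable.copy()
    toggled = np.array([], dtype=int)
    if n_toggle:
        open_these = rng.choice(blocked, size=n_toggle, replace=False)
        close_these = rng.choice(open_, size=n_toggle, replace=False)
        passable[open_these] = True
        passable[close_these] = False
        toggled = np.sort(np.concatenate([open_these, close_these]))
    return SubjectiveModel(arena, passable, toggled)


def sample_gaze_targets(agent: AgentSpec, model: SubjectiveModel, arena: Arena,
                        s0: int, goal: int, rng=None) -> list[int]:
    """Interior edges the agent foveates before navigating."""
    E = arena.n_interior_edges
    k = agent.k
    if k > E:
        raise ValueError(f"k={k} exceeds interior edge count {E}")
    if agent.policy == "blind":
        return []
    rng = np.random.default_rng(agent.seed) if rng is None else rng
    if agent.policy == "random":
        return sorted(int(e) for e in rng.choice(E, size=k, replace=False))
    if agent.policy == "goalward":
        pos = arena.centroids_m[s0]
        gdir = arena.centroids_m[goal] - pos
        theta_g = math.atan2(gdir[1], gdir[0])
        mids = arena.edge_midpoints_m
        bear = np.arctan2(mids[:, 1] - pos[1], mids[:, 0] - pos[0])
        w = np.exp(agent.kappa * np.cos(bear - theta_g))
        # weighted sampling without replacement (exponential-keys trick)
        keys = rng.exponential(size=E) / w
        return sorted(int(e) for e in np.argsort(keys)[:k])
    # directed: top-k relevance on the *subjective* model
    from .relevance import RelevanceCalculator
    omega = RelevanceCalculator(model.arena).omega_matrix(goal)[:, s0]
    order = np.lexsort((np.arange(E), -omega))  # ties -> lowest edge index
    return sorted(int(e) for e in order[:k])


def _observed_edges(mt, s: int, a: int) -> list[int]:
    """Interior edges an agent inspects when attempting move (s, a)."""
    E = mt.n_edges
    req = mt.req[s, a]
    return sorted({int(e) for e in req.ravel() if e < E})


def simulate_trial(arena: Arena, model: SubjectiveModel, agent: AgentSpec,
                   s0: int, goal: int, step_budget: int = 100,
                   rng=None) -> dict:
    """One trial: sample, correct, then navigate greedily on beliefs.

    Returns a dict with success flag, steps, traversed length (m), optimal
    length (m), the visited state sequence, and the updated model.
    Within-trial corrections mutate ``model`` (they persist for this trial
    only under the default per-trial corruption of :func:`run_experiment`).
    """
    if s0 == goal:
        raise ValueError("start must differ from goal")
    if step_budget < 1:
        raise ValueError("step budget must be >= 1")
    rng = np.random.default_rng(agent.seed) if rng is None else rng

    samples = sample_gaze_targets(agent, model, arena, s0, goal, rng)
    model.observe(samples)

    mt = _move_table(arena)
    true_feas = mt.feasibility(arena.passable)
    subj_feas = mt.feasibility(model.passable)
    V = value_iteration(model.arena, goal).values

    s = s0
    visited = [s0]
    traversed_units = 0.0
    steps = 0
    for _ in range(step_budget):
        if s == goal:
            break
        steps += 1
        # greedy on the subjective model; random action when subjectively stuck
        best_a, best_q = None, -np.inf
        for a in range(12):
            if not subj_feas[s, a]:
                continue
            q = -mt.cost[s, a] + V[int(mt.target[s, a])]
            if best_a is None or q > best_q + 1e-12:
                best_a, best_q = a, q
        if best_a is None:
            cand = [a for a in range(12) if mt.target[s, a] >= 0]
            best_a = int(cand[rng.integers(len(cand))])
        obs = _observed_edges(mt, s, best_a)
        if true_feas[s, best_a]:
            if model.observe(obs):  # e.g. discovered an unexpected opening
                subj_feas = mt.feasibility(model.passable)
                V = value_iteration(model.arena, goal).values
            traversed_units += float(mt.cost[s, best_a])
            s = int(mt.target[s, best_a])
            visited.append(s)
        else:
            # bumped into reality: learn the touched walls, stay in place
            model.observe(obs)
            subj_feas = mt.feasibility(model.passable)
            V = value_iteration(model.arena, goal).values
    optimal_units = float(-value_iteration(arena, goal).values[s0])
    side = arena.side_length
    return {
        "success": s == goal,
        "steps": steps,
        "traversed_m": traversed_units * side,
        "optimal_m": optimal_units * side,
        "excess_ratio": (traversed_units / optimal_units
                         if s == goal and optimal_units > 0 else float("nan")),
        "visited": visited,
        "model": model,
    }


def run_experiment(n_arenas: int = 25, granularity: int = 3,
                   trials: int = 100, k_grid=(2, 5, 8, 11, 14),
                   policies=POLICIES, n_obstacles: int = 12,
                   corruption: float = 0.5, step_budget: int = 100,
                   seed=0, side_length: float = 2.0) -> pd.DataFrame:
    """Full factorial simulation: policies x arenas x trials x k.

    A fresh corruption is drawn per trial and shared across policies and k
    values (paired comparisons); start/goal pairs are likewise shared.
    Returns a tidy DataFrame with one row per (policy, arena, trial, k).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ai in range(n_arenas):
        arena = random_arena(granularity, n_obstacles,
                            int(rng.integers(2**31)), side_length)
        for ti in range(trials):
            s0, goal = rng.choice(arena.n_cells, size=2, replace=False)
            corrupt_seed = int(rng.integers(2**31))
            act_seed = int(rng.integers(2**31))
            for k in k_grid:
                for policy in policies:
                    model = corrupt_model(arena, corruption, corrupt_seed)
                    agent = AgentSpec(policy, k=k, seed=act_seed)
                    res = simulate_trial(arena, model, agent, int(s0),
                                         int(goal), step_budget)
                    rows.append({
                        "policy": policy, "arena": ai, "trial": ti, "k": k,
                        "success": res["success"], "steps": res["steps"],
                        "traversed_m": res["traversed_m"],
                        "optimal_m": res["optimal_m"],
                        "excess_ratio": res["excess_ratio"],
                    })
    return pd.DataFrame(rows)
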