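"""Navigation MDP over deltille arenas: actions, value iteration, SR, paths.

The action space has twelve headings spaced 30 degrees apart.  Relative to a
cell's own axes the headings fall into three families with distinct step
lengths (in side-length units):

* edge-crossing moves into the three edge-sharing neighbors, cost ``sqrt(3)/3``
* same-orientation translations along the six 60-degree directions, cost ``1``
* vertex-crossing moves into the three opposite-orientation cells that share
  only a vertex, cost ``2*sqrt(3)/3``

A move is feasible only if the walls it would cross are absent: an edge move
needs its shared edge passable; a translation needs both edges crossed by the
centroid-to-centroid segment passable; a vertex move needs at least one of the
two minimal edge-adjacent detours around the shared vertex fully passable
(``vertex_rule="detour"``, the default) or merely a geometric target
(``vertex_rule="geometric"``).

Value iteration solves the Bellman equation with per-step rewards equal to the
negative step length and the goal state clamped to zero on each sweep, so the
converged value of a state equals the negative geodesic distance to the goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .arena import Arena, OUTSIDE

__all__ = [
    "ActionMove",
    "ValueFunction",
    "Trajectory",
    "SRTable",
    "HEADINGS_DEG",
    "COST_EDGE",
    "COST_TRANSLATE",
    "COST_VERTEX",
    "feasible_actions",
    "value_iteration",
    "sr_values",
    "optimal_path",
    "score_stop",
    "geodesic_distances",
    "move_graph",
]

HEADINGS_DEG = tuple(range(0, 360, 30))
COST_EDGE = math.sqrt(3.0) / 3.0
COST_TRANSLATE = 1.0
COST_VERTEX = 2.0 * math.sqrt(3.0) / 3.0

_NO_TARGET = -1


@dataclass(frozen=True)
class ActionMove:
    heading: int  # degrees
    target: int  # cell id
    cost: float  # side-length units
    feasible: bool = True


@dataclass
class ValueFunction:
    goal: int
    values: np.ndarray  # per-state V*(s) <= 0, side-length units
    gamma: float
    iterations: int


@dataclass
class Trajectory:
    states: list[int]
    polyline: np.ndarray  # (L, 2) centroid waypoints in meters
    length_m: float


@dataclass
class SRTable:
    M: np.ndarray
    horizon: int
    policy: str = "random-walk"


class MoveTable:
    """Vectorized move tables for one arena geometry + vertex rule.

    Arrays indexed ``[state, action]``:

    - ``target``: destination cell id or -1 when no cell lies in that direction
    - ``cost``: step length in side-length units
    - ``req``: ``(S, 12, 2, 3)`` interior-edge requirements; a move is feasible
      iff for some alternative all listed edges are passable.  Sentinel
      ``E`` means "no edge required" (always passes); ``E + 1`` means "this
      alternative does not exist" (always fails).
    """

    def __init__(self, arena: Arena, vertex_rule: str = "detour"):
        if vertex_rule not in ("detour", "geometric"):
            raise ValueError(f"unknown vertex_rule {vertex_rule!r}")
        geom = arena._geom
        S, E = geom.n_cells, geom.n_interior
        self.n_edges = E
        self.vertex_rule = vertex_rule
        target = np.full((S, 12), _NO_TARGET, dtype=np.int64)
        cost = np.zeros((S, 12))
        req = np.full((S, 12, 2, 3), E + 1, dtype=np.int64)

        cent = geom.centroids
        # centroid lookup by integer key (2x, 3y/h)
        h = math.sqrt(3.0) / 2.0
        ckey = {}
        for i, (x, y) in enumerate(cent):
            ckey[(round(2 * x), round(3 * y / h))] = i

        def cell_at(x, y):
            return ckey.get((round(2 * x), round(3 * y / h)), _NO_TARGET)

        pair = geom.pair_to_edge
        for s in range(S):
            orient = geom.lattice[s][2]
            cx, cy = cent[s]
            edge_heads = (30, 150, 270) if orient == "up" else (90, 210, 330)
            vert_heads = (90, 210, 330) if orient == "up" else (30, 150, 270)
            for a, hd in enumerate(HEADINGS_DEG):
                if hd in edge_heads:
                    d = COST_EDGE
                elif hd in vert_heads:
                    d = COST_VERTEX
                else:
                    d = COST_TRANSLATE
                tx = cx + d * math.cos(math.radians(hd))
                ty = cy + d * math.sin(math.radians(hd))
                t = cell_at(tx, ty)
                if t == _NO_TARGET:
                    continue
                target[s, a] = t
                cost[s, a] = d
                if hd in edge_heads:
                    req[s, a, 0] = (pair[(min(s, t), max(s, t))], E, E)
                elif d == COST_TRANSLATE:
                    mids = set(geom.geo_neighbors[s]) & set(geom.geo_neighbors[t])
                    # translations have exactly one intermediate edge-neighbor
                    assert len(mids) == 1, (s, t, mids)
                    m = mids.pop()
                    req[s, a, 0] = (
                        pair[(min(s, m), max(s, m))],
                        pair[(min(m, t), max(m, t))],
                        E,
                    )
                else:  # vertex-crossing
                    if vertex_rule == "geometric":
                        req[s, a, 0] = (E, E, E)
                        continue
                    vx, vy = (cx + tx) / 2.0, (cy + ty) / 2.0
                    vkey = (round(2 * vx), round(vy / h))
                    ring = geom.vertex_cells.get(vkey, [])
                    # order incident cells by angle around the vertex
                    ring = sorted(
                        ring,
                        key=lambda c: math.atan2(
                            cent[c][1] - vy, cent[c][0] - vx
                        ),
                    )
                    if s not in ring or t not in ring:
                        target[s, a] = _NO_TARGET
                        continue
                    L = len(ring)
                    si = ring.index(s)
                    alt = 0
                    for step in (1, -1):  # the two ways around the vertex
                        chain = []
                        i = si
                        ok = True
                        for _ in range(3):  # up to 2 intermediates + target
                            j = (i + step) % L
                            a_, b_ = ring[i], ring[j]
                            key = (min(a_, b_), max(a_, b_))
                            if key not in pair:
                                ok = False
                                break
                            chain.append(pair[key])
                            i = j
                            if ring[i] == t:
                                break
                        if ok and ring[i] == t and len(chain) == 3:
                            req[s, a, alt] = tuple(chain)
                            alt += 1
                    if alt == 0:
                        target[s, a] = _NO_TARGET

        self.target = target
        self.cost = cost
        self.req = req

    def feasibility(self, passable: np.ndarray) -> np.ndarray:
        """(S, 12) boolean mask of feasible moves for an obstacle vector."""
        ext = np.concatenate([passable, [True, False]])
        ok = ext[self.req].all(axis=3).any(axis=2)
        return ok & (self.target != _NO_TARGET)


def _move_table(arena: Arena, vertex_rule: str = "detour") -> MoveTable:
    cache = arena._geom.__dict__.setdefault("_move_tables", {})
    if vertex_rule not in cache:
        cache[vertex_rule] = MoveTable(arena, vertex_rule)
    return cache[vertex_rule]


def feasible_actions(arena: Arena, s: int,
                     vertex_rule: str = "detour") -> list[ActionMove]:
    """All feasible moves from state ``s`` (at most 12)."""
    if not (0 <= s < arena.n_cells):
        raise ValueError(f"invalid state {s}")
    mt = _move_table(arena, vertex_rule)
    feas = mt.feasibility(arena.passable)
    out = []
    for a in range(12):
        if feas[s, a]:
            out.append(
                ActionMove(HEADINGS_DEG[a], int(mt.target[s, a]),
                           float(mt.cost[s, a]))
            )
    return out


def value_iteration(arena: Arena, goal: int, iterations: int = 100,
                    gamma: float = 1.0, tol: float = 1e-12,
                    vertex_rule: str = "detour") -> ValueFunction:
    """Synchronous Bellman backups with the goal value clamped to zero.

    Values start at zero and decrease toward ``-geodesic distance``; states
    unreachable within the iteration horizon keep falling until the sweep
    cap bounds them, which is what makes toggled-obstacle value differences
    finite when a toggle disconnects the goal.
    """
    if not (0 <= goal < arena.n_cells):
        raise ValueError(f"invalid goal state {goal}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mt = _move_table(arena, vertex_rule)
    feas = mt.feasibility(arena.passable)
    tgt = np.where(feas, mt.target, 0)
    V = np.zeros(arena.n_cells)
    it = 0
    for it in range(1, iterations + 1):
        Q = np.where(feas, -mt.cost + gamma * V[tgt], -np.inf)
        Vn = np.where(feas.any(axis=1), Q.max(axis=1), V)
        Vn[goal] = 0.0
        delta = np.abs(Vn - V).max()
        V = Vn
        if delta < tol:
            break
    return ValueFunction(goal, V, gamma, it)


def sr_values(arena: Arena, goal: int, horizon: int = 100,
              return_table: bool = False):
    """State values under the successor representation of a random walk.

    ``M = sum_t T_rw**t`` over ``t = 0..horizon`` with ``T_rw`` the
    row-normalized adjacency; values are ``V = M R`` with a one-hot reward at
    the goal.
    """
    if not arena.is_connected():
        raise ValueError("SR values require a connected arena")
    T = arena.adjacency.astype(float)
    deg = T.sum(axis=1, keepdims=True)
    T_rw = np.divide(T, deg, out=np.zeros_like(T), where=deg > 0)
    S = arena.n_cells
    P = np.eye(S)
    M = np.zeros((S, S))
    for _ in range(horizon + 1):
        M += P
        P = P @ T_rw
    R = np.zeros(S)
    R[goal] = 1.0
    V = M @ R
    if return_table:
        return V, SRTable(M, horizon)
    return V


def optimal_path(arena: Arena, vf: ValueFunction, start: int,
                 vertex_rule: str = "detour") -> Trajectory:
    """Greedy ascent of the value function from ``start`` to the goal.

    Ties are broken by lowest heading index, then lowest target id, so replays
    are deterministic.
    """
    if not (0 <= start < arena.n_cells):
        raise ValueError(f"invalid start state {start}")
    mt = _move_table(arena, vertex_rule)
    feas = mt.feasibility(arena.passable)
    V = vf.values
    states = [start]
    s = start
    for _ in range(arena.n_cells):
        if s == vf.goal:
            break
        best, best_q = None, -np.inf
        for a in range(12):  # ascending heading index -> first tie wins
            if not feas[s, a]:
                continue
            t = int(mt.target[s, a])
            q = -mt.cost[s, a] + V[t]
            if best is None or q > best_q + 1e-12:
                best, best_q = t, q
        if best is None:
            raise ValueError(f"state {s} has no feasible actions")
        states.append(best)
        s = best
    if s != vf.goal:
        raise ValueError(
            f"start state {start} cannot reach goal {vf.goal} by greedy ascent"
        )
    poly = arena.centroids_m[states]
    length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
    return Trajectory(states, poly, length)


def score_stop(arena: Arena, stop_state: int, goal: int,
               require_passable: bool = False) -> tuple[int, bool]:
    """Points earned for stopping: 2 in the goal, 1 sharing a border, else 0.

    Geometric border sharing counts regardless of an obstacle on the shared
    edge unless ``require_passable`` is set.  Returns ``(points, in_reward_zone)``.
    """
    for s in (stop_state, goal):
        if not (0 <= s < arena.n_cells):
            raise ValueError(f"invalid state {s}")
    if stop_state == goal:
        return 2, True
    key = (min(stop_state, goal), max(stop_state, goal))
    if key in arena._geom.pair_to_edge:
        k = arena._geom.pair_to_edge[key]
        if not require_passable or arena.passable[k]:
            return 1, True
    return 0, False


# ---------------------------------------------------------------------------
# graph views used by centrality, alternatives, and test oracles

def move_graph(arena: Arena, vertex_rule: str = "detour"):
    """(rows, cols, weights) sparse description of the feasible-move graph."""
    mt = _move_table(arena, vertex_rule)
    feas = mt.feasibility(arena.passable)
    rows, cols = np.nonzero(feas)
    tgts = mt.target[rows, cols]
    w = mt.cost[rows, cols]
    return rows, tgts, w


def geodesic_distances(arena: Arena, vertex_rule: str = "detour") -> np.ndarray:
    """All-pairs geodesics under the 12-direction metric, side-length units."""
    rows, cols, w = move_graph(arena, vertex_rule)
    S = arena.n_cells
    G = csr_matrix((w, (rows, cols)), shape=(S, S))
    return dijkstra(G, directed=False)
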