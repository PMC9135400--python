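"""Deltille arenas: triangular-lattice state spaces inside a hexagonal boundary.

An arena of granularity ``n`` tiles a regular hexagon of side ``n * s`` meters
with ``6 n**2`` equilateral triangles of side ``s``.  Each triangle is a
discrete *state*; each shared edge between two triangles is a *transition*
that is passable unless an obstacle sits on it.  The arena structure is fully
encapsulated in the symmetric 0/1 adjacency matrix over edge-sharing states.

Lattice scheme
--------------
Rows of alternating up/down triangles, masked to the hexagon, with the hexagon
centered at the origin and two horizontal edges (top and bottom).  Cells are
numbered row-major from the bottom row upward, left to right within a row, so
ids are deterministic for a given ``n``.  Interior edges are numbered sorted by
``(min cell id, max cell id)``, which makes obstacle indices portable across
runs; boundary edges follow after all interior edges.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "OUTSIDE",
    "TriCell",
    "EdgeRecord",
    "Arena",
    "CentralityTable",
    "build_arena",
    "random_arena",
    "state_of_point",
    "states_of_points",
    "centrality",
    "arena_complexity",
    "write_arena_json",
    "read_arena_json",
]

#: Marker returned by :func:`state_of_point` for points outside the hexagon.
OUTSIDE = -1

_H = math.sqrt(3.0) / 2.0  # row height in side-length units


@dataclass(frozen=True)
class TriCell:
    """One triangular state of the tessellation."""

    id: int
    lattice: tuple[int, int, str]  # (row, column-within-row, orientation)
    centroid: tuple[float, float]  # meters

    @property
    def orientation(self) -> str:
        return self.lattice[2]


@dataclass(frozen=True)
class EdgeRecord:
    """One edge of the tessellation (a potential transition or wall)."""

    k: int
    cells: tuple[int, int]  # (a, b) interior with a < b, or (a, OUTSIDE)
    midpoint: tuple[float, float]  # meters
    passable: bool

    @property
    def interior(self) -> bool:
        return self.cells[1] != OUTSIDE


@dataclass
class CentralityTable:
    """Per-state closeness and betweenness summaries of an arena graph."""

    closeness: np.ndarray
    betweenness: np.ndarray
    mean_closeness: float
    distances: np.ndarray  # all-pairs geodesic, side-length units


class Arena:
    """A deltille arena: cells, edges, obstacles and the adjacency matrix.

    Parameters are normally supplied through :func:`build_arena`.  The
    geometry (cells, edge list, vertex incidence) depends only on ``n``; the
    per-edge ``passable`` vector carries the obstacle configuration.
    """

    def __init__(self, n: int, side_length: float, passable: np.ndarray,
                 geometry: "_Geometry"):
        self.n = int(n)
        self.side_length = float(side_length)
        self._geom = geometry
        self.passable = np.asarray(passable, dtype=bool).copy()
        if self.passable.shape != (geometry.n_interior,):
            raise ValueError("passable vector does not match interior edge count")
        self._move_table = None  # lazily built by navgaze.planning

    # -- basic counts -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self._geom.n_cells

    @property
    def n_interior_edges(self) -> int:
        return self._geom.n_interior

    @property
    def obstacles(self) -> list[int]:
        """Interior edge indices currently blocked."""
        return [int(k) for k in np.flatnonzero(~self.passable)]

    # -- derived views ------------------------------------------------------
    @property
    def cells(self) -> list[TriCell]:
        s = self.side_length
        return [
            TriCell(i, lat, (cx * s, cy * s))
            for i, (lat, (cx, cy)) in enumerate(
                zip(self._geom.lattice, self._geom.centroids)
            )
        ]

    @property
    def edges(self) -> list[EdgeRecord]:
        s = self.side_length
        out = []
        for k, (cells, mid) in enumerate(
            zip(self._geom.edge_cells, self._geom.edge_midpoints)
        ):
            passable = bool(self.passable[k]) if k < self._geom.n_interior else False
            out.append(EdgeRecord(k, cells, (mid[0] * s, mid[1] * s), passable))
        return out

    @property
    def centroids_m(self) -> np.ndarray:
        """Cell centroids in meters, shape (n_cells, 2)."""
        return self._geom.centroids * self.side_length

    @property
    def edge_endpoints_m(self) -> np.ndarray:
        """Interior edge segment endpoints in meters, shape (E, 2, 2)."""
        return self._geom.edge_segments[: self._geom.n_interior] * self.side_length

    @property
    def edge_midpoints_m(self) -> np.ndarray:
        return self._geom.edge_midpoints[: self._geom.n_interior] * self.side_length

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 matrix; 1 iff the cells share a passable edge."""
        T = np.zeros((self.n_cells, self.n_cells), dtype=np.int8)
        ec = self._geom.edge_cells_arr[: self._geom.n_interior]
        open_pairs = ec[self.passable]
        T[open_pairs[:, 0], open_pairs[:, 1]] = 1
        T[open_pairs[:, 1], open_pairs[:, 0]] = 1
        return T

    def cell_areas_m2(self) -> np.ndarray:
        area = (math.sqrt(3.0) / 4.0) * self.side_length**2
        return np.full(self.n_cells, area)

    def edge_index(self, a: int, b: int) -> int:
        """Interior edge index for the cell pair (a, b); KeyError if not adjacent."""
        return self._geom.pair_to_edge[(min(a, b), max(a, b))]

    def with_passable(self, passable: np.ndarray) -> "Arena":
        """A sibling arena with the same geometry and a new obstacle vector."""
        return Arena(self.n, self.side_length, passable, self._geom)

    def toggled(self, k: int) -> "Arena":
        """Copy of the arena with interior edge ``k``'s passability flipped."""
        p = self.passable.copy()
        p[k] = ~p[k]
        return self.with_passable(p)

    def is_connected(self) -> bool:
        return self.component_labels()[0] == 1

    def component_labels(self) -> tuple[int, np.ndarray]:
        ncomp, labels = connected_components(
            csr_matrix(self.adjacency), directed=False
        )
        return int(ncomp), labels

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Arena(n={self.n}, side={self.side_length} m, "
                f"{self.n_cells} cells, {len(self.obstacles)} obstacles)")


class _Geometry:
    """Obstacle-independent tessellation data, cached per granularity ``n``.

    All coordinates are in side-length units; callers scale by ``side_length``.
    """

    _cache: dict[int, "_Geometry"] = {}

    def __init__(self, n: int):
        self.n = n
        lattice: list[tuple[int, int, str]] = []
        verts: list[tuple[tuple[int, int], ...]] = []  # integer vertex keys
        # vertex key (kx, ky): x = kx / 2, y = ky * _H
        rows: list[list[tuple[str, int]]] = []
        for r in range(2 * n):
            w_bot = 2 * n - abs(r - n)
            w_top = 2 * n - abs(r - n + 1)
            yb, yt = r - n, r - n + 1
            row: list[tuple[float, tuple[tuple[int, int], ...], str]] = []
            for j in range(w_bot):  # up-pointing: base on the bottom line
                x0 = -w_bot + 2 * j  # kx of left base vertex (x units of 1/2)
                v = ((x0, yb), (x0 + 2, yb), (x0 + 1, yt))
                row.append((x0 + 1, v, "up"))
            for j in range(w_top):  # down-pointing: base on the top line
                x0 = -w_top + 2 * j
                v = ((x0, yt), (x0 + 2, yt), (x0 + 1, yb))
                row.append((x0 + 1, v, "down"))
            row.sort(key=lambda t: t[0])
            for col, (_, v, orient) in enumerate(row):
                lattice.append((r, col, orient))
                verts.append(v)
        self.n_cells = len(lattice)
        assert self.n_cells == 6 * n * n
        self.lattice = lattice
        self.cell_vertices = verts

        cent = np.empty((self.n_cells, 2))
        for i, v in enumerate(verts):
            xs = [kx / 2.0 for kx, _ in v]
            ys = [ky * _H for _, ky in v]
            cent[i] = (sum(xs) / 3.0, sum(ys) / 3.0)
        self.centroids = cent

        # --- edges: match triangles that share a (vertex, vertex) pair
        edge_map: dict[tuple, list[int]] = {}
        for i, v in enumerate(verts):
            for a in range(3):
                key = tuple(sorted((v[a], v[(a + 1) % 3])))
                edge_map.setdefault(key, []).append(i)
        interior, boundary = [], []
        for key, cells in edge_map.items():
            if len(cells) == 2:
                interior.append((min(cells), max(cells), key))
            else:
                boundary.append((cells[0], key))
        interior.sort(key=lambda t: (t[0], t[1]))
        boundary.sort()
        self.n_interior = len(interior)
        assert self.n_interior == 9 * n * n - 3 * n

        self.edge_cells: list[tuple[int, int]] = []
        seg = []
        self.pair_to_edge: dict[tuple[int, int], int] = {}
        for k, (a, b, key) in enumerate(interior):
            self.edge_cells.append((a, b))
            self.pair_to_edge[(a, b)] = k
            seg.append(key)
        for a, key in boundary:
            self.edge_cells.append((a, OUTSIDE))
            seg.append(key)
        self.edge_cells_arr = np.array(
            [(a, b) for a, b in self.edge_cells], dtype=np.int64
        )
        self.edge_segments = np.array(
            [[(kx / 2.0, ky * _H) for kx, ky in key] for key in seg]
        )  # (E_total, 2, 2)
        self.edge_midpoints = self.edge_segments.mean(axis=1)

        # vertex -> incident cell ids (used by the planner's vertex moves)
        self.vertex_cells: dict[tuple[int, int], list[int]] = {}
        for i, v in enumerate(verts):
            for key in v:
                self.vertex_cells.setdefault(key, []).append(i)

        # neighbor map over geometric (not passability) adjacency
        self.geo_neighbors: dict[int, list[int]] = {i: [] for i in range(self.n_cells)}
        for a, b in self.edge_cells[: self.n_interior]:
            self.geo_neighbors[a].append(b)
            self.geo_neighbors[b].append(a)

        # half-plane coefficients for vectorized point-in-cell tests:
        # inside iff nx*(x-x0) + ny*(y-y0) >= 0 for each of the 3 edges
        hp = np.empty((self.n_cells, 3, 3))
        for i, v in enumerate(verts):
            cx, cy = cent[i]
            for a in range(3):
                (kx1, ky1), (kx2, ky2) = v[a], v[(a + 1) % 3]
                x1, y1 = kx1 / 2.0, ky1 * _H
                x2, y2 = kx2 / 2.0, ky2 * _H
                nx, ny = -(y2 - y1), (x2 - x1)
                if nx * (cx - x1) + ny * (cy - y1) < 0:
                    nx, ny = -nx, -ny
                norm = math.hypot(nx, ny)
                hp[i, a] = (nx / norm, ny / norm, -(nx * x1 + ny * y1) / norm)
        self.halfplanes = hp

    @classmethod
    def get(cls, n: int) -> "_Geometry":
        if n not in cls._cache:
            cls._cache[n] = cls(n)
        return cls._cache[n]


# ---------------------------------------------------------------------------
# construction

def build_arena(n: int, side_length: float, obstacles=()) -> Arena:
    """Construct a deltille arena with the given obstacle edges.

    Parameters
    ----------
    n
        Granularity; the arena has ``6 n**2`` triangular states.
    side_length
        Triangle side length in meters.
    obstacles
        Interior edge indices (in the canonical ordering) to block.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"granularity n must be a positive integer, got {n!r}")
    if not side_length > 0:
        raise ValueError(f"side_length must be positive, got {side_length!r}")
    geom = _Geometry.get(int(n))
    obstacles = list(obstacles)
    if len(set(obstacles)) != len(obstacles):
        dupes = sorted({k for k in obstacles if obstacles.count(k) > 1})
        raise ValueError(f"duplicate obstacle indices: {dupes}")
    passable = np.ones(geom.n_interior, dtype=bool)
    for k in obstacles:
        if not (0 <= int(k) < geom.n_interior):
            raise ValueError(
                f"obstacle index {k} is not a valid interior edge "
                f"(0..{geom.n_interior - 1})"
            )
        passable[int(k)] = False
    return Arena(int(n), float(side_length), passable, geom)


def random_arena(n: int, n_obstacles: int, seed, side_length: float = 2.0,
                 max_retries: int = 1000) -> Arena:
    """Random connected arena with obstacles drawn uniformly without replacement.

    Obstacle sets that disconnect the state space are rejected and resampled,
    up to ``max_retries`` draws.
    """
    geom = _Geometry.get(int(n))
    if n_obstacles > geom.n_interior:
        raise ValueError(
            f"n_obstacles={n_obstacles} exceeds interior edge count {geom.n_interior}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        obstacles = rng.choice(geom.n_interior, size=n_obstacles, replace=False)
        arena = build_arena(n, side_length, sorted(int(k) for k in obstacles))
        if arena.is_connected():
            return arena
    raise RuntimeError(
        f"could not sample a connected arena with {n_obstacles} obstacles "
        f"at n={n} within {max_retries} retries"
    )


# ---------------------------------------------------------------------------
# point location

def states_of_points(arena: Arena, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorized cell lookup for an (N, 2) array of points in meters.

    Points outside the hexagon map to :data:`OUTSIDE`.  A point exactly on an
    edge is assigned to the incident cell with the smaller id.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if not np.isfinite(pts).all():
        raise ValueError("non-finite point coordinates")
    u = pts / arena.side_length  # side-length units
    hp = arena._geom.halfplanes  # (C, 3, 3)
    # signed distances, shape (N, C, 3)
    d = (hp[None, :, :, 0] * u[:, None, None, 0]
         + hp[None, :, :, 1] * u[:, None, None, 1]
         + hp[None, :, :, 2])
    inside = (d >= -tol).all(axis=2)  # (N, C)
    any_in = inside.any(axis=1)
    first = np.where(any_in, inside.argmax(axis=1), OUTSIDE)
    return first


def state_of_point(arena: Arena, p) -> int:
    """Cell id containing point ``p`` (meters), or :data:`OUTSIDE`."""
    return int(states_of_points(arena, np.asarray(p, dtype=float))[0])


# ---------------------------------------------------------------------------
# centrality and complexity

def centrality(arena: Arena, distance: str = "metric") -> CentralityTable:
    """Closeness and betweenness centrality of every state.

    Closeness ``C(s) = (N - 1) / sum_s' d(s', s)`` uses geodesic distances
    under the 12-direction planning metric by default (``distance="metric"``,
    side-length units); ``distance="steps"`` counts unit steps on the
    passable-edge graph instead.  Betweenness counts shortest paths on the
    passable-edge graph (each unordered pair once).
    """
    ncomp, labels = arena.component_labels()
    if ncomp != 1:
        sizes = np.bincount(labels)
        small = np.flatnonzero(labels != np.argmax(sizes))
        raise ValueError(
            f"arena is disconnected ({ncomp} components); "
            f"unreachable states include {small[:10].tolist()}"
        )
    if distance == "metric":
        from .planning import geodesic_distances
        dist = geodesic_distances(arena)  # side-length units
    elif distance == "steps":
        from scipy.sparse.csgraph import shortest_path
        dist = shortest_path(csr_matrix(arena.adjacency), unweighted=True)
    else:
        raise ValueError(f"unknown distance mode {distance!r}")
    N = arena.n_cells
    closeness = (N - 1) / dist.sum(axis=0)

    import networkx as nx
    G = nx.Graph()
    G.add_nodes_from(range(N))
    ec = arena._geom.edge_cells_arr[: arena.n_interior_edges]
    G.add_edges_from(ec[arena.passable])
    bt = nx.betweenness_centrality(G, normalized=False)
    betweenness = np.array([bt[i] for i in range(N)])
    return CentralityTable(closeness, betweenness, float(closeness.mean()), dist)


def arena_complexity(mean_closeness_values) -> list[float]:
    """Complexity scores ``-100 * (Cbar - max Cbar)`` across a set of arenas.

    The arena with the greatest mean closeness (the most open one) scores
    exactly 0; all scores are >= 0 and ordering is the reverse of closeness.
    """
    vals = [float(c) for c in mean_closeness_values]
    if not vals:
        raise ValueError("at least one mean-closeness value is required")
    top = max(vals)
    return [100.0 * (top - c) for c in vals]


# ---------------------------------------------------------------------------
# JSON round-trip

def write_arena_json(arena: Arena, path, name: str = "") -> None:
    payload = {
        "n": arena.n,
        "side_length_m": arena.side_length,
        "obstacles": arena.obstacles,
        "name": name,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_arena_json(path) -> tuple[Arena, str]:
    payload = json.loads(Path(path).read_text())
    arena = build_arena(
        payload["n"], payload["side_length_m"], payload["obstacles"]
    )
    return arena, payload.get("name", "")
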