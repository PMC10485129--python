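"""Cell arrangements and contact graphs.

Cells are equal-radius points in the plane.  Two cells are in contact when
they are Delaunay neighbors whose center distance does not exceed the sum of
their radii; the cell distance ``d_ij`` is the hop count of the shortest
path in the resulting contact graph (edge weights 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree

__all__ = [
    "Tissue",
    "CellGraph",
    "GenerationError",
    "generate_disc_tissue",
    "contact_graph",
    "hex_lattice",
    "line_graph",
    "max_independent_set_size",
]


class GenerationError(RuntimeError):
    """Raised when a tissue generator cannot produce a valid arrangement."""


@dataclass(frozen=True)
class Tissue:
    """Cell positions with a common radius."""

    positions: np.ndarray  # (N, 2)
    radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be an (N>=2, 2) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if not (self.radius > 0):
            raise ValueError("radius must be positive")
        # duplicate points break the contact model
        order = np.lexsort(pos.T)
        if np.any(np.all(np.diff(pos[order], axis=0) == 0, axis=1)):
            raise ValueError("duplicate cell positions")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class CellGraph:
    """Contact relation and graph distances of a tissue.

    ``distances`` holds hop counts as floats, ``np.inf`` for unreachable
    pairs.  ``degrees`` are the adjacency row sums.
    """

    adjacency: np.ndarray  # (N, N) bool
    distances: np.ndarray  # (N, N) float

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        dist = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "distances", dist)
        n = adj.shape[0]
        if adj.shape != (n, n) or dist.shape != (n, n):
            raise ValueError("adjacency and distances must be square and matching")
        if np.any(adj != adj.T) or np.any(np.diag(adj)):
            raise ValueError("adjacency must be symmetric with zero diagonal")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def connected(self) -> bool:
        return bool(np.all(np.isfinite(self.distances)))


def _graph_from_adjacency(adj: np.ndarray) -> CellGraph:
    dist = shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)
    return CellGraph(adjacency=adj, distances=dist)


def contact_graph(tissue: Tissue) -> CellGraph:
    """Build the contact graph: Delaunay edges pruned at center distance
    ``2 * radius``; distances filled by breadth-first search."""
    pos = tissue.positions
    n = tissue.n
    cutoff = 2.0 * tissue.radius
    adj = np.zeros((n, n), dtype=bool)
    candidate_pairs = None
    if n >= 3:
        try:
            tri = Delaunay(pos)
        except QhullError:
            candidate_pairs = None  # degenerate (e.g. collinear): prune all pairs
        else:
            simplices = tri.simplices
            candidate_pairs = np.vstack(
                [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
            )
    if candidate_pairs is None:
        ii, jj = np.triu_indices(n, k=1)
        candidate_pairs = np.column_stack([ii, jj])
    i, j = candidate_pairs.T
    keep = np.linalg.norm(pos[i] - pos[j], axis=1) <= cutoff
    adj[i[keep], j[keep]] = True
    adj |= adj.T
    return _graph_from_adjacency(adj)


def _blue_noise_disc(n: int, rng: np.random.Generator, n_candidates: int = 12) -> np.ndarray:
    """Best-candidate blue-noise sample of ``n`` points in the unit disc."""
    pts = np.empty((n, 2))
    pts[0] = _uniform_disc(rng, 1)[0]
    for i in range(1, n):
        cands = _uniform_disc(rng, n_candidates)
        d2 = ((cands[:, None, :] - pts[None, :i, :]) ** 2).sum(axis=2).min(axis=1)
        pts[i] = cands[np.argmax(d2)]
    return pts


def _uniform_disc(rng: np.random.Generator, k: int) -> np.ndarray:
    r = np.sqrt(rng.uniform(0.0, 1.0, size=k))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=k)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _relax(pts: np.ndarray, iterations: int) -> np.ndarray:
    """Lloyd relaxation toward a centroidal Voronoi packing in the unit disc.

    Each point is reflected across the disc boundary before building the
    Voronoi diagram, which bounds every interior region; points then move to
    their region centroids.  This evens out the spacing while preserving the
    irregular (defect-carrying) neighbor structure of the blue-noise seed.
    """
    pts = pts.copy()
    n = len(pts)
    for _ in range(iterations):
        r = np.maximum(np.linalg.norm(pts, axis=1), 1e-9)
        mirror = pts * ((2.0 - r) / r)[:, None]
        vor = Voronoi(np.vstack([pts, mirror]))
        new = pts.copy()
        for i in range(n):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:
                continue
            poly = vor.vertices[region]
            x, y = poly[:, 0], poly[:, 1]
            xs, ys = np.roll(x, -1), np.roll(y, -1)
            cross = x * ys - xs * y
            area = cross.sum() / 2.0
            if abs(area) < 1e-12:
                continue
            new[i] = (
                ((x + xs) * cross).sum() / (6.0 * area),
                ((y + ys) * cross).sum() / (6.0 * area),
            )
        pts = new
        rr = np.linalg.norm(pts, axis=1)
        out = rr > 0.999
        if np.any(out):
            pts[out] *= (0.999 / rr[out])[:, None]
    return pts


def generate_disc_tissue(
    n: int = 177,
    seed: int = 0,
    *,
    contact_factor: float = 1.4,
    relax_iterations: int = 80,
    max_retries: int = 5,
) -> Tissue:
    """Irregular but evenly packed arrangement of ``n`` cells in a disc.

    Seeded blue-noise sampling followed by Lloyd (centroidal Voronoi)
    relaxation.  The common radius is half the median nearest-neighbor
    spacing times ``contact_factor``; even in a well-relaxed irregular
    packing, Delaunay-neighbor center distances spread up to ~1.3x the
    median nearest-neighbor spacing, so a generous factor is needed for
    touching neighbors to register as contacts.  The default keeps bulk
    cells at about six contacts and boundary cells at three to four, giving
    a mean degree near 5.5 at the default size.  Deterministic given
    ``seed``; regenerates from a derived seed (up to ``max_retries`` times)
    in the rare case the contact graph comes out disconnected.
    """
    if n < 2:
        raise ValueError("need at least 2 cells")
    last_graph = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        pts = _blue_noise_disc(n, rng)
        pts = _relax(pts, relax_iterations)
        tree = cKDTree(pts)
        nn_dist = tree.query(pts, k=2)[0][:, 1]
        radius = contact_factor * 0.5 * float(np.median(nn_dist))
        tissue = Tissue(positions=pts, radius=radius)
        graph = contact_graph(tissue)
        if graph.connected:
            return tissue
        last_graph = graph
    n_comp = connected_components(csr_matrix(last_graph.adjacency), directed=False)[0]
    raise GenerationError(
        f"disc tissue disconnected after {max_retries} attempts "
        f"(last attempt: {n_comp} components, n={n}, seed={seed})"
    )


def _hex_positions(rows: int, cols: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = jj + 0.5 * (ii % 2)
    y = ii * (math.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def hex_lattice(rows: int, cols: int, periodic: bool = False) -> tuple[Tissue, CellGraph]:
    """Triangular ("hexagonal-packing") lattice fixture.

    Rows are offset by half a spacing; with ``periodic=True`` the lattice
    wraps in both directions and every cell has exactly six neighbors
    (provided the torus is large enough for simple-graph semantics —
    wrapped duplicate edges are deduplicated).  Periodic wrapping requires
    an even number of rows.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    if periodic and rows % 2:
        raise ValueError("periodic hex lattice requires an even row count")
    idx = lambda i, j: i * cols + j  # noqa: E731
    edges: set[tuple[int, int]] = set()
    for i in range(rows):
        shift = 1 if i % 2 else -1  # column offset of diagonal neighbors
        for j in range(cols):
            neighbors = [
                (i, j - 1),
                (i, j + 1),
                (i - 1, j),
                (i + 1, j),
                (i - 1, j + shift),
                (i + 1, j + shift),
            ]
            for ni, nj in neighbors:
                if periodic:
                    ni %= rows
                    nj %= cols
                elif not (0 <= ni < rows and 0 <= nj < cols):
                    continue
                a, b = idx(i, j), idx(ni, nj)
                if a != b:
                    edges.add((min(a, b), max(a, b)))
    n = rows * cols
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    tissue = Tissue(positions=_hex_positions(rows, cols), radius=0.525)
    return tissue, _graph_from_adjacency(adj)


def line_graph(n: int) -> CellGraph:
    """One-dimensional chain of ``n`` cells; ``d_ij = |i - j|``."""
    if n < 2:
        raise ValueError("need at least 2 cells")
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = True
    return _graph_from_adjacency(adj)


def max_independent_set_size(graph: CellGraph) -> int:
    """Exact size of the largest set of mutually non-adjacent cells.

    Exhaustive branch-and-bound over vertex bitmasks; intended for small
    fixtures (refuses graphs with more than 40 cells).
    """
    n = graph.n
    if n > 40:
        raise ValueError("exhaustive search limited to 40 cells")
    nbr = [0] * n
    ii, jj = np.nonzero(graph.adjacency)
    for a, b in zip(ii.tolist(), jj.tolist()):
        nbr[a] |= 1 << b

    @lru_cache(maxsize=None)
    def mis(mask: int) -> int:
        if mask == 0:
            return 0
        v = (mask & -mask).bit_length() - 1
        without = mis(mask & ~(1 << v))
        with_v = 1 + mis(mask & ~((1 << v) | nbr[v]))
        return max(without, with_v)

    result = mis((1 << n) - 1)
    mis.cache_clear()
    return result
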