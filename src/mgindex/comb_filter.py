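"""One-dimensional lattice detection by comb filtering of projected g-vectors.

A candidate set of lattice planes is parameterized by a unit plane normal û
and a spacing d*.  Projecting every g-vector onto û and counting how many
projections fall within ±ε of a nonzero comb node n·d* (|n|·d* ≤ q_max)
measures how well that 1-D lattice explains the data.  The count is
background-corrected by subtracting the expectation for reflections placed
uniformly at random in the spherical shell [q_min, q_max].

The spacing is scanned on an adaptive grid, d*_{k+1} = d*_k + ε/⌊q_max/d*_k⌋,
so the outermost comb node moves by at most ε per step and no 1-D lattice
can be stepped over.  Because the comb is symmetric (Friedel mates project
to ±x) and has no node at the origin, all counting happens on |x|.

Boxes never overlap: the parameter contract 2ε < d*_min ≤ d* keeps adjacent
boxes separated, so "nearest node within ε" and per-box interval counts are
the same thing and each reflection is counted at most once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CombParams",
    "LatticeCandidate",
    "project",
    "comb_count",
    "expected_random_count",
    "dstar_grid",
    "scan_dstar",
    "scan_directions",
    "refine_local",
]

_EPS_TIE = 1e-12


@dataclass(frozen=True)
class CombParams:
    """Comb geometry: box half-width ε, data cutoff q_max, and the scanned
    d* range.  d*_max defaults to q_max/2 (a 1-D lattice with a single node
    pair inside q_max carries no periodicity information beyond that)."""

    epsilon: float
    q_max: float
    dstar_min: float
    dstar_max: float | None = None

    def __post_init__(self) -> None:
        if self.dstar_max is None:
            object.__setattr__(self, "dstar_max", self.q_max / 2.0)
        if not 0.0 < 2.0 * self.epsilon < self.dstar_min:
            raise ValueError("require 0 < 2*epsilon < dstar_min")
        if not self.dstar_min < self.dstar_max:
            raise ValueError("require dstar_min < dstar_max")
        if self.q_max <= 0:
            raise ValueError("q_max must be > 0")


@dataclass
class LatticeCandidate:
    """A scored 1-D lattice: unit direction û, node spacing d*, raw in-box
    count, background-subtracted score, and the member reflection indices."""

    direction: np.ndarray
    dstar: float
    raw_count: int
    score: float
    members: np.ndarray

    def __post_init__(self) -> None:
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)


def _as_gvectors(pool_or_g) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a GVectorPool (active rows) or a plain (N, 3) array.

    Returns the g-vector array and, for pools, the map from local row to
    pool row index (None for plain arrays)."""
    if hasattr(pool_or_g, "g") and hasattr(pool_or_g, "active_indices"):
        idx = pool_or_g.active_indices()
        return pool_or_g.g[idx], idx
    return np.atleast_2d(np.asarray(pool_or_g, dtype=float)), None


def project(pool_or_g, direction: np.ndarray) -> np.ndarray:
    """Signed projections x_i = g_i·û of the (active) reflections onto û."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    g, _ = _as_gvectors(pool_or_g)
    return g @ direction


def _n_nodes(dstar: float, q_max: float) -> int:
    return int(math.floor(q_max / dstar + 1e-9))


def comb_count(projections, dstar: float, params: CombParams) -> tuple[int, np.ndarray]:
    """Count projections within ε of their nearest nonzero node n·d*, |n|d* ≤ q_max.

    Returns (count, member indices into the projections array)."""
    if not dstar > 2.0 * params.epsilon:
        raise ValueError("require dstar > 2*epsilon")
    x = np.abs(np.asarray(projections, dtype=float))
    if x.size == 0:
        return 0, np.zeros(0, dtype=int)
    m = _n_nodes(dstar, params.q_max)
    if m < 1:
        return 0, np.zeros(0, dtype=int)
    n = np.clip(np.rint(x / dstar), 1, m)
    members = np.flatnonzero(np.abs(x - n * dstar) <= params.epsilon)
    return int(members.size), members


def _shell_projection_cdf_term(q: float, t: np.ndarray) -> np.ndarray:
    """∫₀ᵗ (q² − x²)₊ dx for t ≥ 0."""
    tc = np.clip(t, 0.0, q)
    return q * q * tc - tc**3 / 3.0


def _box_probabilities(nodes: np.ndarray, epsilon: float, q_min: float, q_max: float) -> np.ndarray:
    """Probability that |x| of a uniform shell point lands in [node−ε, node+ε].

    The projection of a point uniform in the shell [q_min, q_max] onto a line
    has density p(x) = 3[(q_max²−x²)₊ − (q_min²−x²)₊] / [4(q_max³−q_min³)];
    both signs of the node contribute (p is even).
    """
    nodes = np.asarray(nodes, dtype=float)
    c = 3.0 / (4.0 * (q_max**3 - q_min**3))
    a = np.maximum(nodes - epsilon, 0.0)
    b = nodes + epsilon
    integral = _shell_projection_cdf_term(q_max, b) - _shell_projection_cdf_term(q_max, a)
    if q_min > 0.0:
        integral -= _shell_projection_cdf_term(q_min, b) - _shell_projection_cdf_term(q_min, a)
    return 2.0 * c * integral


def expected_random_count(
    n_reflections: int, dstar: float, params: CombParams, q_min: float = 0.0
) -> float:
    """Expected comb count for n reflections uniform in the shell [q_min, q_max]."""
    if not q_min < params.q_max:
        raise ValueError("require q_min < q_max")
    m = _n_nodes(dstar, params.q_max)
    if m < 1 or n_reflections == 0:
        return 0.0
    nodes = dstar * np.arange(1, m + 1)
    return float(n_reflections * _box_probabilities(nodes, params.epsilon, q_min, params.q_max).sum())


# --- adaptive d* grid and per-grid node tables, cached per parameter set ---

_table_cache: dict[tuple, dict] = {}


def dstar_grid(params: CombParams) -> np.ndarray:
    """The adaptive scan grid d*_{k+1} = d*_k + ε/⌊q_max/d*_k⌋ over
    [dstar_min, dstar_max]."""
    return _tables(params)["grid"]


def _tables(params: CombParams) -> dict:
    key = (params.epsilon, params.q_max, params.dstar_min, params.dstar_max)
    tab = _table_cache.get(key)
    if tab is not None:
        return tab
    vals = []
    d = params.dstar_min
    while d <= params.dstar_max + 1e-12:
        vals.append(d)
        m = _n_nodes(d, params.q_max)
        if m < 1:
            break
        d += params.epsilon / m
    grid = np.array(vals)
    m_per = np.maximum(np.floor(params.q_max / grid + 1e-9).astype(int), 0)
    offsets = np.concatenate(([0], np.cumsum(m_per)[:-1]))
    # node n-values: 1..m for each grid point, flattened
    total = int(m_per.sum())
    nvals = np.arange(total) - np.repeat(offsets, m_per) + 1
    node_pos = np.repeat(grid, m_per) * nvals
    tab = {
        "grid": grid,
        "m_per": m_per,
        "offsets": offsets,
        "node_lo32": (node_pos - params.epsilon).astype(np.float32),
        "node_hi32": (node_pos + params.epsilon).astype(np.float32),
        "node_lo": node_pos - params.epsilon,
        "node_hi": node_pos + params.epsilon,
        "node_pos": node_pos,
        "prob_cache": {},
    }
    _table_cache[key] = tab
    return tab


def _expected_grid(params: CombParams, q_min: float) -> np.ndarray:
    """Per-reflection membership probability at every grid d* (cached)."""
    tab = _tables(params)
    probs = tab["prob_cache"].get(q_min)
    if probs is None:
        if tab["node_pos"].size:
            per_node = _box_probabilities(tab["node_pos"], params.epsilon, q_min, params.q_max)
            probs = np.add.reduceat(per_node, tab["offsets"])
        else:
            probs = np.zeros(len(tab["grid"]))
        tab["prob_cache"][q_min] = probs
    return probs


def _scan_sorted(absx_sorted: np.ndarray, params: CombParams, q_min: float, n_total: int):
    """Counts and background-subtracted scores over the full d* grid for one
    direction, given sorted |projections|.  Returns (best index, counts, scores)."""
    tab = _tables(params)
    if absx_sorted.dtype == np.float32:
        lo = np.searchsorted(absx_sorted, tab["node_lo32"], side="left")
        hi = np.searchsorted(absx_sorted, tab["node_hi32"], side="right")
    else:
        lo = np.searchsorted(absx_sorted, tab["node_lo"], side="left")
        hi = np.searchsorted(absx_sorted, tab["node_hi"], side="right")
    per_node = hi - lo
    counts = np.add.reduceat(per_node, tab["offsets"])
    scores = counts - n_total * _expected_grid(params, q_min)
    best = len(scores) - 1 - int(np.argmax(scores[::-1]))  # ties -> larger d*
    return best, counts, scores


def scan_dstar(
    projections,
    params: CombParams,
    q_min: float = 0.0,
    direction: np.ndarray | None = None,
) -> LatticeCandidate:
    """Scan d* over the adaptive grid and return the best-scoring candidate
    for this direction (score = count − expected random count; ties broken
    toward larger d*)."""
    x = np.asarray(projections, dtype=float)
    absx = np.sort(np.abs(x))
    k, counts, scores = _scan_sorted(absx, params, q_min, len(x))
    dstar = float(dstar_grid(params)[k])
    count, members = comb_count(x, dstar, params)
    return LatticeCandidate(
        direction=direction,
        dstar=dstar,
        raw_count=count,
        score=float(scores[k]),
        members=members,
    )


def scan_directions(
    g: np.ndarray,
    directions: np.ndarray,
    params: CombParams,
    q_min: float = 0.0,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized scan_dstar over many directions.

    Returns per-direction arrays (best d*, score, raw count).  Projections
    are reduced to float32 for the ranking scan: the resolution (~6e-8 at
    q ≈ 1) is orders of magnitude below ε, and all reported members are
    recomputed in double precision afterwards.
    """
    g32 = np.asarray(g, dtype=np.float32)
    directions = np.asarray(directions, dtype=float)
    nd = len(directions)
    grid = dstar_grid(params)
    best_d = np.empty(nd)
    best_s = np.empty(nd)
    best_c = np.empty(nd, dtype=int)
    for start in range(0, nd, chunk):
        dirs = directions[start : start + chunk]
        X = np.abs(g32 @ dirs.T.astype(np.float32))
        X.sort(axis=0)
        for j in range(X.shape[1]):
            k, counts, scores = _scan_sorted(X[:, j], params, q_min, len(g32))
            best_d[start + j] = grid[k]
            best_s[start + j] = scores[k]
            best_c[start + j] = counts[k]
    return best_d, best_s, best_c


def _orthonormal_complement(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def refine_local(
    pool_or_g,
    candidate: LatticeCandidate,
    params: CombParams,
    q_min: float = 0.0,
) -> LatticeCandidate:
    """Local 9×9×9 grid refinement of (û, d*).

    The direction is tilted about two axes orthogonal to û over
    ±2ε⌊q_max/d*⌋/q_max rad (the tilt that displaces the outermost node by
    2ε) and d* over ± one adaptive step, both in 9 steps.  Exhaustive
    search; never returns a candidate scoring below the input.
    """
    g, idx_map = _as_gvectors(pool_or_g)
    u = np.asarray(candidate.direction, dtype=float)
    u = u / np.linalg.norm(u)
    d0 = candidate.dstar
    m = max(_n_nodes(d0, params.q_max), 1)
    tilt_range = 2.0 * params.epsilon * m / params.q_max
    step_d = params.epsilon / m
    e1, e2 = _orthonormal_complement(u)
    tilts = np.linspace(-tilt_range, tilt_range, 9)
    t1, t2 = np.meshgrid(tilts, tilts, indexing="ij")
    dirs = u[None, :] + t1.ravel()[:, None] * e1[None, :] + t2.ravel()[:, None] * e2[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    ds = np.clip(d0 + np.linspace(-step_d, step_d, 9), params.dstar_min, params.dstar_max)

    X = np.abs(g @ dirs.T)  # (N, 81)
    n_total = len(g)
    best = (candidate.score, None, None)  # (score, dir index, d*)
    for d in ds:
        mm = _n_nodes(d, params.q_max)
        if mm < 1:
            continue
        n = np.clip(np.rint(X / d), 1, mm)
        counts = (np.abs(X - n * d) <= params.epsilon).sum(axis=0)
        scores = counts - expected_random_count(n_total, d, params, q_min)
        j = int(np.argmax(scores))
        if scores[j] > best[0] + _EPS_TIE:
            best = (float(scores[j]), j, float(d))
    if best[1] is None:
        return candidate
    score, j, d = best
    direction = dirs[j]
    count, members = comb_count(g @ direction, d, params)
    if idx_map is not None:
        members = idx_map[members]
    return LatticeCandidate(
        direction=direction, dstar=d, raw_count=count, score=score, members=members
    )
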