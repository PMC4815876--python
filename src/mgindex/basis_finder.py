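"""Direct-lattice basis determination for a cleaned candidate-grain subset.

Differences of a grain's g-vectors are reciprocal lattice vectors, so the
normal of a plane through any three of its reflections points along a
direct-lattice direction.  All triple normals of the 50 reflections
closest to the origin are enumerated, the subset is projected onto each
and the best 1-D lattice spacing d* is read off the projected values
themselves.  Each surviving (direction, d*) pair is a potential direct
lattice vector û/d*; the three shortest linearly independent ones form a
candidate basis, which is validated by counting how many reflections of
the *full* pool lie within 5ε of its reciprocal lattice points.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .comb_filter import CombParams
from .lattice_core import reciprocal_basis
from .pool import GVectorPool

__all__ = [
    "DirectVectorCandidate",
    "GrainHypothesis",
    "triple_normals",
    "lattice_on_direction",
    "collect_direct_vectors",
    "choose_basis",
    "index_against_pool",
    "best_hypothesis",
]


@dataclass
class DirectVectorCandidate:
    """A potential direct-lattice vector: unit direction û, plane spacing d*
    (Å⁻¹) and its comb count.  The vector itself is û/d* (Å)."""

    direction: np.ndarray
    dstar: float
    count: int

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float) / self.dstar

    @property
    def length(self) -> float:
        return 1.0 / self.dstar


@dataclass
class GrainHypothesis:
    """A candidate grain: direct basis plus one-to-one hkl↔reflection
    assignments (pool row indices) with their distances (Å⁻¹)."""

    basis: np.ndarray
    hkl: np.ndarray
    refl: np.ndarray
    dist: np.ndarray

    @property
    def matched_count(self) -> int:
        return len(self.refl)


def triple_normals(
    g_subset: np.ndarray,
    n_closest: int = 50,
    min_cross_rel: float = 0.01,
    dedup_angle_deg: float = 1.0,
) -> np.ndarray:
    """Unit normals of planes through every triple of the n_closest
    reflections by |g|, with near-collinear triples discarded and
    directions within dedup_angle_deg merged (antipodal-equivalent).
    """
    g = np.atleast_2d(np.asarray(g_subset, dtype=float))
    if len(g) < 3:
        raise ValueError("need at least 3 reflections")
    order = np.argsort(np.linalg.norm(g, axis=1), kind="stable")
    pts = g[order[:n_closest]]
    k = len(pts)
    combos = np.array(list(itertools.combinations(range(k), 3)), dtype=int)
    r1, r2, r3 = pts[combos[:, 0]], pts[combos[:, 1]], pts[combos[:, 2]]
    va, vb = r2 - r1, r3 - r1
    nrm = np.cross(va, vb)
    mag = np.linalg.norm(nrm, axis=1)
    keep = mag >= min_cross_rel * np.linalg.norm(va, axis=1) * np.linalg.norm(vb, axis=1)
    nrm, mag = nrm[keep], mag[keep]
    if len(nrm) == 0:
        return np.zeros((0, 3))
    units = nrm / mag[:, None]
    # canonical sign: make the largest-magnitude component positive
    lead = np.take_along_axis(units, np.argmax(np.abs(units), axis=1)[:, None], axis=1)[:, 0]
    units = np.where(lead[:, None] < 0, -units, units)
    chord = 2.0 * math.sin(math.radians(dedup_angle_deg) / 2.0)
    # Plane families produce thousands of near-identical normals; collapse
    # them first by grid bucketing (cells half the merge radius), then run
    # the exact greedy angular merge on the few surviving representatives.
    keys, inverse = np.unique(
        np.round(units / (chord / 2.0)).astype(np.int64), axis=0, return_inverse=True
    )
    sums = np.zeros((len(keys), 3))
    np.add.at(sums, inverse, units)
    coarse = sums / np.linalg.norm(sums, axis=1, keepdims=True)
    tree = cKDTree(coarse)
    neighbors = tree.query_ball_point(coarse, chord)
    merged_mask = np.zeros(len(coarse), dtype=bool)
    reps = []
    for i in range(len(coarse)):
        if merged_mask[i]:
            continue
        group = [j for j in neighbors[i] if not merged_mask[j]]
        merged_mask[group] = True
        rep = coarse[group].mean(axis=0)
        reps.append(rep / np.linalg.norm(rep))
    return np.array(reps)


def lattice_on_direction(
    g_subset: np.ndarray,
    direction: np.ndarray,
    params: CombParams,
) -> tuple[float, int] | None:
    """Best 1-D lattice spacing along a direction, with d* candidates taken
    from the projected values themselves.

    Every |projection| inside [d*_min, d*_max] is scored by its comb count
    on the subset; the returned d* is the *largest* candidate whose count
    reaches 80% of the maximum (sub-multiples of the true spacing index the
    same reflections, so the largest qualifying spacing is the physical
    one).  None when no projection falls in the d* window.

    Unlike the first-step detection comb, the count here includes the box at
    the origin (node n = 0): a reflection projecting to ~0 lies on the
    central plane of the family and is evidence for the direction.  Without
    it, counts along short direct vectors — whose central plane holds a
    large share of a grain's reflections — are systematically depressed
    relative to long (many-node) vectors, and the cross-direction 80% cut
    can eliminate every short axis, leaving only cell diagonals that
    assemble into an enlarged cell.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    g = np.atleast_2d(np.asarray(g_subset, dtype=float))
    ax = np.abs(g @ direction)
    cand = ax[(ax >= params.dstar_min - 1e-12) & (ax <= params.dstar_max + 1e-12)]
    if cand.size == 0:
        return None
    if cand.size > 200:
        # thin near-duplicates: keep one representative projected value per
        # ε/8 cell (representatives are actual projections, not rounded)
        cell = params.epsilon / 8.0
        _, first = np.unique(np.round(cand / cell).astype(np.int64), return_index=True)
        cand = cand[first]
    m = np.floor(params.q_max / cand + 1e-9).astype(int)[:, None]
    n = np.clip(np.rint(ax[None, :] / cand[:, None]), 0, m)
    counts = (np.abs(ax[None, :] - n * cand[:, None]) <= params.epsilon).sum(axis=1)
    cmax = counts.max()
    ok = counts >= 0.8 * cmax - 1e-9
    j = np.flatnonzero(ok)[np.argmax(cand[ok])]
    return float(cand[j]), int(counts[j])


def _zero_comb_count(g: np.ndarray, direction: np.ndarray, dstar: float, params: CombParams) -> int:
    x = g @ direction
    m = math.floor(params.q_max / dstar + 1e-9)
    n = np.clip(np.rint(np.abs(x) / dstar), 0, m)
    return int((np.abs(np.abs(x) - n * dstar) <= params.epsilon).sum())


def _refine_axis(
    g: np.ndarray, direction: np.ndarray, dstar: float, count: int, params: CombParams
) -> tuple[np.ndarray, float, int]:
    """Sharpen a (direction, d*) axis estimate by least squares.

    Triple-normal directions are noise-limited to ~0.05-0.1° and the d*
    candidate is a single noisy projection; the resulting smear at the outer
    comb nodes biases membership counts.  The members' implied plane indices
    n_i = round(g_i·û/d*) define an overdetermined linear system
    g_i·v ≈ n_i for the direct vector v = û/d*, whose solution gives the
    axis to full least-squares accuracy.  Adopted when it does not lose
    members."""
    x = g @ direction
    m = math.floor(params.q_max / dstar + 1e-9)
    n = np.sign(x) * np.clip(np.rint(np.abs(x) / dstar), 0, m)
    mem = np.abs(x - n * dstar) <= params.epsilon
    if mem.sum() < 4 or np.ptp(n[mem]) == 0:
        return direction, dstar, count
    v, *_ = np.linalg.lstsq(g[mem], n[mem], rcond=None)
    length = np.linalg.norm(v)
    if length == 0.0:
        return direction, dstar, count
    d_new = 1.0 / length
    if not params.dstar_min - 1e-12 <= d_new <= params.dstar_max + 1e-12:
        return direction, dstar, count
    u_new = v / length
    c_new = _zero_comb_count(g, u_new, d_new, params)
    if c_new >= count:
        return u_new, d_new, c_new
    return direction, dstar, count


def collect_direct_vectors(
    g_subset: np.ndarray,
    directions: np.ndarray,
    params: CombParams,
) -> list[DirectVectorCandidate]:
    """Apply lattice_on_direction per direction, refine each surviving axis
    by least squares, and keep entries whose count reaches 80% of the best
    count over all directions."""
    g_subset = np.atleast_2d(np.asarray(g_subset, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if len(directions) == 0:
        raise ValueError("directions must be non-empty")
    results = []
    for u in directions:
        hit = lattice_on_direction(g_subset, u, params)
        if hit is not None:
            results.append(_refine_axis(g_subset, u, hit[0], hit[1], params))
    if not results:
        return []
    best = max(r[2] for r in results)
    return [
        DirectVectorCandidate(direction=u, dstar=d, count=c)
        for u, d, c in results
        if c >= 0.8 * best - 1e-9
    ]


def choose_basis(candidates: list[DirectVectorCandidate]) -> np.ndarray | None:
    """Three shortest linearly independent direct-vector candidates as a
    right-handed basis (rows ordered by length; the last row is sign-flipped
    if needed).  Independence thresholds: sine of the angle to the first
    vector > 0.01, and scalar triple product > 0.01 of the length product.
    Returns None when fewer than three independent vectors exist."""
    if not candidates:
        return None
    vecs = np.array([c.vector for c in candidates])
    lengths = np.linalg.norm(vecs, axis=1)
    order = np.argsort(lengths, kind="stable")
    chosen: list[np.ndarray] = []
    for i in order:
        v = vecs[i]
        if len(chosen) == 0:
            chosen.append(v)
        elif len(chosen) == 1:
            sine = np.linalg.norm(np.cross(chosen[0], v)) / (
                np.linalg.norm(chosen[0]) * np.linalg.norm(v)
            )
            if sine > 0.01:
                chosen.append(v)
        else:
            triple = abs(np.dot(np.cross(chosen[0], chosen[1]), v))
            if triple > 0.01 * np.linalg.norm(chosen[0]) * np.linalg.norm(chosen[1]) * np.linalg.norm(v):
                chosen.append(v)
                break
    if len(chosen) < 3:
        return None
    basis = np.array(chosen)
    if np.linalg.det(basis) < 0:
        basis[2] = -basis[2]
    return basis


def _lattice_points(basis: np.ndarray, q_limit: float) -> tuple[np.ndarray, np.ndarray]:
    """All reciprocal lattice points h·B with 0 < |h·B| ≤ q_limit, where B is
    the reciprocal of the given direct basis.  h_i = g·a_i bounds the search
    box per axis."""
    B = reciprocal_basis(basis)
    hmax = np.floor(q_limit * np.linalg.norm(basis, axis=1) + 1e-9).astype(int)
    ranges = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    P = H @ B
    keep = np.linalg.norm(P, axis=1) <= q_limit
    return H[keep], P[keep]


def index_against_pool(
    basis: np.ndarray,
    pool: GVectorPool,
    params: CombParams,
    tree: cKDTree | None = None,
    active_idx: np.ndarray | None = None,
) -> GrainHypothesis:
    """Match the reciprocal lattice of a direct basis against the active pool.

    For each lattice point with |h·B| ≤ q_max + 5ε the nearest active
    reflection within 5ε is found; conflicts are resolved greedily by
    ascending distance so assignments are one-to-one.  A prebuilt KD-tree
    over the active g-vectors (with its row index map) may be supplied to
    amortize construction across calls.
    """
    basis = np.asarray(basis, dtype=float)
    tol = 5.0 * params.epsilon
    H, P = _lattice_points(basis, params.q_max + tol)
    if active_idx is None:
        active_idx = pool.active_indices()
    if tree is None:
        if active_idx.size == 0:
            return GrainHypothesis(basis, np.zeros((0, 3), int), np.zeros(0, int), np.zeros(0))
        tree = cKDTree(pool.g[active_idx])
    dist, jj = tree.query(P, k=1, distance_upper_bound=tol)
    ok = np.isfinite(dist) & (dist < tol)
    H, dist, jj = H[ok], dist[ok], jj[ok]
    order = np.argsort(dist, kind="stable")
    jj_sorted = jj[order]
    _, first = np.unique(jj_sorted, return_index=True)
    sel = order[np.sort(first)]
    return GrainHypothesis(
        basis=basis,
        hkl=H[sel],
        refl=active_idx[jj[sel]],
        dist=dist[sel],
    )


def best_hypothesis(
    candidates: list,
    pool: GVectorPool,
    params: CombParams,
    min_reflections: int = 20,
) -> GrainHypothesis | None:
    """Run the basis-determination chain on each cleaned candidate subset and
    return the hypothesis matching the most pool reflections, provided it
    reaches min_reflections; otherwise None."""
    active_idx = pool.active_indices()
    tree = cKDTree(pool.g[active_idx]) if active_idx.size else None
    best: GrainHypothesis | None = None
    for cand in candidates:
        members = np.asarray(cand.members, dtype=int)
        if members.size < 3:
            continue
        sub = pool.g[members]
        try:
            dirs = triple_normals(sub)
        except ValueError:
            continue
        if len(dirs) == 0:
            continue
        vec_cands = collect_direct_vectors(sub, dirs, params)
        basis = choose_basis(vec_cands)
        if basis is None:
            continue
        hyp = index_against_pool(basis, pool, params, tree=tree, active_idx=active_idx)
        if best is None or hyp.matched_count > best.matched_count:
            best = hyp
    if best is None or best.matched_count < min_reflections:
        return None
    return best
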