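"""Two-pass random-direction search for candidate-grain reflection subsets.

Pass 1 scans N_u1 random plane-normal directions against the full active
pool, keeps the top-scoring comb candidates and refines them locally.
Each kept subset is then cleaned in pass 2: N_u2 fresh directions (away
from the first-pass normal) are scanned against the subset alone with a
widened box, and the best resulting comb's members replace the subset.
A reflection surviving both combs must sit on two independent families of
lattice planes, which random interlopers essentially never do, so the
cleaned subsets are dominated by single grains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .comb_filter import (
    CombParams,
    LatticeCandidate,
    comb_count,
    refine_local,
    scan_directions,
)
from .pool import GVectorPool

__all__ = [
    "SearchConfig",
    "CandidateGrain",
    "sample_directions",
    "first_pass",
    "second_pass",
    "find_candidates",
]


@dataclass(frozen=True)
class SearchConfig:
    """Direction-search budget.  Defaults reproduce the reference
    parameterization: N_u1 = 10000, N_u2 = 5000, N_j = 5 candidates kept,
    top 10 refined per pass, second-pass box widened by 2x."""

    n_u1: int = 10000
    n_u2: int = 5000
    n_j: int = 5
    epsilon2_factor: float = 2.0
    top_k: int = 10
    min_angle_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_u1 < 1 or self.n_u2 < 1 or self.n_j < 1:
            raise ValueError("direction and candidate counts must be >= 1")
        if self.epsilon2_factor < 1.0:
            raise ValueError("epsilon2_factor must be >= 1")
        if self.top_k < self.n_j:
            raise ValueError("top_k must be >= n_j")


@dataclass
class CandidateGrain:
    """A cleaned candidate-grain subset: pool row indices plus the two
    (direction, d*) comb parameters that selected it."""

    members: np.ndarray
    provenance: tuple[tuple[np.ndarray, float], tuple[np.ndarray, float]]


def sample_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the upper hemisphere (antipodal directions
    are equivalent for the symmetric comb)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.where(v[:, 2:3] < 0, -v, v)


def _remap(cand: LatticeCandidate, row_map: np.ndarray) -> LatticeCandidate:
    return LatticeCandidate(
        direction=cand.direction,
        dstar=cand.dstar,
        raw_count=cand.raw_count,
        score=cand.score,
        members=row_map[cand.members],
    )


def first_pass(
    pool: GVectorPool,
    params: CombParams,
    config: SearchConfig,
    rng: np.random.Generator,
    q_min: float = 0.0,
) -> list[LatticeCandidate]:
    """Scan n_u1 random directions over the active pool; refine the top_k
    scorers locally and return them ranked by refined score.  Candidate
    members are pool row indices."""
    act = pool.active_indices()
    if act.size == 0:
        return []
    G = pool.g[act]
    dirs = sample_directions(config.n_u1, rng)
    dstars, scores, counts = scan_directions(G, dirs, params, q_min)
    top = np.argsort(scores, kind="stable")[::-1][: config.top_k]
    refined = []
    for i in top:
        _, members = comb_count(G @ dirs[i], dstars[i], params)
        cand = LatticeCandidate(
            direction=dirs[i],
            dstar=float(dstars[i]),
            raw_count=int(counts[i]),
            score=float(scores[i]),
            members=members,
        )
        refined.append(_remap(refine_local(G, cand, params, q_min), act))
    refined.sort(key=lambda c: c.score, reverse=True)
    return refined


def second_pass(
    candidate: LatticeCandidate,
    pool: GVectorPool,
    params: CombParams,
    config: SearchConfig,
    rng: np.random.Generator,
    q_min: float = 0.0,
) -> CandidateGrain | None:
    """Clean one first-pass subset with a second comb search restricted to
    the subset, using box half-width epsilon2_factor·ε and directions at
    more than min_angle_deg from the first-pass normal.  Returns None for
    subsets too small to clean (< 4 reflections)."""
    members = np.asarray(candidate.members, dtype=int)
    if members.size < 4:
        return None
    params2 = replace(params, epsilon=params.epsilon * config.epsilon2_factor)
    G = pool.g[members]
    u1 = np.asarray(candidate.direction, dtype=float)
    cos_lim = math.cos(math.radians(config.min_angle_deg))
    dirs = np.zeros((0, 3))
    while len(dirs) < config.n_u2:
        batch = sample_directions(config.n_u2, rng)
        keep = np.abs(batch @ u1) < cos_lim
        dirs = np.concatenate([dirs, batch[keep]])
    dirs = dirs[: config.n_u2]
    dstars, scores, counts = scan_directions(G, dirs, params2, q_min)
    top = np.argsort(scores, kind="stable")[::-1][: config.top_k]
    best: LatticeCandidate | None = None
    for i in top:
        _, mem = comb_count(G @ dirs[i], dstars[i], params2)
        cand = LatticeCandidate(
            direction=dirs[i],
            dstar=float(dstars[i]),
            raw_count=int(counts[i]),
            score=float(scores[i]),
            members=mem,
        )
        cand = refine_local(G, cand, params2, q_min)
        if best is None or cand.score > best.score:
            best = cand
    if best is None or best.members.size == 0:
        return None
    return CandidateGrain(
        members=members[best.members],
        provenance=((u1, candidate.dstar), (best.direction, best.dstar)),
    )


def find_candidates(
    pool: GVectorPool,
    params: CombParams,
    config: SearchConfig,
    q_min: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[CandidateGrain]:
    """Full two-pass search: the n_j best first-pass candidates, each cleaned
    by a second pass.  Ordered by descending first-pass score; candidates
    whose subsets are too small are dropped."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[CandidateGrain] = []
    for cand in first_pass(pool, params, config, rng, q_min)[: config.n_j]:
        cleaned = second_pass(cand, pool, params, config, rng, q_min)
        if cleaned is not None:
            out.append(cleaned)
    return out
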