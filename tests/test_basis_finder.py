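"""Basis determination: triple normals, d* selection, shortest vectors, matching."""

import numpy as np
import pytest

from mgindex.basis_finder import (
    DirectVectorCandidate,
    choose_basis,
    collect_direct_vectors,
    index_against_pool,
    lattice_on_direction,
    triple_normals,
)
from mgindex.comb_filter import CombParams
from mgindex.lattice_core import direct_basis_from_cell
from mgindex.pool import GVectorPool
from mgindex.synthetic_data import PhaseSpec, SimulationConfig, simulate
from mgindex.studies import CEMENTITE


def test_triple_normals_plane_example():
    """Three reflections spanning the z = 0.2 plane give the ±z normal.

    The third point must not be the midpoint of the other two — three
    collinear points span no plane and are discarded by the cross-product
    threshold (checked below)."""
    g = np.array([[0.1, 0, 0.2], [0, 0.1, 0.2], [0.08, 0.05, 0.2]])
    dirs = triple_normals(g, n_closest=3)
    assert len(dirs) == 1
    assert abs(dirs[0] @ [0, 0, 1.0]) == pytest.approx(1.0, abs=1e-12)
    degenerate = np.array([[0.1, 0, 0.2], [0, 0.1, 0.2], [0.05, 0.05, 0.2]])
    assert len(triple_normals(degenerate, n_closest=3)) == 0


def test_triple_normals_collinear_discarded():
    g = np.array([[0.1, 0, 0], [0.2, 0, 0], [0.3, 0, 0]])
    assert len(triple_normals(g, n_closest=3)) == 0


def test_triple_normals_requires_three():
    with pytest.raises(ValueError):
        triple_normals(np.array([[0.1, 0, 0], [0, 0.1, 0]]))


def test_triple_normals_dedup(single_grain_pool):
    """Directions are merged within 1°: the list stays far below the ~19600
    triples of the 50 closest reflections."""
    dirs = triple_normals(single_grain_pool.g)
    assert 3 <= len(dirs) < 4000
    assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize(
    "projections,expected_d",
    [
        # counts 8,4,2,2 at d* = 0.1,0.2,0.3,0.4: only 0.1 reaches 80% of 8
        ([0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4], 0.1),
        # counts 4,2: 0.8*4 excludes 0.4
        ([0.2, -0.2, 0.4, -0.4], 0.2),
    ],
)
def test_lattice_on_direction_hand_examples(projections, expected_d):
    params = CombParams(epsilon=0.0005, q_max=0.45, dstar_min=0.05, dstar_max=0.45)
    g = np.array([[0, 0, x] for x in projections])
    out = lattice_on_direction(g, np.array([0, 0, 1.0]), params)
    assert out is not None
    assert out[0] == pytest.approx(expected_d, abs=1e-9)


def test_lattice_on_direction_none_below_window():
    params = CombParams(epsilon=0.0005, q_max=0.6, dstar_min=0.1)
    g = np.array([[0, 0, 0.05], [0, 0, -0.05]])
    assert lattice_on_direction(g, np.array([0, 0, 1.0]), params) is None


def test_collect_direct_vectors_recovers_cubic_axes():
    """A noise-free cubic a = 5 grain yields the three axis vectors of length
    5 Å among the surviving candidates."""
    phase = PhaseSpec("cubic5", __import__("mgindex").UnitCell(5, 5, 5, 90, 90, 90))
    pool = simulate(
        SimulationConfig(phases=[phase], grains_per_phase=1, q_min=0.1, q_max=0.6, sigma=0.0, seed=6)
    )
    params = CombParams(epsilon=0.0005, q_max=0.6, dstar_min=0.1)
    dirs = triple_normals(pool.g)
    vecs = collect_direct_vectors(pool.g, dirs, params)
    assert vecs, "no direct-vector candidates survived"
    lengths = np.array([1 / v.dstar for v in vecs])
    axis_like = [v for v in vecs if abs(1 / v.dstar - 5.0) < 1e-6]
    # the three cubic axes are mutually orthogonal
    units = np.array([v.direction for v in axis_like])
    gram = np.abs(units @ units.T) > 0.99
    assert np.linalg.matrix_rank(gram) == 3
    assert (1 / np.array([v.dstar for v in vecs]) >= 5.0 - 1e-6).all()


def test_choose_basis_shortest_independent():
    cands = [
        DirectVectorCandidate(np.array([1.0, 0, 0]), 1 / 5.0, 10),
        DirectVectorCandidate(np.array([1.0, 0, 0]), 1 / 10.0, 10),
        DirectVectorCandidate(np.array([0, 1.0, 0]), 1 / 4.0, 10),
        DirectVectorCandidate(np.array([0, 0, 1.0]), 1 / 6.0, 10),
    ]
    basis = choose_basis(cands)
    assert basis is not None
    rows = {tuple(np.round(np.abs(r), 6)) for r in basis}
    assert rows == {(0.0, 4.0, 0.0), (5.0, 0.0, 0.0), (0.0, 0.0, 6.0)}
    assert np.linalg.det(basis) > 0  # right-handed after the sign flip


def test_choose_basis_insufficient():
    cands = [
        DirectVectorCandidate(np.array([1.0, 0, 0]), 0.2, 5),
        DirectVectorCandidate(np.array([0, 1.0, 0]), 0.2, 5),
    ]
    assert choose_basis(cands) is None
    assert choose_basis([]) is None


def test_choose_basis_orthonormal_passthrough():
    cands = [
        DirectVectorCandidate(np.eye(3)[i], 1.0, 5) for i in range(3)
    ]
    basis = choose_basis(cands)
    assert np.allclose(np.abs(basis), np.eye(3))
    assert np.linalg.det(basis) > 0


def test_index_against_pool_exact(single_grain_pool, cementite_params):
    """The true basis of a noise-free grain matches every reflection at
    distance zero."""
    H = single_grain_pool.hkl.astype(float)
    B, *_ = np.linalg.lstsq(H, single_grain_pool.g, rcond=None)
    A = np.linalg.inv(B).T
    hyp = index_against_pool(A, single_grain_pool, cementite_params)
    assert hyp.matched_count == len(single_grain_pool)
    assert np.allclose(hyp.dist, 0.0, atol=1e-10)
    # one-to-one
    assert len(np.unique(hyp.refl)) == hyp.matched_count


def test_index_against_pool_incommensurate(single_grain_pool, cementite_params):
    """A basis incommensurate with the scene matches only stray coincidences."""
    A = np.diag([np.pi * 10, np.pi * 10, np.pi * 10])
    hyp = index_against_pool(A, single_grain_pool, cementite_params)
    assert hyp.matched_count < 20


def test_index_against_pool_unimodular_invariance(single_grain_pool, cementite_params):
    """An integer change of basis with det ±1 leaves the assignment set
    unchanged (same lattice, same matches)."""
    H = single_grain_pool.hkl.astype(float)
    B, *_ = np.linalg.lstsq(H, single_grain_pool.g, rcond=None)
    A = np.linalg.inv(B).T
    U = np.array([[1, 1, 0], [0, 1, 0], [1, 1, 1]])  # det 1
    hyp1 = index_against_pool(A, single_grain_pool, cementite_params)
    hyp2 = index_against_pool(U @ A, single_grain_pool, cementite_params)
    assert set(hyp1.refl) == set(hyp2.refl)
    assert np.allclose(np.sort(hyp1.dist), np.sort(hyp2.dist), atol=1e-12)


def test_index_against_pool_noise_tolerance(cementite_params):
    """sigma = 1e-4 and matching radius 5ε = 2.5e-3: at least 99% of the
    grain's reflections are matched by the true basis."""
    pool = simulate(
        SimulationConfig(
            phases=[PhaseSpec("cementite", CEMENTITE)],
            grains_per_phase=1,
            q_min=0.1,
            q_max=0.6,
            sigma=1e-4,
            seed=17,
        )
    )
    H = pool.hkl.astype(float)
    B, *_ = np.linalg.lstsq(H, pool.g, rcond=None)
    A = np.linalg.inv(B).T
    hyp = index_against_pool(A, pool, cementite_params)
    assert hyp.matched_count >= 0.99 * len(pool)


def test_index_against_pool_respects_active_mask(single_grain_pool, cementite_params):
    pool = single_grain_pool.copy()
    pool.deactivate(np.arange(0, len(pool), 2))
    H = single_grain_pool.hkl.astype(float)
    B, *_ = np.linalg.lstsq(H, single_grain_pool.g, rcond=None)
    A = np.linalg.inv(B).T
    hyp = index_against_pool(A, pool, cementite_params)
    assert np.all(pool.active[hyp.refl])
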