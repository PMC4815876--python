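"""Comb filter: membership counting, background model, adaptive scan, refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgindex.comb_filter import (
    CombParams,
    comb_count,
    dstar_grid,
    expected_random_count,
    project,
    refine_local,
    scan_directions,
    scan_dstar,
)
from mgindex.lattice_core import direct_basis_from_cell


def brute_force_comb_count(projections, dstar, params):
    """Independent oracle: check every (reflection, node) pair explicitly."""
    nodes = []
    n = 1
    while n * dstar <= params.q_max + 1e-12:
        nodes.extend([n * dstar, -n * dstar])
        n += 1
    members = set()
    for i, x in enumerate(projections):
        for node in nodes:
            if abs(x - node) <= params.epsilon:
                members.add(i)
    return len(members), sorted(members)


def test_params_validation():
    with pytest.raises(ValueError):
        CombParams(epsilon=0.06, q_max=0.6, dstar_min=0.1)  # 2eps >= dstar_min
    with pytest.raises(ValueError):
        CombParams(epsilon=0.0005, q_max=0.6, dstar_min=0.4)  # empty d* range
    p = CombParams(epsilon=0.0005, q_max=0.6, dstar_min=0.1)
    assert p.dstar_max == pytest.approx(0.3)


def test_project_examples(single_grain_pool):
    u = np.array([0.0, 0.0, 1.0])
    assert project(np.array([[0.1, 0.2, 0.3]]), u)[0] == pytest.approx(0.3)
    x = project(single_grain_pool, u)
    assert np.allclose(project(single_grain_pool, -u), -x)
    with pytest.raises(ValueError):
        project(single_grain_pool, np.array([0.0, 0.0, 2.0]))


@pytest.mark.parametrize(
    "projections,dstar,expected",
    [
        ([0.1, 0.2, 0.3001], 0.1, 3),  # 0.3001 within eps of node 0.3
        ([0.15], 0.1, 0),  # midpoint between nodes
        ([], 0.1, 0),
        # 0.05 is no member (node 0.1 is 0.05 away) and 0.4 is no member
        # (beyond the last node 3·0.1 = 0.3 <= q_max); only -0.1 counts
        ([0.05, -0.1, 0.4], 0.1, 1),
    ],
)
def test_comb_count_hand_examples(projections, dstar, expected):
    params = CombParams(epsilon=0.0005, q_max=0.35, dstar_min=0.05)
    count, members = comb_count(projections, dstar, params)
    assert count == expected == len(members)


def test_comb_count_against_brute_force(rng):
    params = CombParams(epsilon=0.004, q_max=0.6, dstar_min=0.05)
    for _ in range(25):
        x = rng.uniform(-0.7, 0.7, size=rng.integers(1, 1000))
        dstar = rng.uniform(0.05, 0.3)
        count, members = comb_count(x, dstar, params)
        bcount, bmembers = brute_force_comb_count(x, dstar, params)
        assert count == bcount
        assert sorted(members.tolist()) == bmembers


def test_comb_count_monotone_in_epsilon(rng):
    x = rng.uniform(-0.6, 0.6, size=500)
    counts = [
        comb_count(x, 0.11, CombParams(epsilon=e, q_max=0.6, dstar_min=0.05))[0]
        for e in (0.0005, 0.002, 0.008, 0.02)
    ]
    assert counts == sorted(counts)


def test_expected_random_count_analytic():
    """Nodes ±0.3 carry shell density p(0.3) = 0.9375 Å⁻¹; node 0.6 carries
    zero: expected ≈ 1000 · 2ε · 2 · 0.9375 = 1.875."""
    params = CombParams(epsilon=0.0005, q_max=0.6, dstar_min=0.1)
    val = expected_random_count(1000, 0.3, params, q_min=0.0)
    assert val == pytest.approx(1.875, abs=0.01)


def test_expected_random_count_monte_carlo(rng):
    """The analytic background matches the empirical mean over uniform-shell
    samples within 3 standard errors (10⁶ points)."""
    q_min, q_max = 0.1, 0.6
    params = CombParams(epsilon=0.002, q_max=q_max, dstar_min=0.1)
    n = 1_000_000
    # uniform in the shell via radius inversion
    u = rng.uniform(q_min**3, q_max**3, n) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    x = (v * u[:, None]) @ np.array([0.0, 0.0, 1.0])
    for dstar in (0.11, 0.17, 0.29):
        count, _ = comb_count(x, dstar, params)
        expected = expected_random_count(n, dstar, params, q_min)
        se = np.sqrt(expected)
        assert abs(count - expected) <= 3.0 * se


def test_expected_count_vanishes_with_epsilon():
    tiny = CombParams(epsilon=1e-9, q_max=0.6, dstar_min=0.1)
    assert expected_random_count(1000, 0.2, tiny, 0.0) < 1e-3


def test_projection_density_normalized():
    """The shell projection density p integrates to 1: node probabilities of
    an edge-to-edge comb plus the uncovered central gap account for all mass."""
    from mgindex.comb_filter import _box_probabilities, _shell_projection_cdf_term

    q_min, q_max, dstar = 0.12, 0.6, 0.08
    eps = dstar / 2.0
    nodes = dstar * np.arange(1, 200)  # cover far beyond q_max
    node_mass = _box_probabilities(nodes, eps, q_min, q_max).sum()
    c = 3.0 / (4.0 * (q_max**3 - q_min**3))
    gap = 2.0 * c * (
        _shell_projection_cdf_term(q_max, np.array(dstar / 2.0))
        - _shell_projection_cdf_term(q_min, np.array(dstar / 2.0))
    )
    assert node_mass + gap == pytest.approx(1.0, abs=1e-12)


def test_dstar_grid_step_property(cementite_params):
    """Consecutive grid values satisfy floor(q_max/d*_k)(d*_{k+1}−d*_k) ≤ ε."""
    g = dstar_grid(cementite_params)
    m = np.floor(cementite_params.q_max / g[:-1] + 1e-9)
    assert np.all(m * np.diff(g) <= cementite_params.epsilon + 1e-12)
    assert g[0] == pytest.approx(cementite_params.dstar_min)
    assert g[-1] <= cementite_params.dstar_max + 1e-12


def test_scan_dstar_prefers_fundamental_spacing():
    """{±0.2, ±0.4, ±0.6}: d* = 0.1 has the same raw count as 0.2 but twice
    the background, so the scan returns ≈ 0.2."""
    params = CombParams(epsilon=0.0005, q_max=0.65, dstar_min=0.05)
    proj = np.array([0.2, -0.2, 0.4, -0.4, 0.6, -0.6])
    cand = scan_dstar(proj, params, q_min=0.0)
    assert cand.dstar == pytest.approx(0.2, abs=2 * params.epsilon)
    assert cand.raw_count == 6


def test_scan_dstar_on_true_normal(single_grain_pool, cementite_params):
    """Projections of a noise-free grain on a true plane normal are integer
    multiples of the true spacing, and the scan finds it within 2ε."""
    H = single_grain_pool.hkl.astype(float)
    B, *_ = np.linalg.lstsq(H, single_grain_pool.g, rcond=None)
    A = np.linalg.inv(B).T
    v = A[2]  # the c axis: d* = 1/6.73 ≈ 0.1486 within the scan window
    u = v / np.linalg.norm(v)
    x = project(single_grain_pool, u)
    mult = x * np.linalg.norm(v)
    assert np.allclose(mult, np.round(mult), atol=1e-9)
    cand = scan_dstar(x, cementite_params, q_min=0.1, direction=u)
    assert cand.dstar == pytest.approx(1 / np.linalg.norm(v), abs=2 * cementite_params.epsilon)


def test_scan_directions_matches_scan_dstar(single_grain_pool, cementite_params, rng):
    dirs = rng.normal(size=(40, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    d, s, c = scan_directions(single_grain_pool.g, dirs, cementite_params, q_min=0.1)
    for j in (0, 17, 39):
        ref = scan_dstar(single_grain_pool.g @ dirs[j], cementite_params, q_min=0.1)
        assert d[j] == pytest.approx(ref.dstar, abs=1e-9)
        assert c[j] == ref.raw_count


def test_refine_local_never_worsens(single_grain_pool, cementite_params, rng):
    dirs = rng.normal(size=(30, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    for u in dirs:
        cand = scan_dstar(single_grain_pool.g @ u, cementite_params, q_min=0.1, direction=u)
        refined = refine_local(single_grain_pool.g, cand, cementite_params, q_min=0.1)
        assert refined.score >= cand.score - 1e-9


def test_refine_local_recovers_perturbed_normal(single_grain_pool, cementite_params):
    """A true normal perturbed by 0.2° refines back toward the axis, capturing
    at least as many members as the perturbed comb."""
    H = single_grain_pool.hkl.astype(float)
    B, *_ = np.linalg.lstsq(H, single_grain_pool.g, rcond=None)
    A = np.linalg.inv(B).T
    v = A[2]
    u = v / np.linalg.norm(v)
    # perturb by 0.2 degrees
    perp = np.cross(u, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    theta = np.radians(0.2)
    u_pert = np.cos(theta) * u + np.sin(theta) * perp
    x = single_grain_pool.g @ u_pert
    dstar = 1 / np.linalg.norm(v)
    from mgindex.comb_filter import LatticeCandidate, expected_random_count

    count, members = comb_count(x, dstar, cementite_params)
    cand = LatticeCandidate(
        direction=u_pert,
        dstar=dstar,
        raw_count=count,
        score=count - expected_random_count(len(x), dstar, cementite_params, 0.1),
        members=members,
    )
    refined = refine_local(single_grain_pool.g, cand, cementite_params, q_min=0.1)
    angle_after = np.degrees(np.arccos(min(abs(refined.direction @ u), 1.0)))
    assert refined.score >= cand.score
    assert angle_after < 0.05


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    dstar=st.floats(0.06, 0.29),
    n=st.integers(1, 300),
)
def test_comb_count_brute_force_property(seed, dstar, n):
    params = CombParams(epsilon=0.003, q_max=0.6, dstar_min=0.05)
    x = np.random.default_rng(seed).uniform(-0.65, 0.65, n)
    count, members = comb_count(x, dstar, params)
    bcount, bmembers = brute_force_comb_count(x, dstar, params)
    assert count == bcount and sorted(members.tolist()) == bmembers
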