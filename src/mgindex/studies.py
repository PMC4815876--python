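"""Reference materials and simulation-study presets.

The two study types — a single-phase cementite ensemble and a four-mineral
"granite" mixture (quartz, biotite, orthoclase, plagioclase) — exercise the
indexer on crystal symmetries from orthorhombic down to triclinic without
supplying any phase information to the algorithm.
"""

from __future__ import annotations

import numpy as np

from .candidate_search import SearchConfig
from .comb_filter import CombParams
from .evaluation import MeritReport, figures_of_merit
from .lattice_core import UnitCell, cell_volume
from .pool import GVectorPool
from .refinement_loop import IndexedGrain, IndexingConfig, run_indexing
from .synthetic_data import PhaseSpec, SimulationConfig, simulate

__all__ = [
    "CEMENTITE",
    "QUARTZ",
    "BIOTITE",
    "ORTHOCLASE",
    "PLAGIOCLASE",
    "GRANITE_PHASES",
    "cementite_study",
    "granite_study",
    "single_phase_study",
    "matched_cubic_cell",
    "run_study",
]

CEMENTITE = UnitCell(4.51, 5.05, 6.73, 90.0, 90.0, 90.0)
QUARTZ = UnitCell(4.92, 4.92, 5.40, 90.0, 90.0, 120.0)
BIOTITE = UnitCell(5.33, 9.23, 10.17, 90.0, 100.16, 90.0)
ORTHOCLASE = UnitCell(8.56, 13.00, 7.19, 90.0, 116.02, 90.0)
PLAGIOCLASE = UnitCell(8.19, 12.88, 14.12, 93.30, 115.79, 91.12)

GRANITE_PHASES = (
    PhaseSpec("quartz", QUARTZ),
    PhaseSpec("biotite", BIOTITE),
    PhaseSpec("orthoclase", ORTHOCLASE),
    PhaseSpec("plagioclase", PLAGIOCLASE),
)


def _configs(
    phases,
    counts,
    *,
    q_max: float,
    d_star_min: float,
    sigma: float,
    n_u1: int,
    n_u2: int,
    sim_seed: int,
    index_seed: int,
) -> tuple[SimulationConfig, IndexingConfig]:
    sim = SimulationConfig(
        phases=phases,
        grains_per_phase=counts,
        q_min=d_star_min,
        q_max=q_max,
        sigma=sigma,
        seed=sim_seed,
    )
    idx = IndexingConfig(
        comb=CombParams(epsilon=0.0005, q_max=q_max, dstar_min=d_star_min),
        q_min=d_star_min,
        search=SearchConfig(n_u1=n_u1, n_u2=n_u2, n_j=5),
        min_reflections=20,
        n_t=20,
        seed=index_seed,
    )
    return sim, idx


def cementite_study(
    n_grains: int = 500,
    n_u1: int = 10000,
    n_u2: int = 5000,
    sigma: float = 1e-4,
    sim_seed: int = 0,
    index_seed: int = 1,
) -> tuple[SimulationConfig, IndexingConfig]:
    """Single-phase study: n_grains cementite grains, q_max = 0.6 Å⁻¹,
    d*_min = 0.1 Å⁻¹."""
    return _configs(
        (PhaseSpec("cementite", CEMENTITE),),
        [n_grains],
        q_max=0.6,
        d_star_min=0.1,
        sigma=sigma,
        n_u1=n_u1,
        n_u2=n_u2,
        sim_seed=sim_seed,
        index_seed=index_seed,
    )


def granite_study(
    grains_per_phase: int = 50,
    n_u1: int = 10000,
    n_u2: int = 5000,
    sigma: float = 1e-4,
    sim_seed: int = 0,
    index_seed: int = 1,
) -> tuple[SimulationConfig, IndexingConfig]:
    """Four-phase study: equal grain counts of the four granite minerals,
    q_max = 0.5 Å⁻¹, d*_min = 0.05 Å⁻¹."""
    return _configs(
        GRANITE_PHASES,
        [grains_per_phase] * 4,
        q_max=0.5,
        d_star_min=0.05,
        sigma=sigma,
        n_u1=n_u1,
        n_u2=n_u2,
        sim_seed=sim_seed,
        index_seed=index_seed,
    )


def _shell_count(cell: UnitCell, q_min: float, q_max: float) -> int:
    from .synthetic_data import grain_reflections

    H, _ = grain_reflections(PhaseSpec("probe", cell), np.eye(3), q_min, q_max)
    return len(H)


def matched_cubic_cell(
    target_per_grain: int, q_min: float, q_max: float
) -> UnitCell:
    """Cubic cell whose per-grain reflection count in [q_min, q_max] is as
    close as possible to the target — used to build single-phase scenes with
    the same total reflection count as a multiphase scene."""
    # count grows ~ a^3; bracket and scan integer-ish candidates
    a0 = (target_per_grain / (4.0 / 3.0 * np.pi * (q_max**3 - q_min**3))) ** (1.0 / 3.0)
    best = None
    for a in np.linspace(0.8 * a0, 1.2 * a0, 81):
        n = _shell_count(UnitCell(a, a, a, 90, 90, 90), q_min, q_max)
        err = abs(n - target_per_grain)
        if best is None or err < best[0]:
            best = (err, a)
    return UnitCell(best[1], best[1], best[1], 90, 90, 90)


def single_phase_study(
    n_grains: int,
    target_total_reflections: int,
    q_max: float = 0.5,
    d_star_min: float = 0.05,
    n_u1: int = 10000,
    n_u2: int = 5000,
    sigma: float = 1e-4,
    sim_seed: int = 0,
    index_seed: int = 1,
) -> tuple[SimulationConfig, IndexingConfig]:
    """Single-phase scene with n_grains cubic grains sized so the total
    reflection count matches a target (multiphase-comparison control)."""
    cell = matched_cubic_cell(
        max(1, round(target_total_reflections / n_grains)), d_star_min, q_max
    )
    return _configs(
        (PhaseSpec("control", cell),),
        [n_grains],
        q_max=q_max,
        d_star_min=d_star_min,
        sigma=sigma,
        n_u1=n_u1,
        n_u2=n_u2,
        sim_seed=sim_seed,
        index_seed=index_seed,
    )


def run_study(
    sim: SimulationConfig, idx: IndexingConfig
) -> tuple[GVectorPool, list[IndexedGrain], MeritReport]:
    """Simulate, index and evaluate one study scene."""
    pool = simulate(sim)
    grains = run_indexing(pool, idx)
    volumes = {i: cell_volume(p.cell) for i, p in enumerate(sim.phases)}
    report = figures_of_merit(grains, pool, volumes)
    return pool, grains, report
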