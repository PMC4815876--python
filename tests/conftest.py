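import numpy as np
import pytest

from mgindex.comb_filter import CombParams
from mgindex.lattice_core import UnitCell
from mgindex.synthetic_data import PhaseSpec, SimulationConfig, simulate
from mgindex.studies import CEMENTITE


@pytest.fixture(scope="session")
def cementite_params() -> CombParams:
    """Reference comb parameterization for the single-phase material."""
    return CombParams(epsilon=0.0005, q_max=0.6, dstar_min=0.1)


@pytest.fixture(scope="session")
def single_grain_pool():
    """One noise-free cementite grain with truth labels."""
    cfg = SimulationConfig(
        phases=[PhaseSpec("cementite", CEMENTITE)],
        grains_per_phase=1,
        q_min=0.1,
        q_max=0.6,
        sigma=0.0,
        seed=5,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def cubic10_phase() -> PhaseSpec:
    """Cubic a = 10 Å test phase (reciprocal spacing 0.1 Å⁻¹)."""
    return PhaseSpec("cubic10", UnitCell(10, 10, 10, 90, 90, 90))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
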