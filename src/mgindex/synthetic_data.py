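"""Forward simulator for multiphase polycrystal diffraction pools.

Emulates the reflection-level output of a polycrystal diffraction
simulation: every grain is a randomly oriented copy of its phase's
lattice, contributing all reciprocal-lattice points whose length falls in
the accessible band [q_min, q_max], with isotropic Gaussian position noise
added per Cartesian component.  No detector geometry, rotation range or
intensities are modelled — the indexing algorithm consumes sample-frame
positions only, so the simulator enumerates the full reciprocal shell.

Reflection conditions (systematic absences) default to none, i.e. a
primitive lattice with every integer (h, k, l) present; optional
predicates such as C-centering are available for robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .lattice_core import UnitCell, direct_basis_from_cell, reciprocal_basis
from .pool import GVectorPool

__all__ = [
    "PhaseSpec",
    "SimulationConfig",
    "GVectorPool",
    "random_orientation",
    "grain_reflections",
    "simulate",
    "c_centering",
]


def c_centering(h: int, k: int, l: int) -> bool:  # noqa: E741 - crystallographic l
    """Reflection condition for C-centered lattices: h + k even."""
    return (h + k) % 2 == 0


@dataclass(frozen=True)
class PhaseSpec:
    """A crystalline phase: a name, a unit cell, and an optional reflection
    condition encoding systematic absences (applied to every h ≠ (0,0,0))."""

    name: str
    cell: UnitCell
    reflection_condition: Callable[[int, int, int], bool] | None = None


@dataclass
class SimulationConfig:
    phases: Sequence[PhaseSpec] = ()
    grains_per_phase: Sequence[int] | int = 1
    q_min: float = 0.1
    q_max: float = 0.6
    sigma: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.grains_per_phase, (int, np.integer)):
            self.grains_per_phase = [int(self.grains_per_phase)] * len(self.phases)
        else:
            self.grains_per_phase = [int(x) for x in self.grains_per_phase]
        if len(self.grains_per_phase) != len(self.phases):
            raise ValueError("grains_per_phase length must match phases")
        if any(n < 0 for n in self.grains_per_phase):
            raise ValueError("grain counts must be >= 0")
        if not 0.0 <= self.q_min < self.q_max:
            raise ValueError("require 0 <= q_min < q_max")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Proper rotation drawn uniformly from SO(3) (Haar measure).

    Uses the unit-quaternion construction: a 4-vector of i.i.d. standard
    normals, normalized, is uniform on S³ and maps onto a Haar-uniform
    rotation.
    """
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def grain_reflections(
    phase: PhaseSpec,
    orientation: np.ndarray,
    q_min: float,
    q_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free reflections of one grain.

    Returns (H, G): integer Miller triplets h ≠ (0,0,0) with
    q_min ≤ |h·B_rot| ≤ q_max and the reflection condition satisfied, and
    their g-vectors G = (h·B)·Rᵀ in the sample frame.  Both h and −h appear
    (Friedel mates).
    """
    if not q_min < q_max:
        raise ValueError("require q_min < q_max")
    A = direct_basis_from_cell(phase.cell)
    B = reciprocal_basis(A)
    # |h_i| = |g·a_i| <= q_max |a_i| bounds the integer search box per axis.
    hmax = np.floor(q_max * np.linalg.norm(A, axis=1) + 1e-9).astype(int)
    ranges = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    G0 = H @ B
    q = np.linalg.norm(G0, axis=1)
    keep = (q >= q_min - 1e-12) & (q <= q_max + 1e-12)
    H, G0 = H[keep], G0[keep]
    if phase.reflection_condition is not None:
        cond = np.fromiter(
            (phase.reflection_condition(int(h), int(k), int(l)) for h, k, l in H),
            dtype=bool,
            count=len(H),
        )
        H, G0 = H[cond], G0[cond]
    R = np.asarray(orientation, dtype=float)
    return H, G0 @ R.T


def _bounded_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Gaussian displacement vectors with norm capped at 4σ (outliers redrawn)."""
    if sigma == 0.0 or n == 0:
        return np.zeros((n, 3))
    noise = rng.normal(scale=sigma, size=(n, 3))
    bad = np.flatnonzero(np.linalg.norm(noise, axis=1) > 4.0 * sigma)
    while bad.size:
        noise[bad] = rng.normal(scale=sigma, size=(bad.size, 3))
        bad = bad[np.linalg.norm(noise[bad], axis=1) > 4.0 * sigma]
    return noise


def simulate(config: SimulationConfig) -> GVectorPool:
    """Simulate a multiphase grain ensemble into a labelled g-vector pool.

    Grain orientations are Haar-uniform; per-grain reflections are the full
    reciprocal shell (see :func:`grain_reflections`); i.i.d. Gaussian noise
    of standard deviation ``sigma`` is added to each Cartesian component.
    Grain order and noise are reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gs, hs, grain_ids, phase_ids = [], [], [], []
    serial = 0
    for p_idx, (phase, count) in enumerate(zip(config.phases, config.grains_per_phase)):
        for _ in range(count):
            R = random_orientation(rng)
            H, G = grain_reflections(phase, R, config.q_min, config.q_max)
            G = G + _bounded_noise(rng, len(G), config.sigma)
            gs.append(G)
            hs.append(H)
            grain_ids.append(np.full(len(G), serial))
            phase_ids.append(np.full(len(G), p_idx))
            serial += 1
    if not gs:
        return GVectorPool(
            g=np.zeros((0, 3)),
            grain_id=np.zeros(0, dtype=int),
            phase_id=np.zeros(0, dtype=int),
            hkl=np.zeros((0, 3), dtype=int),
        )
    return GVectorPool(
        g=np.concatenate(gs),
        grain_id=np.concatenate(grain_ids),
        phase_id=np.concatenate(phase_ids),
        hkl=np.concatenate(hs),
    )
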