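"""Unit-cell parameterization and direct/reciprocal lattice basis algebra.

Conventions used throughout the package:

* Crystallographic 1/d units: reciprocal vectors have length 1/d in Å⁻¹,
  with no 2π factor.  A reflection with spacing d sits at |g| = 1/d.
* Bases are stored as 3×3 arrays with the basis vectors as *rows*
  (rows of a direct basis are a, b, c in Å; rows of a reciprocal basis
  are a*, b*, c* in Å⁻¹).  A reciprocal lattice point is g = h·B for an
  integer row triplet h = (h, k, l).
* Direct and reciprocal bases are linked by the inverse-transpose:
  A·Bᵀ = I.
* Cell angles are degrees at the interface, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidCellError",
    "UnitCell",
    "cell_volume",
    "direct_basis_from_cell",
    "reciprocal_basis",
    "cell_from_basis",
]


class InvalidCellError(ValueError):
    """Raised for cell parameters that do not describe a real lattice."""


@dataclass(frozen=True)
class UnitCell:
    """Six-parameter unit cell: lengths in Å, angles in degrees.

    The angle triplet must admit a positive metric determinant, i.e. the
    argument under the square root of the volume formula must be > 0.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name} must be in (0, 180) degrees")
        if self._volume_argument() <= 0.0:
            raise InvalidCellError("cell angles admit no positive volume")

    def _volume_argument(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        return cell_volume(self)

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def cell_volume(cell: UnitCell) -> float:
    """Cell volume in Å³: V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ)."""
    arg = cell._volume_argument()
    if arg <= 0.0:
        raise InvalidCellError("cell angles admit no positive volume")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


def direct_basis_from_cell(cell: UnitCell) -> np.ndarray:
    """Direct basis (rows a, b, c, in Å) in the standard Cartesian setting.

    a lies along x; b is in the x–y plane with positive y component; c
    completes a right-handed set.  |det| equals the cell volume.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    arg = cell._volume_argument()
    if arg <= 0.0:
        raise InvalidCellError("cell angles admit no positive volume")
    return np.array(
        [
            [cell.a, 0.0, 0.0],
            [cell.b * cg, cell.b * sg, 0.0],
            [cell.c * cb, cell.c * (ca - cb * cg) / sg, cell.c * math.sqrt(arg) / sg],
        ]
    )


def _require_nonsingular(basis: np.ndarray) -> np.ndarray:
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (3, 3):
        raise ValueError("basis must be a 3x3 array")
    det = np.linalg.det(basis)
    scale = np.prod(np.linalg.norm(basis, axis=1))
    if scale == 0.0 or abs(det) < 1e-12 * scale:
        raise InvalidCellError("singular basis")
    return basis


def reciprocal_basis(direct: np.ndarray) -> np.ndarray:
    """Reciprocal basis B (rows a*, b*, c*, Å⁻¹) with A·Bᵀ = I (1/d convention)."""
    direct = _require_nonsingular(direct)
    return np.linalg.inv(direct).T


def cell_from_basis(direct: np.ndarray) -> UnitCell:
    """Recover the six cell parameters from a direct basis.

    Orientation independent: any rotation of the basis yields the same cell.
    """
    direct = _require_nonsingular(direct)
    a, b, c = (np.linalg.norm(direct[i]) for i in range(3))

    def angle(u: np.ndarray, v: np.ndarray) -> float:
        cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))

    return UnitCell(
        a=float(a),
        b=float(b),
        c=float(c),
        alpha=angle(direct[1], direct[2]),
        beta=angle(direct[0], direct[2]),
        gamma=angle(direct[0], direct[1]),
    )
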