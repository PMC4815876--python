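"""In-memory container for a pooled set of scattering vectors (g-vectors).

The pool is the central mutable object of the indexing run: reflections
assigned to an indexed grain are deactivated ("peeled") so later searches
only see the remainder.  Optional ground-truth labels (grain id, phase id
and Miller indices) travel with the vectors and drive the evaluation
module; measured data has none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GVectorPool"]


@dataclass
class GVectorPool:
    """N scattering vectors (Å⁻¹, Cartesian sample frame) with an active mask.

    Parameters
    ----------
    g:
        (N, 3) float array of g-vectors.
    active:
        (N,) boolean mask; inactive reflections belong to already-indexed
        grains and are ignored by all searches.
    grain_id, phase_id:
        Optional (N,) integer ground-truth labels.
    hkl:
        Optional (N, 3) integer ground-truth Miller indices.
    """

    g: np.ndarray
    active: np.ndarray = field(default=None)  # type: ignore[assignment]
    grain_id: np.ndarray | None = None
    phase_id: np.ndarray | None = None
    hkl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.atleast_2d(np.asarray(self.g, dtype=float))
        if self.g.size == 0:
            self.g = self.g.reshape(0, 3)
        if self.g.ndim != 2 or self.g.shape[1] != 3:
            raise ValueError("g must be an (N, 3) array")
        n = len(self.g)
        if self.active is None:
            self.active = np.ones(n, dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
            if self.active.shape != (n,):
                raise ValueError("active mask length mismatch")
        for name in ("grain_id", "phase_id"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab, dtype=int)
                if lab.shape != (n,):
                    raise ValueError(f"{name} label length mismatch")
                setattr(self, name, lab)
        if self.hkl is not None:
            self.hkl = np.asarray(self.hkl, dtype=int)
            if self.hkl.shape != (n, 3):
                raise ValueError("hkl label shape mismatch")

    def __len__(self) -> int:
        return len(self.g)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def has_labels(self) -> bool:
        return self.grain_id is not None

    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    def deactivate(self, indices: np.ndarray) -> None:
        self.active[np.asarray(indices, dtype=int)] = False

    def copy(self) -> "GVectorPool":
        return GVectorPool(
            g=self.g.copy(),
            active=self.active.copy(),
            grain_id=None if self.grain_id is None else self.grain_id.copy(),
            phase_id=None if self.phase_id is None else self.phase_id.copy(),
            hkl=None if self.hkl is None else self.hkl.copy(),
        )
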