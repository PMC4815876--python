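"""Ground-truth evaluation of an indexing run: grain matching, the success
criterion and the four figures of merit.

A grain counts as successfully identified when its recovered unit-cell
volume is within 1% of the nominal volume of its phase and strictly more
than 90% of the true grain's reflections were assigned to it.  The four
figures of merit are (1) the fraction of true grains successfully
identified, (2) the mean relative absolute volume deviation over
successes, (3) the mean per-grain fraction of true reflections correctly
assigned (completeness) and (4) the mean per-grain fraction of assigned
reflections belonging to a different true grain (false attribution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pool import GVectorPool
from .refinement_loop import IndexedGrain

__all__ = ["MeritReport", "match_grains", "grain_success", "figures_of_merit"]


@dataclass
class MeritReport:
    """The four figures of merit plus a per-grain breakdown table.

    Rows 3 and 4 are averaged over all indexed grains, counting unmatched
    (spurious) grains with completeness 0 and false fraction 1; the
    matched-only variants are also reported.
    """

    fraction_grains_identified: float
    mean_rel_volume_deviation: float
    mean_fraction_correct_per_grain: float
    mean_fraction_false_per_grain: float
    mean_fraction_correct_matched_only: float
    mean_fraction_false_matched_only: float
    n_true_grains: int
    n_indexed_grains: int
    per_grain: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "fraction_grains_identified": self.fraction_grains_identified,
            "mean_rel_volume_deviation": self.mean_rel_volume_deviation,
            "mean_fraction_correct_per_grain": self.mean_fraction_correct_per_grain,
            "mean_fraction_false_per_grain": self.mean_fraction_false_per_grain,
            "mean_fraction_correct_matched_only": self.mean_fraction_correct_matched_only,
            "mean_fraction_false_matched_only": self.mean_fraction_false_matched_only,
            "n_true_grains": self.n_true_grains,
            "n_indexed_grains": self.n_indexed_grains,
            "per_grain": self.per_grain.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def table(self) -> str:
        lines = [
            f"True grains                          : {self.n_true_grains}",
            f"Indexed grains                       : {self.n_indexed_grains}",
            f"Fraction of grains identified        : {self.fraction_grains_identified:.4f}",
            f"Mean rel. volume deviation (success) : {self.mean_rel_volume_deviation:.3e}",
            f"Mean fraction correct per grain      : {self.mean_fraction_correct_per_grain:.4f}",
            f"Mean fraction false per grain        : {self.mean_fraction_false_per_grain:.3e}",
        ]
        return "\n".join(lines)


def _overlap_table(grains: Sequence[IndexedGrain], pool: GVectorPool):
    """Per indexed grain: the plurality true grain and the shared count."""
    rows = []
    for i, grain in enumerate(grains):
        true_ids = pool.grain_id[grain.refl]
        if len(true_ids) == 0:
            rows.append((i, -1, 0))
            continue
        ids, counts = np.unique(true_ids, return_counts=True)
        j = int(np.argmax(counts))
        rows.append((i, int(ids[j]), int(counts[j])))
    return rows


def match_grains(grains: Sequence[IndexedGrain], pool: GVectorPool) -> dict[int, int]:
    """Map indexed grains (by list position) to true grain ids.

    Each indexed grain points at the true grain contributing the plurality
    of its assigned reflections; when several indexed grains claim the same
    true grain, the largest overlap wins (greedy, descending shared count)
    and the others stay unmatched.
    """
    if not pool.has_labels:
        raise ValueError("pool has no ground-truth labels")
    rows = _overlap_table(grains, pool)
    mapping: dict[int, int] = {}
    claimed: set[int] = set()
    for i, true_id, overlap in sorted(rows, key=lambda r: -r[2]):
        if true_id < 0 or true_id in claimed:
            continue
        mapping[i] = true_id
        claimed.add(true_id)
    return mapping


def grain_success(
    grain: IndexedGrain,
    true_id: int,
    pool: GVectorPool,
    true_volume: float,
) -> bool:
    """Success criterion: |V_found − V_true|/V_true ≤ 0.01 and completeness
    (correct assignments / the true grain's total reflections) > 0.9."""
    n_true_total = int((pool.grain_id == true_id).sum())
    if n_true_total == 0:
        return False
    n_correct = int((pool.grain_id[grain.refl] == true_id).sum())
    vol_ok = abs(grain.volume - true_volume) / true_volume <= 0.01
    return vol_ok and (n_correct / n_true_total) > 0.9


def figures_of_merit(
    grains: Sequence[IndexedGrain],
    pool: GVectorPool,
    true_volumes: Mapping[int, float],
) -> MeritReport:
    """Compute the merit report for an indexing run.

    ``true_volumes`` maps phase id (as recorded in the pool labels) to the
    nominal cell volume of that phase, computed from the simulated cell
    parameters.
    """
    if not pool.has_labels:
        raise ValueError("pool has no ground-truth labels")
    true_ids = np.unique(pool.grain_id)
    if true_ids.size == 0:
        raise ValueError("pool contains no true grains")
    mapping = match_grains(grains, pool)

    records = []
    n_success = 0
    vol_devs = []
    for i, grain in enumerate(grains):
        assigned = grain.matched_count
        true_id = mapping.get(i, -1)
        if true_id >= 0:
            phase = int(pool.phase_id[pool.grain_id == true_id][0])
            v_true = float(true_volumes[phase])
            n_true_total = int((pool.grain_id == true_id).sum())
            n_correct = int((pool.grain_id[grain.refl] == true_id).sum())
            completeness = n_correct / n_true_total
            false_frac = (assigned - n_correct) / assigned if assigned else 0.0
            rel_dev = abs(grain.volume - v_true) / v_true
            success = rel_dev <= 0.01 and completeness > 0.9
            if success:
                n_success += 1
                vol_devs.append(rel_dev)
        else:
            phase, v_true, rel_dev = -1, float("nan"), float("nan")
            completeness, false_frac, success = 0.0, 1.0, False
        records.append(
            {
                "serial": grain.serial,
                "true_grain": true_id,
                "phase": phase,
                "assigned": assigned,
                "completeness": completeness,
                "false_fraction": false_frac,
                "volume": grain.volume,
                "rel_volume_deviation": rel_dev,
                "success": success,
            }
        )
    per_grain = pd.DataFrame.from_records(
        records,
        columns=[
            "serial",
            "true_grain",
            "phase",
            "assigned",
            "completeness",
            "false_fraction",
            "volume",
            "rel_volume_deviation",
            "success",
        ],
    )
    matched = per_grain[per_grain["true_grain"] >= 0]
    return MeritReport(
        fraction_grains_identified=n_success / true_ids.size,
        mean_rel_volume_deviation=float(np.mean(vol_devs)) if vol_devs else 0.0,
        mean_fraction_correct_per_grain=(
            float(per_grain["completeness"].mean()) if len(per_grain) else 0.0
        ),
        mean_fraction_false_per_grain=(
            float(per_grain["false_fraction"].mean()) if len(per_grain) else 0.0
        ),
        mean_fraction_correct_matched_only=(
            float(matched["completeness"].mean()) if len(matched) else 0.0
        ),
        mean_fraction_false_matched_only=(
            float(matched["false_fraction"].mean()) if len(matched) else 0.0
        ),
        n_true_grains=int(true_ids.size),
        n_indexed_grains=len(grains),
        per_grain=per_grain,
    )
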