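"""Seed-orchard selection under an effective-population-size constraint.

The orchard set maximises mean EBV subject to (i) exactly Ne individuals and
(ii) no two selections sharing a parent.  Under single-pair mating the
full-sib families are the connected components of the relatedness graph, so
constraint (ii) is "at most one per family" and the integer program has an
exact combinatorial solution: take each family's best candidate and keep the
top Ne family maxima.  For equally contributing, pairwise-unrelated,
non-inbred selections the status effective number equals the census count,
so Ne is implemented as the set size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionResult", "select_unrelated_topset", "realized_gain"]


@dataclass(frozen=True)
class SelectionResult:
    """Indices of the selected offspring (positions in the candidate arrays)
    plus the mean EBV of the set."""

    selected: np.ndarray
    mean_ebv: float
    target_ne: int

    @property
    def n_selected(self) -> int:
        return self.selected.size


def select_unrelated_topset(
    ebv: np.ndarray,
    family_ids: np.ndarray,
    target_ne: int,
) -> SelectionResult:
    """Exact optimum of mean EBV with <= 1 selection per full-sib family.

    Ties in EBV are broken towards the lowest candidate index, making the
    result deterministic.  Raises if fewer families than ``target_ne`` have
    candidates.
    """
    ebv = np.asarray(ebv, float)
    family_ids = np.asarray(family_ids)
    if ebv.size != family_ids.size:
        raise ValueError("ebv and family_ids must align")
    if target_ne < 1:
        raise ValueError("target_ne must be >= 1")
    families = np.unique(family_ids)
    if target_ne > families.size:
        raise ValueError(
            f"infeasible constraint: target_ne={target_ne} exceeds the "
            f"{families.size} available unrelated families"
        )
    best_idx = np.empty(families.size, dtype=int)
    for k, fam in enumerate(families):
        cand = np.flatnonzero(family_ids == fam)
        # max EBV, ties to the lowest index
        order = cand[np.lexsort((cand, -ebv[cand]))]
        best_idx[k] = order[0]
    order = best_idx[np.lexsort((best_idx, -ebv[best_idx]))]
    chosen = np.sort(order[:target_ne])
    return SelectionResult(chosen, float(ebv[chosen].mean()), target_ne)


def realized_gain(
    selection: SelectionResult | np.ndarray,
    tbv_all: np.ndarray,
    sigma_a: float | None = None,
) -> float:
    """Standardised genetic gain of the selected set.

    Delta G = (mean TBV of selected - mean TBV of all offspring) / sigma_A,
    with sigma_A defaulting to the realized additive SD of the offspring
    population.
    """
    idx = selection.selected if isinstance(selection, SelectionResult) else np.asarray(selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    tbv_all = np.asarray(tbv_all, float)
    if sigma_a is None:
        sigma_a = float(np.std(tbv_all, ddof=1))
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    return float((tbv_all[idx].mean() - tbv_all.mean()) / sigma_a)
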