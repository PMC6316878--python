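"""Gene-dosage consistency gate.

A variant is kept only if the heterozygote outcome lies weakly between the
two homozygote outcomes; a heterozygote with the most extreme outcome of the
three groups is biologically implausible under a dosage model and the
variant is excluded.  Survival is summarized per group by the restricted
mean survival time over [0, 120] months; response by the responder
proportion.  With fewer than three genotype groups the rule is not
evaluable and the variant passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import DFS_HORIZON_MONTHS, SurvivalCurve

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
NOT_EVALUABLE = "not-evaluable"


@dataclass(frozen=True)
class DosageVerdict:
    variant_id: str
    metric_by_group: dict[int, float] = field(default_factory=dict)
    verdict: str = NOT_EVALUABLE

    @property
    def passes(self) -> bool:
        # not-evaluable is treated as pass: the rule only *excludes*
        return self.verdict != INCONSISTENT


def _betweenness(m0: float, m1: float, m2: float) -> str:
    lo, hi = min(m0, m2), max(m0, m2)
    return CONSISTENT if lo <= m1 <= hi else INCONSISTENT


def dosage_check_survival(
    curves: dict[int, SurvivalCurve],
    variant_id: str = "",
    horizon: float = DFS_HORIZON_MONTHS,
) -> DosageVerdict:
    """Betweenness check on per-genotype RMST over [0, horizon].

    ``curves`` maps genotype code (0/1/2) to its Kaplan-Meier curve.
    """
    metrics = {g: c.rmst(horizon) for g, c in curves.items()}
    if not set((0, 1, 2)) <= set(curves):
        return DosageVerdict(variant_id, metrics, NOT_EVALUABLE)
    return DosageVerdict(
        variant_id, metrics, _betweenness(metrics[0], metrics[1], metrics[2])
    )


def dosage_check_response(table: np.ndarray, variant_id: str = "") -> DosageVerdict:
    """Betweenness check on per-genotype responder proportions.

    ``table`` is genotype rows (0/1/2) x (responder, non-responder) counts.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError(f"expected a k x 2 table, got {table.shape}")
    if table.shape[0] != 3:
        return DosageVerdict(variant_id, {}, NOT_EVALUABLE)
    totals = table.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-total genotype row")
    props = table[:, 0] / totals
    metrics = {g: float(props[g]) for g in range(3)}
    return DosageVerdict(variant_id, metrics, _betweenness(*props))
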