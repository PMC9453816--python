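"""Incremental cost-effectiveness comparison and decision rules.

For each strategy against a reference: incremental cost and QALYs, the ICER
when incremental QALYs are positive, dominance flags, and the net monetary
benefit ``NMB = lambda * dQ - dC`` at the willingness-to-pay threshold. The
decision label is "dominant"/"dominated" in the strict quadrants and
otherwise "cost-effective" iff NMB > 0 (equivalent to ICER < lambda whenever
dQ > 0). An efficiency frontier with extended dominance is also computed for
simultaneous multi-strategy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["StrategyOutcome", "Comparison", "CEResult", "compare", "decision",
           "efficiency_frontier"]


@dataclass(frozen=True)
class StrategyOutcome:
    name: str
    cost: float
    qalys: float


@dataclass(frozen=True)
class Comparison:
    """One pairwise incremental comparison against the reference."""

    strategy: str
    reference: str
    delta_cost: float
    delta_qalys: float
    icer: float | None  # defined only when delta_qalys > 0
    dominant: bool      # cheaper and more effective than the reference
    dominated: bool     # dearer and less effective than the reference
    nmb: float

    @property
    def label(self) -> str:
        return decision(self)


def decision(cmp: "Comparison") -> str:
    """Decision label: dominance wins outright, otherwise the NMB sign."""
    if cmp.dominant:
        return "dominant"
    if cmp.dominated:
        return "dominated"
    return "cost-effective" if cmp.nmb > 0 else "not cost-effective"


@dataclass(frozen=True)
class CEResult:
    outcomes: tuple[StrategyOutcome, ...]
    reference: str
    wtp: float
    comparisons: tuple[Comparison, ...]
    frontier: tuple[str, ...]

    def comparison(self, strategy: str) -> Comparison:
        for c in self.comparisons:
            if c.strategy == strategy:
                return c
        raise KeyError(strategy)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        by_name = {c.strategy: c for c in self.comparisons}
        for o in self.outcomes:
            c = by_name.get(o.name)
            rows.append(
                {
                    "strategy": o.name, "cost": o.cost, "qalys": o.qalys,
                    "delta_cost": c.delta_cost if c else None,
                    "delta_qalys": c.delta_qalys if c else None,
                    "icer": c.icer if c else None,
                    "nmb": c.nmb if c else None,
                    "decision": c.label if c else "(reference)",
                    "on_frontier": o.name in self.frontier,
                }
            )
        return pd.DataFrame(rows)


def _pairwise(
    outcome: StrategyOutcome, ref: StrategyOutcome, wtp: float
) -> Comparison:
    d_c = outcome.cost - ref.cost
    d_q = outcome.qalys - ref.qalys
    # a ratio is only meaningful in the trade-off quadrant (more QALYs at
    # extra cost); dominance quadrants carry flags instead of a signed ICER
    icer = d_c / d_q if (d_q > 0 and d_c >= 0) else None
    return Comparison(
        strategy=outcome.name,
        reference=ref.name,
        delta_cost=d_c,
        delta_qalys=d_q,
        icer=icer,
        dominant=d_c < 0 and d_q > 0,
        dominated=d_c > 0 and d_q < 0,
        nmb=wtp * d_q - d_c,
    )


def efficiency_frontier(outcomes: Sequence[StrategyOutcome]) -> tuple[str, ...]:
    """Strategies surviving strict and extended dominance.

    Sorted by cost, a strategy is removed if a cheaper one yields at least
    as many QALYs (strict dominance) or if the ICER sequence along the
    remaining strategies is not increasing (extended dominance).
    """
    ordered = sorted(outcomes, key=lambda o: (o.cost, -o.qalys))
    frontier: list[StrategyOutcome] = []
    for o in ordered:
        if frontier and o.qalys <= frontier[-1].qalys:
            continue
        frontier.append(o)
        while len(frontier) >= 3:
            a, b, c = frontier[-3], frontier[-2], frontier[-1]
            icer_ab = (b.cost - a.cost) / (b.qalys - a.qalys)
            icer_bc = (c.cost - b.cost) / (c.qalys - b.qalys)
            if icer_bc < icer_ab:  # b is extendedly dominated
                frontier.pop(-2)
            else:
                break
    return tuple(o.name for o in frontier)


def compare(
    results: Mapping[str, tuple[float, float]] | Sequence[StrategyOutcome],
    reference: str,
    wtp: float,
) -> CEResult:
    """Pairwise incremental comparison of >= 2 strategies vs a reference.

    ``results`` maps strategy name to (discounted cost, discounted QALYs),
    or is a sequence of :class:`StrategyOutcome`.
    """
    if isinstance(results, Mapping):
        outcomes = tuple(
            StrategyOutcome(name, float(c), float(q))
            for name, (c, q) in results.items()
        )
    else:
        outcomes = tuple(results)
    names = [o.name for o in outcomes]
    if len(outcomes) < 2:
        raise ValueError("need at least 2 strategies to compare")
    if reference not in names:
        raise KeyError(f"reference {reference!r} not among strategies {names}")
    ref = outcomes[names.index(reference)]
    comparisons = tuple(
        _pairwise(o, ref, wtp) for o in outcomes if o.name != reference
    )
    return CEResult(
        outcomes=outcomes,
        reference=reference,
        wtp=wtp,
        comparisons=comparisons,
        frontier=efficiency_frontier(outcomes),
    )
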