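"""End-to-end evaluation helpers: config -> traces -> discounted totals -> CEA."""

from __future__ import annotations

from dataclasses import dataclass

from .cea import CEResult, StrategyOutcome, compare
from .config import ModelConfig
from .engine import CohortTrace, run_cohort
from .valuation import CostBreakdown, EffectBreakdown, accrue_costs, accrue_qalys

__all__ = ["StrategyResult", "evaluate_strategy", "evaluate_all", "base_case"]

DEFAULT_REFERENCE = "docetaxel"


@dataclass(frozen=True)
class StrategyResult:
    """One arm's cohort trace with its discounted cost and QALY breakdowns."""

    name: str
    trace: CohortTrace
    costs: CostBreakdown
    effects: EffectBreakdown

    @property
    def cost(self) -> float:
        return self.costs.total

    @property
    def qalys(self) -> float:
        return self.effects.total

    def outcome(self) -> StrategyOutcome:
        return StrategyOutcome(self.name, self.cost, self.qalys)


def evaluate_strategy(
    config: ModelConfig, name: str, method: str = "auto"
) -> StrategyResult:
    strategy = config.strategy(name)
    trace = run_cohort(config.settings, strategy, config.strategies, method=method)
    return StrategyResult(
        name=name,
        trace=trace,
        costs=accrue_costs(trace, strategy, config.settings),
        effects=accrue_qalys(trace, strategy, config.settings),
    )


def evaluate_all(config: ModelConfig, method: str = "auto") -> dict[str, StrategyResult]:
    return {s.name: evaluate_strategy(config, s.name, method) for s in config.strategies}


def base_case(
    config: ModelConfig,
    reference: str = DEFAULT_REFERENCE,
    wtp: float | None = None,
) -> tuple[CEResult, dict[str, StrategyResult]]:
    """Run every arm and compare against the reference at the WTP threshold."""
    results = evaluate_all(config)
    ce = compare(
        {name: (r.cost, r.qalys) for name, r in results.items()},
        reference=reference,
        wtp=config.settings.wtp_per_qaly if wtp is None else wtp,
    )
    return ce, results
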