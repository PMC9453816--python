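"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the model at each parameter's low and high bound with
everything else at baseline and ranks parameters by the width of the outcome
swing (tornado diagram). PSA draws every non-fixed parameter jointly and
independently from its tagged distribution, re-runs the full model per
iteration, and summarizes the fraction of iterations in which the
intervention is cost-effective or dominant at the willingness-to-pay
threshold, plus a cost-effectiveness acceptability curve over a threshold
grid.

The published inputs give ranges but no standard errors; each range is read
as a 95% interval, ``SE = (high - low) / 3.92``, for all families. Beta and
gamma parameters are moment-matched to (mean, SE). Hazard ratios carry a
"Normal" tag but their printed intervals are multiplicatively symmetric, so
they are sampled log-normally by default (``SE_log = (ln high - ln low) /
3.92``); a raw truncated-normal option is retained for fidelity experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import Comparison, compare
from .config import (
    HazardRatio,
    ModelConfig,
    RangedValue,
    apply_override,
    parameter_space,
)
from .model import evaluate_all

__all__ = [
    "TornadoEntry",
    "PsaResult",
    "dsa_one_way",
    "run_dsa",
    "tornado",
    "sample_distribution",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (("tislelizumab", "docetaxel"), ("tislelizumab", "nivolumab"))


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome at a parameter's low and high bound; width = |high - low|."""

    parameter: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float
    flag_low: str = ""   # dominance flag when the ICER is undefined
    flag_high: str = ""

    @property
    def width(self) -> float:
        if np.isnan(self.outcome_low) or np.isnan(self.outcome_high):
            return float("inf")
        return abs(self.outcome_high - self.outcome_low)


def _outcome(
    config: ModelConfig, intervention: str, reference: str, metric: str
) -> tuple[float, str]:
    results = evaluate_all(config)
    ce = compare(
        {n: (r.cost, r.qalys) for n, r in results.items()},
        reference=reference,
        wtp=config.settings.wtp_per_qaly,
    )
    cmp = ce.comparison(intervention)
    if metric == "nmb":
        return cmp.nmb, ""
    if metric == "icer":
        if cmp.icer is None:
            # negative incremental QALYs: report the dominance flag, not a
            # signed ratio
            return float("nan"), ("dominant" if cmp.dominant else "dominated")
        return cmp.icer, ""
    raise ValueError(f"unknown outcome metric {metric!r}")


def dsa_one_way(
    config: ModelConfig,
    parameter: str,
    intervention: str = "tislelizumab",
    reference: str = "docetaxel",
    outcome: str = "icer",
) -> TornadoEntry:
    """Re-run the model at one parameter's low and high bound."""
    space = parameter_space(config)
    if parameter not in space:
        raise KeyError(
            f"unknown parameter {parameter!r}; valid names: {sorted(space)}"
        )
    value = space[parameter].get(config)
    if isinstance(value, HazardRatio):
        low, high = value.ci_low, value.ci_high
    else:
        low, high = value.low, value.high
    out_low, flag_low = _outcome(
        apply_override(config, parameter, low), intervention, reference, outcome
    )
    out_high, flag_high = _outcome(
        apply_override(config, parameter, high), intervention, reference, outcome
    )
    return TornadoEntry(
        parameter=parameter, low_value=low, high_value=high,
        outcome_low=out_low, outcome_high=out_high,
        flag_low=flag_low, flag_high=flag_high,
    )


def run_dsa(
    config: ModelConfig,
    intervention: str = "tislelizumab",
    reference: str = "docetaxel",
    outcome: str = "icer",
    parameters: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """One-way DSA over every swept parameter (those with low < high)."""
    space = parameter_space(config)
    names = list(parameters) if parameters is not None else [
        name
        for name, ref in space.items()
        if _bounds_differ(ref.get(config))
    ]
    return [
        dsa_one_way(config, name, intervention, reference, outcome)
        for name in names
    ]


def _bounds_differ(value: RangedValue | HazardRatio) -> bool:
    if isinstance(value, HazardRatio):
        return value.ci_low < value.ci_high
    return value.low < value.high


def tornado(entries: Sequence[TornadoEntry], k: int = 10) -> list[TornadoEntry]:
    """Top-k entries by descending swing width; ties broken by name."""
    if not entries:
        raise ValueError("need at least one DSA entry")
    ranked = sorted(entries, key=lambda e: (-e.width, e.parameter))
    return ranked[:k]


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter, "low_value": e.low_value,
                "high_value": e.high_value, "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high, "width": e.width,
                "flag_low": e.flag_low, "flag_high": e.flag_high,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity


def sample_distribution(
    value: RangedValue | HazardRatio,
    rng: np.random.Generator,
    hr_sampling: str = "log_normal",
) -> float:
    """Draw one value from a parameter's tagged distribution.

    beta/gamma: moment-matched to (mean, SE) with SE = (high - low)/3.92;
    normal: truncated at 0 by resampling; fixed: the baseline. Hazard ratios
    are drawn log-normally by default, or raw-normal truncated at 0.
    """
    if isinstance(value, HazardRatio):
        if hr_sampling == "log_normal":
            se_log = (np.log(value.ci_high) - np.log(value.ci_low)) / 3.92
            return float(np.exp(rng.normal(np.log(value.mean), se_log)))
        if hr_sampling == "normal":
            se = (value.ci_high - value.ci_low) / 3.92
            draw = rng.normal(value.mean, se)
            while draw <= 0:
                draw = rng.normal(value.mean, se)
            return float(draw)
        raise ValueError(f"unknown hr_sampling {hr_sampling!r}")

    m = value.mean
    se = (value.high - value.low) / 3.92
    if value.distribution == "fixed" or se == 0.0:
        return m
    if value.distribution == "beta":
        if m * (1.0 - m) <= se**2 or not (0.0 < m < 1.0):
            logger.warning(
                "beta moments infeasible for mean=%s se=%s; falling back to "
                "uniform(low, high)", m, se,
            )
            return float(rng.uniform(value.low, value.high))
        nu = m * (1.0 - m) / se**2 - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if value.distribution == "gamma":
        return float(rng.gamma((m / se) ** 2, se**2 / m))
    if value.distribution == "normal":
        draw = rng.normal(m, se)
        while draw <= 0:
            draw = rng.normal(m, se)
        return float(draw)
    raise ValueError(f"unknown distribution {value.distribution!r}")


def _classify(cmp: Comparison) -> tuple[bool, bool]:
    """(cost_effective, dominant) at the comparison's threshold."""
    dominant = cmp.dominant
    cost_effective = dominant or (not cmp.dominated and cmp.nmb > 0)
    return cost_effective, dominant


@dataclass(frozen=True)
class PsaResult:
    """Joint parameter draws with per-iteration outcomes and summaries.

    ``samples`` has one row per iteration: the drawn parameter values, each
    strategy's (cost, qalys), and per-comparison incremental columns with
    cost-effective/dominant flags at the run's threshold.
    """

    samples: pd.DataFrame
    summary: dict[str, dict[str, float]]
    wtp: float
    seed: int | None
    n_skipped: int = 0

    def fraction(self, intervention: str, reference: str, what: str = "cost_effective") -> float:
        return self.summary[f"{intervention}_vs_{reference}"][what]


def run_psa(
    config: ModelConfig,
    n_iter: int = 1000,
    wtp: float | None = None,
    seed: int | None = None,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    hr_sampling: str = "log_normal",
) -> PsaResult:
    """Monte-Carlo PSA: joint independent draws, full model re-run each time.

    Iterations whose model run fails validity checks are skipped and logged;
    more than 1% skipped aborts the run. Bit-reproducible under a fixed seed.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    wtp = config.settings.wtp_per_qaly if wtp is None else float(wtp)
    rng = np.random.default_rng(seed)
    space = parameter_space(config)
    sampled = {
        name: ref
        for name, ref in space.items()
        if _is_sampled(ref.get(config))
    }
    rows: list[dict[str, float | bool]] = []
    n_skipped = 0
    for it in range(n_iter):
        draws = {
            name: sample_distribution(ref.get(config), rng, hr_sampling)
            for name, ref in sampled.items()
        }
        cfg = config
        for name, drawn in draws.items():
            cfg = apply_override(cfg, name, drawn)
        try:
            results = evaluate_all(cfg)
        except Exception as exc:  # invalid iteration: skip and log
            n_skipped += 1
            logger.warning("PSA iteration %d skipped: %s", it, exc)
            if n_skipped > max(1, 0.01 * n_iter):
                raise RuntimeError(
                    f"more than 1% of PSA iterations failed ({n_skipped}/{it + 1})"
                ) from exc
            continue
        row: dict[str, float | bool] = {"iteration": it, **draws}
        for name, res in results.items():
            row[f"cost_{name}"] = res.cost
            row[f"qalys_{name}"] = res.qalys
        for intervention, reference in comparisons:
            ce = compare(
                {n: (results[n].cost, results[n].qalys) for n in (intervention, reference)},
                reference=reference,
                wtp=wtp,
            )
            cmp = ce.comparison(intervention)
            eff, dom = _classify(cmp)
            key = f"{intervention}_vs_{reference}"
            row[f"delta_cost_{key}"] = cmp.delta_cost
            row[f"delta_qalys_{key}"] = cmp.delta_qalys
            row[f"cost_effective_{key}"] = eff
            row[f"dominant_{key}"] = dom
        rows.append(row)
    samples = pd.DataFrame(rows)
    summary = {}
    for intervention, reference in comparisons:
        key = f"{intervention}_vs_{reference}"
        summary[key] = {
            "cost_effective": float(samples[f"cost_effective_{key}"].mean()),
            "dominant": float(samples[f"dominant_{key}"].mean()),
        }
    return PsaResult(
        samples=samples, summary=summary, wtp=wtp, seed=seed, n_skipped=n_skipped
    )


def _is_sampled(value: RangedValue | HazardRatio) -> bool:
    if isinstance(value, HazardRatio):
        return True  # the printed HRs carry a Normal tag
    return value.distribution != "fixed"


def ceac(
    psa: PsaResult,
    wtp_grid: Sequence[float],
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: pointwise fraction with
    positive net monetary benefit (or dominance) at each threshold."""
    if len(psa.samples) == 0:
        raise ValueError("PSA produced no samples")
    out = {"wtp": np.asarray(wtp_grid, dtype=float)}
    for intervention, reference in comparisons:
        key = f"{intervention}_vs_{reference}"
        d_c = psa.samples[f"delta_cost_{key}"].to_numpy()
        d_q = psa.samples[f"delta_qalys_{key}"].to_numpy()
        fracs = [
            float(np.mean((lam * d_q - d_c > 0) | ((d_c < 0) & (d_q > 0))))
            for lam in out["wtp"]
        ]
        out[key] = np.asarray(fracs)
    return pd.DataFrame(out)
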