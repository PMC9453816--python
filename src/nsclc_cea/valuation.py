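"""Discounted cost and QALY accrual over a cohort trace.

Per cycle, PFS-on-therapy accrues drug acquisition (with vial-wastage
rounding) plus routine follow-up and best supportive care; PFS-off-therapy
drops the drug; PD accrues follow-up, BSC and the subsequent-therapy
(anlotinib) cost weighted by the arm's uptake proportion; end-stage disease
accrues palliative care (one-time package at entry by default, per-cycle or
one-time-at-death as configured). The frequency-weighted adverse-event cost
and disutility aggregates are per-patient-course quantities charged once at
model entry. Rewards follow start-of-cycle state membership and are
discounted at ``(1+r)**(-years elapsed)``; an optional half-cycle correction
averages adjacent occupancies instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DosingRule, ModelSettings, StrategySpec, ValidationError
from .engine import CohortTrace, life_years

__all__ = [
    "CostBreakdown",
    "EffectBreakdown",
    "cycle_drug_cost",
    "discount_factor",
    "accrue_costs",
    "accrue_qalys",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted cost components (2021 USD); ``total`` is their exact sum."""

    drug: float
    followup: float
    bsc: float
    palliative: float
    ae: float
    subsequent_therapy: float

    @property
    def total(self) -> float:
        return (
            self.drug + self.followup + self.bsc + self.palliative
            + self.ae + self.subsequent_therapy
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "drug": self.drug, "followup": self.followup, "bsc": self.bsc,
            "palliative": self.palliative, "ae": self.ae,
            "subsequent_therapy": self.subsequent_therapy, "total": self.total,
        }


@dataclass(frozen=True)
class EffectBreakdown:
    """Discounted QALY components; AE disutility is a one-time decrement."""

    pfs: float
    pd: float
    end_stage: float
    ae_disutility: float
    life_years: float

    @property
    def total(self) -> float:
        return self.pfs + self.pd + self.end_stage - self.ae_disutility

    def as_dict(self) -> dict[str, float]:
        return {
            "pfs": self.pfs, "pd": self.pd, "end_stage": self.end_stage,
            "ae_disutility": self.ae_disutility, "life_years": self.life_years,
            "total": self.total,
        }


def cycle_drug_cost(
    dosing: DosingRule, weight_kg: float, bsa_m2: float
) -> float:
    """Acquisition cost of one model cycle of a drug.

    The per-administration dose in mg is resolved from the dosing kind, then
    rounded up to whole pricing units of ``unit_size`` mg (vial wastage); a
    ``per_cycle_pack`` is billed as exactly one unit, no rounding.
    """
    if weight_kg <= 0 or bsa_m2 <= 0:
        raise ValidationError("weight and body surface area must be > 0")
    kind = dosing.dose_kind
    if kind == "flat":
        dose_mg = dosing.dose_value
    elif kind == "per_kg":
        dose_mg = dosing.dose_value * weight_kg
    elif kind == "per_m2":
        dose_mg = dosing.dose_value * bsa_m2
    elif kind == "per_cycle_pack":
        dose_mg = dosing.dose_value
    else:  # pragma: no cover - rejected at parse time
        raise ValidationError(f"unknown dose_kind {kind!r}")
    if dose_mg <= 0:
        raise ValidationError(f"resolved dose must be > 0, got {dose_mg}")
    if kind == "per_cycle_pack":
        units = 1
    else:
        units = math.ceil(dose_mg / dosing.unit_size - 1e-9)
    return units * dosing.unit_price.mean * dosing.administrations_per_cycle


def discount_factor(settings: ModelSettings, t: np.ndarray | float) -> np.ndarray:
    """``(1 + r)**(-t * cycle_length / 365.25)`` for cycle index t >= 0."""
    r = settings.discount_rate_annual.mean
    years = np.asarray(t, dtype=float) * settings.cycle_length_days / 365.25
    return (1.0 + r) ** (-years)


def _residence(trace: CohortTrace, occ: np.ndarray, settings: ModelSettings) -> np.ndarray:
    """Per-cycle residence weights (cycles 0..T-1) for one state's occupancy."""
    if settings.half_cycle_correction:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def accrue_costs(
    trace: CohortTrace, strategy: StrategySpec, settings: ModelSettings
) -> CostBreakdown:
    T = trace.n_cycles
    df = discount_factor(settings, np.arange(T + 1))
    w = df[:T]
    weight = settings.body_weight_kg.mean
    bsa = settings.body_surface_m2.mean
    c_fu = settings.care_costs["followup"].mean
    c_bsc = settings.care_costs["bsc"].mean
    c_pall = settings.care_costs["palliative"].mean

    on = _residence(trace, trace.pfs_on, settings)
    off = _residence(trace, trace.pfs_off, settings)
    pd_occ = _residence(trace, trace.pd, settings)
    end_occ = _residence(trace, trace.end_stage, settings)

    drug = float(np.sum(w * on) * cycle_drug_cost(strategy.dosing, weight, bsa))
    followup = float(np.sum(w * (on + off + pd_occ)) * c_fu)
    bsc = float(np.sum(w * (on + off + pd_occ)) * c_bsc)
    anl_cycle = cycle_drug_cost(settings.anlotinib.dosing, weight, bsa)
    subsequent = float(
        np.sum(w * pd_occ)
        * strategy.subsequent_therapy_proportion.mean
        * anl_cycle
    )
    mode = settings.palliative_cost_mode
    if mode == "per_cycle":
        palliative = float(np.sum(w * end_occ) * c_pall)
    elif mode == "one_time":
        palliative = float(np.sum(df * trace.end_entries) * c_pall)
    else:  # one_time_at_death
        palliative = float(np.sum(df * trace.end_deaths) * c_pall)
    ae = strategy.ae_cost.mean
    return CostBreakdown(
        drug=drug, followup=followup, bsc=bsc, palliative=palliative,
        ae=ae, subsequent_therapy=subsequent,
    )


def accrue_qalys(
    trace: CohortTrace, strategy: StrategySpec, settings: ModelSettings
) -> EffectBreakdown:
    T = trace.n_cycles
    cycle_years = settings.cycle_length_days / 365.25
    w = discount_factor(settings, np.arange(T + 1))[:T] * cycle_years
    u = settings.utilities
    pfs_occ = _residence(trace, trace.pfs_on + trace.pfs_off, settings)
    pd_occ = _residence(trace, trace.pd, settings)
    end_occ = _residence(trace, trace.end_stage, settings)
    return EffectBreakdown(
        pfs=float(np.sum(w * pfs_occ) * u["pfs"].mean),
        pd=float(np.sum(w * pd_occ) * u["pd"].mean),
        end_stage=float(np.sum(w * end_occ) * u["end_stage"].mean),
        ae_disutility=strategy.ae_disutility.mean,
        life_years=life_years(trace, settings),
    )
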