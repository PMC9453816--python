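"""Markov cohort engine.

Health-state topology (one treatment arm)::

    PFS_ON ──discontinuation──> PFS_OFF
      │  \\                        │  \\
      │   progression             │   progression
      │        v                  │        v
      │        PD ──progression on 3rd line──> END_STAGE
      │        │                                  │
      └────────┴───────────── death ──────────────┘

All patients start in PFS on therapy. Deaths in the PFS sub-states follow
the arm's overall-survival curve; progressions are the remainder of the
PFS-curve exit after removing deaths (competing-risk split, clipped at
zero). Post-progression transitions follow the third-line (anlotinib)
curves on a tunnel clock counted from PD entry (``pd_clock_mode =
"state_entry"``, the default) or on model time; end-stage mortality either
continues the same clock on the anlotinib OS curve or is a fixed per-cycle
probability.

Because post-progression hazards depend only on time-since-entry under the
default clock, every PD-entry cohort evolves identically and the trace is
the convolution of the PFS progression outflow with a single unit-cohort
response — run_cohort uses that O(T log T) path when valid and an explicit
tunnel-state iteration otherwise; both produce identical traces and are
cross-checked in the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    HrDerivedEndpoint,
    LogLogisticParams,
    ModelSettings,
    StrategySpec,
    ValidationError,
    n_cycles,
)
from .survival import SurvivalCurve, apply_hazard_ratio

__all__ = [
    "HealthState",
    "CohortTrace",
    "resolve_curves",
    "pfs_exit_probs",
    "discontinuation_prob",
    "pd_exit_probs",
    "end_stage_death_prob",
    "run_cohort",
    "life_years",
]


class HealthState(enum.Enum):
    PFS_ON = "pfs_on"
    PFS_OFF = "pfs_off"
    PD = "pd"
    END_STAGE = "end_stage"
    DEATH = "death"


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort occupancy (fractions) plus the flows valuation needs.

    Arrays are indexed by cycle 0..T; tunnel occupancy is aggregated (PD and
    END_STAGE sum over time-since-entry). ``pd_entries[t]`` is the mass
    arriving in PD at cycle t, ``end_entries``/``end_deaths`` likewise for
    end-stage arrival and death out of end-stage.
    """

    pfs_on: np.ndarray
    pfs_off: np.ndarray
    pd: np.ndarray
    end_stage: np.ndarray
    death: np.ndarray
    pd_entries: np.ndarray
    end_entries: np.ndarray
    end_deaths: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.pfs_on.size - 1

    @property
    def alive(self) -> np.ndarray:
        return self.pfs_on + self.pfs_off + self.pd + self.end_stage

    def occupancy(self, state: HealthState) -> np.ndarray:
        return getattr(self, state.value)

    def row_sums(self) -> np.ndarray:
        return self.alive + self.death

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles + 1),
                "pfs_on": self.pfs_on,
                "pfs_off": self.pfs_off,
                "pd": self.pd,
                "end_stage": self.end_stage,
                "death": self.death,
                "pd_entries": self.pd_entries,
                "end_entries": self.end_entries,
                "end_deaths": self.end_deaths,
            }
        )


def resolve_curves(
    strategy: StrategySpec, strategies: tuple[StrategySpec, ...] | None = None
) -> tuple[SurvivalCurve, SurvivalCurve]:
    """OS and PFS curves of an arm, resolving HR-derived endpoints."""
    curves = []
    for ep_name in ("os", "pfs"):
        ep = getattr(strategy, ep_name)
        if isinstance(ep, LogLogisticParams):
            curves.append(SurvivalCurve.loglogistic(ep))
            continue
        assert isinstance(ep, HrDerivedEndpoint)
        if strategies is None:
            raise ValidationError(
                f"{strategy.name}.{ep_name} is HR-derived; the full strategy "
                "list is needed to resolve its reference"
            )
        ref = next((s for s in strategies if s.name == ep.reference), None)
        if ref is None:
            raise ValidationError(
                f"{strategy.name}.{ep_name} references unknown strategy "
                f"{ep.reference!r}"
            )
        base = getattr(ref, ep.endpoint)
        if not isinstance(base, LogLogisticParams):
            raise ValidationError(
                f"reference endpoint {ep.reference}.{ep.endpoint} must be a "
                "fitted curve, not itself HR-derived"
            )
        curves.append(
            apply_hazard_ratio(SurvivalCurve.loglogistic(base), ep.hr.mean)
        )
    return curves[0], curves[1]


def pfs_exit_probs(
    os_curve: SurvivalCurve, pfs_curve: SurvivalCurve, t: int
) -> tuple[float, float]:
    """(p_death, p_progress) out of the PFS sub-states during cycle t >= 1.

    Death is taken from the OS curve; progression is the PFS-exit remainder,
    clipped at zero when the OS hazard transiently exceeds the PFS hazard.
    """
    p_death = float(os_curve.transition_prob(t))
    p_leave = float(pfs_curve.transition_prob(t))
    return p_death, max(0.0, p_leave - p_death)


def discontinuation_prob(strategy: StrategySpec, t: int = 1) -> float:
    """Constant per-cycle probability of AE-driven PFS_ON -> PFS_OFF."""
    if t < 1:
        raise ValidationError("cycle index must be >= 1")
    return strategy.discontinuation_prob_per_cycle.mean


def pd_exit_probs(settings: ModelSettings, tau: int) -> tuple[float, float]:
    """(p_death, p_to_end_stage) out of PD at tunnel time tau >= 1.

    Both exits follow the third-line (anlotinib) trial curves: death from
    its OS, progression-to-end-stage as the PFS-exit remainder.
    """
    os_c = SurvivalCurve.loglogistic(settings.anlotinib.os)
    pfs_c = SurvivalCurve.loglogistic(settings.anlotinib.pfs)
    return pfs_exit_probs(os_c, pfs_c, tau)


def end_stage_death_prob(settings: ModelSettings, tau: int) -> float:
    """Per-cycle death probability in END_STAGE at tunnel time tau >= 1.

    Default mode continues the anlotinib OS clock from PD entry (the tunnel
    index keeps counting); the alternative is a fixed per-cycle probability.
    """
    if settings.end_stage_mortality_mode == "fixed":
        return float(settings.end_stage_fixed_prob)  # validated in (0, 1]
    if settings.end_stage_mortality_mode == "anlotinib_os":
        return float(
            SurvivalCurve.loglogistic(settings.anlotinib.os).transition_prob(tau)
        )
    raise ValidationError(
        f"unknown end_stage_mortality_mode {settings.end_stage_mortality_mode!r}"
    )


def _transition_arrays(
    settings: ModelSettings, os_curve: SurvivalCurve, pfs_curve: SurvivalCurve, T: int
):
    """Vectorized per-cycle transition probabilities for cycles/tunnels 1..T."""
    grid = np.arange(T + 1, dtype=float)
    s_os = os_curve.survival(grid)
    s_pfs = pfs_curve.survival(grid)
    p_death = 1.0 - s_os[1:] / s_os[:-1]
    p_prog = np.maximum(0.0, (1.0 - s_pfs[1:] / s_pfs[:-1]) - p_death)

    s_aos = SurvivalCurve.loglogistic(settings.anlotinib.os).survival(grid)
    s_apfs = SurvivalCurve.loglogistic(settings.anlotinib.pfs).survival(grid)
    pd_death = 1.0 - s_aos[1:] / s_aos[:-1]
    pd_to_end = np.maximum(0.0, (1.0 - s_apfs[1:] / s_apfs[:-1]) - pd_death)
    if settings.end_stage_mortality_mode == "fixed":
        end_death = np.full(T, float(settings.end_stage_fixed_prob))
    else:
        end_death = pd_death.copy()
    for name, arr in (
        ("p_death", p_death), ("p_prog", p_prog), ("pd_death", pd_death),
        ("pd_to_end", pd_to_end), ("end_death", end_death),
    ):
        bad = np.flatnonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))
        if bad.size:
            raise ValidationError(
                f"transition probability {name} outside [0,1] at cycle {bad[0] + 1}"
            )
    return p_death, p_prog, pd_death, pd_to_end, end_death


def _run_convolution(settings, strategy, p_death, p_prog, pd_death, pd_to_end,
                     end_death, T: int) -> CohortTrace:
    disc = strategy.discontinuation_prob_per_cycle.mean
    grid = np.arange(T + 1, dtype=float)

    pexit = p_death + p_prog
    pfs_total = np.concatenate([[1.0], np.cumprod(1.0 - pexit)])
    pfs_on = pfs_total * (1.0 - disc) ** grid
    pfs_off = pfs_total - pfs_on

    pd_entries = np.zeros(T + 1)
    pd_entries[1:] = pfs_total[:-1] * p_prog

    # unit PD-entry cohort response over time-since-entry j (tunnel j + 1)
    u_pd = np.concatenate([[1.0], np.cumprod(1.0 - pd_death - pd_to_end)])
    u_end_in = np.zeros(T + 1)
    u_end_in[1:] = u_pd[:-1] * pd_to_end
    u_end = np.zeros(T + 1)
    u_end_death = np.zeros(T + 1)
    keep_end = 1.0 - end_death
    for j in range(1, T + 1):
        u_end_death[j] = u_end[j - 1] * end_death[j - 1]
        u_end[j] = u_end[j - 1] * keep_end[j - 1] + u_end_in[j]

    pd_occ = np.convolve(pd_entries, u_pd)[: T + 1]
    end_occ = np.convolve(pd_entries, u_end)[: T + 1]
    end_entries = np.convolve(pd_entries, u_end_in)[: T + 1]
    end_deaths = np.convolve(pd_entries, u_end_death)[: T + 1]

    death = 1.0 - (pfs_on + pfs_off + pd_occ + end_occ)
    return CohortTrace(
        pfs_on=pfs_on, pfs_off=pfs_off, pd=np.maximum(pd_occ, 0.0),
        end_stage=np.maximum(end_occ, 0.0), death=np.maximum(death, 0.0),
        pd_entries=pd_entries, end_entries=end_entries, end_deaths=end_deaths,
    )


def _run_iterative(settings, strategy, p_death, p_prog, pd_death, pd_to_end,
                   end_death, T: int) -> CohortTrace:
    disc = strategy.discontinuation_prob_per_cycle.mean
    model_clock = settings.pd_clock_mode == "model_time"

    pfs_on = np.zeros(T + 1); pfs_off = np.zeros(T + 1)
    pd_occ = np.zeros(T + 1); end_occ = np.zeros(T + 1); death = np.zeros(T + 1)
    pd_entries = np.zeros(T + 1); end_entries = np.zeros(T + 1)
    end_deaths = np.zeros(T + 1)
    pfs_on[0] = 1.0
    pd_tun = np.zeros(T + 2)   # occupancy by tunnel index (1-based)
    end_tun = np.zeros(T + 2)

    for t in range(T):
        i = t  # transition into cycle t+1 uses probabilities indexed t (cycle t+1)
        # order within the cycle: death, then progression, then discontinuation
        new_pd_mass = 0.0
        dying = (pfs_on[t] + pfs_off[t]) * p_death[i]
        new_pd_mass = (pfs_on[t] + pfs_off[t]) * p_prog[i]
        rem_on = pfs_on[t] * (1.0 - p_death[i] - p_prog[i])
        rem_off = pfs_off[t] * (1.0 - p_death[i] - p_prog[i])
        moved = rem_on * disc
        pfs_on[t + 1] = rem_on - moved
        pfs_off[t + 1] = rem_off + moved

        taus = np.arange(1, t + 2)
        idx = np.full(taus.shape, i) if model_clock else taus - 1
        pd_m = pd_tun[taus]
        pd_d = pd_m * pd_death[idx]
        pd_e = pd_m * pd_to_end[idx]
        end_m = end_tun[taus]
        end_d = end_m * end_death[idx]

        new_pd = np.zeros(T + 2); new_end = np.zeros(T + 2)
        new_pd[taus + 1] = pd_m - pd_d - pd_e
        new_end[taus + 1] = end_m - end_d + pd_e
        new_pd[1] = new_pd_mass
        dying += pd_d.sum() + end_d.sum()

        pd_tun, end_tun = new_pd, new_end
        pd_occ[t + 1] = pd_tun.sum()
        end_occ[t + 1] = end_tun.sum()
        death[t + 1] = death[t] + dying
        pd_entries[t + 1] = new_pd_mass
        end_entries[t + 1] = pd_e.sum()
        end_deaths[t + 1] = end_d.sum()

        total = pfs_on[t + 1] + pfs_off[t + 1] + pd_occ[t + 1] + end_occ[t + 1] + death[t + 1]
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"cohort mass not conserved at cycle {t + 1}: row sum {total!r}"
            )
    return CohortTrace(
        pfs_on=pfs_on, pfs_off=pfs_off, pd=pd_occ, end_stage=end_occ,
        death=death, pd_entries=pd_entries, end_entries=end_entries,
        end_deaths=end_deaths,
    )


def run_cohort(
    settings: ModelSettings,
    strategy: StrategySpec,
    strategies: tuple[StrategySpec, ...] | None = None,
    method: str = "auto",
) -> CohortTrace:
    """Propagate a unit cohort from 100% PFS_ON over the model horizon.

    ``method`` selects the implementation: "convolution" (fast path, valid
    for the state-entry tunnel clock), "iterative" (explicit tunnel states,
    any clock mode) or "auto" (convolution when valid).
    """
    T = n_cycles(settings)
    os_curve, pfs_curve = resolve_curves(strategy, strategies)
    probs = _transition_arrays(settings, os_curve, pfs_curve, T)
    if method == "auto":
        method = (
            "convolution" if settings.pd_clock_mode == "state_entry" else "iterative"
        )
    if method == "convolution":
        if settings.pd_clock_mode != "state_entry":
            raise ValidationError(
                "convolution path requires pd_clock_mode='state_entry'"
            )
        return _run_convolution(settings, strategy, *probs, T)
    if method == "iterative":
        return _run_iterative(settings, strategy, *probs, T)
    raise ValueError(f"unknown method {method!r}")


def life_years(trace: CohortTrace, settings: ModelSettings) -> float:
    """Undiscounted life-years: alive-fraction time at the cycle length."""
    cycle_years = settings.cycle_length_days / 365.25
    alive = trace.alive
    if settings.half_cycle_correction:
        weights = 0.5 * (alive[:-1] + alive[1:])
    else:
        weights = alive[:-1]
    return float(weights.sum() * cycle_years)
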