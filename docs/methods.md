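# Methods

## Model structure and assumptions

The model is a Markov cohort simulation over five health states: PFS on
therapy, PFS with therapy discontinued, progressive disease (PD), end-stage
disease, and death. A unit cohort starts in PFS on therapy and is propagated
for `floor(30 × 365.25 / 21) = 521` three-week cycles. The topology is
PFS → {PD, death}, PD → {end-stage, death}, end-stage → death; there is no
direct PFS → end-stage arrow and death is absorbing.

**Survival extrapolation.** All endpoints use the decision-model
log-logistic parameterization `S(t) = 1/(1 + θ·t^κ)` with `t` in cycles.
This convention is pinned by the published parameter values themselves: the
tislelizumab OS pair (θ = 0.00927, κ = 1.4607) gives a median of 24.6 cycles
≈ 17.0 months and the docetaxel pair 16.3 cycles ≈ 11.3 months, matching the
source trials' medians only under this form. Per-cycle transition
probabilities are `p(t) = 1 − S(t)/S(t−1)`, which telescopes so that
cumulative risk over T cycles equals `1 − S(T)` exactly.

**Competing-risk split in PFS.** Only marginal OS and PFS curves exist, so
deaths out of the PFS states are taken from the OS curve and progressions
are the remainder of the PFS exit, clipped at zero
(`p_prog = max(0, p_PFS − p_OS)`). Within a cycle the event order is death →
progression → discontinuation; because per-cycle probabilities are small
(≤ ~0.1), order effects are O(p²) and below reporting precision.

**Hazard-ratio–derived arm.** The nivolumab curves are
`S_niv = S_tis^HR` (proportional hazards on the cumulative hazard,
HR_OS = 1.170, HR_PFS = 1.235) — the meta-analytic meaning of an HR. An
accelerated-failure-time alternative (θ scaled by HR) is available in
`apply_hazard_ratio(..., mode="aft")` for sensitivity exploration. The HR
application satisfies identity (HR = 1 leaves the curve unchanged) and
composition (`HR=a` then `HR=b` equals `HR=a·b`), both enforced by tests.

**Post-progression clock.** PD and end-stage transitions follow the
anlotinib (third-line) OS/PFS curves. Those are trial curves clocked from
anlotinib start, so the default keys them to time since PD entry
(`pd_clock_mode: state_entry`), implemented as tunnel states; a
`model_time` mode (clock = model cycle) is provided because the original
TreeAge implementation may have used it. Under the default clock every
PD-entry cohort evolves identically, so the engine computes one unit-cohort
response and convolves it with the PFS progression outflow; an explicit
tunnel-state iteration covers the general case and the two paths agree to
1e-12, which the suite checks.

**End-stage mortality.** No survival law is published for end-stage
disease. The default continues the anlotinib OS clock from PD entry
(smooth, conservative); a fixed per-cycle probability mode is exposed
(`end_stage_mortality_mode: fixed`), with p = 1 making end-stage a single
terminal cycle.

## Valuation

Rewards follow start-of-cycle state membership, discounted at
`(1+r)^(−t·21/365.25)` with r = 5%/year (swept 0–8% in DSA, fixed in PSA).
Half-cycle correction (averaging adjacent occupancies) is off by default,
matching common cohort-software defaults, and exposed as a flag.

- **Drug acquisition.** Per administration, the dose (200 mg flat
  tislelizumab; 75 mg/m² × 1.72 m² docetaxel; 3 mg/kg × 65 kg nivolumab) is
  rounded **up** to whole pricing units (vial wastage). Nivolumab's 2-week
  schedule gives 1.5 administrations per 3-week cycle by default (1.0 is a
  config alternative; this is the largest single lever on the nivolumab
  arm's cost). Anlotinib is one 168 mg pack per cycle, no wastage.
- **Care costs per cycle.** Follow-up ($55.60) and BSC ($337.50) accrue in
  the PFS sub-states and PD; PD additionally accrues the anlotinib cycle
  cost weighted by the arm's subsequent-therapy proportion; end-stage
  accrues palliative care only.
- **Palliative care.** Although the published input is labelled per cycle
  ($2,627.80), charging it every end-stage cycle is irreconcilable with the
  published totals: under any mortality mode consistent with the published
  QALYs the cohort spends 7–9 discounted cycles in end-stage, making
  palliative care alone ($19k–24k) exceed the entire published docetaxel-arm
  total ($14,360). The default therefore treats it as a one-time
  terminal-care package charged at end-stage entry
  (`palliative_cost_mode: one_time`); `per_cycle` and `one_time_at_death`
  remain available.
- **Adverse events.** The frequency-weighted AE cost and disutility
  aggregates are per-patient-course quantities and are charged once at
  model entry; charging them per cycle would exceed the published totals by
  an order of magnitude.
- **QALYs.** Occupancy × Chinese utility weights (PFS 0.856, PD 0.768,
  end-stage 0.703) × cycle length in years, discounted, minus the one-time
  AE disutility.

## Sensitivity analysis

The published table gives ranges but no standard errors; every range is
read as a 95% interval, `SE = (high − low)/3.92`. Beta and gamma parameters
are moment-matched to (mean, SE), with an infeasible-moments fallback to
uniform(low, high) (logged; never triggered by the bundled inputs). Weight
and body surface area are normal, truncated at zero by resampling. Hazard
ratios carry a "Normal" tag, but their printed intervals (e.g. 0.509–2.683
around 1.170) are multiplicatively, not additively, symmetric, so they are
sampled log-normally by default; a raw truncated-normal option is retained.
Joint draws are independent (no correlation structure is published), and
survival shape parameters θ/κ are fixed in both DSA and PSA, as published.

DSA re-runs the model at each parameter's bounds with everything else at
baseline; entries with negative incremental QALYs at a bound are flagged as
dominance rather than reported as a signed ICER. The tornado ranks by swing
width (ties alphabetical). PSA defaults to 1,000 iterations; the summary
reports, per pairwise comparison, the fraction of iterations that are
cost-effective (dominant, or positive NMB at λ) and strictly dominant, and
the CEAC is computed pointwise over a λ grid.

## Synthetic pseudo-IPD

The generator emulates reconstructed patient-level data from published
trial curves: event times by inverse CDF `t = ((1−u)/(θu))^{1/κ}`,
administrative censoring at 35 cycles (~24 months, second-line trial
follow-up scale; configurable), optional exponential dropout. The
KM-coordinate inversion is the simplified no-interval-censoring variant
(events at step times, residual survivors censored at the last coordinate),
not a full numbers-at-risk–aware reconstruction: it reproduces step heights
and is statistically faithful, but it places each interval's events at the
interval end, so inverting a *continuous* curve sampled on a grid carries a
discretization bias of order the grid step. What passing tests show is
parameter recovery under the model's own assumptions — not robustness to
digitization error, informative censoring, or model misspecification in
real trial figures.

## Numerical choices

- MLE fitting: L-BFGS-B on unconstrained coordinates (log of positive
  parameters; the log-normal location stays linear), three seeded random
  restarts around moment-based initial values, `ftol` 1e-10; families
  failing to converge are dropped from selection with an aggregated error
  if all fail. Gompertz is restricted to positive shape (no defective
  plateau). The log-logistic MLE matches lifelines' independent
  implementation to ~7 significant digits on censored data (tested).
- AIC ascending ranks families; ties break by BIC, then input order.
- Cohort traces conserve probability mass to 1e-9 per cycle (checked at
  run time in the iterative path and by tests in both paths).
- Vial counts use `ceil(dose/unit − 1e-9)` to absorb float noise at exact
  multiples.
- ICERs are computed from full-precision totals and rounded only for
  display; a ratio is reported only in the trade-off quadrant (ΔQ > 0,
  ΔC ≥ 0) — dominance quadrants carry flags.

## Problem sizes

The base case runs 521 cycles × 3 arms in well under a second; the full
1,000-iteration PSA (3,000 model runs) takes a few seconds on one CPU via
the convolution engine; the test suite, including a 100,000-draw
moment-matching check and 5,000-subject fitting exercises, runs in well
under a minute.

## Reproduction fidelity and known limitations

With the documented defaults the model reproduces the published per-arm
QALYs within 1–4%, the tislelizumab-vs-docetaxel incremental cost within
2%, the nivolumab arm cost within 10%, the base-case ICER within 10%, all
three decision labels (tislelizumab cost-effective vs docetaxel, dominant
over nivolumab; nivolumab dominated), the efficiency frontier, and the DSA
finding that the tislelizumab price is the only decision-flipping
parameter.

Two published quantities are **not** reproduced and are left as failing
acceptance checks rather than calibrated away:

- **Absolute docetaxel/tislelizumab arm costs** come out 12–18% below the
  published totals. The gap is concentrated in end-stage care composition,
  which the source does not specify; accruing follow-up + BSC during
  end-stage alongside palliative care would close most of it, but the
  documented default excludes those there.
- **The PSA proportion for tislelizumab vs docetaxel** (published: 42.1%
  cost-effective, 12.0% dominant) comes out ≈90% / 0%. The published figure
  is hard to reconcile with the published base case: at the published
  totals the NMB is +$2,483 (ICER $27,959 < λ $35,663), while
  moment-matching the published ranges yields an incremental-cost spread of
  only ≈$2,800, implying a cost-effectiveness probability near 0.9. A ≈42%
  probability would require joint parameter spreads several times wider
  than the printed 95% ranges. The vs-nivolumab proportion (95.6%
  published) reproduces within 5 points.

Other limitations: no correlation structure or EVPI in the PSA; no
spline/flexible parametric survival models or interval censoring; sex
subgroup scenarios ship only the published nivolumab-vs-tislelizumab OS
hazard ratios — the sex-specific tislelizumab-vs-docetaxel contrast needed
to reproduce the published subgroup table is not public and must be
supplied by the user.
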