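"""Synthetic individual patient-level data (pseudo-IPD) utilities.

Published oncology trials release survival as Kaplan-Meier figures, not
patient records. The fitting stage of the pipeline is therefore exercised
against synthetic stand-ins: event times drawn from a specified log-logistic
law with administrative censoring (mimicking trial follow-up) and optional
exponential dropout, plus a simplified inversion that turns digitized-style
KM step coordinates back into an event/censoring table. IPD travels as a
two-column pandas DataFrame (``time`` in cycles, ``event`` in {0, 1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .config import LogLogisticParams, ValidationError
from .survival import SurvivalCurve

__all__ = ["KmCurve", "simulate_ipd", "km_estimate", "invert_km_coordinates"]


def _as_ipd_frame(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"time": times.astype(float), "event": events.astype(int)})


@dataclass(frozen=True)
class KmCurve:
    """Kaplan-Meier step coordinates: S starts at 1 and is non-increasing."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.size != s.size or t.size == 0:
            raise ValidationError("times and survival must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise ValidationError("survival must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12) or s[0] > 1.0:
            raise ValidationError("survival must be non-increasing from 1")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times, "survival": self.survival})
        if self.at_risk is not None:
            out["at_risk"] = self.at_risk
        return out


def simulate_ipd(
    law: SurvivalCurve | LogLogisticParams,
    n: int,
    admin_censor_time: float,
    dropout_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw right-censored pseudo-IPD from a log-logistic survival law.

    Event times come from the inverse CDF ``t = ((1-u)/(theta*u))**(1/kappa)``
    with ``u ~ U(0,1)`` (a hazard-ratio power on the curve is absorbed by
    transforming ``u``); an independent exponential dropout time with the
    given per-cycle hazard and administrative censoring at
    ``admin_censor_time`` right-censor the record if either precedes the
    event. Deterministic under a fixed ``seed``.
    """
    curve = law if isinstance(law, SurvivalCurve) else SurvivalCurve.loglogistic(law)
    if curve.family != "loglogistic":
        raise ValidationError("simulate_ipd requires a log-logistic law")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not admin_censor_time > 0:
        raise ValidationError("admin_censor_time must be > 0")
    if dropout_rate < 0:
        raise ValidationError("dropout_rate must be >= 0")
    theta, kappa = curve.params
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    u = rng.uniform(size=n)
    v = u ** (1.0 / curve.hr)  # S(t)**hr = u  =>  S(t) = u**(1/hr)
    t_event = ((1.0 - v) / (theta * v)) ** (1.0 / kappa)
    censor = np.full(n, float(admin_censor_time))
    if dropout_rate > 0:
        censor = np.minimum(censor, rng.exponential(1.0 / dropout_rate, size=n))
    event = (t_event <= censor).astype(int)
    time = np.where(event == 1, t_event, censor)
    return _as_ipd_frame(time, event)


def km_estimate(ipd: pd.DataFrame) -> KmCurve:
    """Product-limit (Kaplan-Meier) estimate of an IPD table."""
    if len(ipd) == 0:
        raise ValidationError("empty IPD table")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], event_observed=ipd["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(ipd.loc[ipd["event"] == 1, "time"].to_numpy(float))
    times = np.concatenate([[0.0], event_times])
    surv = sf.reindex(times, method="ffill").to_numpy(float)
    at_risk = [
        int((ipd["time"].to_numpy(float) >= t - 1e-12).sum()) for t in times
    ]
    return KmCurve(
        times=tuple(times), survival=tuple(surv), at_risk=tuple(at_risk)
    )


def invert_km_coordinates(curve: KmCurve, n_start: int) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from KM step coordinates.

    At each downward step, ``round(n_start * delta_S)`` events are placed at
    the step time (with cumulative rounding so totals do not drift); the
    residual survivors are administratively censored at the last coordinate.
    This is the simplified no-interval-censoring inversion: it reproduces the
    step heights, not the within-interval censoring pattern of the original
    trial.
    """
    if n_start < 1:
        raise ValidationError(f"n_start must be >= 1, got {n_start}")
    times = np.asarray(curve.times, dtype=float)
    surv = np.asarray(curve.survival, dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    rec_t: list[float] = []
    rec_e: list[int] = []
    assigned = 0
    for i in range(1, times.size):
        cum_events = int(round(n_start * (1.0 - surv[i])))
        k = cum_events - assigned
        if k > 0:
            rec_t.extend([times[i]] * k)
            rec_e.extend([1] * k)
            assigned = cum_events
    survivors = n_start - assigned
    if survivors > 0:
        rec_t.extend([times[-1]] * survivors)
        rec_e.extend([0] * survivors)
    return _as_ipd_frame(np.asarray(rec_t), np.asarray(rec_e))
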