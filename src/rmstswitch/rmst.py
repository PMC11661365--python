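"""Kaplan-Meier estimation, restricted mean survival time, and the NI test.

The restricted mean survival time (RMST) at a horizon tau is the area under
the survival curve on [0, tau].  Here it is computed exactly as the area
under the Kaplan-Meier step function, with the product-limit variance

    Var(R_hat(tau)) = sum_{t_i <= tau} [∫_{t_i}^{tau} S_hat(t) dt]^2
                      * d_i / (n_i (n_i - d_i)),

summing over distinct event times t_i with d_i events among n_i at risk
(terms with n_i = d_i are dropped, the conventional treatment of a terminal
event).  Censored observations tied with an event time count as at risk for
that event time.  Beyond the largest observed time the last Kaplan-Meier
value is carried forward to tau.

The one-sided non-inferiority decision for the difference in RMSTs
Delta = R2 - R1 rejects the null Delta <= -delta when

    Delta_hat - z_{1-alpha} * SE(Delta_hat) > -delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "NIResult",
    "km_fit",
    "rmst_hat",
    "rmst_var",
    "ni_test",
    "drmst_ni_test",
    "read_survival_csv",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Observed follow-up times and event indicators of one arm."""

    times: np.ndarray
    events: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be 1-D arrays of equal length")
        if times.size == 0:
            raise ValueError("a survival sample needs at least one subject")
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("times must be finite and nonnegative")
        if not np.isin(np.unique(events), (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(bool))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    event_times: np.ndarray  # strictly increasing, each with >= 1 event
    survival: np.ndarray  # S_hat just after each event time
    at_risk: np.ndarray
    deaths: np.ndarray
    n_subjects: int = field(default=0)


def km_fit(sample: SurvivalSample) -> KMCurve:
    """Product-limit estimate; an all-censored sample yields S_hat == 1."""
    t, e = sample.times, sample.events
    event_times, deaths = np.unique(t[e], return_counts=True)
    t_sorted = np.sort(t)
    at_risk = t.size - np.searchsorted(t_sorted, event_times, side="left")
    survival = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        deaths=deaths,
        n_subjects=t.size,
    )


def _step_segments(curve: KMCurve, tau: float):
    """Segment widths and S_hat values of the KM step function on [0, tau]."""
    k = int(np.searchsorted(curve.event_times, tau, side="left"))
    knots = np.concatenate(([0.0], curve.event_times[:k], [tau]))
    values = np.concatenate(([1.0], curve.survival[:k]))
    return k, np.diff(knots), values


def rmst_hat(curve: KMCurve, tau: float) -> float:
    """Area under the KM step function on [0, tau] (last value carried forward)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    _, widths, values = _step_segments(curve, tau)
    return float(np.dot(widths, values))


def rmst_var(curve: KMCurve, tau: float) -> float:
    """Product-limit variance of the RMST estimate (see module docstring)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    k, widths, values = _step_segments(curve, tau)
    if k == 0:
        return 0.0
    segment_areas = widths * values
    # tail[i] = area under S_hat from event time i to tau
    tail = np.cumsum(segment_areas[::-1])[::-1][1:]
    d = curve.deaths[:k].astype(float)
    n = curve.at_risk[:k].astype(float)
    ok = n > d
    return float(np.sum(tail[ok] ** 2 * d[ok] / (n[ok] * (n[ok] - d[ok]))))


@dataclass(frozen=True)
class NIResult:
    """Outcome of the one-sided DRMST non-inferiority test."""

    delta_hat: float  # R2_hat - R1_hat
    se: float
    lower_bound: float  # delta_hat - z * se
    margin: float
    alpha: float
    reject: bool
    r1: float | None = None
    r2: float | None = None
    var1: float | None = None
    var2: float | None = None

    def to_dict(self) -> dict:
        return {
            "delta_hat": self.delta_hat,
            "se": self.se,
            "lower_bound": self.lower_bound,
            "margin": self.margin,
            "alpha": self.alpha,
            "non_inferior": bool(self.reject),
            "rmst_control": self.r1,
            "rmst_experimental": self.r2,
        }


def ni_test(
    r1_hat: float,
    var1: float,
    r2_hat: float,
    var2: float,
    delta: float,
    alpha: float,
) -> NIResult:
    """Reject H0: Delta <= -delta iff Delta_hat - z_{1-alpha} SE > -delta."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    delta_hat = r2_hat - r1_hat
    se = float(np.sqrt(var1 + var2))
    z = float(stats.norm.ppf(1.0 - alpha))
    lower = delta_hat - z * se
    return NIResult(
        delta_hat=delta_hat,
        se=se,
        lower_bound=lower,
        margin=delta,
        alpha=alpha,
        reject=bool(lower > -delta),
        r1=r1_hat,
        r2=r2_hat,
        var1=var1,
        var2=var2,
    )


def drmst_ni_test(
    control: SurvivalSample,
    experimental: SurvivalSample,
    tau: float,
    delta: float,
    alpha: float,
) -> NIResult:
    """Fit both arms, estimate RMSTs at tau, and run the NI decision."""
    c1 = km_fit(control)
    c2 = km_fit(experimental)
    return ni_test(
        rmst_hat(c1, tau),
        rmst_var(c1, tau),
        rmst_hat(c2, tau),
        rmst_var(c2, tau),
        delta,
        alpha,
    )


def read_survival_csv(path) -> dict[str, SurvivalSample]:
    """Read a (time, event, arm) table into one SurvivalSample per arm."""
    frame = pd.read_csv(path)
    missing = {"time", "event", "arm"} - set(frame.columns)
    if missing:
        raise ValueError(f"survival CSV is missing columns {sorted(missing)}")
    samples = {}
    for arm, group in frame.groupby("arm", sort=True):
        samples[str(arm)] = SurvivalSample(
            times=group["time"].to_numpy(dtype=float),
            events=group["event"].to_numpy(),
            label=str(arm),
        )
    return samples
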