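"""Accrual, Weibull event-time, and censoring models for two-arm survival trials.

Subjects enter the trial uniformly over an accrual window ``[0, Ta]`` and are
followed until the trial ends at calendar time ``Te``, so a subject entering at
``v`` is administratively censored ``Te - v`` after randomization.  Event times
in the two arms are Weibull with a common shape parameter and arm-specific
scales fixed by the median survivals.  Dropout censoring, when present, is
uniform on ``(0, h)``; the bound ``h`` is calibrated so the *total* censoring
probability of the control arm (dropout plus administrative, in the absence of
treatment switching) equals a requested rate.  Both arms share the same
censoring law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "InfeasibleError",
    "TrialDesign",
    "ArmEventModel",
    "CensoringModel",
    "WeibullMoments",
    "solve_weibull_params",
    "weibull_moments",
    "sample_entry_times",
    "censoring_probability",
    "solve_dropout_bound",
    "sample_censoring_times",
]

_LOG2 = math.log(2.0)


class InfeasibleError(ValueError):
    """A calibration target cannot be met by the assumed model family."""


def _round_half_away(x: float) -> int:
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TrialDesign:
    """Trial-level design constants.

    Parameters
    ----------
    Ta : float
        Accrual duration; entry times are uniform on ``[0, Ta]`` (all zero
        when ``Ta == 0``).
    Te : float
        Total trial duration from first enrollment, ``Te >= Ta``.
    tau : float
        Horizon of the restricted mean survival time, ``0 < tau <= Te``.
    n : int
        Control-arm sample size (``>= 2``).
    r : float
        Allocation ratio experimental:control; the experimental arm holds
        ``round(r * n)`` subjects (half-away-from-zero rounding).
    alpha : float
        One-sided significance level of the non-inferiority test.
    n_simulations, seed : int
        Monte-Carlo controls.
    """

    Ta: float
    Te: float
    tau: float
    n: int
    r: float = 1.0
    alpha: float = 0.025
    n_simulations: int = 5000
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.Ta < 0:
            raise ValueError("Ta must be >= 0")
        if self.Te < self.Ta or self.Te <= 0:
            raise ValueError("Te must be positive and >= Ta")
        if not 0 < self.tau <= self.Te:
            raise ValueError("tau must satisfy 0 < tau <= Te")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError("n must be an integer >= 2")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.n_experimental < 2:
            raise ValueError("round(r * n) must be >= 2")

    @property
    def n_experimental(self) -> int:
        return _round_half_away(self.r * self.n)


@dataclass(frozen=True)
class ArmEventModel:
    """Weibull event-time law of one arm, parameterized by its median.

    Satisfies ``scale * (log 2)**(1/shape) == median``.
    """

    median: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.shape <= 0 or self.scale <= 0:
            raise ValueError("median, shape and scale must all be positive")
        implied = self.scale * _LOG2 ** (1.0 / self.shape)
        if not math.isclose(implied, self.median, rel_tol=1e-8):
            raise ValueError(
                "inconsistent Weibull parameters: scale*(log 2)^(1/shape) "
                f"= {implied:.10g} but median = {self.median:.10g}"
            )

    @classmethod
    def from_median(cls, median: float, shape: float) -> "ArmEventModel":
        shp, scale = solve_weibull_params(median, shape=shape)
        return cls(median=median, shape=shp, scale=scale)

    @classmethod
    def from_survival_point(
        cls, median: float, ref_time: float, ref_survival: float
    ) -> "ArmEventModel":
        shp, scale = solve_weibull_params(median, ref_time, ref_survival)
        return cls(median=median, shape=shp, scale=scale)

    def survival(self, t):
        """S(t) = exp(-(t/scale)^shape)."""
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale) ** self.shape))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.scale * rng.weibull(self.shape, size)


def solve_weibull_params(
    median: float,
    ref_time: float | None = None,
    ref_survival: float | None = None,
    *,
    shape: float | None = None,
) -> tuple[float, float]:
    """Weibull (shape, scale) from the median plus one extra constraint.

    The extra constraint is either the shape itself, or a survival
    probability ``ref_survival`` at time ``ref_time``.  The pair solves

        scale * (log 2)**(1/shape) = median
        exp(-(ref_time/scale)**shape) = ref_survival

    Eliminating the scale gives the closed form
    ``shape = log(log(ref_survival)/log(1/2)) / log(ref_time/median)``.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if shape is not None:
        if shape <= 0:
            raise ValueError("shape must be positive")
        return float(shape), median / _LOG2 ** (1.0 / shape)
    if ref_time is None or ref_survival is None:
        raise ValueError("supply either shape, or both ref_time and ref_survival")
    if not 0 < ref_survival < 1:
        raise ValueError("ref_survival must lie strictly in (0, 1)")
    if ref_time <= 0:
        raise ValueError("ref_time must be positive")

    # ratio of log-survivals against the defining 50% point
    target = math.log(ref_survival) / math.log(0.5)
    at_median = math.isclose(ref_time, median, rel_tol=1e-12)
    at_half = math.isclose(target, 1.0, rel_tol=1e-12)
    if at_half and at_median:
        raise InfeasibleError(
            "under-determined: ref_survival = 0.5 at the median holds for every shape"
        )
    if at_half or at_median:
        raise InfeasibleError(
            "infeasible reference point: ref_survival = 0.5 can only occur at the "
            "median (and conversely) for a Weibull law"
        )
    shp = math.log(target) / math.log(ref_time / median)
    if shp <= 0:
        raise InfeasibleError(
            f"no positive Weibull shape matches S({ref_time}) = {ref_survival} "
            f"with median {median}"
        )
    return shp, median / _LOG2 ** (1.0 / shp)


class WeibullMoments(NamedTuple):
    mean: float
    variance: float
    second_moment: float


def weibull_moments(model: ArmEventModel) -> WeibullMoments:
    """Mean, variance and E[T^2] of a Weibull event-time law."""
    mean = model.scale * special.gamma(1.0 + 1.0 / model.shape)
    second = model.scale**2 * special.gamma(1.0 + 2.0 / model.shape)
    return WeibullMoments(mean=mean, variance=second - mean**2, second_moment=second)


def sample_entry_times(
    design: TrialDesign, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Entry (accrual) times, uniform on [0, Ta]; all zero when Ta == 0."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if design.Ta == 0:
        return np.zeros(count)
    return rng.uniform(0.0, design.Ta, count)


@dataclass(frozen=True)
class CensoringModel:
    """Common censoring law of both arms.

    ``mode`` is ``"administrative-only"`` (no dropout; a subject entering at v
    is censored at Te - v if event-free) or ``"total-rate"`` (additional
    uniform U(0, h) dropout, with h solved so the control arm's total
    censoring probability equals ``target_rate`` under no switching).
    """

    mode: str
    h: float = math.inf
    target_rate: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("administrative-only", "total-rate"):
            raise ValueError(f"unknown censoring mode {self.mode!r}")
        if self.mode == "total-rate":
            if self.target_rate is None or not 0 < self.target_rate < 1:
                raise ValueError("total-rate mode needs target_rate in (0, 1)")
            if not self.h > 0 or math.isinf(self.h):
                raise ValueError("total-rate mode needs a finite dropout bound h > 0")

    @classmethod
    def administrative_only(cls) -> "CensoringModel":
        return cls(mode="administrative-only")

    @classmethod
    def calibrated(
        cls, rate: float, control_model: ArmEventModel, design: TrialDesign
    ) -> "CensoringModel":
        h = solve_dropout_bound(rate, control_model, design)
        return cls(mode="total-rate", h=h, target_rate=rate)


def _integral_survival(model: ArmEventModel, x: float) -> float:
    """∫_0^x S(u) du for a Weibull survival function (lower incomplete gamma)."""
    if x <= 0:
        return 0.0
    k, lam = model.shape, model.scale
    z = (x / lam) ** k
    return lam / k * special.gamma(1.0 / k) * special.gammainc(1.0 / k, z)


def censoring_probability(
    control_model: ArmEventModel, design: TrialDesign, h: float = math.inf
) -> float:
    """P(censored) for a control-arm subject under no switching.

    The censoring time is ``C = min(U(0, h), Te - v)`` with entry
    ``v ~ U(0, Ta)``; the subject is censored when ``C < T``.  ``h = inf``
    gives the administrative-only probability ``E_v[S(Te - v)]``.
    """

    def given_v(v: float) -> float:
        admin = design.Te - v
        s_admin = float(control_model.survival(admin))
        if math.isinf(h):
            return s_admin
        cut = min(h, admin)
        val = _integral_survival(control_model, cut)
        if h > admin:
            val += (h - admin) * s_admin
        return val / h

    if design.Ta == 0:
        return given_v(0.0)
    value, _ = integrate.quad(
        given_v, 0.0, design.Ta, epsabs=1e-10, epsrel=1e-10, limit=200
    )
    return value / design.Ta


def solve_dropout_bound(
    rate: float, control_model: ArmEventModel, design: TrialDesign
) -> float:
    """Upper bound h of the U(0, h) dropout law matching a total censoring rate.

    Solves ``P(min(U(0,h), Te - v) < T) = rate`` for the control arm by
    bracketing bisection; the probability is decreasing in h, from 1 (h -> 0)
    down to the administrative-only floor (h -> inf).
    """
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    floor = censoring_probability(control_model, design)
    if rate <= floor + 1e-9:
        raise InfeasibleError(
            f"requested censoring rate {rate:.6g} is at or below the purely "
            f"administrative censoring probability {floor:.6g}"
        )

    def excess(h: float) -> float:
        return censoring_probability(control_model, design, h) - rate

    lo = 1e-9 * max(design.Te, 1.0)
    hi = max(design.Te, 1.0)
    for _ in range(200):
        if excess(hi) < 0.0:
            break
        hi *= 2.0
    else:  # pragma: no cover - requires rate within 1e-9 of the floor
        raise InfeasibleError(
            f"could not bracket the dropout bound for censoring rate {rate}"
        )
    h = optimize.brentq(excess, lo, hi, xtol=1e-12 * hi, rtol=8.9e-16)
    achieved = censoring_probability(control_model, design, h)
    if abs(achieved - rate) > 1e-6:  # pragma: no cover - defensive
        raise InfeasibleError(
            f"dropout calibration did not converge: achieved {achieved:.8g} "
            f"for target {rate:.8g}"
        )
    return float(h)


def sample_censoring_times(
    cens: CensoringModel,
    entry_times: np.ndarray,
    design: TrialDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Censoring times C = min(U(0, h), Te - v); dropout omitted if admin-only."""
    entry_times = np.asarray(entry_times, dtype=float)
    admin = design.Te - entry_times
    if cens.mode == "administrative-only":
        return admin
    dropout = rng.uniform(0.0, cens.h, entry_times.shape[0])
    return np.minimum(dropout, admin)
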