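"""Switching-time models and the structural failure-time transform.

Control-arm subjects (or experimental-arm subjects, for the mirrored
direction) may cross over to the other treatment at a random switching time
``s``, with marginal probability ``ps``.  From the switch onward their
residual survival is stretched by the acceleration factor — the ratio of the
destination-arm to origin-arm median survivals — which is the generative form
of the rank-preserving structural failure time model:

    T* = s + (T - s) * acceleration        (if the subject switches and s < T)

Four random families for ``s`` are supported.  Three set ``s = X * T`` with
``X`` independent of the origin-arm event time ``T`` (``X`` uniform, beta, or
gamma), so ``s`` is positively correlated with ``T``; one draws ``s``
exponential independently of ``T``; finally ``s`` may be a fixed constant
(e.g. 0 for switching at the start of the study).  The free parameters are
calibrated from two moments: ``rs = E(s)/E(T)`` and, for the beta and gamma
families, the Pearson correlation ``rho_s = corr(s, T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

from .event_model import InfeasibleError, WeibullMoments

__all__ = [
    "SWITCH_FAMILIES",
    "SwitchingModel",
    "solve_switch_params",
    "sample_switch_times",
    "apply_rpsftm",
]

SWITCH_FAMILIES = ("unif", "beta", "gamma", "indepExp")


@dataclass(frozen=True)
class SwitchingModel:
    """A calibrated switching mechanism for one direction of crossover.

    ``s_dist`` is one of :data:`SWITCH_FAMILIES` or a numeric constant;
    ``params`` holds the solved family parameters; ``acceleration`` is the
    median ratio applied to post-switch residual survival (m2/m1 for control
    to experimental switching, m1/m2 for the mirror).
    """

    s_dist: str | float
    ps: float
    acceleration: float
    direction: str = "1to2"
    rs: float | None = None
    rho_s: float | None = None
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.ps <= 1:
            raise ValueError("ps must lie in [0, 1]")
        if self.acceleration <= 0:
            raise ValueError("acceleration must be > 0")
        if self.direction not in ("1to2", "2to1"):
            raise ValueError('direction must be "1to2" or "2to1"')
        if isinstance(self.s_dist, str) and self.s_dist not in SWITCH_FAMILIES:
            raise ValueError(
                f"s_dist must be one of {SWITCH_FAMILIES} or a numeric constant"
            )


def _pearson_corr(ex: float, varx: float, moments: WeibullMoments) -> float:
    # s = X*T with X independent of T:
    #   cov(s, T) = E(X) Var(T);  Var(s) = Var(X) E(T^2) + E(X)^2 Var(T)
    cov = ex * moments.variance
    sd_s = math.sqrt(varx * moments.second_moment + ex * ex * moments.variance)
    return cov / (math.sqrt(moments.variance) * sd_s)


def solve_switch_params(
    s_dist: str | float,
    rs: float | None,
    rho_s: float | None,
    event_moments: WeibullMoments,
) -> dict[str, float]:
    """Solve the switching-time family parameters from (rs, rho_s).

    For the beta family ``X ~ Beta(a, b)`` with ``E(X) = a/(a+b) = rs``; for
    the gamma family ``X ~ Gamma(shape=a, rate=b)`` with ``E(X) = a/b = rs``.
    In both cases the remaining free parameter is found by a monotone 1-D
    root-find on the exact Pearson correlation of ``s = X*T`` with ``T``.
    The uniform family has no free parameter and requires ``rs = 0.5``; the
    independent-exponential family sets ``rate = 1/(rs * E(T))``; a numeric
    ``s_dist`` is the fixed switching time itself.
    """
    if not isinstance(s_dist, str):
        value = float(s_dist)
        if value < 0:
            raise ValueError("a fixed switching time must be >= 0")
        return {"value": value}

    if s_dist == "unif":
        if rs is None or not math.isclose(rs, 0.5, rel_tol=0, abs_tol=1e-9):
            raise InfeasibleError(
                "s_dist='unif' implies E(s)/E(T) = 0.5 exactly; "
                f"it does not satisfy rs={rs}"
            )
        return {}

    if rs is None or rs <= 0:
        raise ValueError(f"s_dist={s_dist!r} needs rs > 0")

    if s_dist == "indepExp":
        return {"rate": 1.0 / (rs * event_moments.mean)}

    if s_dist not in ("beta", "gamma"):
        raise ValueError(f"unknown switching-time family {s_dist!r}")
    if s_dist == "beta" and not rs < 1:
        raise ValueError("the beta family needs 0 < rs < 1")
    if rho_s is None or not 0 < rho_s < 1:
        raise ValueError(f"s_dist={s_dist!r} needs rho_s in (0, 1)")

    if s_dist == "beta":
        # b = a(1-rs)/rs from the mean constraint; Var(X) shrinks as a grows
        def varx(a: float) -> float:
            return rs * (1.0 - rs) / (a / rs + 1.0)

    else:  # gamma, b = a/rs
        def varx(a: float) -> float:
            return rs * rs / a

    def corr_of(log_a: float) -> float:
        return _pearson_corr(rs, varx(math.exp(log_a)), event_moments)

    lo, hi = -40.0, 40.0
    corr_lo, corr_hi = corr_of(lo), corr_of(hi)
    if not corr_lo < rho_s < corr_hi:
        raise InfeasibleError(
            f"rho_s={rho_s} is unattainable for s_dist={s_dist!r} with rs={rs}: "
            f"the attainable correlations lie in ({corr_lo:.6g}, {corr_hi:.6g})"
        )
    log_a = optimize.brentq(lambda x: corr_of(x) - rho_s, lo, hi, xtol=1e-13)
    a = math.exp(log_a)
    if s_dist == "beta":
        params = {"shape1": a, "shape2": a * (1.0 - rs) / rs}
    else:
        params = {"shape": a, "rate": a / rs}
    achieved = _pearson_corr(rs, varx(a), event_moments)
    if abs(achieved - rho_s) > 1e-6:  # pragma: no cover - defensive
        raise InfeasibleError(
            f"correlation calibration did not converge for {s_dist!r}"
        )
    return params


def sample_switch_times(
    model: SwitchingModel, T_origin: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one switching time per subject of the origin arm.

    The uniform/beta/gamma families multiply the subject's own latent event
    time by an independent factor X; the independent-exponential family and a
    fixed constant ignore ``T_origin`` (apart from its length).
    """
    T_origin = np.asarray(T_origin, dtype=float)
    n = T_origin.shape[0]
    dist, p = model.s_dist, model.params
    if not isinstance(dist, str):
        return np.full(n, p["value"])
    if dist == "unif":
        return rng.uniform(0.0, 1.0, n) * T_origin
    if dist == "beta":
        return rng.beta(p["shape1"], p["shape2"], n) * T_origin
    if dist == "gamma":
        return rng.gamma(p["shape"], 1.0 / p["rate"], n) * T_origin
    if dist == "indepExp":
        return rng.exponential(1.0 / p["rate"], n)
    raise ValueError(f"unknown switching-time family {dist!r}")  # pragma: no cover


def apply_rpsftm(
    T: np.ndarray,
    s: np.ndarray,
    switch_flags: np.ndarray,
    acceleration: float,
) -> np.ndarray:
    """Stretch post-switch residual survival by the acceleration factor.

    Only subjects whose switch flag is set *and* whose switching time
    precedes the latent event (``s < T``) are affected; a draw of ``s >= T``
    means the event happened first and the switch never occurs.
    """
    if acceleration <= 0:
        raise ValueError("acceleration must be > 0")
    T = np.asarray(T, dtype=float)
    s = np.asarray(s, dtype=float)
    effective = np.asarray(switch_flags, dtype=bool) & (s < T)
    return np.where(effective, s + (T - s) * acceleration, T)
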