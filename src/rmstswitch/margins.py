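"""Non-inferiority margins on the restricted-mean-survival-time scale.

The margin delta is the largest tolerable deficit in RMST at the horizon tau:
non-inferiority is claimed when the one-sided lower confidence bound for
R2(tau) - R1(tau) exceeds -delta.  Three constructions are supported:

* preserved fraction f1 of the control RMST:   delta = (1 - f1) * R1(tau);
* preserved fraction f2 of the control-vs-placebo RMST difference:
  delta = (1 - f2) * (R1(tau) - R0(tau)), with the placebo survival sharing
  the Weibull shape of the treatment arms and median m0;
* conversion of a proportional-hazards margin 1/theta > 1:
  delta = R1(tau) minus the integral of S1(t)**(1/theta) over [0, tau];

plus a directly supplied numeric delta.  Exactly one option may be active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate

from .event_model import ArmEventModel

__all__ = ["MarginSpec", "true_rmst", "hr_margin_to_delta", "resolve_margin"]


@dataclass(frozen=True)
class MarginSpec:
    """A resolved non-inferiority margin (time units)."""

    option: str  # "preserved-control-rmst" | "preserved-drmst" | "hr-conversion" | "explicit"
    delta: float
    details: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"the margin delta must be > 0, got {self.delta}")


def true_rmst(model: ArmEventModel, tau: float) -> float:
    """R(tau) = ∫_0^tau S(t) dt of a parametric Weibull survival law."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    value, _ = integrate.quad(
        lambda t: np.exp(-((t / model.scale) ** model.shape)),
        0.0,
        tau,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    return value


def hr_margin_to_delta(
    control_model: ArmEventModel, hr_margin: float, tau: float
) -> float:
    """delta implied by a hazard-ratio margin 1/theta > 1 under proportional hazards.

    Raising the control survival to the power 1/theta gives the survival of a
    just-tolerable experimental arm; delta is the RMST gap between the two.
    """
    if hr_margin < 1:
        raise ValueError("the hazard-ratio margin 1/theta must be >= 1")
    r1 = true_rmst(control_model, tau)
    r_theta, _ = integrate.quad(
        lambda t: np.exp(-hr_margin * (t / control_model.scale) ** control_model.shape),
        0.0,
        tau,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    return r1 - r_theta


def resolve_margin(
    control_model: ArmEventModel,
    tau: float,
    *,
    f1: float | None = None,
    f2: float | None = None,
    m0: float | None = None,
    margin: float | None = None,
    hr_margin: float | None = None,
) -> MarginSpec:
    """Resolve the margin delta from exactly one of the supported options.

    Supplying several options is rejected rather than silently prioritized,
    and the preserved-DRMST option requires R1(tau) > R0(tau).
    """
    if f2 is not None and m0 is None:
        raise ValueError("the f2 margin option also needs the placebo median m0")
    supplied = {
        "f1": f1 is not None,
        "f2/m0": f2 is not None,
        "margin": margin is not None,
        "hr_margin": hr_margin is not None,
    }
    active = [name for name, given in supplied.items() if given]
    if len(active) == 0:
        raise ValueError(
            "no margin option supplied: give one of f1, (f2, m0), margin or hr_margin"
        )
    if len(active) > 1:
        raise ValueError(f"margin options are mutually exclusive; got {active}")

    r1 = true_rmst(control_model, tau)
    if f1 is not None:
        if not 0 < f1 < 1:
            raise ValueError("f1 must lie in (0, 1)")
        return MarginSpec(
            "preserved-control-rmst", (1.0 - f1) * r1, {"f1": f1, "R1": r1}
        )
    if f2 is not None:
        if not 0 < f2 < 1:
            raise ValueError("f2 must lie in (0, 1)")
        placebo = ArmEventModel.from_median(m0, control_model.shape)
        r0 = true_rmst(placebo, tau)
        if r1 <= r0:
            raise ValueError(
                "the preserved-DRMST option requires R1(tau) > R0(tau); got "
                f"R1={r1:.6g}, R0={r0:.6g}"
            )
        return MarginSpec(
            "preserved-drmst",
            (1.0 - f2) * (r1 - r0),
            {"f2": f2, "m0": m0, "R1": r1, "R0": r0},
        )
    if hr_margin is not None:
        delta = hr_margin_to_delta(control_model, hr_margin, tau)
        return MarginSpec(
            "hr-conversion", delta, {"hr_margin": hr_margin, "R1": r1}
        )
    return MarginSpec("explicit", float(margin), {})
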