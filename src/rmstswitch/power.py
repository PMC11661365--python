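"""Monte-Carlo power for the DRMST non-inferiority test under switching.

A scenario is resolved once (Weibull calibration, dropout-bound calibration,
margin, switching-time parameters) and then simulated trial by trial.  Each
replicate draws entry times, latent event times, censoring times, and — if
switching is active — per-subject switch flags and switching times; the
structural failure-time transform stretches post-switch survival, the
intention-to-treat samples are formed as Y = min(T*, C) labelled by the
randomized arm, and the one-sided non-inferiority test is applied.  Power is
the rejection fraction; the expected event counts E1 and E2 are averaged over
the same replicates.

Reproducibility: the root seed is expanded with ``numpy.random.SeedSequence``
into one independent stream per replicate, so results are bit-identical for a
fixed seed regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .config import ConfigError, ScenarioConfig
from .event_model import (
    ArmEventModel,
    CensoringModel,
    TrialDesign,
    sample_censoring_times,
    sample_entry_times,
    weibull_moments,
)
from .margins import MarginSpec, resolve_margin
from .rmst import SurvivalSample, km_fit, rmst_hat, rmst_var
from .switching import SwitchingModel, apply_rpsftm, sample_switch_times, solve_switch_params

__all__ = ["ResolvedScenario", "PowerResult", "resolve_scenario", "simulate_trial", "calculate_power"]


@dataclass(frozen=True)
class ResolvedScenario:
    """A fully calibrated scenario, ready for simulation."""

    config: ScenarioConfig
    design: TrialDesign
    control_model: ArmEventModel
    experimental_model: ArmEventModel
    censoring: CensoringModel
    margin: MarginSpec
    switching: SwitchingModel | None


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power and expected event counts of one scenario."""

    power: float
    E1: float  # mean number of control-arm events per trial
    E2: float  # mean number of experimental-arm events per trial
    mc_se: float  # binomial standard error of the power estimate
    n: int
    n_experimental: int
    n_simulations: int
    seed: int
    delta: float
    config: ScenarioConfig | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_se": self.mc_se,
            "E1": self.E1,
            "E2": self.E2,
            "n": self.n,
            "n_experimental": self.n_experimental,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "delta": self.delta,
        }


def resolve_scenario(config: ScenarioConfig) -> ResolvedScenario:
    """Calibrate every component of a scenario (no randomness involved)."""
    design = TrialDesign(
        Ta=config.Ta,
        Te=config.Te,
        tau=config.tau,
        n=int(config.n),
        r=config.r,
        alpha=config.one_sided_alpha,
        n_simulations=config.n_simulations,
        seed=config.seed,
    )
    control = ArmEventModel.from_median(config.m1, config.shape)
    experimental = ArmEventModel.from_median(config.m2, config.shape)
    if config.censoring_rate == "AC.only":
        censoring = CensoringModel.administrative_only()
    else:
        censoring = CensoringModel.calibrated(
            float(config.censoring_rate), control, design
        )
    margin = resolve_margin(
        control,
        config.tau,
        f1=config.f1,
        f2=config.f2,
        m0=config.m0,
        margin=config.margin,
    )
    switching = None
    if config.ps > 0:
        if config.s_dist is None:
            raise ConfigError("s_dist is required when ps > 0")
        if config.TXswitch == "1to2":
            origin, acceleration = control, config.m2 / config.m1
        else:
            origin, acceleration = experimental, config.m1 / config.m2
        params = solve_switch_params(
            config.s_dist, config.rs, config.rho_s, weibull_moments(origin)
        )
        switching = SwitchingModel(
            s_dist=config.s_dist,
            ps=config.ps,
            acceleration=acceleration,
            direction=config.TXswitch,
            rs=config.rs,
            rho_s=config.rho_s,
            params=params,
        )
    return ResolvedScenario(
        config=config,
        design=design,
        control_model=control,
        experimental_model=experimental,
        censoring=censoring,
        margin=margin,
        switching=switching,
    )


def simulate_trial(
    resolved: ResolvedScenario, rng: np.random.Generator
) -> tuple[SurvivalSample, SurvivalSample]:
    """One intention-to-treat trial: (control, experimental) observed samples.

    Draw order is fixed (entries, event times, censoring, then switching) so
    that switching-related draws never perturb the non-switching part of a
    replicate.  Ties between event and censoring time count as events.
    """
    design = resolved.design
    n1, n2 = design.n, design.n_experimental

    v1 = sample_entry_times(design, n1, rng)
    v2 = sample_entry_times(design, n2, rng)
    t1 = resolved.control_model.sample(n1, rng)
    t2 = resolved.experimental_model.sample(n2, rng)
    c1 = sample_censoring_times(resolved.censoring, v1, design, rng)
    c2 = sample_censoring_times(resolved.censoring, v2, design, rng)

    sw = resolved.switching
    if sw is not None and sw.ps > 0:
        if sw.direction == "1to2":
            flags = rng.random(n1) < sw.ps
            s = sample_switch_times(sw, t1, rng)
            t1 = apply_rpsftm(t1, s, flags, sw.acceleration)
        else:
            flags = rng.random(n2) < sw.ps
            s = sample_switch_times(sw, t2, rng)
            t2 = apply_rpsftm(t2, s, flags, sw.acceleration)

    y1, e1 = np.minimum(t1, c1), t1 <= c1
    y2, e2 = np.minimum(t2, c2), t2 <= c2
    return (
        SurvivalSample(times=y1, events=e1, label="control"),
        SurvivalSample(times=y2, events=e2, label="experimental"),
    )


def calculate_power(
    config: ScenarioConfig | None = None,
    *,
    resolved: ResolvedScenario | None = None,
    n: int | None = None,
    n_simulations: int | None = None,
    seed: int | None = None,
) -> PowerResult:
    """Estimate power (and expected event counts) for one scenario.

    Either a :class:`ScenarioConfig` or an already-resolved scenario may be
    given; ``n``, ``n_simulations`` and ``seed`` optionally override the
    configured values (the sample-size search uses this to re-run a resolved
    scenario on a grid of n without recalibrating).
    """
    if (config is None) == (resolved is None):
        raise ValueError("give exactly one of config or resolved")
    if resolved is None:
        if n is not None or n_simulations is not None or seed is not None:
            config = config.replace(
                **{
                    k: v
                    for k, v in (
                        ("n", n), ("n_simulations", n_simulations), ("seed", seed)
                    )
                    if v is not None
                }
            )
        resolved = resolve_scenario(config)
        n = resolved.design.n
        n_simulations = resolved.design.n_simulations
        seed = resolved.design.seed
    else:
        config = resolved.config
        n = resolved.design.n if n is None else int(n)
        n_simulations = (
            resolved.design.n_simulations if n_simulations is None else n_simulations
        )
        seed = resolved.design.seed if seed is None else seed
        if n != resolved.design.n:
            design = TrialDesign(
                Ta=resolved.design.Ta,
                Te=resolved.design.Te,
                tau=resolved.design.tau,
                n=n,
                r=resolved.design.r,
                alpha=resolved.design.alpha,
                n_simulations=n_simulations,
                seed=seed,
            )
            resolved = ResolvedScenario(
                config=config.replace(n=n, n_simulations=n_simulations, seed=seed),
                design=design,
                control_model=resolved.control_model,
                experimental_model=resolved.experimental_model,
                censoring=resolved.censoring,
                margin=resolved.margin,
                switching=resolved.switching,
            )

    design = resolved.design
    tau = design.tau
    delta = resolved.margin.delta
    z = float(stats.norm.ppf(1.0 - design.alpha))

    streams = np.random.SeedSequence(seed).spawn(n_simulations)
    rejections = 0
    events1 = 0.0
    events2 = 0.0
    for stream in streams:
        rng = np.random.default_rng(stream)
        control, experimental = simulate_trial(resolved, rng)
        curve1 = km_fit(control)
        curve2 = km_fit(experimental)
        delta_hat = rmst_hat(curve2, tau) - rmst_hat(curve1, tau)
        se = np.sqrt(rmst_var(curve1, tau) + rmst_var(curve2, tau))
        if delta_hat - z * se > -delta:
            rejections += 1
        events1 += int(control.events.sum())
        events2 += int(experimental.events.sum())

    power = rejections / n_simulations
    return PowerResult(
        power=power,
        E1=events1 / n_simulations,
        E2=events2 / n_simulations,
        mc_se=float(np.sqrt(power * (1.0 - power) / n_simulations)),
        n=design.n,
        n_experimental=design.n_experimental,
        n_simulations=n_simulations,
        seed=seed,
        delta=delta,
        config=resolved.config,
    )
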