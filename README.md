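# rmstswitch

Monte-Carlo power and sample-size calculation for **non-inferiority (NI)
survival trials with treatment switching (crossover)**, analysed under
intention-to-treat by the **difference in restricted mean survival times
(DRMST)**.

It is written for trial statisticians designing two-arm time-to-event NI
trials in which control-arm participants may cross over to the experimental
treatment (or vice versa) — for example after disease progression — and who
want to preview how that crossover erodes or inflates the power of the ITT
analysis before the trial is run.

## The method

For survival functions S1 (control) and S2 (experimental), the restricted
mean survival time at horizon τ is Ri(τ) = ∫₀^τ Si(t) dt, and the treatment
effect is the difference Δ(τ) = R2(τ) − R1(τ).  Non-inferiority with margin
δ > 0 tests H0: Δ(τ) ≤ −δ against H1: Δ(τ) > −δ and rejects, at one-sided
level α, when

    Δ̂(τ) − z₁₋α · SE(Δ̂(τ)) > −δ,

with R̂i(τ) the area under the Kaplan–Meier curve and its product-limit
(Greenwood-type) variance.  The margin can be set three ways: as a preserved
fraction f1 of the control RMST, δ = (1 − f1) R1(τ); as a preserved fraction
f2 of the control-vs-placebo difference, δ = (1 − f2)(R1(τ) − R0(τ)); or by
converting a proportional-hazards margin 1/θ, δ = R1(τ) − ∫₀^τ S1(t)^{1/θ} dt.

Trials are simulated with uniform accrual on [0, Ta], Weibull event times
with common shape and medians m1, m2, and censoring that combines uniform
U(0, h) dropout with administrative censoring at Te − entry; h is calibrated
so the control arm attains a requested total censoring rate.  A control-arm
subject switches with probability ps at a random switching time s (uniform,
beta, or gamma multiple of their event time, independent exponential, or a
constant), calibrated from rs = E(s)/E(T1) and the correlation ρs; from the
switch onward survival is stretched by m2/m1 (the rank-preserving structural
failure time model, used generatively).  Power is the rejection fraction
over simulated trials; the required sample size inverts a monotone smoothed
(isotonic + shape-preserving spline) power curve over a grid of n.

## Worked example

An NI trial with medians m1 = 6.0 and m2 = 6.4 months (exponential event
times), instant accrual, 26-month duration, RMST compared at τ = 12 months
with margin δ = 0.2·R1(12), 5% control censoring, and one-sided α = 0.005:

```bash
rmstswitch power --n 232 --m1 6.0 --m2 6.4 --shape 1 --ta 0 --te 26 \
    --tau 12 --f1 0.8 --censoring-rate 0.05 --one-sided-alpha 0.005 \
    --n-simulations 2000 --seed 7
```

```json
{
  "power": 0.8875,
  "mc_se": 0.007065541380531291,
  "E1": 220.4515,
  "E2": 218.077,
  "n": 232,
  "n_experimental": 232,
  "n_simulations": 2000,
  "seed": 7,
  "delta": 1.2984255368000668
}
```

With 232 participants per arm the trial has ≈ 89% power (Monte-Carlo SE
0.7%); about 220 control-arm and 218 experimental-arm events are expected,
and the resolved margin is δ = 1.298 months.  Adding heavy crossover —
switching probability ps = 0.89 at a gamma-family switching time with
rs = 0.3 and ρs = 0.5 (`--ps 0.89 --rs 0.3 --rho-s 0.5 --s-dist gamma`) —
drops the power to 0.8045: the ITT contrast is diluted because most control
participants eventually receive the experimental treatment.

The same API is available from Python:

```python
from rmstswitch import ScenarioConfig, SizeSearchSpec, calculate_power, calculate_size

config = ScenarioConfig(n=100, m1=1.0, m2=1.1, shape=1.0, Ta=3.0, Te=5.0,
                        tau=5.0, f2=0.5, m0=0.5, censoring_rate=0.2,
                        one_sided_alpha=0.025, n_simulations=2000, seed=7)
result = calculate_size(config, SizeSearchSpec(nL=100, nU=250, B=10, epwr=0.8))
print(result.n_required)   # -> 154
```

i.e. roughly 154 control-arm participants (and as many experimental, r = 1)
give 80% power in that design.  Other subcommands: `rmstswitch size`
(sample-size search with a grid CSV), `rmstswitch test` (standalone DRMST NI
test on a `time,event,arm` CSV), `rmstswitch fixture` (small demonstration
datasets), and `rmstswitch batch` (a YAML list of scenarios to a results
table).

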