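# Methods

This note documents the statistical model behind `rmstswitch`, the
calibration steps, the numerical choices, and the limits of what the test
suite demonstrates.

## Trial model

A two-arm randomized trial is simulated subject by subject.

**Accrual and follow-up.** Entry times are uniform on `[0, Ta]` (all zero
when `Ta = 0`).  The trial ends at calendar time `Te ≥ Ta`, so a subject
entering at `v` has at most `Te − v` of follow-up; the RMST horizon must
satisfy `τ ≤ Te`.  The control arm holds `n` subjects and the experimental
arm `round(r·n)` (half-away-from-zero; the allocation ratio `r` is
experimental:control).

**Event times.** Both arms are Weibull with a common shape `k` and medians
`m1`, `m2`, so `scale_i = m_i / (log 2)^{1/k}`.  Proportional hazards holds
within this family, which keeps hazard-ratio-based margins meaningful.  When
the shape is not given directly it can be recovered from the median plus a
survival probability at a reference time; the two defining equations reduce
to the closed form `k = log(log S_ref / log ½) / log(t_ref / m)`, which is
rejected as under-determined when the reference point *is* the median at 50%
and as infeasible when no positive shape fits.

**Censoring.** Both arms share one censoring law
`C = min(U(0, h), Te − v)`.  With `censoring_rate = "AC.only"` there is no
dropout (`h = ∞`).  With a numeric rate `q`, `h` solves

    P(C < T1) = q      (control arm, no switching),

where, conditional on `v`, `P(C < T1 | v) = [∫₀^{min(h, A)} S1(u) du +
max(h − A, 0)·S1(A)] / h` with `A = Te − v`.  The inner integral is the
Weibull lower incomplete gamma (evaluated exactly); the outer average over
`v` uses adaptive quadrature (tolerance 1e−10); the root in `h` is found by
bracketed Brent iteration after doubling the upper bracket (the probability
decreases from 1 at `h → 0` to the administrative-only floor
`E_v[S1(Te − v)]` at `h → ∞`).  A rate at or below that floor is reported as
infeasible rather than silently clipped.  Note the calibrated rate is the
*total* censoring probability — dropout plus administrative — which is why,
absent switching, the expected control event count is `n(1 − q)`.

## Treatment switching

With probability `ps` (an independent Bernoulli draw per subject of the
switching arm) a subject becomes a switcher at switching time `s`.  Five
families for `s` are available:

| family     | construction                    | free parameters          |
|------------|---------------------------------|--------------------------|
| `unif`     | `s = U(0,1) · T`                | none (forces rs = 0.5)   |
| `beta`     | `s = Beta(a, b) · T`            | a, b from (rs, ρs)       |
| `gamma`    | `s = Gamma(a, rate b) · T`      | a, b from (rs, ρs)       |
| `indepExp` | `s ~ Exp(rate b)`, independent  | b = 1/(rs · E(T))        |
| constant   | `s ≡ c` (e.g. 0: switch at start) | none                   |

`T` is the subject's own latent event time in the origin arm, so the first
three families make `s` positively correlated with survival, and `s < T`
always holds for `unif`/`beta`.  Calibration uses two moments of the origin
arm's Weibull law: `rs = E(s)/E(T)` and the exact Pearson correlation.
Because `s = X·T` with `X ⫫ T`,

    cov(s, T) = E(X)·Var(T),
    Var(s)    = Var(X)·E(T²) + E(X)²·Var(T),
    ρs        = cov(s, T) / (sd(s)·sd(T)).

The mean constraint pins `E(X) = rs` (`b = a(1−rs)/rs` for beta, `b = a/rs`
for gamma) and the remaining parameter is found by a monotone 1-D root-find
in `log a`; the correlation increases from a family-specific floor (named in
the error message when `ρs` is unattainable) to 1.  For exponential event
times the gamma solution has the closed form `a = 2ρs²/(1 − ρs²)`, used as
an oracle in the tests; the beta family at `rs = 0.5, ρs = 0.7746`
degenerates to `Beta(1,1) = U(0,1)`.

**Effect of switching.** From the switch onward, residual survival is
stretched by the acceleration factor — the destination:origin median ratio
(`m2/m1` for control→experimental switching, `m1/m2` for the `2to1`
mirror):

    T* = s + (T − s) · acceleration    if switching and s < T,   else T.

This is the rank-preserving structural failure time model used generatively
(a common treatment effect for all switchers).  Subjects whose drawn `s`
exceeds `T` experienced the event first and never switch; their Bernoulli
draw is not re-used.  For the `2to1` direction the switching-time moments
(`rs`, `ρs`) refer to the experimental arm's event-time law.  Observables
are `Y = min(T*, C)` with event indicator `T* ≤ C` (a tie counts as an
event), labelled by the randomized arm (intention-to-treat).

## Estimation and test

The Kaplan–Meier curve is computed by the product-limit formula with the
standard tie convention (censored observations tied with an event time are
at risk for it).  `R̂(τ)` is the exact area under the step function on
`[0, τ]`, carrying the last value forward if the largest observation
precedes `τ`.  Its variance is the product-limit form

    Var(R̂(τ)) = Σ_{t_i ≤ τ} [∫_{t_i}^{τ} Ŝ(t) dt]² · d_i / (n_i (n_i − d_i)),

dropping terms with `n_i = d_i`.  The point estimates agree with
`lifelines` to machine precision in the test suite, and the variance is
validated against a bootstrap oracle.  The NI test rejects when
`Δ̂(τ) − z_{1−α}·SE > −δ` (strict inequality; `SE = √(Var₁ + Var₂)`).

## Power and sample size

`calculate_power` simulates `n_simulations` independent trials and reports
the rejection fraction, its binomial standard error, and the mean event
counts `E1`, `E2` from the same replicates.  The root seed is expanded via
`numpy.random.SeedSequence.spawn` into one stream per replicate, so results
are bit-identical for a fixed seed and invariant to execution order.
Switching-related draws happen after the core trial draws, so with
`m1 = m2` (acceleration 1) switching provably leaves every observable — and
the power — unchanged, a property the tests assert exactly.

`calculate_size` evaluates power on the grid `n = nL + k·w`, `k = 0..B`,
`w = round((nU − nL)/B)` (deduplicated if degenerate), each grid point with
its own seed derived from the root seed and `n`.  A monotone nondecreasing
power curve is then fitted: isotonic regression (pool-adjacent-violators)
at the grid points — which interpolates already-monotone points exactly —
joined by a PCHIP shape-preserving cubic, so the curve is continuous,
nondecreasing, and confined to `[0, 1]` without overshoot.  The required
sample size is the smallest integer in `[nL, nU]` whose fitted power
reaches `epwr`; a curve that never reaches `epwr` raises an error asking
for a larger `nU`, and a curve already above `epwr` at `nL` returns `nL`
with a warning to lower the bound.  Default `B = 10` (11 grid points)
balances grid resolution against simulation cost.  Recomputing power at the
returned `n` lands within about two percentage points of `epwr` (asserted
in the tests), consistent with the Monte-Carlo noise of the grid.

## Defaults and problem sizes

* `n_simulations = 5000` — power SE ≤ 0.7 points; used for all direct power
  and event-count estimates in tests and the acceptance script.
* Sample-size searches use 2000 replicates per grid point (11 points), a
  deliberate cost/precision trade-off: the isotonic-spline fit pools
  information across the grid, leaving a residual uncertainty of a few
  participants in the returned `n`.
* `one_sided_alpha` defaults to 0.025, `TXswitch` to `"1to2"`,
  `censoring_rate` to `"AC.only"`.

## What the simulations do and do not emulate

The generator reproduces the design assumptions exactly: uniform accrual,
common-shape Weibull events, non-informative uniform-plus-administrative
censoring identical in both arms, switching with a common treatment effect,
and a marginal switch probability independent of prognosis given the
switching time.  Real trials can violate any of these — switchers are often
prognostically worse (a constant attenuating the acceleration factor can be
emulated by passing an adjusted `m2`), censoring can be informative, and
accrual is rarely uniform — so passing tests demonstrate correctness of the
calculation under the stated model, not robustness of a design to
model misspecification.

## Known limitations

* Event times are restricted to the common-shape Weibull family
  (three-parameter families are deliberately out of scope).
* Per-protocol analyses, covariate adjustment, two-sided or superiority
  tests, and estimation of the structural model from observed data are not
  provided; the structural model is generative only.
* The margin is fixed at a single horizon τ; time-varying margins are not
  supported.
* Power inversion searches a user-supplied bracket `[nL, nU]` with a fixed
  grid; it does not adaptively refine, and no optimization over the
  allocation ratio is attempted.
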