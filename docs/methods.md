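# Methods

## Model

An organism is represented as `N` interchangeable subsystems, each either
intact or failed. Failures are interdependent: each intact subsystem fails at
rate `r * f`, proportional to the current failed count `f` (with `r` in
1/(year·subsystem)). The total failure intensity of the organism in state `f`
is therefore

    w(f) = r * f * (N - f).

Death is not tied to a fixed damage threshold: any of many subsystem-failure
combinations can be fatal, and the probability that an individual's current
state is fatal is taken proportional to its failed fraction, giving the
individual hazard

    mu_i(t) = k * f_i(t) / N.

**Mean field.** Averaging gives the logistic ODE `dF/dt = r F (N - F)` with
solution `F(t) = N F0 / (F0 + (N - F0) e^{-rNt})`. While `F/N` is small,
`F ≈ F0 e^{rNt}`, so the population hazard is Gompertzian,
`mu ≈ R0 e^{bt}` with `b = rN` and `R0 = k F0/N`. The exponential regime
ends at the inflection age `tau = ln(N/F0 - 1)/(rN)`, where `F(tau) = N/2`;
beyond it the hazard saturates at `k` (late-life mortality deceleration).
Requiring the Gompertz window to cover a human lifespan forces `F0/N` to be
very small (~1e-5 for `tau` in the thousands of years).

**Hazard-scale convention.** Only proportionality between hazard and failed
fraction is part of the model; the constant is fixed here by `k = R0 N / F0`
so that `mu(0) = R0` exactly. This is the unique convention under which a
printed `(R0, b)` pair fully specifies the hazard, and it is what
`HazardScale.from_r0` implements.

**Stochastic version.** The failed count is a Markov pure-birth chain with
intensity `w(f)` (a birth-death chain once repair is enabled). Trajectories
are simulated exactly (Gillespie): exponential waiting times with the current
total rate, no time discretisation. When `epsilon = alpha = 0` the state
ladder is deterministic (`f0, f0+1, ...`), so waiting times are drawn in
vectorised blocks — mathematically identical to the event loop. A fixed-step
binomial-thinning scheme (`scheme="fixed"`, per-step failure probability
`r (f + eps N) dt` per intact subsystem) is provided purely as a
cross-check; unit events within a step are spread at sorted uniform times so
trajectory invariants (strictly increasing event times, ±1 steps) hold.

Death times are drawn from each trajectory's own hazard, which is piecewise
constant between events: a unit-exponential threshold is compared against the
accumulated hazard segment by segment (exact, no discretisation). Coupling is
one-way — death draws never alter failure dynamics — so cohort statistics can
ignore deaths entirely (`ignore_deaths`, avoiding right censoring) or censor
individuals at death (`censor_at_death`).

**Master equation.** `P(f,t)` obeys the linear system
`dP(f)/dt = w(f-1)P(f-1) - w(f)P(f)` (plus `alpha` terms for repair). In the
Gompertz regime the occupied states remain tiny relative to `N`, so the
generator is built on a truncated support `0..f_max` with an explicit
absorbing leak state that accumulates the truncated flux. Defaults:
`f_max = max(50, 20 * F0 * e^{rN t_end})` capped at `min(N, 40000)`;
integration by BDF with the (constant, sparse) generator as Jacobian,
rtol 1e-9 / atol 1e-14; if leak mass exceeds 1e-6 at any output time the
support is doubled and the solve repeated. The returned `(P, leak)` pair is
renormalised by its total at each output time (a projection onto the
conserved-mass manifold), so conservation holds to 1e-12 regardless of
integrator drift. The forward-Euler `discrete_time_step` (jump probability
capped at 0.1 per state) exists for cross-validation and converges to the
adaptive solution at first order. The discrete median uses the
smallest-`f`-with-CDF ≥ 0.5 convention.

**Linear noise approximation.** The system-size expansion gives the logistic
mean and the variance ODE `dV/dt = 2r(N - 2<f>)V + r<f>(N - <f>)`. With zero
initial variance and `t << tau` this has the closed form
`V = f0 e^{2rNt}(1 - e^{-rNt})`. The general variance is realised numerically
(LSODA, rtol 1e-9) rather than as a transcribed closed form; the ODE path is
the ground truth outside the early-age regime, and the closed form warns
beyond `tau/4`. Note `d ln V/dt = rN (2e^{rNt} - 1)/(e^{rNt} - 1)`, which
decreases monotonically toward `2rN` from above: the variance grows almost
exponentially but always slower than `f0 e^{2rNt}`.

**Model alterations.** Spontaneous failure adds `r * epsilon * N` to every
intact subsystem's rate; the mean-field ODE `dF/dt = r(F + epsN)(N - F)` is
integrated adaptively (the shifted variable `G = F + epsN` is logistic with
capacity `N(1+eps)`, used as a test oracle). When `epsN >> F0` early growth
is linear, not exponential — the hazard degenerates toward the
constant-failure-rate null model, whose log-hazard slope `C(N-F)/F` is
strictly decreasing (non-Gompertzian). Repair at rate `alpha` per failed
subsystem is absorbed into an effective capacity `N' = N - alpha/r`
(`apply_repair`); when `N' <= max(F0, 1)` the function warns ("sub-critical")
and returns `None` rather than an invalid parameter set.

## Calibration

`empirical_hazard` bins ages at death (closed cohort observed from age 0)
into half-open bins and computes person-year exposure as the time lived
inside each bin; hazard = deaths/exposure. `fit_gompertz` runs unweighted OLS
of `ln(hazard)` on bin midpoints — the simplest defensible estimator;
Poisson-likelihood weighting would be a natural extension but is not the
default. The default fit window is 0–100 years (the human-relevant range).
`map_to_micc` inverts the parameter map: `r = b/N`, `F0 = round(f0_frac N)`
(≥ 1), `k = R0 N/F0`, warning when the implied `tau` falls inside the fit
window.

**Lag-correction factor.** The median (and mean) of the stochastic model lag
slightly behind the mean-field curve, so stochastic simulations use
`rN = b / 0.977` under the Danish calibration. `estimate_lag_factor`
reproduces this number: simulate ≥ 1000 trajectories with deaths ignored,
take the median failed count at yearly ages, fit the exponential growth rate
of the log median over the window (default 0–150 y), and report
`slope / (rN)` with a trajectory-resampling bootstrap SE. The regression is
anchored at the known initial condition `ln F0` by default
(`intercept="fixed"`): every individual starts at exactly `F0`, so the
intercept is not a free parameter. This choice matters — free-intercept OLS
absorbs almost all of the median's lag into the intercept and returns a
ratio ≈ 0.994, whereas the anchored fit gives ≈ 0.973 under the Danish
calibration (analytic pure-birth value 0.9729; the endpoint projection
`ln(med(150)/F0)/(150 rN)` gives 0.9772). The median is used rather than the
mean because the mean of the near-linear birth process is unbiased (ratio 1
by construction); the lag resides in the typical trajectory.

## Synthetic data

The fixture generator stands in for register-style lifespan data (one age at
death per person) so that no external data are ever required. Mode
`analytic` inverts the closed-form cumulative hazard
`(k/b) ln((F0 e^{bt} + N - F0)/N)` against unit-exponential draws — exact
samples from the model's lifespan distribution. Mode `stochastic` runs full
event-driven cohorts with death events and writes censoring counts to the
sidecar. What the generator does **not** emulate: period/cohort structure,
parameter heterogeneity between individuals, infant/accident mortality
humps, or measurement error in recorded ages — passing recovery tests shows
the estimators are correct under the model, not that the model fits any
particular population.

Two parameter regimes are used deliberately. The published Danish calibration
(`b = 9.24e-3`/yr, `R0 = 4.2e-5`/yr, `N = 1e6`, `F0/N = 1e-5`) defines all
simulation conditions tied to published quantities. Under the `mu(0) = R0`
scale convention this hazard is shallow — survival to age 150 is ≈ 0.987 —
so lifespan-distribution checks run cohorts to age 1000, where essentially
everyone has died. Parameter-recovery checks on register-style data instead
use a realistic human Gompertz set (`R0 = 1e-4`/yr, `b = 0.09`/yr), chosen
once so that deaths concentrate at 60–100 years and every yearly bin in the
fit window is populated at n = 1e5.

## Numerical choices and problem sizes

- Adaptive integrations: rtol 1e-9 (mean-field/LNA), BDF rtol 1e-9 for the
  master equation; fixed-step RK4 appears only as an independent oracle in
  tests.
- Cumulative hazard in log space via `logaddexp`, anchored at its `t = 0`
  value so `S(0) = 1` exactly; no overflow for arbitrarily large `bt`.
- Reproducibility: cohorts derive per-individual streams by spawning
  `SeedSequence(master_seed)`; each individual's stream drives its trajectory
  first, then its death draw, so results are order-independent and
  bit-reproducible.
- Monte-Carlo sizes in the shipped tests: 2e4 trajectories for
  distribution-level comparisons at `N = 200`; 1e4–2e4 trajectories for
  `N = 1e6` cohort means and the lag factor (the lag estimator uses 2e4
  because the integer-valued median quantises, leaving ~0.002 bootstrap SE);
  220 for the published cohort size; 1e5 synthetic deaths for hazard
  recovery.
- Chi-square comparisons pool adjacent states to expected counts ≥ 5 and fold
  truncated tail mass into the last state; KS tests use the exact closed-form
  CDF.

## Known limitations

- No network structure: the model is a fully connected, uniformly weighted
  interaction graph; clustered or scale-free damage propagation is out of
  scope.
- No between-individual parameter heterogeneity; all individuals share
  `(N, r, F0)` and differ only through stochastic event timing.
- The analytic lifespan density uses the mean-field hazard; individual
  trajectory heterogeneity makes true cohort survival slightly heavier-tailed
  (a frailty effect of order 1e-2 in CDF under the Danish calibration).
- `biological_age` maps `f = N` to infinity and rejects counts below `F0`;
  it presumes the projection target is the base-model mean.
- The repair variant's effective-capacity reduction is exact for the mean
  field but only approximate for higher moments.
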