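# Methods

## Model

The unit of analysis is one year (2012) in nine coastal sub-areas of the
central and northern Baltic (E1–E3 Estonia, F1–F3 Finland, S1–S3 Sweden),
each assumed internally homogeneous in seal abundance and gear use.  Two
gear classes matter for grey-seal by-catch: trap nets (effort in
gear-days; active in every sub-area) and gill nets (effort in km-days;
by-catch-relevant only in S1 and S2).

**Survival model.**  By-catch mortality is assumed additive to natural
mortality and memoryless in effort: given catchability `C_{g,a}` (the
per-unit-effort hazard of dying in gear `g` in sub-area `a`), the effort
a seal survives is exponentially distributed.  With several gears acting
simultaneously the hazards add, the year-survival probability is
`exp(-h)` with `h = sum_g C_{g,a} E_{g,a}`, and the death probability in
gear `g` is the competing-risks allocation `(C_g E_g / h) (1 - exp(-h))`.
This is the unique allocation consistent with additive exponential
hazards; it also makes predictions consistent under splitting the year's
effort into a surveyed and a remaining phase (the memoryless
factorization property verified by exhaustive enumeration in the tests).

**Observation model.**  The survey covers a known fraction of each
slot's effort.  Given the average number of seals `N_a` present, the
vector (deaths per sampled gear, survivors) under the *sampled* efforts
is multinomial.  Reported counts are treated as true counts; the
under-reporting concern is handled by a scenario analysis and by the
synthetic generator, not inside the likelihood.

**Priors.**
* `N_tot` (seals alive bar by-catch): log-normal, 5%/95% quantiles
  28 000 / 40 000.  The 2012 moult count (28 255) is taken as a
  conservative minimum; dividing by the lowest plausible counting
  efficiency (0.70) gives the optimistic maximum.  Mean ≈ 34 000.
* Allocation `(N_a)`: Dirichlet-multinomial over the nine sub-areas plus
  an explicit residual "outside study area" category (expected share
  0.11), so the composition is proper while the residual never touches
  the likelihood.  The base vector is the expected-proportion column of
  the survey table; the scale (s ≈ 226) is calibrated by root-finding so
  the Beta marginal of the largest sub-area, F2, puts 90% mass between
  its minimum and maximum estimates (0.25–0.35).  Because relative
  Dirichlet dispersion grows as proportions shrink, small sub-areas end
  up with less of their band covered (~56% for E1/E2) — an emergent
  property, not a target.
* Catchabilities: one shared hierarchy `ln C_{g,a} ~ N(mu, sigma2)`
  across both gears and all areas.  `mu` is Gaussian with
  `exp(mu)` median 1.5e-6 and 95% below 1e-5 (in original effort units);
  the anchors come from expert elicitation: a common catchability of
  1.5e-6 reproduces the experts' central guess of ~1200 dead seals per
  year, 8e-6 a pessimistic ~5500.  `sigma2` is scaled inverse-chi-squared
  with 4 degrees of freedom and scale 1.  A config option allows
  gear-specific hyper-means; it is off by default because trap and gill
  catchabilities are on comparable scales once efforts are in their
  native units.

**Effort scaling.**  Efforts are multiplied by 1e-4 inside the
likelihood (catchabilities correspondingly by 1e4) so log-catchabilities
sit in a well-conditioned range; every reported catchability is
transformed back to original units at the API boundary.

## Sampling

Blockwise random-walk Metropolis–Hastings:

1. per sub-area, the (1–2) log-catchabilities jointly, Gaussian steps;
2. `(mu, log sigma2)` jointly, with the log-walk Jacobian in the ratio;
3. `ln N_tot`, with the induced change in `round(N_tot)` absorbed by the
   residual allocation count — the move is invertible, so only the
   log-walk Jacobian enters, and the constraint
   `sum_a N_a = round(N_tot)` holds exactly at all times;
4. ten paired integer transfers between two random allocation
   categories per iteration (symmetric, feasibility-bounded by the
   observed by-catch in each area).

Proposal scales (and the transfer step size) adapt by Robbins–Monro
towards 30% acceptance during burn-in and are frozen afterwards, so the
retained chain is time-homogeneous.  Defaults: 4 chains × 50 000
iterations, 20 000 burn-in, thinning 10 — the full analysis runs in
about two minutes on one CPU.  Chains are seeded via
`numpy.random.SeedSequence(seed).spawn`, making runs bit-reproducible.
Convergence is summarised by rank-normalised split-Rhat and bulk ESS
(via arviz), flagging Rhat > 1.05.  Sampler validity is tested by prior
recovery (likelihood disabled, marginals checked against their analytic
priors on the probability scale with ESS-scaled tolerances) and by
simulation-based calibration with the truth redrawn from the priors,
where 90% intervals must cover at their nominal rate.

The starting state is deterministic: prior means for `N_tot` and the
allocation (repaired to sum exactly and to dominate the observed
counts), moment estimates `ln(y / (N_a E))` for catchabilities with
observed by-catch, hyper-prior medians elsewhere.

## Prediction

Per posterior draw, the survivors of the sampled effort
(`N_a - sum_g y_{g,a}`) are exposed to the remaining effort
(total − sampled) under the same competing-risks multinomial — valid by
the memoryless factorization.  Slots with survey information use the
draw's catchability; slots without any sampled effort (trap nets in F3,
S1, S3) draw `ln C` from `N(mu, sigma2)` at the draw's hyperparameters.
Both exposure kinds compete jointly within a sub-area (relevant in S1,
where gill nets are surveyed but trap nets are not).  The reported total
is always the observed survey count (339) plus all predicted components,
additive draw by draw.  Hazard shares are computed in log space and the
survival cell clamped at zero so saturating predictive hazards cannot
produce invalid multinomial probabilities.

Quantiles use numpy's default linear interpolation between order
statistics.  The reporting layer optionally rounds counts to the nearest
10; raw draws are always retained.

## Scenario and sensitivity runs

The sensitivity grid refits the model with the population prior mean
halved/raised 50%, the expected proportion of F2/S1/S2 moved ±30%
(renormalised), and the catchability hyper-mean scale halved/doubled.

The F2 counterfactual asks what the totals would be if F2's trap-net
catchability resembled its neighbours' (F2 reported only 5 dead seals
despite holding ~30% of the population and a third of all trap effort).
Two definitions are provided.  The default *refit* ties F2's trap
catchability to a donor area's parameter (F1 or S2) and re-runs the
MCMC, so F2's own survey data informs the shared value; reporting both
donors brackets the counterfactual.  The alternative *replace* mode
substitutes, draw by draw, a donor draw for F2's catchability without
refitting.  Replace is simpler but ignores that F2's 5 observed deaths
are strong evidence about any catchability attributed to it, and with
donors whose posteriors sit near 4e-6 it implies implausibly large
Finnish totals; the refit is therefore the default.

## Synthetic data

The generator mirrors the fitted hierarchy exactly: multinomial
allocation of `N_tot` over sub-areas, competing-risks multinomial deaths
under the sampled efforts, sequential exposure of survivors to the
remaining effort (giving the latent true yearly by-catch), and optional
per-country binomial thinning of the *reported* counts to emulate
under-reporting.  Default conditions reproduce the 2012 study design:
its efforts, survey coverage fractions, expected proportions,
`N_tot = 34 000`, and a common catchability of 1.5e-6 (the expert
central anchor).  What the generator does not emulate: seasonal effort
structure, fisherman-level heterogeneity within a sub-area,
gear-selective reporting, or mis-recorded effort — so passing recovery
tests demonstrate internal consistency of the estimator, not robustness
to those real-world features.

## Numerical and design notes

* The Dirichlet-multinomial log-pmf is written directly with `gammaln`
  because the sampler needs cheap two-category deltas; it is cross-checked
  in the tests against `scipy.stats.dirichlet_multinomial` and against
  brute-force enumeration.
* `N_a` are latent integers; `N_tot` stays continuous with
  `round(N_tot)` as the multinomial total, keeping the log-normal prior
  exact while making the allocation well-defined.
* Degenerate inputs: zero elicitation intervals give point-mass priors
  (scale 0); a zero-coverage survey contributes nothing to the
  likelihood; empty post-burn-in runs return a valid empty chain;
  unreachable Dirichlet calibration targets raise with the achievable
  coverage range.
* Test problem sizes: the shared test fit uses 2 chains × 25 000
  iterations; simulation-based calibration uses 50 replicates at 6 000
  iterations each; property checks enumerate exhaustively at N ≤ 20.
  These sizes keep the full suite under a few minutes while leaving
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The upper tail of the total by-catch is dominated by the predictive
  catchability in unsurveyed slots and is therefore sensitive to the
  `sigma2` hyperprior; the scaled-Inv-chi2(4, 1) choice implies an
  across-area coefficient of variation with median ≈ 1.5 and a long
  right tail, and a tighter variance prior would lighten the predicted
  extremes.  Point summaries and surveyed-area intervals are far less
  sensitive (see the sensitivity runner).
* Reported counts are taken at face value; systematic under-reporting
  biases country totals downward, which is why the F2 scenario and the
  generator's thinning mechanism exist.
* The model is annual-average: no within-year interaction between seal
  movement and effort timing.
* No extrapolation beyond the nine sub-areas is attempted; the residual
  population category carries no effort by construction.
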