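# Methods

`itcvigour` implements a complete, self-contained analysis of intertemporal
choice with concurrent motor-vigour and gaze measures: hierarchical Bayesian
fitting of hyperbolic-discounting choice models (softmax and drift-diffusion
variants), trial-wise Gaussian modelling of grip-force pulses, and
hierarchical regressions linking decision conflict and subjective value to
response vigour and fixation shifts.  Because no behavioural dataset ships
with the package, every analysis runs on synthetic cohorts generated by the
package itself from explicit ground truth; all empirical claims in this
note are therefore claims about parameter recovery and internal
consistency, not about any particular dataset.

## Task design

A trial offers a smaller-sooner (SS) amount, available immediately, against
a larger-later (LL) amount `A = ss_amount * ratio` paid after a delay.  The
default grid crosses two SS magnitudes (10 EUR *low*, 20 EUR *high*
condition), sixteen LL/SS ratios
(1.03, 1.05, 1.10, 1.15, 1.20, 1.25, 1.35, 1.45, 1.50, 1.70, 1.90, 2.20,
2.50, 2.90, 3.30, 3.80) and six delays (1, 7, 13, 31, 58, 122 days),
giving 192 trials per subject.  Trial order and LL screen side are permuted
per subject under the cohort seed.

## Valuation and choice models

**Hyperbolic discounting.**  The subjective value of the delayed option is

    SV(LL) = A / (1 + exp(k + I*s) * IRI)

with `k` the log-space discount rate of the low condition, `s` an additive
shift of log(k) in the high condition (the magnitude effect: `s < 0` means
larger rewards are discounted less), `I` the 0/1 condition indicator and
`IRI` the delay in days.  The shift enters the exponent — `exp(k + I*s)`
multiplies the delay — which is the standard log-scale parametrisation of
hyperbolic discounting.  SS is immediate, so `SV(SS)` is its amount.

**Softmax.**  P(LL) is the logistic of `beta * (SV(LL) - SV(SS))`, computed
in log-space via the value difference; this matters because under
per-condition value normalisation the fitted inverse temperature is around
27 and the naive two-exponential form overflows.

**Drift diffusion.**  Choices and response times follow a two-boundary
Wiener process with boundary separation `alpha` (lower boundary = SS,
upper = LL; stimulus coding, SS response times negated), start fraction
`z` in (0,1) (`z = 0.5` unbiased, below 0.5 biased toward SS),
non-decision time `tau` (s) and drift `v` (evidence/s, positive toward
LL).  Drift variants:

* `null` — constant per-subject drift;
* `linear` — `v_t = v_coeff * dSV_t`;
* `sigmoid` — `v_t = S(v_coeff * dSV_t)` with
  `S(m) = 2*v_max/(1+exp(-m)) - v_max` (equivalently `v_max*tanh(m/2)`),
  bounding drift at ±`v_max`;
* `sigmoid-shift` — additive high-condition shifts `s_alpha, s_tau, s_z,
  s_vcoeff, s_vmax` on the respective parameters.  The drift of this
  variant comes entirely from the sigmoid mapping; no separate base-drift
  shift is estimated (none is identifiable alongside the mapping, and the
  reduced parameterisation matches the reported model summaries).

Values enter either in euros (`absolute`) or divided by the largest LL
amount of the trial's condition (38/76 EUR; `normalised`).

**WFPT density.**  The first-passage density is evaluated with the standard
small-time/large-time series decomposition of the normalised density, the
branch chosen per evaluation by comparing the number of terms each series
needs for truncation error ≤ 1e-7.  The upper-boundary density uses the
reflection identity (`z -> 1-z`, `v -> -v`).  Response times at or below
`tau` receive zero density (log-density −inf) rather than an exception:
preprocessing should have removed them, and during sampling an invalid
proposal is then rejected naturally.

**Diffusion simulation.**  First passages are simulated by Euler–Maruyama
with a Brownian-bridge boundary-crossing correction applied at every step
(the probability that the within-step bridge crossed either boundary is
evaluated in closed form), which removes the leading O(sqrt(dt))
first-passage bias.  At the default `dt = 1e-3` s the simulated signed-RT
distribution is indistinguishable from the analytic density at n = 1e5
(Kolmogorov–Smirnov distance ≈ 0.004, the pure sampling-noise level);
`dt` is a parameter for users who want to verify this trade-off.

## Hierarchical estimation

Subject-level parameters live on unconstrained sampling scales — log for
strictly positive quantities (`alpha`, `tau`, `beta`, `v_coeff`, `v_max`),
logit for `z`, identity for `log(k)`, `s` and the condition shifts — and
are drawn from group Gaussians on those scales.  Hyperpriors are weakly
informative: group means Normal(0, 10²) (the log(k) mean centred at −4,
the empirically sensible region for day-scaled delays), group SDs
half-Normal(0, 2²).

The sampler is Metropolis-within-Gibbs:

* subject-level parameters — vectorised random-walk Metropolis, one
  parameter block at a time across all subjects (subjects are independent
  given the group level), proposal scales adapted toward ~44% acceptance
  during burn-in only, so retained draws come from a fixed kernel;
* group means — exact conjugate normal-normal Gibbs draws;
* group SDs — univariate slice sampling on log(sigma).

Defaults: the **desk profile** (2 chains, 2,000 burn-in, 2,000 retained
draws) used by the bundled analyses; a **reduced profile**
(1,500/1,500) for the costlier DDM fits; and a **full profile**
(2 chains, 50,000 burn-in, thinning 2) for users who want classic
long-run JAGS-style settings.  Convergence is summarised by classic split R-hat and a
Geyer initial-positive-sequence effective sample size per group-level
parameter; a fit with any R-hat above 1.01 is flagged, never silently
accepted.  Group means of log/logit-sampled parameters are reported on the
natural scale as the back-transform of the posterior-mean group mean
(i.e. the posterior median of the natural-scale group location).

**DIC.**  `DIC = Dbar + pD` with `pD = Dbar − D(theta_bar)`, deviance
`D = −2 log L` evaluated at the subject-level likelihood, and `theta_bar`
the posterior mean of the subject-level parameters on the unconstrained
scale (the common convention; the plug-in point is documented because DIC
is not invariant to it).

**Posterior predictive RTs.**  Signed-RT datasets are simulated from
random posterior draws (full cohort per draw), pooled per subject and
kernel-smoothed (Gaussian KDE).  The bundled analysis uses 100 simulated
datasets; the original-scale 10,000 is a parameter.

## Synthetic cohorts

`GeneratingTruth` holds natural-scale group means, group SDs on the
sampling scales, and the vigour couplings.  Default group means are the
published group-level posterior means for this task family (softmax:
log(k) = −4.44, s = −0.80, beta = 0.43 absolute / −4.44, −0.74, 27.23
normalised; sigmoid DDM, absolute values: alpha = 3.27, tau = 1.23 s,
z = 0.51, v_coeff = 0.77, v_max = 1.07, log(k) = −4.45, s = −0.82).
Group SDs are not reported for that study; the defaults are 0.5 for
log(k) and 0.3 for everything else on the sampling scale — heterogeneity
typical of hierarchical discounting fits.  Bounded parameters are drawn on
the unconstrained scale and back-transformed, so the group-Gaussian
statement holds exactly on the sampling scale.

**Grip pulses.**  Each trial's force trace is a Gaussian pulse
`a*exp(-((t-b)/c)^2) + h` at 2000 Hz: amplitude (fraction of MVC)
`a = 0.2142 + 0.02*z(value sum) + 0.01*z(value diff) + N(0, 0.02)`,
centroid at the response time (plus an optional value-difference slope,
default 0), width 0.13 s, additive trace noise SD 0.004 — base amplitude,
width and noise scale match the reported pulse statistics; the coupling
slopes and the trial-level amplitude SD of 0.02 are modelling choices (the
source study reports no generative account of grip variability) sized so
that value effects are present but do not make the amplitude a
deterministic function of value, which no real grip series is.  The trace
spans `centroid + 6 widths`.  Amplitudes are clipped to (0, 1] of MVC.

**Fixation shifts.**  Counts are Poisson with
`log rate = log(3.2) − 0.3 * z(|dSV|)`: base rate near the reported mean
shift counts; the slope is a modelling choice strong enough to reproduce
the qualitative finding that shifts decrease with value difference (the
reported directional Bayes factors for that effect were decisive).  Both
vigour couplings are explicitly *not* claims about the original data —
they exist so that every regression in the package has a recoverable
ground truth.

What the generator does **not** emulate: sequential effects across trials,
RT autocorrelation, lapses and attention drift, non-Gaussian grip-pulse
shapes (real pulses skew right), gaze-position dynamics (only shift counts
are generated), and any dependence of MVC or noise on fatigue.  Passing
recovery tests therefore show that the estimation machinery is correct and
well calibrated under the stated generative model — not that the models
are adequate for any particular dataset.

## Preprocessing

Order is fixed and asserted by tests: (1) drop trials with RT < 200 ms or
> 10 s; (2) drop trials flagged as below the 0.70 kgf force logging
threshold (an acquisition constant, recorded in config); (3) for DDM fits
only, remove each subject's `floor(n * 0.025)` fastest and slowest trials
(floor per tail; the same trial set is removed from grip and gaze tables).
Grip traces are baseline-corrected (mean of the first 100 samples — the
window is configurable since only "baseline-corrected" is specified),
normalised to the subject's MVC (maximum over three maximal contractions)
and smoothed with a 50-sample moving average (shrinking windows at the
edges).

## Pulse fitting and magnitude tests

The Gaussian pulse model is fitted per trial by nonlinear least squares
with deterministic starts (`a = max − min`, `b` at the peak, `c` from the
half-width at half-maximum, `h = min`) and positivity bounds on `a` and
`c`; non-convergence flags the trial for downstream exclusion.  Condition
tests on per-subject condition means: Lilliefors normality on the paired
differences, Wilcoxon signed-rank for the pulse parameters (one-tailed
high > low for amplitude, one-tailed for centroid, two-tailed for width;
zero differences dropped — the classic signed-rank convention), paired
one-tailed t-tests for LL proportion and mean RT.  No multiple-comparison
correction is applied, matching the original analysis choice.

## Conflict, value outcomes and regression

Softmax conflict is the LL choice probability with values above 0.5
flipped (`1 − p`), so 0.5 is maximal conflict; flipped values are binned
into five equal intervals of [0, 0.5] with upper-edge-inclusive bins
(0.10 falls in bin 1; any single consistent convention leaves the binning
invariant under `p <-> 1−p`, and ties have measure zero for continuous
probabilities).  Drift-rate conflict evaluates the sigmoid mapping at
posterior-mean parameters.  Value outcomes are |dSV|, the subjective value
sum, and an objective amount-sum variant, from Eq-style subject-specific
discount parameters (by default subject-level posterior means of the
absolute-value DDM fit; configurable).

The hierarchical regression `y_t = a + b1*amp + b2*cen + b3*wid + b4*d`
uses within-subject z-scored grip amplitude/centroid/width and the raw
(unstandardised) fixation count `d` (a standardised option exists behind a
flag).  The regression orientation (outcome = conflict/value, predictors =
vigour) follows the original analysis even though it reads causally
inverted; fidelity over reinterpretation.  Subject-level coefficient
vectors are multivariate-normal conjugate given group Gaussians and the
residual variance, so the sampler is pure Gibbs; group SDs are
slice-sampled under half-Normal(0, 2); the residual variance takes a
conjugate inverse-gamma(0.5, 0.5) prior (chosen over a half-normal purely
for conjugacy — with thousands of trials the residual posterior is
data-dominated and the prior choice is immaterial).

**Decisions.**  Directional Bayes factors are the ratio of posterior mass
below vs. above zero, computed from a Gaussian KDE (Silverman bandwidth)
integrated by trapezoid on a 4,096-point grid spanning ±8 posterior SDs;
a side with zero numerical mass yields a capped ratio (1e±308) with the
evidence label preserved.  Evidence bands: 1–3 anecdotal, 3–10 moderate,
10–30 strong, 30–100 very strong, >100 extreme (inverses for the
opposite direction).  85% and 95% highest-density intervals use the
shortest-interval method on sorted draws.  ROPE limits are ±0.05 (for
standardised coefficients); the decision is reject-null if the 95% HDI is
wholly outside the ROPE, accept-null if wholly inside, else undecided,
with the ROPE overlap percentage of the 95% HDI reported.

## Problem sizes and profiles

The bundled experiments are sized for a single CPU: softmax recovery at
40 subjects × 192 trials with the desk profile (~15 s per fit); DDM_sig
recovery at 20 subjects × 192 trials with the reduced profile (~1 min);
the four-variant DIC comparison at 8 subjects with a 600/600 profile
(~1 min); grip Monte-Carlo at 500 pulses; regressions at 10–12 subjects.
These sizes keep every recovery target well-identified while the whole
reproduction script finishes in under two minutes; all sizes are
parameters.

## Known limitations

* The random-walk subject updates mix slowly for weakly identified
  parameter pairs (notably `log(k)` and `s` under absolute-value softmax,
  where large value differences saturate the choice rule); the flagged
  R-hat makes this visible, and the full profile resolves it at
  cost.
* DIC is reported because it is the comparison statistic of record for
  this analysis family; no WAIC/LOO is provided.
* The regression treats trials as exchangeable within subject; no
  autoregressive structure is modelled.
* `upper_probability` and the DDM simulator assume constant within-trial
  parameters; inter-trial variability parameters of the "full" DDM are
  deliberately out of scope.
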