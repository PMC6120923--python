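# Methods

`socialddm` models binary mini-dictator-game decisions — a *selfish*
option that pays the dictator more versus a *pro-social* option that
pays the receiver more and reduces inequality — as the output of a
drift-diffusion process whose starting point can be biased toward a
subject's habitually preferred option.  This note records the models,
the numerical choices, and what the synthetic data do and do not
establish.

## Task design

Games cross the dictator payoff difference DicDiff ∈ {2, 4, 6, 8, 10}
with the receiver payoff difference ReceDiff ∈ {3, 9, …, 57}
(50 cells).  Both options always leave the dictator ahead, so only
advantageous inequality is in play.  Absolute payoff levels are not
identified by any downstream quantity (utility differences, drift
rates and indifference points depend only on the two differences), so
the generator draws them once per cell — the selfish-option dictator
payoff uniformly from [70, 100], the selfish-option receiver payoff
from [10, 25] — and derives the other blocks by shifting all four
payoffs of each game by ±1 (time-pressure and time-delay blocks) or ±2
(second time-free block, games 51–100), half the games down and half
up, seeded.

The **indifference β** of a game, the inequality-aversion level at
which both options have equal utility, is
DicDiff/(DicDiff + ReceDiff); it ranges from 2/59 to 10/13 over the
design, with median ≈ 0.167.  That median is the selfish/pro-social
classification cutoff.

## Preference model

Fehr–Schmidt utility with advantageous inequality only:

    U(u_d, u_r) = u_d − β (u_d − u_r)

Choices follow a logistic rule on the utility difference,
P(selfish) = σ(s · [DicDiff − β (DicDiff + ReceDiff)]), with one
sensitivity s > 0 per subject and condition.  β and log s are estimated
by Nelder–Mead maximum likelihood from three starts, with β boxed to
(−50, 400) to tolerate one-sided choosers, and the SE of β taken from
the observed information (finite-difference Hessian).

Identification caveat: when fewer than five trials have predicted
probabilities inside (0.01, 0.99), the choices are explained by a
deterministic cutoff rule, β is only interval-identified, and the
curvature SE is meaningless; such fits are flagged non-converged with
an infinite SE.  This happens routinely for strongly one-sided subjects
(the analogue of the extreme empirical β values), which is why all
downstream inference on β uses rank-based statistics (Spearman,
Wilcoxon, rank-sum) that tolerate arbitrary monotone distortion.

## Diffusion model

Evidence R accumulates between absorbing bounds at 0 (pro-social) and
a (selfish) from R₀ = z·a, with drift v > 0 pushing selfish-ward and
diffusion coefficient σ = 1 evidence·s^(−1/2) throughout the fitting
engine (under this convention fitted thresholds come out near 3–4; the
alternative 0.1 convention merely rescales all parameters).  The drift
is a linear function of the design cell, v = d_c + d_d·DicDiff +
d_r·ReceDiff; response time is decision time plus a non-decision
constant t₀.

*Density.* The defective first-passage density uses the classic
small-time/large-time series, switching per time point to the expansion
needing fewer terms for a 1e−7 truncation error (terms capped at 60).
Inter-trial starting-point variability (range szr, uniform) is
integrated with 11-node Gauss–Legendre quadrature.  The density at the
selfish bound for (v, z) equals the density at the pro-social bound for
(−v, 1−z); both normalize with the analytic absorption probabilities
(1 − e^(−2vza/σ²))/(1 − e^(−2va/σ²)).

*Simulation.* Walkers take exact Gaussian increments (the drift is
constant, so Euler transitions are exact); undetected within-step
boundary crossings are optionally restored by drawing the
Brownian-bridge crossing probability exp(−2(b−x)(b−x′)/(σ² dt)) per
step, which makes simulated choice probabilities exact at any step
size.  RT resolution remains one step; for RT-sensitive checks the step
is 1 ms.

*Individual fits.* Maximum likelihood over (z, a, t₀, d_c, d_d, d_r)
— z fixed at 0.5 for the unbiased variant (6 vs 5 parameters) — by
bounded Nelder–Mead from five seeded starts (bounds: z ∈ (0.02, 0.98),
a ∈ (0.3, 8), t₀ ∈ (0.05, min RT − 0.01), drift coefficients ±5/s).
Densities are floored at 1e−10 so outlier RTs keep the objective
finite without a formal contaminant model.  BIC = ln(n)·k − 2·lnL.

*Group fits.* Pooled trials of a subject group are fit by minimizing
the count-weighted sum over design cells of the Kolmogorov–Smirnov
distance between the empirical signed-RT distribution (pro-social RTs
negated) and the model's defective signed CDF, tabulated by
trapezoidal integration on a 5–10 ms decision-time grid extending past
the slowest observed response.  One drift per cell is profiled out at
every outer step by a vectorized grid-refinement line search (13-point
coarse grid, three 7-point refinements, final drift resolution
≈ 0.05/s, all 50 cells searched simultaneously); the outer
Nelder–Mead runs over (z, a, t₀, szr), with szr parameterized as a
fraction (≤ 0.9) of 2·min(z, 1−z) so starts stay inside the bounds.
Group-level SEs use leave-one-subject-out jackknife,
SE² = (n−1)/n · Σ(θ̂₋ᵢ − θ̄)².

## Synthetic cohort

The generator emulates the study conditions: 102 subjects × 200 games
in four blocks (time-free ×2, pressure ≤ 2 s, delay ≥ 10 s).  Defaults,
chosen once:

| parameter | default | rationale |
|---|---|---|
| β mixture | ½·N(0.1, 0.1²) + ½·N(0.7, 0.15²), truncated to (−1, 2) | a selfish and a pro-social sub-population on either side of the design's indifference range |
| start-point link | z = 0.5 − κ(β − 0.35), κ = 0.5, clipped to [0.05, 0.95] | anchor midway between the mixture components gives both groups comparable bias magnitudes (z ≈ 0.62 / 0.33); fitted group-level z then spreads over ≈ 0.40–0.57, the range typical of empirical fits |
| drift scale | v = 0.05 · (U_selfish − U_prosocial) per second | time-free RT means ≈ 2.5 s and graded (non-degenerate) choice probabilities |
| threshold a | N(3.5, 0.4²), clipped to [1, 8] | the magnitude regime of fitted thresholds under the σ = 1 convention |
| t₀ | U(0.25, 0.45) s | encoding + motor time |
| pressure | threshold × 0.5, hard 2 s deadline | the same halving the threshold-manipulation experiment contrasts (a = 2 vs 1); optional linear bound collapse to a/2 at the deadline |
| pressure timeout | resolved by the sign of the evidence about a/2 (fair coin at the midline), RT = deadline | the deadline rule is otherwise underdetermined; resolving rather than re-drawing avoids conditioning the data on early termination |
| delay | threshold × 1.5; RT = 10 s + max(0.15, N(0.5, 0.2²)) motor latency, flagged censored | decisions finish before the response cue; the decision time is unobservable |

Because the delay decision time is never observed, that block is
simulated with a 5 ms step and a 300 s absorption budget (choices stay
exact via the bridge correction).

What the generator does **not** emulate: learning or order effects
across the 200 trials, block counterbalancing structure beyond
independent per-condition simulation, the two-person payoff matching,
inter-trial drift variability, and any contaminant (lapse) process.
Passing recovery and contrast tests therefore shows the estimators and
the inferential chain work when the biased-DDM assumptions hold — not
that real data satisfy those assumptions.

## Threshold-manipulation simulation experiment

Fifty simulated subjects carry a single drift v ~ U[−2·10⁻⁴, 2·10⁻⁴]
per ms and run 1000 trials at threshold separations a = 2 and a = 1
(1 ms steps), with the starting point (i) unbiased, (ii) proportional
to drift, R₀ = a/2 + 5000·v, or (iii) a fixed offset R₀ = a/2 ± 0.25.
The diffusion coefficient here is σ = 0.45–0.5 in the per-second
convention (per-step sd ≈ 0.0158); it is a free choice because the
original protocol states drifts and thresholds but no noise scale, and
it matters:

* With z = 0.5, P(selfish) = logistic(v·a/σ²), so σ = 1 confines all
  choice probabilities to ≈ [0.40, 0.60] and the narrow-threshold
  contrast drowns in binomial noise at 1000 trials.
* A small-v expansion gives the per-subject amplification gap
  |P(a=1) − 0.5| − |P(a=2) − 0.5| = v_s·(2.5 − 1/(4σ²)) for the
  proportional construction (v_s in s⁻¹), so amplification requires
  σ² > 0.1; for the fixed ±0.25 construction the gap is
  0.125 − v_s/(4σ²), so the bias-dominated regime covers the median
  subject only for σ² ≳ 0.22.

σ = 0.5 (σ² = 0.25) satisfies all three regimes simultaneously and
spreads the unbiased panel's probabilities over ≈ [0.17, 0.83].  With
it, narrowing the threshold moves unbiased subjects toward chance and
start-biased subjects away from chance; the fixed-offset variant shows
the same amplification for the typical subject (the drift term erodes
it at the largest drifts) plus a discontinuity in P(selfish) across
v = 0.

## Pipeline and evaluation

The full pipeline generates a cohort, estimates β per subject for
time-free (both blocks pooled), pressure and delay, classifies social
type (β_f vs the median indifference β) and predisposition
(β_p < β_d ⇒ selfishly predisposed; exact ties, a measure-zero event,
go to pro-socially predisposed with a warning), fits biased and
unbiased DDMs per subject on the time-free data, compares them by BIC,
fits group-level KS models per predisposition group on games 1–50 and
predicts games 51–100 (5000 simulations per game), and benchmarks
against logistic baselines (intercept + DicDiff + ReceDiff, optionally
+ RT, with the held-out trial's observed RT used as the regressor —
prediction conditional on RT).  Out-of-sample quality is summarized by
per-game absolute error against empirical choice fractions (equal
trial weight) and by Cramer's λ = P̄⁺ − P̄⁻, computed per model by
pooling all held-out trials across groups with group-specific
predictions.

The RT/strength-of-preference analysis standardizes per-trial utility
differences to [−1, 1] within subject, pools each condition into 11
equal-count bins (subject means averaged within bin; SEs across
subjects), and summarizes the relationship by per-subject OLS slopes
of log RT on |ΔU| with a one-sample t-test across subjects.  This
two-stage procedure deliberately replaces a mixed-effects regression:
its test statistics are not comparable to mixed-model t-values, but
its sign and binned profile are.  The time-free analysis restricts to
games 1–50 by default for comparability with the constrained blocks.
The delay condition is excluded (all its RTs are censored).

Every artifact (CSV, JSON) embeds a 12-hex hash of the fully resolved
configuration; reruns with an identical configuration are bit-identical.
Compute scaling knobs — the number of subjects given individual DDM
fits (`fit_subject_limit`), optimizer starts, group-fit grid step and
iteration caps, simulation counts — are part of the configuration; the
shipped analyses use 26-subject fit subsets, 15–20 recovery replicates
and a 10 ms group-fit grid, sizes at which every reported contrast is
already decisively resolved.

## Known limitations

* Group-level KS estimates on small heterogeneous subgroups are
  attenuated toward z = 0.5 (aggregation over subjects with different
  a and t₀); homogeneous-cohort recovery is accurate.
* Group fits on *predisposition-classified* groups additionally inherit
  classification noise: at 50 trials per constrained condition the
  per-subject sign of β_p − β_d is only ~60–65% accurate, so each group
  contains a sizeable contaminating minority.  Because the contaminants
  in the selfishly predisposed group are strong pro-socials whose fast
  pro-social responses dominate that response tail, the group's fitted
  starting point is dragged toward (and can cross) 0.5, and the pooled
  Cramer's λ of the biased group model can fall below the unbiased
  one's even while its summed absolute error is smaller.  The
  population-level contrasts (rank statistics over all subjects,
  individual-level fits) are unaffected.
* The β MLE's curvature SE is meaningful only away from
  (quasi-)separation; flagged estimates should enter analyses only
  through rank statistics.
* The KS group objective reproduces the published objective's
  *definition*; it does not replicate any particular optimizer's
  internals, so group estimates can differ in the second decimal from
  other implementations.
* Inter-trial variability of drift and non-decision time is not
  modelled (only szr is), and collapsing-bound fits are not provided —
  only collapsing-bound simulation.
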