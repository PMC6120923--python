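# socialddm

Biased drift-diffusion modelling of social decision making.

People deciding between a **selfish** allocation (more money for
themselves) and a **pro-social** one (more for the other person, less
inequality) show a puzzling pattern: time pressure makes pro-social
people *more* pro-social and selfish people *more* selfish, while an
unbiased evidence-accumulation account predicts that less deliberation
should push everyone toward chance.  `socialddm` implements the
resolution: a drift-diffusion model (DDM) whose **starting point** is
biased toward a subject's habitually preferred option.  Narrowing the
decision thresholds (time pressure) then amplifies the starting-point
bias instead of washing preferences out.

The package is aimed at decision scientists who want a tested,
end-to-end reference implementation of this modelling chain:

* **Task design** — mini-dictator games crossing the dictator payoff
  difference (DicDiff ∈ {2,…,10}) with the receiver payoff difference
  (ReceDiff ∈ {3,…,57}), and the per-game indifference point
  β* = DicDiff/(DicDiff+ReceDiff).
* **Preferences** — Fehr–Schmidt advantageous inequality aversion,
  U(u_d, u_r) = u_d − β(u_d − u_r), estimated per subject and time
  condition by logistic-choice maximum likelihood, plus the
  nonparametric test battery (Wilcoxon signed-rank, Spearman, exact
  binomial).
* **DDM engine** — Wiener first-passage-time densities
  (small/large-time series), exact bridge-corrected simulation,
  individual maximum-likelihood fits of the biased
  (z free) vs unbiased (z = 0.5) model with
  v = d_c + d_d·DicDiff + d_r·ReceDiff, group-level Kolmogorov–Smirnov
  fits with 50 per-cell drifts and starting-point variability, BIC,
  and jackknife standard errors.
* **Evaluation** — split-half out-of-sample prediction (games 1–50 →
  51–100), summed absolute error per game, logistic baselines, and
  Cramer's λ = P̄⁺ − P̄⁻.
* **Synthetic cohort** — a generator producing 102 subjects × 200
  trials in time-free / time-pressure / time-delay blocks from a
  biased DDM whose starting point anti-correlates with β, so the whole
  chain is testable without any data download.

## Worked example

```python
from socialddm import (CohortConfig, analytic_choice_prob, fit_individual,
                       full_design, sample_subjects, simulate_trial_set)
from socialddm.ddm import attach_game_columns

# the amplification mechanism in one line: halving the threshold pulls
# an unbiased subject toward chance ...
print(analytic_choice_prob(v=0.3, a=2.0, z=0.5),
      analytic_choice_prob(v=0.3, a=1.0, z=0.5))
# 0.6456563062257954 0.574442516811659
# ... but pushes a start-biased subject away from it.  The bias is an
# absolute evidence offset R0 - a/2 = 0.3, so z = 0.65 at a = 2
# becomes z = 0.8 at a = 1:
print(analytic_choice_prob(v=0.3, a=2.0, z=0.65),
      analytic_choice_prob(v=0.3, a=1.0, z=0.8))
# 0.7750279089370259 0.8449167547089128

# recover a pro-social starting-point bias from 100 time-free trials
games = full_design(seed=11)
cfg = CohortConfig(n_subjects=1)
subj = sample_subjects(1, cfg, seed=5)[0]
trials = attach_game_columns(
    simulate_trial_set([subj], games, seed=6, config=cfg), games)
fit = fit_individual(trials[trials.condition.isin(["free1", "free2"])],
                     biased=True, seed=0)
print(round(subj.ddm.z, 3), round(fit.params.z, 3))
# 0.424 0.431
```

The first block prints the analytic absorption probabilities that
define the phenomenon: with an unbiased start the narrow threshold
moves P(selfish) from 0.646 toward 0.574 (closer to chance), while the
same narrowing amplifies a subject with a fixed selfish-ward evidence
offset from 0.775 to 0.845 — away from chance, because the drift loses
influence faster than the bias does.  The second block simulates one
synthetic subject whose
true relative starting point is 0.424 and recovers 0.431 from 100
trials.

A command-line interface mirrors the pipeline stages:

```bash
socialddm simulate --seed 7 --out runs/demo
socialddm fit-preferences --trials runs/demo/trials.csv \
    --games runs/demo/games.csv --out runs/demo/estimates.csv
socialddm threshold-sim --bias-mode proportional --seed 7 --out runs/sim.csv
socialddm report --seed 7 --out runs/full
```

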