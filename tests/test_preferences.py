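"""Fehr-Schmidt utilities, the beta MLE and the nonparametric tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socialddm.preferences import (
    classify_predisposition,
    classify_social_type,
    exact_binomial_two_sided,
    fit_beta_mle,
    fs_utility,
    spearman_rho,
    utility_difference,
    wilcoxon_signed_rank,
)


class TestUtility:
    def test_reference_values(self):
        assert fs_utility(95, 21, 0.0) == 95
        assert fs_utility(95, 21, 0.5) == pytest.approx(58.0)  # 95 - 0.5*74
        for beta in (-1.0, 0.0, 0.77, 5.0):
            assert fs_utility(40, 40, beta) == 40

    def test_difference_depends_only_on_diffs(self):
        # adding c to both payoffs of both options adds c to each utility,
        # so the selfish-minus-prosocial difference is shift-invariant
        for beta in (-0.5, 0.0, 0.4, 1.3):
            base = fs_utility(95, 18, beta) - fs_utility(85, 21, beta)
            shifted = fs_utility(97, 20, beta) - fs_utility(87, 23, beta)
            assert base == pytest.approx(shifted)
            assert base == pytest.approx(utility_difference(10, 3, beta))


class TestBetaMLE:
    @staticmethod
    def _trials(free_games, beta, sens, n_trials, seed):
        rng = np.random.default_rng(seed)
        reps = int(np.ceil(n_trials / len(free_games)))
        df = pd.concat([free_games] * reps).iloc[:n_trials].copy()
        p = 1 / (1 + np.exp(-sens * utility_difference(
            df["dic_diff"], df["rece_diff"], beta)))
        df["choice"] = np.where(rng.random(n_trials) < p, "selfish", "prosocial")
        return df

    def test_recovery_within_se(self, free_games):
        # identified replicates must cover the truth; quasi-separated ones
        # (choices perfectly explained by a cutoff rule) are flagged with
        # an infinite SE instead of a spuriously tight one
        n_converged = 0
        for rep in range(12):
            df = self._trials(free_games, beta=0.6, sens=3.0, n_trials=100,
                              seed=rep)
            est = fit_beta_mle(df)
            if est.converged:
                n_converged += 1
                assert abs(est.beta - 0.6) < 3 * est.se_beta
            else:
                assert not np.isfinite(est.se_beta)
        assert n_converged >= 3

    def test_one_sided_chooser_flagged(self, free_games):
        df = free_games.copy()
        df["choice"] = "prosocial"
        est = fit_beta_mle(df)
        assert not est.converged
        assert est.beta > 10 / 13  # beyond the largest indifference beta

        df["choice"] = "selfish"
        est = fit_beta_mle(df)
        assert not est.converged
        assert est.beta < 2 / 59

    def test_near_zero_sensitivity_blows_up_se(self, free_games):
        noisy = self._trials(free_games, beta=0.3, sens=0.003, n_trials=100,
                             seed=0)
        moderate = self._trials(free_games, beta=0.3, sens=1.0, n_trials=100,
                                seed=0)
        e_noisy = fit_beta_mle(noisy)
        e_mod = fit_beta_mle(moderate)
        assert e_mod.converged and e_mod.se_beta < 0.2
        # chance-level choices: either flagged unidentified or hugely uncertain
        assert (not e_noisy.converged) or e_noisy.se_beta > 5 * e_mod.se_beta

    def test_loglik_nonpositive_and_counts(self, free_games):
        df = self._trials(free_games, beta=0.3, sens=1.0, n_trials=80, seed=1)
        est = fit_beta_mle(df)
        assert est.loglik <= 0
        assert est.n_trials == 80
        assert est.sensitivity > 0


class TestClassification:
    def test_social_type_cutoff(self):
        assert classify_social_type(0.16, 0.17) == "selfish"
        assert classify_social_type(0.18, 0.17) == "prosocial"
        assert classify_social_type(0.17, 0.17) == "prosocial"

    def test_predisposition(self):
        assert classify_predisposition(0.2, 0.4) == "selfishly_predisposed"
        assert classify_predisposition(0.5, 0.1) == "prosocially_predisposed"
        with pytest.warns(UserWarning):
            assert classify_predisposition(0.3, 0.3) == "prosocially_predisposed"


class TestPredispositionRecovery:
    def test_sign_matches_true_start_bias(self):
        """Subjects whose pressure/delay data come from a z-biased DDM are
        classified on the side of their true bias for >= 75% of subjects
        with |z - 0.5| >= 0.05 (three design repetitions per condition to
        measure each subject's beta shift precisely)."""
        import pandas as pd

        from socialddm.cohort import CohortConfig, sample_subjects, simulate_trial_set
        from socialddm.preferences import estimate_all
        from socialddm.task_design import full_design

        games = full_design(7)
        tripled = pd.concat([games] * 3, ignore_index=True)
        cfg = CohortConfig(n_subjects=30)
        subs = sample_subjects(30, cfg, seed=21)
        trials = simulate_trial_set(subs, tripled, seed=22, config=cfg)
        est = estimate_all(trials, games)
        wide = est.pivot(index="subject_id", columns="condition", values="beta")
        z = pd.Series({s.subject_id: s.ddm.z for s in subs})
        biased = np.abs(z - 0.5) >= 0.05
        selfishly = wide["pressure"] < wide["delay"]
        agreement = (selfishly == (z > 0.5))[biased].mean()
        assert agreement >= 0.75


class TestWilcoxon:
    def test_identical_pairs_carry_no_evidence(self):
        x = np.arange(10.0)
        stat, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_exact_small_sample_all_positive(self):
        # all six differences positive: the most extreme of the 2^6 sign
        # assignments, two-sided p = 2/64
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x - np.array([0.5, 0.4, 0.3, 0.2, 0.6, 0.7])
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(2 / 64)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(12)
        n_rep, n = 600, 60  # n > 25 exercises the corrected normal branch
        rejections = 0
        for _ in range(n_rep):
            d = rng.normal(0, 1, n)
            _, p = wilcoxon_signed_rank(d, np.zeros(n))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)
        assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman_rho([1.0, 2.0], [1.0, 2.0])


class TestBinomial:
    def test_reported_split(self):
        # 40 of 56 starting points above one half
        assert exact_binomial_two_sided(40, 56) == pytest.approx(0.002, abs=5e-4)

    def test_closed_forms(self):
        assert exact_binomial_two_sided(5, 5) == pytest.approx(2 * 0.5**5)
        assert exact_binomial_two_sided(3, 6) == 1.0

    def test_enumeration_oracle(self):
        # double the upper-tail mass of Binomial(10, 1/2) at k=8
        k, n = 8, 10
        tail = sum(sps.binom.pmf(j, n, 0.5) for j in range(k, n + 1))
        assert exact_binomial_two_sided(k, n) == pytest.approx(2 * tail)

    def test_invalid(self):
        with pytest.raises(ValueError):
            exact_binomial_two_sided(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_two_sided(7, 5)
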