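"""DDM parameter containers, likelihood, BIC, individual and group fits."""

import numpy as np
import pandas as pd
import pytest

from socialddm.ddm import (
    DDMParams,
    bic,
    drift_rate,
    drift_rates,
    fit_group_ks,
    fit_individual,
    jackknife_se,
    loglik_trials,
)
from socialddm.wfpt import wiener_fpt_density


def _params(**kw):
    base = dict(a=3.5, z=0.4, t0=0.3, drift_coefs=(0.0, 0.03, -0.02))
    base.update(kw)
    return DDMParams(**base)


class TestParams:
    def test_invariants(self):
        with pytest.raises(ValueError):
            DDMParams(a=-1, drift_coefs=(0, 0, 0))
        with pytest.raises(ValueError):
            DDMParams(a=2, z=1.0, drift_coefs=(0, 0, 0))
        with pytest.raises(ValueError):
            DDMParams(a=2, z=0.2, szr=0.4, drift_coefs=(0, 0, 0))
        with pytest.raises(ValueError):
            DDMParams(a=2)  # no drift specification

    def test_drift_rate_linear_form(self):
        p = DDMParams(a=2, drift_coefs=(0.1, 0.05, -0.01))
        assert drift_rate(p, (10, 3)) == pytest.approx(0.57)
        p0 = DDMParams(a=2, drift_coefs=(0.0, 0.0, 0.0))
        assert drift_rate(p0, (8, 21)) == 0.0

    def test_drift_shift_invariance(self, design):
        # payoff shifts leave (DicDiff, ReceDiff) and hence v unchanged
        p = _params()
        free1 = design[design.condition == "free1"].sort_values(["dic_diff", "rece_diff"])
        press = design[design.condition == "pressure"].sort_values(["dic_diff", "rece_diff"])
        np.testing.assert_allclose(drift_rates(p, free1), drift_rates(p, press))

    def test_cell_form_missing_cell(self):
        p = DDMParams(a=2, cell_drifts={(2, 3): 0.1})
        assert drift_rate(p, (2, 3)) == 0.1
        with pytest.raises(KeyError):
            drift_rate(p, (4, 9))


class TestLoglik:
    def _one_trial(self, choice, rt):
        return pd.DataFrame({"choice": [choice], "rt": [rt],
                             "dic_diff": [10], "rece_diff": [3]})

    def test_single_trial_is_log_density(self):
        p = _params()
        tr = self._one_trial("selfish", 1.2)
        v = drift_rate(p, (10, 3))
        d = wiener_fpt_density(1.2, "selfish", v=v, a=p.a, z=p.z, t0=p.t0)
        assert loglik_trials(p, tr) == pytest.approx(np.log(d))

    def test_additivity(self, subject_trials_factory, free_games):
        p = _params()
        tr = subject_trials_factory(p, free_games, seed=0)
        ll = loglik_trials(p, tr)
        doubled = pd.concat([tr, tr], ignore_index=True)
        assert loglik_trials(p, doubled) == pytest.approx(2 * ll)

    def test_floor_keeps_outliers_finite(self):
        p = _params()
        tr = self._one_trial("selfish", 0.05)  # faster than t0
        assert loglik_trials(p, tr) == pytest.approx(np.log(1e-10))

    def test_self_consistency_at_truth(self, subject_trials_factory, free_games):
        # the generating parameters beat coordinate-wise perturbations
        p = _params()
        big = pd.concat([subject_trials_factory(p, free_games, seed=s)
                         for s in range(20)], ignore_index=True)
        ll_true = loglik_trials(p, big)
        for perturbed in (_params(z=0.55), _params(a=4.5), _params(t0=0.15),
                          _params(drift_coefs=(0.3, 0.03, -0.02))):
            assert ll_true > loglik_trials(perturbed, big)


class TestBIC:
    def test_arithmetic(self):
        assert bic(0.0, 1, 0) == 0.0
        assert bic(-120.0, 100, 6) == pytest.approx(6 * np.log(100) + 240)

    def test_monotone_in_loglik(self):
        assert bic(-100, 50, 6) < bic(-110, 50, 6)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bic(-1.0, 0, 2)


class TestIndividualFit:
    def test_unbiased_constraints(self, subject_trials_factory, free_games):
        p = _params(z=0.5)
        tr = subject_trials_factory(p, free_games, seed=4)
        fr = fit_individual(tr, biased=False, n_starts=2, maxfev=600)
        assert fr.k_params == 5
        assert fr.params.z == 0.5
        assert fr.n_obs == len(tr)
        assert fr.bic == pytest.approx(bic(fr.objective, fr.n_obs, 5))

    def test_biased_fit_finds_low_start(self, subject_trials_factory, free_games):
        p = _params(z=0.3)
        tr = subject_trials_factory(p, free_games, seed=5)
        fr = fit_individual(tr, biased=True, n_starts=3, seed=1)
        assert fr.k_params == 6
        assert fr.params.z < 0.5
        assert 0.3 < fr.params.a < 8
        # the fit should never be worse than the generating parameters
        assert fr.objective >= loglik_trials(p, tr) - 1e-6

    def test_small_sample_warns(self, subject_trials_factory, free_games):
        p = _params()
        tr = subject_trials_factory(p, free_games.head(20), seed=6)
        with pytest.warns(UserWarning, match="trials"):
            fit_individual(tr, n_starts=1, maxfev=150)


class TestGroupKS:
    def test_recovers_prosocial_start_bias(self, subject_trials_factory, free_games):
        # homogeneous cohort simulated with z = 0.40
        pooled = []
        for s in range(8):
            tr = subject_trials_factory(_params(z=0.40), free_games, seed=100 + s)
            tr = tr.assign(subject_id=s)
            pooled.append(tr)
        pooled = pd.concat(pooled, ignore_index=True)
        fr = fit_group_ks(pooled, biased=True, grid_dt=0.02, maxiter=40,
                          n_starts=1, seed=0)
        assert fr.params.z < 0.5
        assert len(fr.params.cell_drifts) == 50
        assert fr.k_params == 54
        # objective at the fit beats the start-flipped parameter vector
        from socialddm.ddm import _cell_arrays, _GroupObjective
        cells, signed = _cell_arrays(pooled)
        obj = _GroupObjective(cells, signed, 0.02,
                              float(pooled.rt.max() + 0.5), (-5, 5))
        p = fr.params
        _, ks_fit = obj.best_drifts(p.z, p.a, p.t0, p.szr)
        _, ks_flip = obj.best_drifts(1 - p.z, p.a, p.t0, min(p.szr, 1.8 * p.z))
        assert np.sum(obj.counts * ks_fit) <= np.sum(obj.counts * ks_flip)

    def test_empty_cells_warn(self, subject_trials_factory, free_games, design):
        tr = subject_trials_factory(_params(), free_games.head(30), seed=7)
        with pytest.warns(UserWarning):
            fit_group_ks(tr, design, biased=False, grid_dt=0.05, maxiter=5,
                         n_starts=1)


class TestJackknife:
    def test_data_ignoring_estimator(self):
        se = jackknife_se(lambda ids: {"theta": 1.23}, list(range(6)))
        assert se["theta"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_estimator_closed_form(self):
        rng = np.random.default_rng(0)
        vals = {i: rng.normal() for i in range(12)}

        def fit(ids):
            return {"m": float(np.mean([vals[i] for i in ids]))}

        se = jackknife_se(fit, list(vals))
        arr = np.array(list(vals.values()))
        # the jackknife SE of a mean equals the usual SE of the mean
        expected = arr.std(ddof=1) / np.sqrt(len(arr))
        assert se["m"] == pytest.approx(expected)
        assert se["m"] >= 0

    def test_failing_subjects_are_skipped(self):
        def fit(ids):
            if 3 not in ids:
                raise RuntimeError("boom")
            return {"m": float(np.mean(ids))}

        with pytest.warns(UserWarning, match="leave-one-out"):
            se = jackknife_se(fit, list(range(8)))
        assert se["m"] > 0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            jackknife_se(lambda ids: {"t": 0.0}, [1, 2])
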