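"""Wiener first-passage machinery: analytic probabilities, densities and
the simulator, cross-checked against each other and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialddm.simulate import simulate_wiener
from socialddm.wfpt import (
    analytic_choice_prob,
    defective_cdf,
    mean_decision_time,
    wiener_fpt_density,
)


class TestAnalyticChoiceProb:
    def test_zero_drift_equals_start(self):
        assert analytic_choice_prob(0.0, 2.0, 0.5) == pytest.approx(0.5)
        assert analytic_choice_prob(0.0, 2.0, 0.75) == pytest.approx(0.75)
        assert analytic_choice_prob(0.0, 7.0, 0.3) == pytest.approx(0.3)

    def test_monotone_in_drift_and_threshold(self):
        v = np.linspace(-2, 2, 41)
        p = analytic_choice_prob(v, 2.0, 0.5)
        assert np.all(np.diff(p) > 0)
        # with z=0.5, widening a pushes P toward its drift-sign limit,
        # halving a moves it toward 0.5
        for v0 in (0.3, -0.7, 1.5):
            p2 = analytic_choice_prob(v0, 2.0, 0.5)
            p1 = analytic_choice_prob(v0, 1.0, 0.5)
            assert abs(p1 - 0.5) < abs(p2 - 0.5)

    def test_extreme_drift_is_stable(self):
        assert analytic_choice_prob(50.0, 8.0, 0.5) == pytest.approx(1.0)
        assert analytic_choice_prob(-50.0, 8.0, 0.5) == pytest.approx(0.0)

    def test_sigma_rescaling(self):
        # (v, a, sigma) -> (v/s, a/s, 1) leaves the probability unchanged
        assert analytic_choice_prob(0.3, 2.0, 0.4, sigma=0.5) == pytest.approx(
            analytic_choice_prob(0.6, 4.0, 0.4, sigma=1.0))


class TestAnalyticProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(v=st.floats(-3, 3), a=st.floats(0.3, 6), z=st.floats(0.05, 0.95),
           sigma=st.floats(0.2, 2))
    def test_probability_bounds_and_scaling(self, v, a, z, sigma):
        p = analytic_choice_prob(v, a, z, sigma)
        assert 0.0 <= p <= 1.0
        # rescaling evidence units leaves the absorption probability alone
        assert p == pytest.approx(
            analytic_choice_prob(v / sigma, a / sigma, z, 1.0), abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(v=st.floats(-2, 2), a=st.floats(0.5, 5))
    def test_monotone_in_start(self, v, a):
        z = np.linspace(0.05, 0.95, 19)
        p = analytic_choice_prob(v, a, z)
        assert np.all(np.diff(p) > -1e-12)


class TestDensity:
    GRID = [(0.2, 2.0, 0.5), (-0.5, 3.5, 0.35), (1.0, 1.0, 0.7)]

    def test_zero_before_nondecision_time(self):
        d = wiener_fpt_density(np.array([0.1, 0.29, 0.3, 0.31]), "selfish",
                               v=0.5, a=2.0, z=0.5, t0=0.3)
        assert d[0] == d[1] == d[2] == 0.0
        assert d[3] > 0.0

    def test_reflection_symmetry(self):
        t = np.linspace(0.01, 8, 200)
        for v, a, z in self.GRID:
            up = wiener_fpt_density(t, "selfish", v=v, a=a, z=z)
            lo = wiener_fpt_density(t, "prosocial", v=-v, a=a, z=1 - z)
            np.testing.assert_allclose(up, lo, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("szr", [0.0, 0.3])
    def test_normalization_and_defectiveness(self, szr):
        t = np.arange(5e-4, 60, 1e-3)
        for v, a, z in self.GRID:
            if szr >= 2 * min(z, 1 - z):
                continue
            ds = wiener_fpt_density(t, "selfish", v=v, a=a, z=z, szr=szr)
            dp = wiener_fpt_density(t, "prosocial", v=v, a=a, z=z, szr=szr)
            total = np.trapezoid(ds + dp, t)
            assert total == pytest.approx(1.0, abs=1e-4)
            p_up = np.trapezoid(ds, t)
            if szr == 0.0:
                assert p_up == pytest.approx(analytic_choice_prob(v, a, z), abs=1e-4)

    def test_mean_decision_time_from_density(self):
        t = np.arange(5e-4, 80, 1e-3)
        ds = wiener_fpt_density(t, "selfish", v=0.2, a=2.0, z=0.5)
        dp = wiener_fpt_density(t, "prosocial", v=0.2, a=2.0, z=0.5)
        mean_t = np.trapezoid(t * (ds + dp), t)
        assert mean_t == pytest.approx(mean_decision_time(0.2, 2.0), abs=2e-3)

    def test_defective_cdf_monotone(self):
        t = np.linspace(0, 10, 2001)
        F = defective_cdf(t, "selfish", v=0.3, a=2.0, z=0.4, t0=0.2)
        assert np.all(np.diff(F) >= 0)
        assert F[-1] <= 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, "selfish", v=0.1, a=-1.0, z=0.5)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, "selfish", v=0.1, a=2.0, z=1.2)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, "selfish", v=0.1, a=2.0, z=0.2, szr=0.5)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, "sideways", v=0.1, a=2.0, z=0.5)


class TestSimulator:
    def test_boundary_start_is_immediate(self):
        rng = np.random.default_rng(0)
        res = simulate_wiener(100, 0.0, 2.0, 0.999999, rng=rng)
        # starting essentially at the selfish bound
        res2 = simulate_wiener(100, 0.0, 2.0, 1.0, rng=rng)
        assert res2.choice_selfish.all() and (res2.decision_time == 0).all()
        assert res.resolved.all()

    def test_choice_fraction_matches_analytic(self):
        rng = np.random.default_rng(42)
        for v, a, z in [(0.4, 2.0, 0.5), (-0.6, 3.0, 0.6)]:
            n = 40000
            res = simulate_wiener(n, v, a, z, dt=0.01, rng=rng, bridge=True)
            p = res.choice_selfish.mean()
            pa = analytic_choice_prob(v, a, z)
            se = np.sqrt(pa * (1 - pa) / n)
            assert abs(p - pa) < 3 * se + 1e-3

    def test_deadline_and_collapse(self):
        rng = np.random.default_rng(1)
        res = simulate_wiener(2000, 0.0, 3.0, 0.5, dt=0.005, deadline=1.0,
                              rng=rng)
        assert np.nanmax(res.decision_time[res.resolved]) <= 1.0 + 1e-9
        assert not res.resolved.all()  # some walkers time out at a=3 in 1 s
        col = simulate_wiener(2000, 0.0, 3.0, 0.5, dt=0.005, deadline=1.0,
                              collapse=True, rng=rng)
        # collapsing bounds force a decision by the deadline
        assert col.resolved.mean() > 0.99

    def test_per_trial_heterogeneity(self):
        rng = np.random.default_rng(3)
        v = np.array([-5.0] * 500 + [5.0] * 500)
        a = np.array([2.0] * 500 + [1.0] * 500)
        res = simulate_wiener(1000, v, a, 0.5, dt=0.002, rng=rng, bridge=True)
        assert res.choice_selfish[500:].mean() > 0.95
        assert res.choice_selfish[:500].mean() < 0.05

    def test_seeded_reproducibility(self):
        r1 = simulate_wiener(500, 0.2, 2.0, 0.4, dt=0.01,
                             rng=np.random.default_rng(7), bridge=True)
        r2 = simulate_wiener(500, 0.2, 2.0, 0.4, dt=0.01,
                             rng=np.random.default_rng(7), bridge=True)
        np.testing.assert_array_equal(r1.choice_selfish, r2.choice_selfish)
        np.testing.assert_array_equal(r1.decision_time, r2.decision_time)
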