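"""Success probability, hazard extraction, and the a-priori ligand success."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latkin import (SuccessModel, SuccessProbabilityModel, apriori_success,
                    apriori_success_closed_form, bin_success,
                    extract_propensity, integrate_hazard, kpr_propensity,
                    make_bins, observed_delay_density, productive_counts)


class TestBins:
    def test_linearly_increasing_widths(self):
        bins = make_bins(np.array([50.0]), first_width=4.0, increment=2.0)
        widths = np.diff(bins.edges)
        np.testing.assert_allclose(widths, 4.0 + 2.0 * np.arange(len(widths)))

    def test_zero_increment_gives_uniform_bins(self):
        bins = make_bins(np.array([19.0]), first_width=5.0, increment=0.0)
        np.testing.assert_allclose(np.diff(bins.edges), 5.0)

    def test_partition_counts_sum_to_n(self, event_table):
        dwells = event_table["dwell_obs"].to_numpy()
        bins = make_bins(dwells)
        curve = bin_success(event_table, bins)
        assert curve.n.sum() == len(event_table)
        # each dwell lands in exactly one bin
        idx = bins.assign(dwells)
        assert idx.min() >= 0 and idx.max() < bins.n_bins

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            make_bins(np.array([]))


class TestBinnedSuccess:
    def test_zero_productive_bin(self, truth_model):
        import pandas as pd

        ev = pd.DataFrame({"dwell_obs": np.full(20, 2.0),
                           "productive": np.zeros(20, dtype=bool),
                           "delay": np.full(20, np.nan)})
        curve = bin_success(ev, make_bins(ev["dwell_obs"].to_numpy()))
        assert curve.p_hat[0] == 0.0 and curve.se[0] == 0.0

    def test_binomial_se_closed_form(self):
        import pandas as pd

        prod = np.zeros(16, dtype=bool)
        prod[:4] = True
        ev = pd.DataFrame({"dwell_obs": np.full(16, 2.0), "productive": prod,
                           "delay": np.where(prod, 1.0, np.nan)})
        curve = bin_success(ev, make_bins(ev["dwell_obs"].to_numpy()))
        assert curve.p_hat[0] == pytest.approx(0.25)
        assert curve.se[0] == pytest.approx(np.sqrt(0.25 * 0.75 / 16), abs=1e-12)

    def test_binned_p_matches_model_within_3se(self, event_table, truth_model):
        """p_hat per bin tracks the generative success model."""
        curve = bin_success(event_table,
                            make_bins(event_table["dwell_obs"].to_numpy()))
        mask = curve.n >= 20
        expected = truth_model(curve.centers[mask])
        se = np.sqrt(np.maximum(expected * (1 - expected), 1e-6)
                     / curve.n[mask])
        assert np.all(np.abs(curve.p_hat[mask] - expected) < 3.5 * se)

    def test_invariant_to_event_ordering(self, event_table):
        bins = make_bins(event_table["dwell_obs"].to_numpy())
        shuffled = event_table.sample(frac=1.0, random_state=1)
        a = bin_success(event_table, bins)
        b = bin_success(shuffled, bins)
        np.testing.assert_allclose(a.p_hat, b.p_hat, equal_nan=True)

    def test_rejects_delay_exceeding_dwell(self):
        import pandas as pd

        ev = pd.DataFrame({"dwell_obs": [5.0] * 25, "productive": [True] * 25,
                           "delay": [6.0] * 25})
        with pytest.raises(ValueError):
            bin_success(ev, make_bins(ev["dwell_obs"].to_numpy()))


class TestParametricModel:
    def test_limits(self, truth_model):
        assert truth_model(0.0) == 0.0
        assert truth_model(1e6) == pytest.approx(0.25, abs=1e-12)
        assert truth_model.t_half_max == pytest.approx(24.0, abs=1e-9)

    def test_half_max_root(self):
        """The N=2 half-max root: P_reg(2, 1.6783) = 1/2."""
        m = SuccessModel(0.25, 2.0, 1.6783 / 24.0)
        assert m.t_half_max == pytest.approx(24.0, rel=1e-4)

    def test_invalid_parameters_rejected(self):
        for bad in [(0.0, 2, 0.1), (1.2, 2, 0.1), (0.25, 0.5, 0.1),
                    (0.25, 2, 0.0)]:
            with pytest.raises(ValueError):
                SuccessModel(*bad)

    def test_fit_recovers_model_on_clean_curve(self, truth_model):
        """Noiseless binned curve returns the generating parameters."""
        import pandas as pd

        from latkin.success import SuccessCurve

        t = np.array([2.0, 5.0, 9.0, 14.0, 20.0, 27.0, 35.0, 44.0, 54.0,
                      65.0, 77.0, 90.0])
        curve = SuccessCurve(t, np.asarray(truth_model(t)),
                             np.full_like(t, 0.01), np.full(len(t), 100))
        fit = SuccessProbabilityModel(curve).fit()
        assert fit.amplitude == pytest.approx(0.25, rel=1e-4)
        assert fit.shape == pytest.approx(2.0, rel=1e-3)
        assert fit.t_half_max == pytest.approx(24.0, rel=1e-4)

    def test_fit_on_synthetic_ensemble_is_sane(self, event_table):
        fit = SuccessProbabilityModel.from_events(event_table).fit()
        assert 0.1 < fit.amplitude < 0.45
        assert 10.0 < fit.t_half_max < 45.0
        assert fit.t_half_max_se > 0

    def test_too_few_bins_rejected(self):
        import pandas as pd

        ev = pd.DataFrame({"dwell_obs": [1.0, 2.0] * 30,
                           "productive": [False, True] * 30,
                           "delay": [np.nan, 1.0] * 30})
        with pytest.raises(ValueError):
            SuccessProbabilityModel.from_events(ev)


class TestPropensity:
    def test_constant_hazard_for_exponential_success(self):
        """P(t) = 1 - e^{-kt} has hazard identically k."""
        m = SuccessModel(1.0, 1.0, 0.05)
        t = np.linspace(0.0, 100.0, 50)
        prop = extract_propensity(m, t)
        np.testing.assert_allclose(prop.k_c, 0.05, rtol=1e-9)

    def test_amplitude_one_equals_gamma_hazard(self):
        """With a unit plateau the hazard is the N-step proofreading form."""
        m = SuccessModel(1.0, 2.0, 0.03)
        t = np.linspace(0.1, 150.0, 200)
        np.testing.assert_allclose(m.hazard(t), kpr_propensity(2.0, 0.03, t),
                                   rtol=1e-8)

    def test_round_trip_hazard_probability(self, truth_model):
        """extract -> integrate closes to 1e-6 sup-norm on [0, 120] s."""
        t = np.linspace(0.0, 120.0, 121)
        P = integrate_hazard(lambda x: truth_model.hazard(x), t)
        assert np.max(np.abs(P - truth_model(t))) < 1e-6

    def test_empirical_extraction_reproduces_rise_then_decline(self, truth_model):
        """Spline hazard from a well-sampled curve rises over ~15 s, then falls."""
        from latkin.success import SuccessCurve

        centers = np.array([2.0, 5.0, 9.0, 14.0, 20.0, 27.0, 35.0, 44.0,
                            54.0, 65.0, 77.0, 90.0])
        rng = np.random.default_rng(8)
        n = np.full(len(centers), 2000)
        p_true = np.asarray(truth_model(centers))
        p_hat = rng.binomial(n, p_true) / n
        curve = SuccessCurve(centers, p_hat, np.sqrt(p_hat * (1 - p_hat) / n), n)
        t = np.linspace(0.0, 80.0, 161)
        emp = extract_propensity(curve, t)
        assert np.all(emp.k_c >= 0.0)
        peak = t[np.argmax(emp.k_c)]
        assert 5.0 < peak < 35.0  # rise over roughly the first 15 s
        assert emp.k_c[-1] < emp.k_c.max()  # then a decline

    def test_empirical_extraction_nonnegative_on_noisy_ensemble(self, event_table):
        curve = bin_success(event_table,
                            make_bins(event_table["dwell_obs"].to_numpy()))
        t = np.linspace(0.0, 60.0, 121)
        emp = extract_propensity(curve, t)
        assert np.all(np.isfinite(emp.k_c)) and np.all(emp.k_c >= 0.0)


class TestAprioriSuccess:
    def test_quadrature_matches_closed_form(self, truth_model):
        for k in (1 / 6.0, 1 / 45.0, 1 / 10.0, 1.0):
            assert apriori_success(k, truth_model) == pytest.approx(
                apriori_success_closed_form(k, truth_model), abs=1e-8)

    def test_reference_ligand_values(self, truth_model):
        """Dwell-mixed success: 0.022 (6 s), ~0.135 (45 s), ~0.044 (10 s)."""
        assert apriori_success(1 / 6.0, truth_model) == pytest.approx(0.022,
                                                                      abs=5e-4)
        assert apriori_success(1 / 45.0, truth_model) == pytest.approx(0.135,
                                                                       rel=0.10)
        assert apriori_success(1 / 10.0, truth_model) == pytest.approx(0.044,
                                                                       rel=0.10)

    def test_limits_in_k_off(self, truth_model):
        assert apriori_success(1e4, truth_model) < 1e-6
        assert apriori_success(1e-6, truth_model) == pytest.approx(0.25,
                                                                   abs=1e-3)

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(0.005, 1.0), dk=st.floats(0.001, 0.5),
           a=st.floats(0.05, 0.9), da=st.floats(0.01, 0.1))
    def test_monotone_in_k_off_and_amplitude(self, k, dk, a, da):
        m1 = SuccessModel(a, 2.0, 0.07)
        m2 = SuccessModel(min(a + da, 1.0), 2.0, 0.07)
        p = apriori_success_closed_form
        assert p(k + dk, m1) < p(k, m1)
        assert p(k, m2) > p(k, m1)


class TestDelayDensity:
    def test_normalized_on_grid(self, truth_model):
        t = np.linspace(0.0, 300.0, 3001)
        d = observed_delay_density(1 / 23.8, truth_model, t)
        assert np.trapezoid(d.density, d.t) == pytest.approx(1.0, abs=1e-6)

    def test_zero_kobs_reduces_to_intrinsic_delay_density(self, truth_model):
        t = np.linspace(0.0, 400.0, 4001)
        d = observed_delay_density(0.0, truth_model, t)
        intrinsic = truth_model.pdf(t) / truth_model.amplitude
        np.testing.assert_allclose(d.density, intrinsic, atol=1e-6)

    def test_sampler_gof_against_closed_form(self, truth_model, rng):
        """5000 draws pass a KS test against the analytic observed density."""
        from scipy import integrate as sint
        from scipy import stats

        t = np.linspace(0.0, 300.0, 6001)
        d = observed_delay_density(1 / 23.8, truth_model, t)
        samples = d.sample(5000, rng)
        cdf_grid = sint.cumulative_trapezoid(d.density, t, initial=0.0)
        res = stats.kstest(samples, lambda x: np.interp(x, t, cdf_grid))
        assert res.pvalue > 0.01


class TestProductiveCounts:
    def test_zero_amplitude_gives_zeros(self, event_table):
        bins = make_bins(event_table["dwell_obs"].to_numpy())
        tiny = SuccessModel(1e-300, 2.0, 0.07)
        counts = productive_counts(bins, tiny, len(event_table), 1 / 23.8)
        assert np.allclose(counts, 0.0)

    def test_fine_bin_sum_matches_apriori(self, truth_model):
        """Riemann sum over fine bins converges to n * p(k_obs)."""
        bins = make_bins(np.array([400.0]), first_width=0.5, increment=0.0)
        counts = productive_counts(bins, truth_model, 1000.0, 1 / 23.8)
        expected = 1000.0 * apriori_success_closed_form(1 / 23.8, truth_model)
        assert counts.sum() == pytest.approx(expected, rel=0.05)

    def test_expected_counts_match_realized(self, event_table, truth_model):
        """Predicted per-bin productive counts agree with the ensemble."""
        bins = make_bins(event_table["dwell_obs"].to_numpy())
        curve = bin_success(event_table, bins)
        k_obs = 1 / 23.8  # generative truth of the fixture
        expected = productive_counts(bins, truth_model, len(event_table), k_obs)
        realized = bins.n_productive
        mask = expected > 1.0
        resid = np.abs(realized[mask] - expected[mask])
        assert np.all(resid < 3.5 * np.sqrt(expected[mask]) + 1.0)
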