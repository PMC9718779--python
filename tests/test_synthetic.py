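"""Generator fixtures must carry the statistical structure the analysis assumes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latkin import (EventGenConfig, PulseModel, SuccessModel,
                    apriori_success_closed_form, estimate_bleach_rate,
                    fit_frap, generate_bleach_series, generate_event_table,
                    generate_traces, lat_pulse, nfat_translocation_time,
                    sample_binding_arrivals, superpose_wholecell)


class TestEventTable:
    def test_dwell_marginal_is_exponential(self, truth_model):
        """KS test of the observed-dwell marginal against Exp(k_off + k_bleach)."""
        cfg = EventGenConfig(k_off=1 / 30.0, k_bleach=1 / 60.0,
                             plat_model=truth_model, n_events=5000,
                             t_resolution=0.0, seed=11)
        ev = generate_event_table(cfg)
        k_obs = 1 / 30.0 + 1 / 60.0
        stat = stats.kstest(ev["dwell_obs"], "expon", args=(0, 1 / k_obs))
        assert stat.pvalue > 0.01

    def test_bleach_fraction_matches_competing_rates(self, bleached_table):
        """Fraction of bleach-terminated events is k_bleach/(k_bleach + k_off)."""
        frac = (bleached_table["end_cause"] == "bleach").mean()
        expected = (1 / 99.0) / (1 / 99.0 + 1 / 44.0)
        n = len(bleached_table)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_productive_fraction_matches_dwell_mixed_success(self, event_table,
                                                             truth_model):
        """Overall productive fraction converges to the closed-form p(k_off)."""
        p = apriori_success_closed_form(1 / 23.8, truth_model)
        frac = event_table["productive"].mean()
        se = np.sqrt(p * (1 - p) / len(event_table))
        assert abs(frac - p) < 3 * se

    def test_delays_bounded_by_dwell(self, event_table):
        prod = event_table[event_table["productive"]]
        assert (prod["delay"] <= prod["dwell_obs"]).all()
        assert (prod["delay"] >= 0).all()
        non = event_table[~event_table["productive"]]
        assert non["delay"].isna().all()

    def test_zero_amplitude_model_yields_no_productive_events(self):
        flat = SuccessModel(1e-300, 2.0, 0.07)  # effectively zero plateau
        cfg = EventGenConfig(k_off=0.05, k_bleach=0.0, plat_model=flat,
                             n_events=100, t_resolution=0.0, seed=3)
        ev = generate_event_table(cfg)
        assert ev["productive"].sum() == 0

    def test_long_dwell_productive_fraction_approaches_plateau(self, truth_model):
        """Events bound far beyond t_half succeed with probability ~ amplitude."""
        cfg = EventGenConfig(k_off=1 / 500.0, k_bleach=0.0, plat_model=truth_model,
                             n_events=3000, t_resolution=0.0, seed=9)
        ev = generate_event_table(cfg)
        long = ev[ev["dwell_obs"] > 200.0]
        frac = long["productive"].mean()
        se = np.sqrt(0.25 * 0.75 / len(long))
        assert abs(frac - 0.25) < 3 * se

    def test_frame_discretization_contract(self, truth_model):
        """Dwells land on frame boundaries and sub-frame events are dropped."""
        cfg = EventGenConfig(k_off=0.1, k_bleach=0.0, plat_model=truth_model,
                             n_events=500, t_resolution=2.0, seed=5)
        ev = generate_event_table(cfg)
        assert len(ev) == 500
        assert (ev["dwell_obs"] >= 2.0).all()
        assert np.allclose(ev["dwell_obs"] % 2.0, 0.0)

    def test_reproducible_given_seed(self, truth_model):
        cfg = EventGenConfig(k_off=0.05, k_bleach=0.01, plat_model=truth_model,
                             n_events=200, seed=77)
        pd.testing.assert_frame_equal(generate_event_table(cfg),
                                      generate_event_table(cfg))

    def test_rejects_invalid_rates(self, truth_model):
        with pytest.raises(ValueError):
            EventGenConfig(k_off=np.inf, k_bleach=0.0, plat_model=truth_model,
                           n_events=10)
        with pytest.raises(ValueError):
            EventGenConfig(k_off=-1.0, k_bleach=0.0, plat_model=truth_model,
                           n_events=10)


class TestArrivals:
    def test_poisson_mean(self):
        counts = [len(sample_binding_arrivals(3.8, 0.5, 200.0, seed=s))
                  for s in range(200)]
        mean = np.mean(counts)
        se = np.sqrt(380.0 / 200)
        assert abs(mean - 380.0) < 3 * se

    def test_zero_density_gives_empty(self):
        assert len(sample_binding_arrivals(3.8, 0.0, 100.0, seed=0)) == 0

    def test_low_density_expected_count(self):
        """k_on 3.8 um^2/s at 0.1/um^2 over 60 s averages ~23 events."""
        counts = [len(sample_binding_arrivals(3.8, 0.1, 60.0, seed=s))
                  for s in range(300)]
        assert abs(np.mean(counts) - 22.8) < 3 * np.sqrt(22.8 / 300)


class TestPulses:
    def test_peak_equals_amplitude_at_peak_time(self):
        pulse = PulseModel(amplitude=258.0)
        t = np.linspace(0.0, 60.0, 6001)
        trace = lat_pulse(t, pulse)
        assert trace.max() == pytest.approx(258.0, rel=1e-4)
        assert t[np.argmax(trace)] == pytest.approx(pulse.peak_time, abs=0.05)

    def test_zero_before_onset(self):
        pulse = PulseModel()
        t = np.linspace(0.0, 50.0, 500)
        trace = lat_pulse(t, pulse, onset=20.0)
        assert np.all(trace[t <= 20.0] == 0.0)

    def test_unit_density_integrates_to_one(self):
        pulse = PulseModel()
        t = np.linspace(0.0, 300.0, 30001)
        assert np.trapezoid(pulse.density(t), t) == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_shape_scale(self):
        with pytest.raises(ValueError):
            PulseModel(shape=0.0)
        with pytest.raises(ValueError):
            PulseModel(scale=-1.0)


class TestWholeCell:
    @staticmethod
    def _delay_sampler(n, rng):
        return rng.gamma(2.0, 12.0, size=n)

    def test_first_detection_earlier_with_more_pulses(self):
        pulse = PulseModel()
        t_grid = np.arange(0.0, 400.0, 0.5)
        medians = []
        for n in (10, 100, 1000):
            firsts = []
            for seed in range(30):
                tr = superpose_wholecell(n, self._delay_sampler, pulse, seed=seed,
                                         t_grid=t_grid, threshold=300.0)
                if tr.first_detection is not None:
                    firsts.append(tr.first_detection)
            medians.append(np.median(firsts))
        assert medians[0] > medians[1] > medians[2]

    def test_unreachable_threshold_never_detects(self):
        pulse = PulseModel(amplitude=10.0)
        tr = superpose_wholecell(3, self._delay_sampler, pulse, seed=1,
                                 threshold=1e6)
        assert tr.first_detection is None

    def test_single_pulse_trace_is_shifted_pulse(self):
        pulse = PulseModel()
        t_grid = np.arange(0.0, 200.0, 0.5)
        tr = superpose_wholecell(1, lambda n, rng: np.full(n, 30.0), pulse,
                                 seed=0, t_grid=t_grid)
        expected = lat_pulse(t_grid, pulse, onset=30.0)
        np.testing.assert_allclose(tr.intensity, expected)


class TestBleachSeries:
    def test_zero_rate_is_constant(self):
        counts = generate_bleach_series(0.0, 500, 100, 2.0, seed=0)
        assert np.all(counts == 500)

    def test_counts_monotone_nonincreasing(self):
        counts = generate_bleach_series(0.02, 500, 150, 2.0, seed=1)
        assert np.all(np.diff(counts) <= 0)

    def test_fit_recovers_generating_rate(self):
        """1/99 s^-1 decay over 150 2-s frames is recovered within 3 SEM."""
        k = 1 / 99.0
        ks = [estimate_bleach_rate(
            generate_bleach_series(k, 500, 150, 2.0, seed=s), 2.0
        ).k_bleach for s in range(30)]
        sem = np.std(ks, ddof=1) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - k) < 3 * sem


class TestTraces:
    def test_frap_rate_recovered(self):
        trace = generate_traces("frap", {"k": 0.24, "noise_sd": 0.005}, seed=4)
        fit = fit_frap(trace)
        assert fit.rate == pytest.approx(0.24, rel=0.05)

    def test_nfat_noise_free_crossover_detected_exactly(self):
        trace = generate_traces("nfat", {"t_cross": 300.0, "noise_sd": 0.0})
        t = nfat_translocation_time(trace["nuclear"], trace["cytosolic"],
                                    trace["t"])
        assert t == 300.0

    def test_nfat_never_crossing_reports_none(self):
        trace = generate_traces("nfat", {"t_cross": None})
        assert nfat_translocation_time(trace["nuclear"], trace["cytosolic"],
                                       trace["t"]) is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_traces("calcium", {})
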