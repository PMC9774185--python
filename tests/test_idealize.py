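"""Idealization, NPo, dwell statistics, mixture fits and rate recovery."""

import numpy as np
import pytest

from pipgate import synth
from pipgate.idealize import (
    DwellSummary,
    EventList,
    compute_npo,
    dwell_summary,
    estimate_baseline,
    estimate_channel_count,
    fit_exponential_mixture,
    idealize,
    recover_rates_from_titration,
)
from pipgate.fitting import ExponentialMixture
from pipgate.kinetics import mean_sojourn_times, two_state_scheme
from pipgate.synth import Trace


def _trace(samples, dt=0.25, **meta):
    return Trace(sampling_interval=dt, samples=np.asarray(samples, dtype=float),
                 metadata=meta)


class TestEventList:
    def test_npo_equals_time_average_exactly(self):
        ev = EventList(levels=[0, 1, 2, 0], starts=[0, 40, 70, 80],
                       durations=[40, 30, 10, 20], total_time=100.0)
        assert compute_npo(ev) == pytest.approx((30 * 1 + 10 * 2) / 100.0)

    def test_worked_npo_arithmetic(self):
        # 100 s record: 30 s at one open channel, 10 s at two -> NPo = 0.5
        ev = EventList(levels=[0, 1, 2], starts=[0, 60_000, 90_000],
                       durations=[60_000, 30_000, 10_000], total_time=100_000.0)
        assert compute_npo(ev) == pytest.approx(0.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            EventList(levels=[0, 0], starts=[0, 10], durations=[10, 10], total_time=20.0)
        with pytest.raises(ValueError):
            EventList(levels=[0, 1], starts=[0, 10], durations=[10, 5], total_time=20.0)

    def test_all_closed_npo_zero(self):
        ev = EventList(levels=[0], starts=[0.0], durations=[50.0], total_time=50.0)
        assert compute_npo(ev) == 0.0

    def test_always_open_npo_one(self):
        ev = EventList(levels=[1], starts=[0.0], durations=[50.0], total_time=50.0)
        assert compute_npo(ev) == 1.0


class TestBaseline:
    def test_all_zero_trace(self):
        assert estimate_baseline(_trace(np.zeros(100))) == 0.0

    def test_constant_trace(self):
        assert estimate_baseline(_trace(np.full(100, 3.2))) == pytest.approx(3.2)

    def test_simulated_patch_baseline_within_half_noise(self, worked_scheme):
        scheme = two_state_scheme(0.001 / 4, 0.01)  # Po ~ 0.2 at 20 uM
        trace, _ = synth.simulate_patch(1, scheme, 20.0, 60_000.0, unit_current=0.5,
                                        noise_sd=0.1, filter_cutoff=None, seed=4)
        assert abs(estimate_baseline(trace)) < 0.05


class TestIdealize:
    def test_noiseless_square_pulse_recovered(self):
        dt = 0.25
        samples = np.zeros(1000)
        samples[400:600] = 1.0  # 50 ms open pulse
        ev = idealize(_trace(samples, dt), unit_current=1.0)
        open_ev = ev.durations[ev.levels == 1]
        assert len(open_ev) == 1
        assert open_ev[0] == pytest.approx(50.0, abs=dt)

    def test_polarity_mismatch_raises(self):
        samples = np.zeros(1000)
        samples[400:600] = -1.0
        with pytest.raises(ValueError, match="polarity"):
            idealize(_trace(samples), unit_current=+1.0)
        # correct signed unit current handles inward openings
        ev = idealize(_trace(samples), unit_current=-1.0)
        assert ev.max_level == 1

    def test_event_below_dead_time_missed(self):
        # 0.05/f_c pulse filtered to < half amplitude never crosses threshold
        fc = 100.0
        dt_ms = 1e3 / 40_000.0
        width_ms = 0.05 / fc * 1e3
        samples = np.zeros(40_000)
        n_open = int(width_ms / dt_ms)
        samples[20_000:20_000 + n_open] = 1.0
        path_trace = synth.render_trace(
            [synth.StatePath(np.array([0.0, 500.0, 500.0 + width_ms]),
                             np.array([0, 1, 0]), 1000.0)],
            [False, True], 1.0, 0.0, fc, 40_000.0, 0)
        ev = idealize(path_trace, unit_current=1.0, baseline=0.0)
        assert ev.max_level == 0

    def test_dwell_recovery_on_simulated_single_channel(self, worked_scheme):
        trace, _ = synth.simulate_patch(1, worked_scheme, 20.0, 400_000.0,
                                        unit_current=0.5, noise_sd=0.05,
                                        filter_cutoff=1000.0, sampling_rate=4000.0, seed=6)
        s = dwell_summary(idealize(trace, unit_current=0.5, max_levels=1, baseline=0.0))
        truth = mean_sojourn_times(worked_scheme, 20.0)
        assert s.mean_open == pytest.approx(truth.mean_open, rel=0.05)
        assert s.mean_closed == pytest.approx(truth.mean_closed, rel=0.05)


class TestChannelCount:
    def test_single_channel(self, worked_scheme):
        trace, _ = synth.simulate_patch(1, worked_scheme, 20.0, 60_000.0,
                                        unit_current=0.5, noise_sd=0.05,
                                        filter_cutoff=1000.0, seed=3)
        assert estimate_channel_count(trace, 0.5, baseline=0.0) == 1

    def test_three_channels_recovered(self):
        scheme = two_state_scheme(0.00043, 0.02)  # Po ~ 0.3 at 20 uM
        trace, truth = synth.simulate_patch(3, scheme, 20.0, 300_000.0,
                                            unit_current=0.5, noise_sd=0.05,
                                            filter_cutoff=1000.0, seed=9)
        assert truth.max_level == 3
        assert estimate_channel_count(trace, 0.5, baseline=0.0) == 3

    def test_underestimate_warning_at_low_po_short_record(self):
        scheme = two_state_scheme(2.6e-5, 0.01)  # Po ~ 0.05
        trace, _ = synth.simulate_patch(2, scheme, 20.0, 30_000.0,
                                        unit_current=0.5, noise_sd=0.05,
                                        filter_cutoff=1000.0, seed=12)
        with pytest.warns(UserWarning, match="underestimate"):
            estimate_channel_count(trace, 0.5, baseline=0.0)


class TestDwellSummary:
    def test_hand_means_and_censoring(self):
        # interior events: open 10, 30 ms -> mean 20; first/last excluded
        ev = EventList(levels=[1, 0, 1, 0, 1, 0],
                       starts=[0, 5, 25, 35, 75, 105],
                       durations=[5, 20, 10, 40, 30, 15], total_time=120.0)
        s = dwell_summary(ev)
        assert s.mean_open == pytest.approx(20.0)
        assert s.n_open_events == 2
        assert s.n_closed_events == 2  # censored final closed excluded

    def test_multichannel_rejected(self):
        ev = EventList(levels=[0, 2, 0], starts=[0, 10, 20],
                       durations=[10, 10, 10], total_time=30.0)
        with pytest.raises(ValueError, match="single-channel"):
            dwell_summary(ev)

    def test_knockout_mean_open_recovery(self):
        # closing rate 1/41.1 per ms as generative truth
        scheme = two_state_scheme(0.001, 1.0 / 41.1)
        trace, _ = synth.simulate_patch(1, scheme, 20.0, 190_000.0,
                                        unit_current=0.5, noise_sd=0.05,
                                        filter_cutoff=1000.0, seed=2)
        s = dwell_summary(idealize(trace, unit_current=0.5, max_levels=1))
        se = s.sd_open / np.sqrt(s.n_open_events)
        assert s.n_open_events >= 2000
        assert abs(s.mean_open - 41.1) < 2 * se


class TestMixture:
    def test_single_component_mle_is_sample_mean(self, rng):
        data = rng.exponential(25.0, size=500)
        fit = fit_exponential_mixture(data, n_components=1)
        assert fit.taus[0] == pytest.approx(data.mean(), rel=1e-6)

    def test_two_component_recovery(self, rng):
        data = np.concatenate([rng.exponential(10.0, size=2500),
                               rng.exponential(200.0, size=2500)])
        fit = fit_exponential_mixture(data, n_components=2, seed=1)
        assert fit.taus[0] == pytest.approx(10.0, rel=0.1)
        assert fit.taus[1] == pytest.approx(200.0, rel=0.1)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert fit.converged

    def test_em_likelihood_nondecreasing_in_iterations(self, rng):
        data = np.concatenate([rng.exponential(5.0, size=400),
                               rng.exponential(80.0, size=400)])
        lls = []
        for iters in (2, 5, 10, 50, 200):
            est = ExponentialMixture(n_components=2, max_iter=iters,
                                     n_init=1, random_state=3).fit(data)
            lls.append(est.log_likelihood_)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_two_open_states_detected_by_likelihood_ratio(self, worked_scheme):
        # open times of the aggregated two-state open class are a genuine
        # 2-exponential mixture: LRT must reject the single exponential
        path = synth.sample_path(worked_scheme, 20.0, 1_500_000.0, seed=8)
        d = path.durations()
        states = np.asarray(path.states)
        # aggregate open-class sojourns
        open_sojourns = []
        acc = 0.0
        for s, dur in zip(states, d):
            if s > 0:
                acc += dur
            elif acc > 0:
                open_sojourns.append(acc)
                acc = 0.0
        open_sojourns = np.array(open_sojourns)
        f1 = fit_exponential_mixture(open_sojourns, 1)
        f2 = fit_exponential_mixture(open_sojourns, 2, seed=2)
        lrt = 2 * (f2.log_likelihood - f1.log_likelihood)
        from scipy.stats import chi2
        assert chi2.sf(lrt, df=2) < 0.01

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_mixture(np.full(100, 3.0), 1)
        with pytest.raises(ValueError):
            fit_exponential_mixture(np.arange(1, 30, dtype=float), 2)  # < 50


class TestTitrationRecovery:
    def test_noiseless_closed_forms(self):
        # worked chain means at L = 10, 20, 50
        L = [10.0, 20.0, 50.0]
        summaries = [
            DwellSummary(mean_open=200.0, mean_closed=100.0, sd_open=1, sd_closed=1,
                         n_open_events=100, n_closed_events=100),
            DwellSummary(mean_open=300.0, mean_closed=50.0, sd_open=1, sd_closed=1,
                         n_open_events=100, n_closed_events=100),
            DwellSummary(mean_open=600.0, mean_closed=20.0, sd_open=1, sd_closed=1,
                         n_open_events=100, n_closed_events=100),
        ]
        r = recover_rates_from_titration(L, summaries)
        assert r.k_on1 == pytest.approx(0.001, rel=1e-10)
        assert r.k_off1 == pytest.approx(0.01, rel=1e-10)
        assert r.k2_ratio == pytest.approx(0.1, rel=1e-10)

    def test_simulated_titration_recovery(self, worked_scheme):
        L_values = [10.0, 20.0, 50.0]
        summaries = []
        for i, L in enumerate(L_values):
            trace, _ = synth.simulate_patch(1, worked_scheme, L, 450_000.0,
                                            unit_current=0.5, noise_sd=0.05,
                                            filter_cutoff=1000.0, seed=20 + i)
            summaries.append(dwell_summary(idealize(trace, 0.5, max_levels=1, baseline=0.0)))
        r = recover_rates_from_titration(L_values, summaries)
        assert r.k_on1 == pytest.approx(0.001, rel=0.1)
        assert r.k_off1 == pytest.approx(0.01, rel=0.2)
        assert r.k2_ratio == pytest.approx(0.1, rel=0.3)

    def test_too_few_concentrations_rejected(self):
        s = DwellSummary(1, 1, 1, 1, 10, 10)
        with pytest.raises(ValueError):
            recover_rates_from_titration([10.0, 20.0], [s, s])
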