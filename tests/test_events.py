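"""PSC event detection, classification, kinetics, and the oPSC/sPSC
ratio estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sparseconn import (
    EventParams,
    PSCEvent,
    SimConfig,
    Trace,
    classify_opto,
    detect_events,
    event_stats,
    fit_kinetics,
    latency_ms,
    ratio_histogram,
    simulate_opto_trial,
    simulate_spontaneous_pscs,
)
from sparseconn.core import VOLTAGE_CLAMP
from sparseconn.synth import psc_kernel, _add_events


def inject_events(fs, duration_s, times, amps, noise_sd, seed=0,
                  rise=0.5, decay=6.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, int(duration_s * fs))
    kern = psc_kernel(fs, rise, decay)
    _add_events(x, np.round(np.asarray(times) * fs).astype(int),
                -np.asarray(amps, dtype=float), kern)
    return Trace(x, fs, VOLTAGE_CLAMP)


class TestDetectEvents:
    def test_injection_recovery(self, fs):
        times = (np.arange(10) + 0.5) * 0.45
        tr = inject_events(fs, 5.0, times, [20.0] * 10, noise_sd=2.0)
        events = detect_events(tr, EventParams(polarity="inward"))
        assert len(events) == 10
        for ev, t in zip(events, times):
            assert ev.peak_amp_pA == pytest.approx(20.0, rel=0.10)
            assert ev.onset_s == pytest.approx(t, abs=2e-3)

    def test_noiseless_single_event_exact(self, fs):
        tr = inject_events(fs, 2.0, [1.0], [30.0], noise_sd=0.0)
        events = detect_events(tr, EventParams())
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_amp_pA == pytest.approx(30.0, rel=0.02)
        assert ev.onset_s == pytest.approx(1.0, abs=5e-4)

    def test_null_false_positive_rate_per_second(self, fs):
        # nominal false-positive budget: 0.1 events per second
        n_fp, seconds = 0, 0.0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tr = Trace(rng.normal(0, 2.0, int(60 * fs)), fs, VOLTAGE_CLAMP)
            n_fp += len(detect_events(tr, EventParams()))
            seconds += 60.0
        assert n_fp / seconds <= 0.1

    def test_amplitude_bias_small_at_high_snr(self, fs):
        # SNR 5 injections: mean recovered amplitude within 5% of truth
        times = (np.arange(60) + 0.5) * 0.1
        tr = inject_events(fs, 6.5, times, [10.0] * 60, noise_sd=2.0)
        events = detect_events(tr, EventParams())
        amps = np.array([e.peak_amp_pA for e in events])
        assert len(events) == 60
        assert abs(amps.mean() - 10.0) / 10.0 <= 0.05

    def test_unknown_polarity_rejected(self, fs):
        tr = inject_events(fs, 1.0, [0.5], [20.0], 1.0)
        with pytest.raises(ValueError):
            detect_events(tr, EventParams(polarity="sideways"))

    def test_same_method_for_both_event_kinds(self, fs):
        """Classification must not alter detection: the identical
        algorithm and alignment serve sPSCs and oPSCs."""
        cfg = SimConfig(seed=13)
        cfg.opto.n_connected = 2
        sw = simulate_opto_trial(cfg, n_pulses=30)
        tr = sw.trials[0]["post"]
        before = detect_events(tr, EventParams())
        onsets_before = [e.onset_s for e in before]
        amps_before = [e.peak_amp_pA for e in before]
        classify_opto(before, sw.metadata["light_times"])
        after = detect_events(tr, EventParams())
        assert [e.onset_s for e in after] == onsets_before
        assert [e.peak_amp_pA for e in after] == amps_before

    def test_robust_to_runaway_action_currents(self, fs):
        # opsin+ cells show brief very large action currents; the post-cell
        # analysis must not be confused when such artifacts are in-trace
        cfg = SimConfig(seed=14)
        cfg.opto.n_connected = 1
        sw = simulate_opto_trial(cfg, n_pulses=30, include_opsin_cell=True)
        post = detect_events(sw.trials[0]["post"], EventParams())
        assert len(post) > 20  # detection still functional on the post cell


class TestClassifyAndLatency:
    def _ev(self, onset, kind="spontaneous"):
        return PSCEvent(onset_s=onset, peak_s=onset + 0.002, peak_amp_pA=20.0,
                        kind=kind)

    def test_event_in_window_is_optogenetic(self):
        events = [self._ev(1.0 + 0.0073)]  # 7.3 ms after light
        classify_opto(events, [1.0])
        assert events[0].kind == "optogenetic"

    def test_event_far_after_light_is_spontaneous(self):
        events = [self._ev(1.5)]
        classify_opto(events, [1.0])
        assert events[0].kind == "spontaneous"

    def test_no_lights_all_spontaneous(self):
        events = [self._ev(0.3), self._ev(0.9)]
        classify_opto(events, [])
        assert all(e.kind == "spontaneous" for e in events)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            classify_opto([], [1.0, 1.01])

    def test_latency_constructed_value(self):
        ev = self._ev(2.0025, kind="optogenetic")
        assert latency_ms(ev, 2.0) == pytest.approx(2.5)

    def test_latency_zero_at_light_onset(self):
        ev = self._ev(2.0, kind="optogenetic")
        assert latency_ms(ev, 2.0) == 0.0

    def test_latency_requires_optogenetic_kind(self):
        with pytest.raises(ValueError):
            latency_ms(self._ev(2.0), 1.9)

    def test_onset_before_light_rejected(self):
        ev = self._ev(1.9, kind="optogenetic")
        with pytest.raises(ValueError):
            latency_ms(ev, 2.0)

    def test_jittered_simulation_recovers_mean_latency(self, fs):
        cfg = SimConfig(seed=15)
        cfg.opto.n_connected = 1
        cfg.opto.p_multiplet = 0.0
        cfg.opto.latency_mean_ms = 6.0
        sw = simulate_opto_trial(cfg, n_pulses=80)
        events = detect_events(sw.trials[0]["post"], EventParams())
        classify_opto(events, sw.metadata["light_times"])
        lights = np.asarray(sw.metadata["light_times"])
        lats = []
        for e in events:
            if e.kind == "optogenetic":
                i = np.searchsorted(lights, e.onset_s) - 1
                lats.append(latency_ms(e, lights[i]))
        assert len(lats) > 50
        # onset is the 10%-of-peak crossing, slightly after the true latency
        assert np.mean(lats) == pytest.approx(6.0, abs=1.0)


class TestEventStats:
    def _events(self, spsc_amps, opsc_amps=()):
        evs = [PSCEvent(0.0, 0.0, a, kind="spontaneous") for a in spsc_amps]
        evs += [PSCEvent(0.0, 0.0, a, kind="optogenetic") for a in opsc_amps]
        return evs

    def test_top5_mean_of_1_to_100(self):
        st_ = event_stats(self._events(np.arange(1.0, 101.0)))
        assert st_.top5_mean_pA == pytest.approx(98.0)

    def test_reported_group_means_give_ratio_1_6(self):
        # groups constructed with means 20.3 (sPSC) and 32.8 pA (oPSC)
        spsc = 20.3 + np.linspace(-5, 5, 40)
        opsc = 32.8 + np.linspace(-8, 8, 20)
        st_ = event_stats(self._events(spsc, opsc))
        assert st_.mean_spsc_pA == pytest.approx(20.3)
        assert st_.mean_opsc_pA == pytest.approx(32.8)
        assert st_.ratio == pytest.approx(32.8 / 20.3)
        assert round(st_.ratio, 1) == 1.6
        assert st_.est_presyn_count == 2  # 1.62 rounds up

    def test_matched_populations_give_unit_ratio(self):
        amps = 20.0 + np.linspace(-3, 3, 30)
        st_ = event_stats(self._events(amps, amps))
        assert st_.ratio == pytest.approx(1.0)
        assert st_.est_presyn_count == 1

    def test_no_opsc_estimates_zero_sources(self):
        st_ = event_stats(self._events(np.linspace(10, 30, 25)))
        assert np.isnan(st_.ratio)
        assert st_.est_presyn_count == 0

    def test_no_spsc_returns_unavailable(self):
        assert event_stats(self._events([], [20.0])) is None

    def test_too_few_spsc_for_top5_rejected(self):
        with pytest.raises(ValueError):
            event_stats(self._events(np.linspace(10, 30, 5)))

    @given(st.lists(st.floats(1.0, 500.0), min_size=20, max_size=200))
    @settings(max_examples=50, derandomize=True)
    def test_top5_mean_always_at_least_mean(self, amps):
        st_ = event_stats(self._events(amps))
        assert st_.top5_mean_pA >= st_.mean_spsc_pA - 1e-9


class TestKinetics:
    def test_noiseless_kernel_decay_recovered(self, fs):
        kern = 25.0 * psc_kernel(fs, 0.5, 10.0, length_ms=80.0)
        out = fit_kinetics(kern, fs)
        assert out is not None
        rise, tau = out
        assert tau == pytest.approx(10.0, abs=0.1)
        assert 0.3 < rise < 1.5

    def test_shape_invariance_under_scaling(self, fs):
        kern = psc_kernel(fs, 0.5, 8.0, length_ms=60.0)
        r1, t1 = fit_kinetics(10 * kern, fs)
        r2, t2 = fit_kinetics(170 * kern, fs)
        assert r1 == pytest.approx(r2, rel=1e-6)
        assert t1 == pytest.approx(t2, rel=1e-6)

    def test_incomplete_decay_unavailable(self, fs):
        kern = psc_kernel(fs, 0.5, 10.0, length_ms=12.0)  # cut before 20%
        assert fit_kinetics(kern, fs) is None

    def test_compound_biphasic_event_flagged(self, fs):
        # two superposed PSCs 4 ms apart: one compound detection whose
        # amplitude is the full compound peak, kinetics withheld
        tr = inject_events(fs, 2.0, [1.0, 1.004], [20.0, 20.0], noise_sd=1.0)
        events = detect_events(tr, EventParams())
        assert len(events) == 1
        ev = events[0]
        assert ev.compound
        assert ev.peak_amp_pA > 25.0  # full compound peak, not single-template
        assert np.isnan(ev.rise_ms) and np.isnan(ev.decay_tau_ms)


class TestRatioHistogram:
    def _stats(self, ratio):
        return event_stats.__wrapped__ if False else None

    def test_unit_ratios_fall_in_one_bin(self):
        from sparseconn.events import CellEventStats
        stats = [CellEventStats(30, 5, 20.0, 30.0, 20.0, 1.0, 1)
                 for _ in range(6)]
        edges, counts, mean, sd = ratio_histogram(stats)
        assert counts.sum() == 6
        assert (counts > 0).sum() == 1
        assert mean == 1.0 and sd == 0.0

    def test_mixture_of_one_and_two_sources_is_bimodal(self):
        ratios = []
        for i, nc in enumerate([1, 2] * 6):
            cfg = SimConfig(seed=40 + i)
            cfg.opto.n_connected = nc
            sw = simulate_opto_trial(cfg, n_pulses=40)
            events = detect_events(sw.trials[0]["post"], EventParams())
            classify_opto(events, sw.metadata["light_times"])
            st_ = event_stats(events)
            ratios.append(st_.est_presyn_count)
        assert set(ratios) <= {1, 2, 3}
        assert ratios.count(1) >= 4 and ratios.count(2) >= 4
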