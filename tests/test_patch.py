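import numpy as np
import pytest
from scipy.optimize import brentq

from dopaphys import (
    CurrentTrace,
    DetectionConfig,
    TraceSimConfig,
    ahp_measures,
    biexp_kernel,
    cell_summary,
    detect_minis,
    event_kinetics,
    gaba_evoked_peak,
    ih_and_passive,
    percent_blockade,
    pool_for_cumulative,
    simulate_mipsc_trace,
    simulate_step_response,
)
from dopaphys.errors import ProtocolError, ResolutionError, ValidationError

from conftest import make_noise_trace

TAU_RISE, TAU_DECAY = 1.5, 7.0


def analytic_rise_10_90(tau_rise, tau_decay):
    """Closed-form 10-90 % rise time of the biexponential, by root-finding."""
    t_pk = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)

    def f(t):
        return biexp_kernel(np.array([t]), tau_rise, tau_decay)[0]

    t10 = brentq(lambda t: f(t) - 0.1, 1e-9, t_pk)
    t90 = brentq(lambda t: f(t) - 0.9, 1e-9, t_pk)
    return t90 - t10


def single_event_trace(amp=30.0, fs=10000.0, onset=0.1, tau_rise=TAU_RISE,
                       tau_decay=TAU_DECAY, noise_sd=0.0, seed=0, duration=0.5):
    t = np.arange(int(duration * fs)) / fs
    cur = -amp * biexp_kernel((t - onset) * 1e3, tau_rise, tau_decay)
    if noise_sd:
        cur = cur + np.random.default_rng(seed).normal(0, noise_sd, cur.size)
    return CurrentTrace("one", fs, cur, -60.0, protocol="mipsc")


class TestDetection:
    def test_pure_noise_yields_no_events(self):
        assert detect_minis(make_noise_trace(seed=1, noise_sd=1.5)) == []

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ResolutionError):
            detect_minis(make_noise_trace(seed=1, fs=1000.0, duration=5.0))

    def test_wrong_protocol_rejected(self):
        trace, _ = simulate_step_response("ahp", {"amplitude_pa": 50.0, "tau_ms": 20.0})
        with pytest.raises(ProtocolError):
            detect_minis(trace)

    def test_recovery_against_generator_truth(self, mipsc_trace_and_truth):
        trace, truth = mipsc_trace_and_truth
        events = detect_minis(trace)
        n_true = truth["onset_times"].size
        freq = len(events) / trace.duration
        assert freq == pytest.approx(n_true / trace.duration, rel=0.10)
        det = np.array([e.onset_time for e in events])
        hits = sum(np.min(np.abs(det - t)) < 2e-3 for t in truth["onset_times"])
        assert hits / n_true >= 0.90

    def test_detection_translation_invariance(self):
        trace, _ = simulate_mipsc_trace(TraceSimConfig(duration=20.0, seed=5))
        shifted = CurrentTrace(
            trace.cell_id, trace.sampling_rate, trace.current + 150.0,
            trace.holding_potential, protocol="mipsc",
        )
        a = [e.peak_time for e in detect_minis(trace)]
        b = [e.peak_time for e in detect_minis(shifted)]
        assert a == b

    def test_overlapping_pair_flagged_double(self):
        fs = 10000.0
        t = np.arange(int(0.5 * fs)) / fs
        cur = -30.0 * biexp_kernel((t - 0.1) * 1e3, TAU_RISE, TAU_DECAY)
        cur -= 30.0 * biexp_kernel((t - 0.107) * 1e3, TAU_RISE, TAU_DECAY)
        trace = CurrentTrace("pair", fs, cur, -60.0, protocol="mipsc")
        events = detect_minis(trace)
        assert 1 <= len(events) <= 2
        assert all(e.is_double_peak for e in events)
        summ = cell_summary(events, trace)
        assert summ.n_events == 0  # nothing accepted for kinetics/amplitude


class TestKinetics:
    def test_noiseless_event_exact_recovery(self):
        trace = single_event_trace()
        (ev,) = event_kinetics(detect_minis(trace), trace)
        assert ev.amplitude == pytest.approx(30.0, rel=0.01)
        assert ev.decay_tau == pytest.approx(TAU_DECAY, rel=0.01)
        assert ev.rise_time_10_90 == pytest.approx(
            analytic_rise_10_90(TAU_RISE, TAU_DECAY), rel=0.03
        )

    @pytest.mark.parametrize("tau", [5.0, 7.0, 9.0, 12.0])
    def test_noisy_tau_recovery_within_10_percent(self, tau):
        taus = []
        for seed in range(25):
            trace = single_event_trace(
                amp=30.0, tau_decay=tau, noise_sd=2.0, seed=seed
            )
            events = event_kinetics(detect_minis(trace), trace)
            taus.extend(e.decay_tau for e in events if np.isfinite(e.decay_tau))
        assert np.median(taus) == pytest.approx(tau, rel=0.10)

    def test_table_regime_ensemble_tau(self):
        """tau_decay = 8.5 ms regime, noisy ensemble: mean within 10 %."""
        trace, _ = simulate_mipsc_trace(
            TraceSimConfig(seed=17, tau_rise=1.9, tau_decay=8.5, duration=60.0)
        )
        events = event_kinetics(detect_minis(trace), trace)
        taus = [e.decay_tau for e in events if np.isfinite(e.decay_tau)]
        assert len(taus) > 50
        assert np.median(taus) == pytest.approx(8.5, rel=0.10)


class TestCellSummary:
    def test_49_events_no_kinetics_but_amplitude_reported(self):
        trace, _ = simulate_mipsc_trace(TraceSimConfig(duration=60.0, seed=3))
        events = detect_minis(trace)
        accepted = [e for e in events if not e.is_double_peak][:49]
        assert len(accepted) == 49
        summ = cell_summary(accepted, trace)
        assert summ.n_events == 49
        assert np.isnan(summ.averaged_decay_tau)
        assert np.isfinite(summ.mean_amplitude)
        assert summ.event_frequency > 0

    def test_empty_event_list(self):
        trace = make_noise_trace(seed=2, duration=10.0)
        summ = cell_summary([], trace)
        assert summ.n_events == 0
        assert summ.event_frequency == 0.0
        assert np.isnan(summ.mean_amplitude)

    def test_averaged_waveform_tau_matches_per_event(self, mipsc_trace_and_truth):
        trace, _ = mipsc_trace_and_truth
        events = event_kinetics(detect_minis(trace), trace)
        summ = cell_summary(events, trace)
        per_event = cell_summary(events, trace, kinetics_mode="per_event")
        assert summ.averaged_decay_tau == pytest.approx(TAU_DECAY, rel=0.10)
        assert per_event.averaged_decay_tau == pytest.approx(
            summ.averaged_decay_tau, rel=0.15
        )


class TestPooling:
    def test_pool_size_and_determinism(self):
        rng = np.random.default_rng(0)
        cells = {f"c{i}": rng.normal(30, 5, 150) for i in range(3)}
        pooled, excluded = pool_for_cumulative(cells, events_per_cell=100, seed=9)
        assert pooled.size == 300 and not excluded
        pooled2, _ = pool_for_cumulative(cells, events_per_cell=100, seed=9)
        np.testing.assert_array_equal(pooled, pooled2)

    def test_under_sampled_cell_excluded(self):
        cells = {"big": np.ones(120), "small": np.ones(40)}
        pooled, excluded = pool_for_cumulative(cells, events_per_cell=100, seed=1)
        assert excluded == ["small"]
        assert pooled.size == 100

    def test_shifted_distributions_detected_by_ks(self):
        """5 pA amplitude shift across ~15 cells/group: KS p < 0.01."""
        from dopaphys import ks_test

        rng = np.random.default_rng(3)
        a = {f"a{i}": rng.normal(30, 5, 150) for i in range(15)}
        b = {f"b{i}": rng.normal(25, 5, 150) for i in range(15)}
        pa, _ = pool_for_cumulative(a, seed=1)
        pb, _ = pool_for_cumulative(b, seed=2)
        assert ks_test(pa, pb).p_value < 0.01


class TestEvoked:
    def test_gaba_plateau_peak(self):
        trace, truth = simulate_step_response(
            "gaba_puff", {"amplitude_pa": 800.0, "duration": 1.5, "plateau_s": 0.5}
        )
        r = gaba_evoked_peak(trace)
        assert r.peak_amplitude == pytest.approx(truth["peak_pa"], rel=1e-6)
        assert r.direction == "inward"

    def test_cohort_means_recovered(self):
        rng = np.random.default_rng(7)
        for mean_pa in (825.0, 491.0):
            peaks = []
            for c in range(12):
                amp = max(rng.normal(mean_pa, 150.0), 50.0)
                trace, _ = simulate_step_response(
                    "gaba_puff",
                    {"amplitude_pa": amp, "noise_sd": 3.0, "duration": 1.5,
                     "plateau_s": 0.5},
                    seed=c,
                )
                peaks.append((gaba_evoked_peak(trace).peak_amplitude, amp))
            measured, truth = zip(*peaks)
            assert np.mean(measured) == pytest.approx(np.mean(truth), rel=0.05)

    def test_percent_blockade(self):
        control, _ = simulate_step_response(
            "gaba_puff", {"amplitude_pa": 800.0, "duration": 1.5, "plateau_s": 0.5}
        )
        blocked, _ = simulate_step_response(
            "gaba_puff", {"amplitude_pa": 80.0, "duration": 1.5, "plateau_s": 0.5}
        )
        rc, rb = gaba_evoked_peak(control), gaba_evoked_peak(blocked)
        assert percent_blockade(rc, rb) == pytest.approx(10.0, abs=0.1)
        assert percent_blockade(rc, rc) == pytest.approx(100.0)
        zero = simulate_step_response(
            "gaba_puff", {"amplitude_pa": 1e-9, "duration": 1.5, "plateau_s": 0.5}
        )[0]
        assert percent_blockade(rc, gaba_evoked_peak(zero)) == pytest.approx(0.0, abs=0.01)

    def test_blockade_undefined_for_zero_control(self):
        from dopaphys.datatypes import EvokedResponse

        zero = EvokedResponse("z", 0.0, 0.0, (0.0, 1.0))
        ok = EvokedResponse("c", 100.0, 0.0, (0.0, 1.0))
        with pytest.raises(ValidationError):
            percent_blockade(zero, ok)


class TestAHP:
    def test_analytic_charge_transfer(self):
        trace, _ = simulate_step_response(
            "ahp", {"amplitude_pa": 100.0, "tau_ms": 50.0, "duration": 1.0}
        )
        r = ahp_measures(trace)
        assert r.peak_amplitude == pytest.approx(100.0, rel=0.01)
        assert r.charge_transfer == pytest.approx(5000.0, rel=0.01)

    def test_noisy_peak_recovery(self):
        trace, truth = simulate_step_response(
            "ahp",
            {"amplitude_pa": 662.0, "tau_ms": 16.3, "noise_sd": 2.0, "duration": 1.0},
            seed=5,
        )
        r = ahp_measures(trace)
        assert r.peak_amplitude == pytest.approx(truth["peak_pa"], rel=0.05)

    def test_zero_tail_flagged(self):
        trace, _ = simulate_step_response(
            "ahp", {"amplitude_pa": 0.0, "tau_ms": 50.0, "noise_sd": 1.0}, seed=2
        )
        r = ahp_measures(trace)
        assert r.zero_response
        assert r.peak_amplitude == 0.0

    def test_charge_error_decreases_with_sampling_rate(self):
        # long trace so the window-truncation term (identical at every
        # rate) is negligible and the discretization error is what is left
        errs = []
        for fs in (5000.0, 10000.0, 50000.0):
            trace, _ = simulate_step_response(
                "ahp",
                {"amplitude_pa": 100.0, "tau_ms": 50.0, "duration": 3.0,
                 "t_pulse_end": 0.2, "sampling_rate": fs},
            )
            r = ahp_measures(trace)
            errs.append(abs(r.charge_transfer - 5000.0))
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[0] < 50.0  # all within 1 %


class TestIhAndPassive:
    def test_sag_recovery(self):
        trace, _ = simulate_step_response("ih", {"sag_pa": 425.0, "duration": 2.0})
        assert ih_and_passive(trace).i_h == pytest.approx(425.0, rel=0.02)

    def test_zero_sag(self):
        trace, _ = simulate_step_response("ih", {"sag_pa": 0.0, "duration": 2.0})
        assert ih_and_passive(trace).i_h == pytest.approx(0.0, abs=1.0)

    def test_rc_passive_recovery_within_2_percent(self):
        trace, _ = simulate_step_response(
            "seal_test",
            {"rs_mohm": 15.0, "rm_mohm": 366.0, "cm_pf": 122.0, "step_mv": 10.0,
             "duration": 0.6},
        )
        p = ih_and_passive(trace, step_mv=10.0)
        assert p.rs == pytest.approx(15.0, rel=0.02)
        assert p.rm == pytest.approx(366.0, rel=0.02)
        assert p.cm == pytest.approx(122.0, rel=0.02)

    def test_missing_step_size_rejected(self):
        trace, _ = simulate_step_response(
            "seal_test",
            {"rs_mohm": 15.0, "rm_mohm": 366.0, "cm_pf": 122.0, "duration": 0.6},
        )
        with pytest.raises(ProtocolError):
            ih_and_passive(trace)


class TestFalsePositiveRate:
    def test_below_0p05_per_second_on_pure_noise(self):
        total_events, total_s = 0, 0.0
        for seed in range(3):
            trace = make_noise_trace(seed=seed, noise_sd=2.0, duration=120.0)
            total_events += len(detect_minis(trace))
            total_s += trace.duration
        assert total_events / total_s < 0.05
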