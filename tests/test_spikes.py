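import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopaphys import (
    SpikeTrain,
    SpikeTrainSimConfig,
    burst_stats,
    cohort_firing_table,
    cv_of_isis,
    detect_bursts,
    qc_filter_units,
    simulate_spike_train,
)
from dopaphys.errors import InsufficientDataError, ValidationError

from conftest import make_train


def bursts_by_rule_string(isis_ms):
    """Independent burst finder: encode each ISI as a symbol and let the
    regex engine apply the two rules verbatim — a burst is a leftmost
    maximal run of one sub-80 ms onset interval followed by any number of
    intervals that do not exceed 160 ms.

    Returns a list of (first_spike, last_spike) index pairs.
    """
    code = "".join(
        "s" if isi < 80.0 else ("m" if isi <= 160.0 else "l") for isi in isis_ms
    )
    out = []
    for match in re.finditer(r"s[sm]*", code):
        a, b = match.span()  # ISIs a..b-1 -> spikes a..b
        out.append((a, b))
    return out


def detector_pairs(train):
    return [(b.first_spike_index, b.last_spike_index) for b in detect_bursts(train)]


class TestBurstDetection:
    def test_hand_enumerated_two_bursts(self, six_spike_train):
        assert detector_pairs(six_spike_train) == [(0, 2), (4, 5)]

    def test_no_onset_no_bursts(self):
        train = make_train([100] * 6)
        assert detector_pairs(train) == []

    def test_continuation_band_extends_but_does_not_open(self):
        # ISIs 50, 120, 50: one burst of 4 spikes
        assert detector_pairs(make_train([50, 120, 50])) == [(0, 3)]
        # a 120 ms ISI alone cannot open a burst
        assert detector_pairs(make_train([120, 120])) == []

    def test_boundary_ties(self):
        # exactly 80 ms does not open; exactly 160 ms continues
        assert detector_pairs(make_train([80.0, 80.0])) == []
        assert detector_pairs(make_train([50.0, 160.0, 170.0])) == [(0, 2)]

    def test_fewer_than_two_spikes_empty(self):
        assert len(detect_bursts(SpikeTrain("u", [0.5], 2.0))) == 0
        assert len(detect_bursts(SpikeTrain("u", [], 2.0))) == 0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([40.0, 100.0, 120.0, 200.0]), min_size=1, max_size=12)
    )
    def test_matches_independent_rule_applier(self, isis):
        assert detector_pairs(make_train(isis)) == bursts_by_rule_string(isis)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=5.0, max_value=500.0, allow_nan=False),
            min_size=1,
            max_size=15,
        ),
        st.floats(min_value=0.0, max_value=50.0),
    )
    def test_translation_invariance(self, isis, shift):
        a = detector_pairs(make_train(isis))
        times = 0.1 + shift + np.concatenate([[0.0], np.cumsum(np.asarray(isis) / 1e3)])
        b = detector_pairs(SpikeTrain("u", times, times[-1] + shift + 1.0))
        assert a == b

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=5.0, max_value=500.0, allow_nan=False),
            min_size=2,
            max_size=12,
        )
    )
    def test_late_spike_locality(self, isis):
        """Appending a spike > 160 ms after the last never changes existing bursts."""
        before = detector_pairs(make_train(isis))
        after = detector_pairs(make_train(isis + [200.0]))
        assert [p for p in after if p[1] <= len(isis)] == before


class TestBurstStats:
    def test_swb_counting(self, six_spike_train):
        st_ = burst_stats(six_spike_train, detect_bursts(six_spike_train))
        assert st_.swb == pytest.approx(100.0 * 5 / 6)
        assert st_.n_bursts == 2

    def test_tonic_train_zero_swb(self):
        train = make_train([200.0] * 8, epoch=3.0)
        st_ = burst_stats(train, detect_bursts(train))
        assert st_.swb == 0.0
        assert st_.burst_frequency == 0.0
        assert np.isnan(st_.mean_burst_duration)

    def test_single_burst_frequency_arithmetic(self):
        train = make_train([50.0] * 9, epoch=120.0)
        st_ = burst_stats(train, detect_bursts(train))
        assert st_.burst_frequency == pytest.approx(1.0 / 120.0)
        assert st_.swb == 100.0
        assert st_.mean_rate == pytest.approx(10.0 / 120.0)

    def test_mismatched_train_rejected(self, six_spike_train):
        other = make_train([50.0, 50.0], unit_id="other")
        with pytest.raises(ValidationError):
            burst_stats(six_spike_train, detect_bursts(other))

    def test_swb_boundary_iff_properties(self):
        """SWB = 0 iff no ISI < 80 ms; SWB = 100 iff every spike in a burst."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            isis = rng.uniform(10.0, 400.0, rng.integers(2, 30))
            train = make_train(isis)
            bs = detect_bursts(train)
            st_ = burst_stats(train, bs)
            if (isis < 80.0).any():
                assert st_.swb > 0.0
            else:
                assert st_.swb == 0.0
            assert (st_.swb == 100.0) == bs.in_burst_mask(train.n_spikes).all()

    def test_detector_swb_equals_generator_labels(self):
        cfg = SpikeTrainSimConfig(
            mean_rate=5.0, in_burst_fraction_target=0.67, epoch_duration=120.0,
            n_units=10, seed=3, isi_model="two_state_burst",
        )
        trains, labels = simulate_spike_train(cfg)
        for tr, lab in zip(trains, labels):
            mask = detect_bursts(tr).in_burst_mask(tr.n_spikes)
            np.testing.assert_array_equal(mask, lab)


class TestQC:
    def test_long_duration_in_vivo_unit_accepted(self):
        tr = make_train([100.0] * 5, spike_durations=[1.5] * 6)
        acc, rej = qc_filter_units([tr])
        assert len(acc) == 1 and not rej

    def test_short_duration_in_vivo_unit_rejected_with_reason(self):
        tr = make_train([100.0] * 5, spike_durations=[0.9] * 6)
        acc, rej = qc_filter_units([tr])
        assert not acc
        assert rej[0][1] == "duration<1.1ms"

    def test_in_vitro_short_spikes_dropped(self):
        tr = make_train(
            [100.0, 100.0], spike_durations=[2.5, 1.0, 2.5], setting="in_vitro"
        )
        (pruned,), _ = qc_filter_units([tr])
        assert pruned.n_spikes == 2
        assert (pruned.spike_durations >= 2.0).all()

    def test_missing_durations_is_validation_error(self):
        with pytest.raises(ValidationError):
            qc_filter_units([make_train([100.0] * 3)])


class TestCVofISIs:
    def test_periodic_train_zero_cv(self):
        cv, fit = cv_of_isis(make_train([200.0] * 15))
        assert cv == pytest.approx(0.0, abs=1e-9)
        assert fit.fallback_used

    def test_pacemaker_parameter_recovery(self):
        """mu 500 ms, sigma 25 ms, ~2000 ISIs: Gaussian-fit CV = 5 +/- 1 %."""
        cfg = SpikeTrainSimConfig(
            mean_rate=2.0, inter_event_isi=(500.0, 25.0), epoch_duration=1001.0,
            seed=21, isi_model="pacemaker_gaussian",
        )
        (tr,), _ = simulate_spike_train(cfg)
        assert tr.n_spikes > 1900
        cv, fit = cv_of_isis(tr)
        assert fit.fit_ok and not fit.fallback_used
        assert cv == pytest.approx(5.0, abs=1.0)
        assert fit.mu == pytest.approx(500.0, rel=0.02)

    def test_bimodal_isis_use_fallback_and_exceed_unimodal(self):
        bimodal = make_train([50.0, 500.0] * 30)
        cv_b, fit_b = cv_of_isis(bimodal)
        unimodal = make_train(
            (275.0 + 10.0 * np.sin(np.arange(60))).tolist()
        )
        cv_u, _ = cv_of_isis(unimodal)
        isis = np.asarray([50.0, 500.0] * 30)
        sample_cv = 100.0 * isis.std(ddof=1) / isis.mean()
        if fit_b.fallback_used:
            assert cv_b == pytest.approx(sample_cv)
        assert cv_b > cv_u

    def test_too_few_isis_raises(self):
        with pytest.raises(InsufficientDataError):
            cv_of_isis(make_train([100.0] * 5))


class TestCohortTable:
    def test_one_row_per_unit(self):
        cfg = SpikeTrainSimConfig(epoch_duration=30.0, n_units=3, seed=2)
        trains, _ = simulate_spike_train(cfg)
        table = cohort_firing_table(trains)
        assert len(table) == 3
        assert list(table["unit_id"]) == [t.unit_id for t in trains]

    def test_group_swb_ordering_follows_generator_targets(self):
        tables = []
        for seed, target, n in ((1, 0.31, 12), (2, 0.67, 12)):
            cfg = SpikeTrainSimConfig(
                mean_rate=5.0, in_burst_fraction_target=target,
                epoch_duration=120.0, n_units=n, seed=seed,
                isi_model="two_state_burst", group=f"target{target}",
            )
            trains, _ = simulate_spike_train(cfg)
            tables.append(cohort_firing_table(trains))
        low, high = tables
        assert high["swb_percent"].mean() > low["swb_percent"].mean() + 20.0

    def test_empty_input_header_only(self):
        table = cohort_firing_table([])
        assert table.empty
        assert "swb_percent" in table.columns

    def test_qc_failed_unit_never_appears(self):
        good = make_train([100.0] * 12, unit_id="good", spike_durations=[1.5] * 13)
        bad = make_train([100.0] * 12, unit_id="bad", spike_durations=[0.8] * 13)
        acc, _ = qc_filter_units([good, bad])
        table = cohort_firing_table(acc)
        assert "bad" not in set(table["unit_id"])
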