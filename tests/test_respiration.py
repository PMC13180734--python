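"""Breath detection, IBI extraction, apnoea screening and rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neobag import respiration as R
from neobag import synthetic as S


def _amp_ratio(freq, fs=62.5, dur=120.0):
    t = np.arange(0, dur, 1 / fs)
    out = R.filter_ip(R.IPSignal(np.sin(2 * np.pi * freq * t), fs=fs))
    mid = out.samples[int(30 * fs):int(90 * fs)]
    return np.max(np.abs(mid))


class TestFilter:
    def test_respiratory_band_preserved(self):
        assert _amp_ratio(1.0) > 0.95

    def test_cardiac_band_attenuated(self):
        assert _amp_ratio(2.3) < 0.20

    def test_dc_removed(self):
        sig = R.IPSignal(np.full(3000, 10.0), fs=62.5)
        assert abs(R.filter_ip(sig).samples.mean()) < 1e-6

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            R.filter_ip(R.IPSignal(np.zeros(10), fs=62.5))


class TestDetectBreaths:
    def test_clean_train_counts_and_intervals(self):
        sig, truth = S.simulate_ip(60.0, 60.0, noise_spec=S.NoiseSpec.none(),
                                   seed=1)
        breaths = R.detect_breaths(R.filter_ip(sig))
        assert abs(len(breaths) - 60) <= 1
        ibis = R.extract_ibis(breaths)
        assert np.all(np.abs(ibis.intervals - 1.0) < 0.016)

    def test_no_breaths_inside_silence(self):
        sig, _ = S.simulate_ip(120.0, 60.0, apnoea_spec=[(50.0, 20.0)],
                               noise_spec=S.NoiseSpec.none(), seed=2)
        times = [b.onset_time for b in R.detect_breaths(R.filter_ip(sig))]
        assert not any(50.5 < t < 69.5 for t in times)

    def test_shallow_segment_below_threshold(self):
        # breaths at 0.2x the local amplitude fall below 0.4*SD
        sig, _ = S.simulate_ip(120.0, 60.0, shallow_spec=[(40.0, 20.0, 0.2)],
                               noise_spec=S.NoiseSpec.none(), seed=3)
        times = [b.onset_time for b in R.detect_breaths(R.filter_ip(sig))]
        assert not any(40.5 < t < 59.5 for t in times)

    def test_all_zero_signal_gives_no_breaths(self):
        assert R.detect_breaths(R.IPSignal(np.zeros(5000), fs=62.5)) == []

    def test_amplitude_rescaling_invariance(self):
        sig, _ = S.simulate_ip(300.0, 55.0, apnoea_spec=[(100.0, 20.0)], seed=4)
        t1 = np.array([b.onset_time for b in R.detect_breaths(R.filter_ip(sig))])
        scaled = R.IPSignal(sig.samples * 37.5, fs=sig.fs)
        t2 = np.array([b.onset_time
                       for b in R.detect_breaths(R.filter_ip(scaled))])
        assert len(t1) == len(t2)
        np.testing.assert_allclose(t1, t2, atol=1e-9)


class TestExtractIbis:
    @pytest.mark.parametrize("onsets, expected", [
        ([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0]),
        ([0.0, 1.0, 21.0], [1.0, 20.0]),
    ])
    def test_interval_examples(self, onsets, expected):
        breaths = [R.BreathEvent(t, 1.0) for t in onsets]
        assert R.extract_ibis(breaths).intervals.tolist() == expected

    def test_non_monotone_onsets_rejected(self):
        breaths = [R.BreathEvent(t, 1.0) for t in (0.0, 2.0, 1.0)]
        with pytest.raises(ValueError, match="increasing"):
            R.extract_ibis(breaths)

    def test_fewer_than_two_breaths_rejected(self):
        with pytest.raises(ValueError):
            R.extract_ibis([R.BreathEvent(0.0, 1.0)])


class TestApnoeaScreen:
    def test_balanced_accuracy_on_synthetic_segments(self, apnoea_clf):
        assert apnoea_clf.holdout_balanced_accuracy >= 0.9

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            R.train_apnoea_classifier(np.random.default_rng(0).normal(size=(20, 3)),
                                      np.ones(20))

    def test_unlearnable_labels_give_chance_accuracy(self):
        x = np.tile(np.array([[1.0, 2.0, 3.0]]), (40, 1))
        y = np.tile([0, 1], 20)
        clf = R.train_apnoea_classifier(x, y, seed=0)
        assert abs(clf.holdout_balanced_accuracy - 0.5) < 0.2

    def test_training_deterministic(self):
        feats, labels = S.make_apnoea_training_set(30, seed=5)
        a = R.train_apnoea_classifier(feats, labels, seed=1)
        b = R.train_apnoea_classifier(feats, labels, seed=1)
        grid = np.random.default_rng(0).normal(size=(50, 3))
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_true_apnoea_vs_shallow_labels(self, apnoea_clf):
        sig, _ = S.simulate_ip(180.0, 60.0, apnoea_spec=[(60.0, 20.0)], seed=6)
        ibis = R.extract_ibis(R.detect_breaths(R.filter_ip(sig)))
        events = R.classify_long_ibis(ibis, sig, apnoea_clf)
        assert [e.label for e in events] == [R.LABEL_APNOEA]

        # noise-free so the undetectable shallow segment yields a long IBI
        sig2, _ = S.simulate_ip(180.0, 60.0,
                                shallow_spec=[(60.0, 20.0, 0.2)],
                                noise_spec=S.NoiseSpec.none(), seed=7)
        ibis2 = R.extract_ibis(R.detect_breaths(R.filter_ip(sig2)))
        events2 = R.classify_long_ibis(ibis2, sig2, apnoea_clf)
        assert all(e.label == R.LABEL_REJECTED for e in events2)
        assert len(events2) >= 1

    def test_exactly_15s_is_not_a_candidate(self, apnoea_clf):
        ibis = R.IBISeries(intervals=np.array([1.0, 15.0, 1.0]),
                           interval_start_times=np.array([0.0, 1.0, 16.0]),
                           total_duration_h=17.0 / 3600)
        sig = R.IPSignal(np.zeros(2000), fs=62.5)
        assert R.classify_long_ibis(ibis, sig, apnoea_clf) == []

    def test_untrained_classifier_rejected(self):
        ibis = R.IBISeries(intervals=np.array([20.0]),
                           interval_start_times=np.array([0.0]),
                           total_duration_h=0.01)
        with pytest.raises(RuntimeError, match="trained"):
            R.classify_long_ibis(ibis, R.IPSignal(np.zeros(4000), fs=62.5),
                                 R.ApnoeaClassifier())


def _series(intervals):
    intervals = np.asarray(intervals, float)
    return R.IBISeries(intervals=intervals,
                       interval_start_times=np.concatenate(
                           [[0.0], np.cumsum(intervals[:-1])]),
                       total_duration_h=float(intervals.sum()) / 3600)


class TestRates:
    @pytest.mark.parametrize("intervals, expected", [
        ([1.5] * 10, 40.0),
        ([1.0, 1.0, 1.0, 20.0], 60.0),      # median is robust to the apnoea
    ])
    def test_respiratory_rate_examples(self, intervals, expected):
        assert R.respiratory_rate(_series(intervals)) == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0.3, max_value=40.0), min_size=1,
                    max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_respiratory_rate_matches_median_oracle(self, intervals):
        oracle = 60.0 / float(np.median(np.asarray(intervals)))
        assert R.respiratory_rate(_series(intervals)) == pytest.approx(oracle)

    def test_respiratory_rate_empty_rejected(self):
        empty = R.IBISeries(intervals=np.array([]),
                            interval_start_times=np.array([]),
                            total_duration_h=1.0)
        with pytest.raises(ValueError):
            R.respiratory_rate(empty)

    def test_apnoea_rate_examples(self):
        evs = [R.ApnoeaEvent(0.0, 20.0, R.LABEL_APNOEA)] * 4
        assert R.apnoea_rate(evs, 2.0) == pytest.approx(2.0)
        assert R.apnoea_rate([], 2.0) == 0.0
        with pytest.raises(ValueError):
            R.apnoea_rate(evs, 0.0)

    def test_rejected_ibis_never_increase_apnoea_count(self):
        evs = [R.ApnoeaEvent(0.0, 20.0, R.LABEL_APNOEA),
               R.ApnoeaEvent(100.0, 30.0, R.LABEL_REJECTED)]
        assert R.apnoea_rate(evs, 1.0) == 1.0
        kept = R.drop_rejected_ibis(
            _series([1.0, 20.0, 1.0, 30.0, 1.0]),
            [R.ApnoeaEvent(1.0, 20.0, R.LABEL_APNOEA),
             R.ApnoeaEvent(22.0, 30.0, R.LABEL_REJECTED)])
        assert 30.0 not in kept.intervals
        assert 20.0 in kept.intervals

    @pytest.mark.parametrize("n, passed", [(0, False), (99, False),
                                           (100, True), (500, True)])
    def test_qc_boundary(self, n, passed):
        series = _series([1.0] * n) if n else R.IBISeries(
            intervals=np.array([]), interval_start_times=np.array([]),
            total_duration_h=0.1)
        assert R.qc_recording(series) is passed

    def test_recovered_rate_matches_inserted_events(self, apnoea_clf):
        rng = np.random.default_rng(11)
        apnoeas = S.draw_apnoea_events(3600.0, 6.0, rng)
        sig, truth = S.simulate_ip(3600.0, 55.0, apnoea_spec=apnoeas, seed=11)
        ibis = R.extract_ibis(R.detect_breaths(R.filter_ip(sig)))
        events = R.classify_long_ibis(ibis, sig, apnoea_clf)
        summary = R.summarise_recording(ibis, events)
        n_detected = summary.apnoea_rate * ibis.total_duration_h
        assert abs(n_detected - len(truth.apnoeas)) <= 1.0
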