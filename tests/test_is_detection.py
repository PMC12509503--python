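"""Detector, scoring, tuning, and the solitary/BIRD/seizure taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spikelapse import is_detection as isd
from spikelapse import synthetic_data as sd


def _clean_trace(times, duration=60.0, amp=1500.0, noise=0.0):
    cfg = sd.SynthConfig(seed=9, duration_s=duration, is_amp_uV=amp,
                         noise_rms_uV=noise, theta_amp_uV=0.0)
    return sd.make_lfp(cfg, np.asarray(times))


class TestOrientPolarity:
    def test_positive_transients_unchanged(self):
        tr = _clean_trace([10.0, 20.0])
        out = isd.orient_polarity(tr)
        assert np.array_equal(out.samples, tr.samples)

    def test_negated_trace_flipped_back(self):
        tr = _clean_trace([10.0, 20.0])
        neg = isd.LfpTrace(samples=-tr.samples, fs_hz=tr.fs_hz)
        out = isd.orient_polarity(neg)
        assert np.allclose(out.samples, tr.samples)

    def test_skew_sign_inverted_on_output(self, rng):
        x = -rng.gamma(1.0, 1.0, 20000)  # strongly negative skew
        sk_in = stats.skew(x)
        out = isd.orient_polarity(isd.LfpTrace(samples=x, fs_hz=1000.0))
        assert stats.skew(out.samples) == pytest.approx(-sk_in, rel=1e-9)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            isd.orient_polarity(isd.LfpTrace(samples=np.ones(100), fs_hz=1000.0))


class TestDetectSpikes:
    CFG = isd.DetectorConfig(threshold_uV=900.0, low_hz=2.0, high_hz=400.0)

    def test_zero_trace_gives_no_detections(self):
        tr = isd.LfpTrace(samples=np.zeros(5000), fs_hz=1000.0)
        assert len(isd.detect_spikes(tr, self.CFG)) == 0

    def test_planted_transients_recovered(self):
        truth = [5.0, 12.0, 20.0, 33.0, 47.0]
        tr = _clean_trace(truth)
        det = isd.detect_spikes(tr, self.CFG)
        assert len(det) == 5
        assert np.all(np.abs(det - np.array(truth)) <= 0.015)

    def test_threshold_above_max_prominence_empty(self):
        tr = _clean_trace([5.0, 12.0])
        det = isd.detect_spikes(tr, isd.DetectorConfig(10_000.0, 2.0, 400.0))
        assert len(det) == 0

    def test_count_monotone_in_threshold(self):
        tr = _clean_trace([5.0, 12.0, 20.0], noise=300.0)
        counts = [
            len(isd.detect_spikes(tr, isd.DetectorConfig(thr, 2.0, 400.0)))
            for thr in (300, 600, 900, 1200, 1500, 3000)
        ]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))

    def test_infeasible_passband_rejected(self):
        tr = isd.LfpTrace(samples=np.zeros(5000), fs_hz=1000.0)
        with pytest.raises(ValueError):
            isd.detect_spikes(tr, isd.DetectorConfig(900.0, 2.0, 600.0))

    def test_resamples_other_rates(self):
        cfg = sd.SynthConfig(seed=9, duration_s=30.0, fs_hz=2000.0,
                             noise_rms_uV=0.0, theta_amp_uV=0.0)
        tr = sd.make_lfp(cfg, np.array([10.0]))
        det = isd.detect_spikes(tr, self.CFG)
        assert len(det) == 1 and abs(det[0] - 10.0) <= 0.015


class TestScoreDetector:
    def test_hand_worked_example(self):
        # windows: one single-hit, one double-hit, one missed; one stray
        wins = [isd.LabeledWindow(0.0, 1.0), isd.LabeledWindow(2.0, 3.0),
                isd.LabeledWindow(4.0, 5.0)]
        det = np.array([0.5, 2.2, 2.8, 7.0])
        s = isd.score_detector(det, wins)
        assert (s.tp, s.fp, s.fn) == (2, 2, 1)
        assert s.precision == pytest.approx(0.5)
        assert s.recall == pytest.approx(2 / 3)
        assert s.f_beta == pytest.approx(0.526, abs=5e-4)

    def test_perfect_detection(self):
        wins = [isd.LabeledWindow(i, i + 0.5) for i in range(5)]
        det = np.array([i + 0.25 for i in range(5)])
        s = isd.score_detector(det, wins)
        assert s.precision == s.recall == s.f_beta == 1.0

    def test_table_row_m2(self):
        assert round(isd.f_beta(0.97, 0.76, 0.5), 2) == 0.92

    def test_overlapping_windows_rejected(self):
        wins = [isd.LabeledWindow(0.0, 1.0), isd.LabeledWindow(0.5, 2.0)]
        with pytest.raises(ValueError):
            isd.score_detector(np.array([0.1]), wins)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            isd.f_beta(0.5, 0.5, beta=0.0)

    @given(p1=st.floats(0.01, 1.0), p2=st.floats(0.01, 1.0), r=st.floats(0.01, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_f_beta_monotone_in_precision(self, p1, p2, r):
        lo, hi = sorted([p1, p2])
        assert isd.f_beta(lo, r) <= isd.f_beta(hi, r) + 1e-12


class TestTuneDetector:
    def test_single_element_grid_returned(self):
        tr = _clean_trace([5.0, 12.0])
        wins = sd.make_labeled_windows(np.array([5.0, 12.0]),
                                       rng=np.random.default_rng(0))
        only = isd.DetectorConfig(800.0, 2.0, 400.0)
        cfg, _ = isd.tune_detector(tr, wins, [only])
        assert cfg == only

    def test_argmax_over_grid(self):
        tr = _clean_trace([5.0, 12.0, 20.0], noise=300.0)
        tr = isd.orient_polarity(tr)
        wins = sd.make_labeled_windows(np.array([5.0, 12.0, 20.0]),
                                       rng=np.random.default_rng(0))
        grid = [isd.DetectorConfig(t, lo, 400.0)
                for t in (300.0, 900.0, 1400.0) for lo in (2.0, 8.0)]
        best_cfg, best = isd.tune_detector(tr, wins, grid)
        for g in grid:
            s = isd.score_detector(isd.detect_spikes(tr, g), wins)
            assert best.f_beta >= s.f_beta - 1e-12


class TestTaxonomy:
    def test_single_spike_is_solitary(self):
        ev = isd.classify_events(np.array([10.0]))
        assert list(ev.labels) == ["solitary"]

    def test_worked_example_two_birds_one_solitary(self):
        ev = isd.classify_events(np.array([0.0, 0.5, 1.0, 10.0, 20.0, 20.5]))
        assert list(ev.labels) == ["bird_first", "bird_within", "bird_last",
                                   "solitary", "bird_first", "bird_last"]
        assert list(ev.bird_id) == [0, 0, 0, -1, 1, 1]

    def test_all_long_isis_all_solitary(self):
        ev = isd.classify_events(np.array([0.0, 3.0, 6.0, 9.0]))
        assert np.all(ev.labels == "solitary")

    @given(st.lists(st.floats(0.0, 500.0), min_size=0, max_size=60, unique=True))
    @settings(deadline=None, max_examples=60)
    def test_partition_property(self, times):
        times = np.sort(np.array(times))
        ev = isd.classify_events(times)
        n_bird = np.sum(ev.labels != "solitary")
        n_sol = np.sum(ev.labels == "solitary")
        assert n_bird + n_sol == len(times)
        # members of a bird are consecutive with ISIs < 2 s
        for b in np.unique(ev.bird_id[ev.bird_id >= 0]):
            t = ev.times_s[ev.bird_id == b]
            assert len(t) >= 2 and np.all(np.diff(t) < isd.BIRD_ISI_S)

    def test_seizure_detected_from_long_train(self):
        times = np.arange(0, 15.5, 0.5)
        spans = isd.detect_seizures(times)
        assert spans == [(0.0, 15.0)]

    def test_short_train_is_not_a_seizure(self):
        times = np.arange(0, 8.5, 0.5)
        assert isd.detect_seizures(times) == []

    def test_empty_input(self):
        assert isd.detect_seizures(np.array([])) == []


class TestEventStatistics:
    def test_rates_and_bird_summaries(self):
        times = np.concatenate([np.linspace(0, 4, 5), [50.0], [70.0]])
        ev = isd.classify_events(times)
        stats_ = isd.event_statistics(ev, 100.0)
        assert stats_["is_rate_hz"] == pytest.approx(0.07)
        assert stats_["solitary_rate_hz"] == pytest.approx(0.02)
        assert stats_["bird_rate_hz"] == pytest.approx(0.01)
        assert stats_["bird_durations_s"][0] == pytest.approx(4.0)
        assert stats_["spikes_per_bird"][0] == 5

    def test_pooled_rate_conserved_regardless_of_taxonomy(self, rng):
        times = np.sort(rng.uniform(0, 500, 80))
        ev = isd.classify_events(times)
        stats_ = isd.event_statistics(ev, 500.0)
        assert stats_["is_rate_hz"] == pytest.approx(len(times) / 500.0)
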