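import warnings

import numpy as np
import pytest

from sleepbelt import ecg as ep
from sleepbelt import synthetic as syn
from sleepbelt.types import InsufficientDataError, QualitySegment, RPeakSeries, SignalRecord


def _ecg_record(samples, fs=250.0):
    return SignalRecord(channel="ecg", device="belt", fs=fs, t0=0.0,
                        samples=np.asarray(samples, dtype=float))


def _spike_train(times, fs=250.0, duration=12.0, sigma=0.01):
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    for c in times:
        x += np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return _ecg_record(x, fs)


class TestDetectRPeaks:
    def test_zero_signal_empty(self):
        rec = _ecg_record(np.zeros(250 * 15))
        assert len(ep.detect_r_peaks(rec)) == 0

    def test_wrong_channel(self):
        rec = SignalRecord(channel="excursion", device="belt", fs=250.0,
                           t0=0.0, samples=np.zeros(250 * 15))
        with pytest.raises(ValueError):
            ep.detect_r_peaks(rec)

    def test_too_short(self):
        rec = _ecg_record(np.zeros(250 * 5))
        with pytest.raises(InsufficientDataError):
            ep.detect_r_peaks(rec)

    def test_refractory_merges_close_peaks(self):
        # two candidates 100 ms apart -> only one survives
        rec = _spike_train([5.0, 5.1])
        peaks = ep.detect_r_peaks(rec)
        assert len(peaks) == 1

    def test_matches_ground_truth(self, clean_ecg):
        peaks = ep.detect_r_peaks(clean_ecg)
        gt = clean_ecg.truth["r_times"]
        d = np.abs(peaks.times[:, None] - gt[None, :]).min(axis=0)
        assert np.mean(d < 0.020) >= 0.99


def _make_complex_matrix(rng, n_beats=10, n_samples=30, noise=0.0):
    base = np.sin(np.linspace(0, np.pi, n_samples)) + 0.3
    return base[None, :] + noise * rng.standard_normal((n_beats, n_samples))


class TestSegmentR:
    def test_identical_complexes_r_one(self, rng):
        mat = _make_complex_matrix(rng, noise=0.0)
        assert ep.segment_r(mat) == pytest.approx(1.0)

    def test_noise_complexes_low_r(self, rng):
        mat = rng.standard_normal((10, 30))
        assert ep.segment_r(mat) < 0.5

    def test_too_few_beats_undefined(self, rng):
        assert np.isnan(ep.segment_r(_make_complex_matrix(rng)[:2]))

    def test_brute_force_oracle(self, rng):
        # direct per-beat Pearson against the median reference
        for _ in range(20):
            n = rng.integers(3, 20)
            mat = _make_complex_matrix(rng, n_beats=int(n), noise=0.3)
            ref = np.median(mat, axis=0)
            expected = np.mean([np.corrcoef(row, ref)[0, 1] for row in mat])
            assert ep.segment_r(mat) == pytest.approx(expected, rel=1e-12)

    def test_noise_never_increases_r_statistically(self, rng):
        clean = [ep.segment_r(_make_complex_matrix(np.random.default_rng(s), noise=0.05))
                 for s in range(30)]
        noisy = [ep.segment_r(_make_complex_matrix(np.random.default_rng(s), noise=0.5))
                 for s in range(30)]
        assert np.mean(noisy) < np.mean(clean)


class TestCorrelationVerdict:
    def test_exact_threshold_not_accepted(self):
        # strict inequality at 0.98
        assert not ep.correlation_verdict(0.98, 0.98)

    def test_above_threshold_accepted_either_complex(self):
        assert ep.correlation_verdict(0.981, 0.10)
        assert ep.correlation_verdict(0.10, 0.981)

    def test_undefined_rs_rejected(self):
        assert not ep.correlation_verdict(float("nan"), float("nan"))


class TestPlausibilityVerdict:
    def test_narrow_band_accepted(self):
        assert ep.plausibility_verdict(np.array([800.0, 810.0, 820.0]))

    def test_below_333_rejected(self):
        assert not ep.plausibility_verdict(np.array([800.0, 250.0, 820.0]))

    def test_above_2000_rejected(self):
        assert not ep.plausibility_verdict(np.array([800.0, 2100.0]))

    def test_deviation_rule(self):
        # 1100/800 - 1 = 37.5% > 33%
        assert not ep.plausibility_verdict(np.array([800.0, 800.0, 1100.0]))

    def test_empty_rejected(self):
        assert not ep.plausibility_verdict(np.array([]))

    def test_exact_band_edges_accepted(self):
        assert ep.plausibility_verdict(np.array([333.0, 333.0]))
        assert ep.plausibility_verdict(np.array([2000.0, 2000.0]))


class TestSegmentTemplateQuality:
    def test_clean_night_accepted_by_correlation(self, clean_ecg):
        peaks = ep.detect_r_peaks(clean_ecg)
        segments = ep.segment_template_quality(clean_ecg, peaks)
        frac = np.mean([s.verdict == "accepted_by_correlation" for s in segments])
        assert frac >= 0.99

    def test_white_noise_not_accepted_by_correlation(self, rng):
        x = rng.standard_normal(250 * 30)
        rec = _ecg_record(x)
        peaks = ep.detect_r_peaks(rec)
        segments = ep.segment_template_quality(rec, peaks)
        assert all(s.verdict != "accepted_by_correlation" for s in segments)

    def test_segment_count(self, clean_ecg):
        peaks = ep.detect_r_peaks(clean_ecg)
        segments = ep.segment_template_quality(clean_ecg, peaks, segment_s=15.0)
        assert len(segments) == int(np.ceil(clean_ecg.duration / 15.0))


def _uniform_peaks(duration=120.0, rr_s=1.0):
    return RPeakSeries(times=np.arange(0.2, duration, rr_s))


def _segments_for(peaks, duration=120.0, reject=()):
    segs = []
    for k in range(int(duration / 15)):
        verdict = "rejected" if k in reject else "accepted_by_correlation"
        r = 0.5 if k in reject else 0.999
        segs.append(QualitySegment(start=15.0 * k, duration=15.0,
                                   r_qrs=r, r_pqrst=r, verdict=verdict, n_beats=15))
    return segs


class TestFilteredRR:
    def test_all_accepted_identity(self):
        peaks = _uniform_peaks()
        out = ep.filtered_rr(peaks, _segments_for(peaks))
        np.testing.assert_array_equal(out.times, peaks.times)
        t, rr = out.valid_rr()
        assert len(rr) == len(peaks) - 1

    def test_one_rejected_segment_drops_about_15_intervals(self):
        peaks = _uniform_peaks()
        out = ep.filtered_rr(peaks, _segments_for(peaks, reject={3}))
        _, rr = out.valid_rr()
        n_dropped = (len(peaks) - 1) - len(rr)
        assert 14 <= n_dropped <= 16

    def test_all_rejected_empty_with_warning(self):
        peaks = _uniform_peaks()
        segs = _segments_for(peaks, reject=set(range(8)))
        with pytest.warns(UserWarning):
            out = ep.filtered_rr(peaks, segs)
        assert len(out) == 0

    def test_no_gap_spanning_intervals(self):
        peaks = _uniform_peaks()
        out = ep.filtered_rr(peaks, _segments_for(peaks, reject={2, 5}))
        _, rr = out.valid_rr()
        assert rr.max() < 2000.0  # no ~15 s pseudo-interval leaks through


class TestFilterSoundness:
    def test_surviving_rr_in_band_or_correlation_accepted(self, rng):
        # mixed night: corrupt one stretch, check every surviving interval
        spec = syn.SubjectSpec("s", ahi=20.0, noise_level=0.3, seed=8)
        events = syn.schedule_apneas(spec, 300.0, 8)
        rec = syn.synthesize_ecg(spec, events, fs=250.0, duration=300.0)
        rec = syn.inject_artifacts(rec, 0.2, 8)
        peaks = ep.detect_r_peaks(rec)
        segments = ep.segment_template_quality(rec, peaks)
        out = ep.filtered_rr(peaks, segments)
        t, rr = out.valid_rr()
        starts = np.array([s.start for s in segments])
        for ti, ri in zip(t, rr):
            k = int(np.clip(np.searchsorted(starts, ti, side="right") - 1,
                            0, len(segments) - 1))
            assert segments[k].accepted
            if segments[k].verdict == "accepted_by_plausibility":
                assert 333.0 <= ri <= 2000.0


class TestQualitySummary:
    def test_perfect_segments(self):
        segs = [QualitySegment(start=15.0 * k, duration=15.0, r_qrs=1.0,
                               r_pqrst=1.0, verdict="accepted_by_correlation",
                               n_beats=15) for k in range(4)]
        s = ep.quality_summary(segs)
        assert s.r_mean == pytest.approx(1.0)
        assert s.r_sd == pytest.approx(0.0)
        assert s.fraction_accepted == 1.0

    def test_half_rejected_fraction(self):
        segs = _segments_for(_uniform_peaks(), reject={0, 1, 2, 3})
        assert ep.quality_summary(segs).fraction_accepted == pytest.approx(0.5)

    def test_r_mean_matches_brute_force(self, rng):
        segs = []
        for k in range(12):
            r = float(rng.uniform(0.2, 1.0))
            v = "accepted_by_correlation" if r > 0.98 else "rejected"
            segs.append(QualitySegment(start=15.0 * k, duration=15.0,
                                       r_qrs=r, r_pqrst=r - 0.1, verdict=v,
                                       n_beats=10))
        expected = np.mean([max(s.r_qrs, s.r_pqrst) for s in segs])
        assert ep.quality_summary(segs).r_mean == pytest.approx(expected)

    def test_no_defined_r_raises(self):
        segs = [QualitySegment(start=0.0, duration=15.0, r_qrs=float("nan"),
                               r_pqrst=float("nan"), verdict="rejected", n_beats=0)]
        with pytest.raises(InsufficientDataError):
            ep.quality_summary(segs)


class TestEndToEnd:
    def test_noise_free_night_high_acceptance(self, clean_ecg):
        _, segments, summary = ep.filter_ecg(clean_ecg)
        assert summary.fraction_accepted >= 0.99
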