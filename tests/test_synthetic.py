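import numpy as np
import pytest

from sleepbelt import synthetic as syn
from sleepbelt import ecg as ep


class TestScheduleApneas:
    def test_zero_rate_gives_empty_schedule(self):
        spec = syn.SubjectSpec("s", ahi=0.0, seed=0)
        assert syn.schedule_apneas(spec, 7 * 3600.0, 0) == []

    def test_negative_duration_rejected(self):
        spec = syn.SubjectSpec("s", ahi=10.0, seed=0)
        with pytest.raises(ValueError):
            syn.schedule_apneas(spec, -1.0, 0)

    def test_deterministic_given_seed(self):
        spec = syn.SubjectSpec("s", ahi=33.0, seed=0)
        a = syn.schedule_apneas(spec, 3600.0, 42)
        b = syn.schedule_apneas(spec, 3600.0, 42)
        assert [(e.onset, e.duration, e.type) for e in a] == \
               [(e.onset, e.duration, e.type) for e in b]

    def test_mean_count_matches_rate(self):
        # Monte-Carlo over seeds: mean count within 3 SE of ahi * hours
        spec = syn.SubjectSpec("s", ahi=33.0, seed=0)
        counts = np.array([len(syn.schedule_apneas(spec, 7 * 3600.0, s))
                           for s in range(1000)])
        expected = 33.0 * 7
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 1.0  # +1 edge-truncation slack

    def test_events_fit_and_do_not_overlap(self):
        spec = syn.SubjectSpec("s", ahi=60.0, seed=0)
        for seed in range(20):
            events = syn.schedule_apneas(spec, 60.0, seed)
            for ev in events:
                assert 0 <= ev.onset and ev.end <= 60.0
                assert ev.duration >= 10.0
            # brute-force pairwise overlap check
            for i, a in enumerate(events):
                for b in events[i + 1:]:
                    assert a.end <= b.onset or b.end <= a.onset


class TestSynthesizeEcg:
    def test_low_fs_rejected(self, clean_subject):
        with pytest.raises(ValueError, match="125"):
            syn.synthesize_ecg(clean_subject, [], fs=100.0, duration=60.0)

    def test_constant_rhythm_beat_count(self, clean_subject):
        rec = syn.synthesize_ecg(clean_subject, [], fs=250.0, duration=60.0)
        peaks = ep.detect_r_peaks(rec)
        assert abs(len(peaks) - 60) <= 1

    def test_rr_variability_elevated_around_events(self):
        spec = syn.SubjectSpec("s", ahi=30.0, seed=3)
        events = syn.schedule_apneas(spec, 1800.0, 3)
        assert events
        rec = syn.synthesize_ecg(spec, events, fs=250.0, duration=1800.0)
        r_times = rec.truth["r_times"][:-1]
        rr = rec.truth["rr_ms"]
        in_event = np.zeros(len(rr), dtype=bool)
        for ev in events:
            in_event |= (r_times >= ev.onset) & (r_times < ev.end + 15.0)
        assert in_event.any() and (~in_event).any()
        assert rr[in_event].std(ddof=1) > rr[~in_event].std(ddof=1)

    def test_ground_truth_rr_in_plausibility_band(self):
        for seed in range(5):
            spec = syn.SubjectSpec("s", ahi=45.0, seed=seed)
            events = syn.schedule_apneas(spec, 900.0, seed)
            rec = syn.synthesize_ecg(spec, events, fs=250.0, duration=900.0)
            rr = rec.truth["rr_ms"]
            assert rr.min() >= 333.0 and rr.max() <= 2000.0


class TestSynthesizeExcursion:
    def test_low_fs_rejected(self, clean_subject):
        with pytest.raises(ValueError):
            syn.synthesize_excursion(clean_subject, [], fs=5.0, duration=60.0)

    def test_baseline_breath_count(self, clean_subject):
        rec = syn.synthesize_excursion(clean_subject, [], fs=25.0, duration=60.0)
        onsets = rec.truth["onset_times"]
        in_first_minute = onsets[onsets < 60.0]
        assert abs(len(in_first_minute) - 14) <= 1

    def test_central_event_flattens_signal(self):
        spec = syn.SubjectSpec("s", ahi=5.0, seed=4)
        ev = syn.ApneaEvent(onset=60.0, duration=20.0, type="central")
        rec = syn.synthesize_excursion(spec, [ev], fs=25.0, duration=180.0)
        t = rec.times
        inside = rec.samples[(t > 62.0) & (t < 78.0)]
        outside = rec.samples[(t > 10.0) & (t < 50.0)]
        assert np.ptp(inside) < 0.05 * np.ptp(outside)

    def test_obstructive_event_amplitude_drop(self):
        spec = syn.SubjectSpec("s", ahi=5.0, seed=4)
        ev = syn.ApneaEvent(onset=60.0, duration=20.0, type="obstructive")
        rec = syn.synthesize_excursion(spec, [ev], fs=25.0, duration=180.0)
        t = rec.times
        inside = rec.samples[(t > 62.0) & (t < 78.0)]
        outside = rec.samples[(t > 10.0) & (t < 50.0)]
        assert np.ptp(inside) <= 0.30 * np.ptp(outside)  # >= 70% reduction

    def test_ground_truth_rate_in_band_outside_events(self):
        spec = syn.SubjectSpec("s", ahi=40.0, seed=5)
        events = syn.schedule_apneas(spec, 900.0, 5)
        rec = syn.synthesize_excursion(spec, events, fs=25.0, duration=900.0)
        onsets = rec.truth["onset_times"]
        rate = 60.0 / np.diff(onsets)
        assert rate.min() >= 5.0 and rate.max() <= 50.0


class TestInjectArtifacts:
    def test_zero_fraction_identity(self, clean_ecg):
        out = syn.inject_artifacts(clean_ecg, 0.0, 1)
        np.testing.assert_array_equal(out.samples, clean_ecg.samples)

    def test_fraction_out_of_range(self, clean_ecg):
        with pytest.raises(ValueError):
            syn.inject_artifacts(clean_ecg, 1.5, 1)
        with pytest.raises(ValueError):
            syn.inject_artifacts(clean_ecg, -0.1, 1)

    def test_corrupted_share_near_target(self, clean_ecg):
        out = syn.inject_artifacts(clean_ecg, 0.3, 7)
        share = out.truth["corrupt_mask"].mean()
        assert 0.2 <= share <= 0.4

    def test_fully_corrupted_night_mostly_rejected(self, clean_ecg):
        import warnings
        bad = syn.inject_artifacts(clean_ecg, 1.0, 7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peaks = ep.detect_r_peaks(bad)
            segments = ep.segment_template_quality(bad, peaks)
        accepted = sum(s.accepted for s in segments)
        assert accepted / len(segments) < 0.10

    def test_deterministic(self, clean_ecg):
        a = syn.inject_artifacts(clean_ecg, 0.3, 9)
        b = syn.inject_artifacts(clean_ecg, 0.3, 9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestAhiDistribution:
    def test_cohort_median_matches_target(self, rng):
        # 200 cohorts of 51: the median of simulated medians near 33
        dist = syn.AhiDistribution()
        medians = [np.median(dist.sample(51, np.random.default_rng(s)))
                   for s in range(200)]
        assert 25.0 <= np.median(medians) <= 41.0


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        a = syn.generate_cohort(2, rng_seed=3, night_duration=120.0)
        b = syn.generate_cohort(2, rng_seed=3, night_duration=120.0)
        assert a.records.keys() == b.records.keys()
        for key in a.records:
            np.testing.assert_array_equal(a.records[key].samples,
                                          b.records[key].samples)

    def test_single_subject_cardinality(self):
        c = syn.generate_cohort(1, rng_seed=0, night_duration=120.0)
        assert len(c.records) == 4  # 2 channels x 2 devices

    def test_invalid_n_subjects(self):
        with pytest.raises(ValueError):
            syn.generate_cohort(0, rng_seed=0)

    def test_shared_ground_truth_across_devices(self):
        c = syn.generate_cohort(1, rng_seed=1, night_duration=120.0)
        sid = c.subjects[0].subject_id
        belt = c.records[(sid, 1, "ecg", "belt")]
        psg = c.records[(sid, 1, "ecg", "psg")]
        np.testing.assert_array_equal(belt.truth["r_times"], psg.truth["r_times"])


class TestSubjectSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"ahi": -1.0},
        {"ahi": 10.0, "n_nights": 0},
        {"ahi": 10.0, "base_hr": 20.0},
        {"ahi": 10.0, "base_bf": 60.0},
        {"ahi": 10.0, "noise_level": -0.5},
    ])
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ValueError):
            syn.SubjectSpec("s", **kwargs)

    def test_short_event_rejected(self):
        with pytest.raises(ValueError):
            syn.ApneaEvent(onset=0.0, duration=5.0)
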