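"""Breathing-cycle detection and template-matching quality filtering.

Cycles detected on the thoracic-excursion trace are graded in 32-s
segments: each cycle is phase-wise time-normalized (inhale and exhale
resampled separately) and amplitude-normalized, then correlated with the
segment's median reference cycle; acceptance needs mean r >= 0.75
(inclusive). Breath-to-breath intervals outside 5–50 breaths/min are
excluded regardless of segment verdict.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import BreathQualitySegment, BreathSeries, SignalRecord

R_THRESHOLD = 0.75
SEGMENT_S = 32.0
MIN_BPM = 5.0
MAX_BPM = 50.0
_N_INHALE = 30  # resampled points per phase
_N_EXHALE = 50


def detect_breaths(rec: SignalRecord) -> BreathSeries:
    """Detect breathing cycles: onset = trough starting the inhale,
    inhale duration = onset-to-peak time, amplitude = peak minus onset
    trough. Flat signals yield an empty series."""
    if rec.channel != "excursion":
        raise ValueError(f"expected an excursion record, got channel={rec.channel!r}")
    if rec.fs < 10:
        raise ValueError("fs must be >= 10 Hz")
    x = rec.samples
    if len(x) == 0 or np.ptp(x) == 0:
        return BreathSeries(onset_times=np.array([]), inhale_durations=np.array([]),
                            amplitudes=np.array([]), source=rec.device)
    fs = rec.fs
    sos = sps.butter(2, min(1.2, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    sm = sps.sosfiltfilt(sos, x)
    dist = max(int(60.0 / MAX_BPM * fs * 0.9), 1)
    prom = 0.15 * (np.percentile(sm, 95) - np.percentile(sm, 5))
    if prom <= 0:
        return BreathSeries(onset_times=np.array([]), inhale_durations=np.array([]),
                            amplitudes=np.array([]), source=rec.device)
    peaks, _ = sps.find_peaks(sm, distance=dist, prominence=prom)
    troughs, _ = sps.find_peaks(-sm, distance=dist, prominence=prom)
    if len(peaks) == 0 or len(troughs) == 0:
        return BreathSeries(onset_times=np.array([]), inhale_durations=np.array([]),
                            amplitudes=np.array([]), source=rec.device)
    onsets, inhale, amps = [], [], []
    for tr in troughs:
        nxt = peaks[peaks > tr]
        if len(nxt) == 0:
            continue
        pk = nxt[0]
        # ensure no other trough between this trough and its peak
        between = troughs[(troughs > tr) & (troughs < pk)]
        if len(between) > 0:
            continue
        onsets.append(rec.t0 + tr / fs)
        inhale.append((pk - tr) / fs)
        amps.append(sm[pk] - sm[tr])
    onsets = np.asarray(onsets)
    order = np.argsort(onsets)
    return BreathSeries(onset_times=onsets[order],
                        inhale_durations=np.asarray(inhale)[order],
                        amplitudes=np.asarray(amps)[order],
                        source=rec.device)


def _normalize_cycle(rec: SignalRecord, onset: float, peak_t: float,
                     next_onset: float) -> np.ndarray | None:
    """Phase-wise time normalization + unit amplitude scaling of one cycle."""
    fs = rec.fs
    grid = rec.t0 + np.arange(len(rec.samples)) / fs
    if peak_t <= onset or next_onset <= peak_t:
        return None
    t_in = np.linspace(onset, peak_t, _N_INHALE)
    t_ex = np.linspace(peak_t, next_onset, _N_EXHALE + 1)[1:]
    y = np.interp(np.concatenate([t_in, t_ex]), grid, rec.samples)
    rng_y = np.ptp(y)
    if rng_y == 0:
        return y - y[0]
    return (y - y.min()) / rng_y


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
    if denom == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.clip(ac @ bc / denom, -1.0, 1.0))


def breath_verdict(r: float, r_threshold: float = R_THRESHOLD) -> bool:
    """Breathing acceptance rule: inclusive minimum (r >= threshold)."""
    return not np.isnan(r) and r >= r_threshold


def breath_template_quality(rec: SignalRecord, breaths: BreathSeries,
                            segment_s: float = SEGMENT_S,
                            r_threshold: float = R_THRESHOLD) -> list[BreathQualitySegment]:
    """Grade consecutive 32-s segments by normalized-cycle template match.

    Segments with fewer than 2 complete cycles are rejected outright
    (r recorded as NaN).
    """
    n_segments = int(np.ceil(rec.duration / segment_s))
    onsets = breaths.onset_times
    segments = []
    for k in range(n_segments):
        start = rec.t0 + k * segment_s
        in_seg = np.where((onsets >= start) & (onsets < start + segment_s))[0]
        cycles = []
        for i in in_seg:
            if i + 1 >= len(onsets):
                continue  # incomplete cycle at the end of the record
            c = _normalize_cycle(rec, onsets[i],
                                 onsets[i] + breaths.inhale_durations[i],
                                 onsets[i + 1])
            if c is not None:
                cycles.append(c)
        if len(cycles) < 2:
            segments.append(BreathQualitySegment(start=start, duration=segment_s,
                                                 r_template=float("nan"),
                                                 verdict="rejected",
                                                 n_cycles=len(cycles)))
            continue
        mat = np.vstack(cycles)
        ref = np.median(mat, axis=0)
        r = float(np.mean([_pearson(row, ref) for row in mat]))
        verdict = "accepted" if breath_verdict(r, r_threshold) else "rejected"
        segments.append(BreathQualitySegment(start=start, duration=segment_s,
                                             r_template=r, verdict=verdict,
                                             n_cycles=len(cycles)))
    return segments


def breath_rate_filter(breaths: BreathSeries, min_bpm: float = MIN_BPM,
                       max_bpm: float = MAX_BPM) -> BreathSeries:
    """Mask out breath-to-breath intervals whose instantaneous rate falls
    outside [min_bpm, max_bpm] breaths/min (interval outside [60/max, 60/min] s)."""
    bb = breaths.bb_intervals
    rate = np.divide(60.0, bb, out=np.full_like(bb, np.inf), where=bb > 0)
    in_band = (rate >= min_bpm) & (rate <= max_bpm)
    mask = in_band if breaths.bb_mask is None else (breaths.bb_mask & in_band)
    return BreathSeries(onset_times=breaths.onset_times,
                        inhale_durations=breaths.inhale_durations,
                        amplitudes=breaths.amplitudes,
                        source=breaths.source, gaps=list(breaths.gaps),
                        bb_mask=mask)


def filtered_bb(breaths: BreathSeries, segments: list[BreathQualitySegment],
                min_bpm: float = MIN_BPM, max_bpm: float = MAX_BPM) -> BreathSeries:
    """Combine the segment verdicts with the rate band: an interval survives
    only if its rate is in [min_bpm, max_bpm] AND its starting onset lies in
    an accepted segment."""
    rate_filtered = breath_rate_filter(breaths, min_bpm, max_bpm)
    if len(breaths) < 2:
        return rate_filtered
    starts = np.array([s.start for s in segments])
    accepted = np.array([s.accepted for s in segments])
    idx = np.clip(np.searchsorted(starts, breaths.onset_times[:-1], side="right") - 1,
                  0, len(segments) - 1)
    seg_ok = accepted[idx] if len(segments) else np.zeros(len(breaths) - 1, dtype=bool)
    mask = rate_filtered.bb_mask & seg_ok
    gaps = [(s.start, s.start + s.duration) for s in segments if not s.accepted]
    return BreathSeries(onset_times=breaths.onset_times,
                        inhale_durations=breaths.inhale_durations,
                        amplitudes=breaths.amplitudes,
                        source=breaths.source, gaps=gaps, bb_mask=mask)


def filter_breaths(rec: SignalRecord, **kwargs):
    """Convenience end-to-end: detect cycles, grade segments, filter intervals.

    Returns (filtered BreathSeries, segments).
    """
    breaths = detect_breaths(rec)
    segments = breath_template_quality(rec, breaths)
    return filtered_bb(breaths, segments, **kwargs), segments
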