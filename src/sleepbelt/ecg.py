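"""R-peak detection and segment-wise template-correlation quality filtering.

The quality algorithm works on fixed 15-s segments: every beat's QRS and
PQRST complex is correlated against the element-wise median reference
complex of its segment; a segment is accepted when the mean per-beat
correlation exceeds 0.98 for either complex (strict inequality). Segments
failing the correlation route fall through to an RR-interval plausibility
check (333–2000 ms band, <=33% deviation from the segment median).
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import InsufficientDataError, QualitySegment, QualitySummary, RPeakSeries, SignalRecord

R_THRESHOLD = 0.98
SEGMENT_S = 15.0
RR_MIN_MS = 333.0
RR_MAX_MS = 2000.0
MAX_DEV = 0.33
QRS_WINDOW_S = (-0.060, 0.060)
PQRST_WINDOW_S = (-0.250, 0.400)
REFRACTORY_S = 0.200


def detect_r_peaks(rec: SignalRecord, refractory_s: float = REFRACTORY_S) -> RPeakSeries:
    """Derivative-energy R-peak detector (Pan–Tompkins family).

    Band-pass 5–35 Hz, squared, integrated over 150 ms; candidate peaks
    thresholded per 10-s block (robust to long artifact stretches), then
    refined to the local maximum of the filtered signal with parabolic
    sub-sample interpolation. A >=200 ms refractory period is enforced.
    """
    if rec.channel != "ecg":
        raise ValueError(f"expected an ecg record, got channel={rec.channel!r}")
    if rec.fs < 125:
        raise ValueError("fs must be >= 125 Hz")
    if rec.duration < 10:
        raise InsufficientDataError("signal shorter than 10 s")
    x = rec.samples
    if np.ptp(x) == 0:
        return RPeakSeries(times=np.array([]), source=rec.device)

    fs = rec.fs
    sos = sps.butter(2, [5, 35], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    energy = filt ** 2
    win = max(int(0.150 * fs), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    dist = max(int(refractory_s * fs), 1)
    block = int(10 * fs)
    floor = 0.02 * integ.max()  # global floor: ignore near-flat blocks
    cand: list[int] = []
    for lo in range(0, len(x), block):
        hi = min(lo + block, len(x))
        seg = integ[lo:hi]
        if np.ptp(seg) == 0:
            continue
        thr = max(0.3 * np.percentile(seg, 98), floor)
        pk, _ = sps.find_peaks(seg, height=thr, distance=dist)
        cand.extend(pk + lo)
    if not cand:
        return RPeakSeries(times=np.array([]), source=rec.device)

    # snap each candidate to the filtered-signal maximum within +-60 ms
    half = int(0.060 * fs)
    times = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, len(filt))
        i = lo + int(np.argmax(filt[lo:hi]))
        t = i / fs
        if 0 < i < len(filt) - 1:  # parabolic sub-sample refinement
            y0, y1, y2 = filt[i - 1], filt[i], filt[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                t += 0.5 * (y0 - y2) / denom / fs
        times.append(rec.t0 + t)
    times = np.unique(np.round(np.asarray(times), 6))
    # enforce refractory after snapping: keep the first of close pairs
    keep = [0]
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= refractory_s:
            keep.append(i)
    return RPeakSeries(times=times[keep], source=rec.device)


def _pearson_rows(mat: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of ``mat`` against ``ref``; 0 where undefined
    unless the row equals the reference exactly (then 1)."""
    mc = mat - mat.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((mc ** 2).sum(axis=1) * (rc ** 2).sum())
    num = mc @ rc
    r = np.zeros(len(mat))
    ok = denom > 0
    r[ok] = num[ok] / denom[ok]
    degenerate = ~ok
    if degenerate.any():
        r[degenerate] = np.where(
            np.all(np.isclose(mat[degenerate], ref), axis=1), 1.0, 0.0)
    return np.clip(r, -1.0, 1.0)


def _extract_complexes(rec: SignalRecord, peak_times: np.ndarray,
                       window_s: tuple) -> np.ndarray:
    """Per-beat complexes on a native-rate grid centred at each peak time
    (linear interpolation handles sub-sample alignment). Beats whose window
    leaves the record are dropped."""
    fs = rec.fs
    offs = np.arange(round(window_s[0] * fs), round(window_s[1] * fs) + 1) / fs
    t_end = rec.t0 + (len(rec.samples) - 1) / fs
    ok = (peak_times + offs[0] >= rec.t0) & (peak_times + offs[-1] <= t_end)
    pts = peak_times[ok]
    if len(pts) == 0:
        return np.empty((0, len(offs)))
    grid = rec.t0 + np.arange(len(rec.samples)) / fs
    out = np.empty((len(pts), len(offs)))
    for i, pt in enumerate(pts):
        out[i] = np.interp(pt + offs, grid, rec.samples)
    return out


def segment_r(complexes: np.ndarray) -> float:
    """Mean per-beat Pearson r against the element-wise median reference.

    NaN when fewer than 3 complexes are available.
    """
    if len(complexes) < 3:
        return float("nan")
    ref = np.median(complexes, axis=0)
    return float(np.mean(_pearson_rows(complexes, ref)))


def correlation_verdict(r_qrs: float, r_pqrst: float,
                        r_threshold: float = R_THRESHOLD) -> bool:
    """Acceptance rule for the correlation route: the better of the two
    complex correlations must strictly exceed the threshold."""
    rs = [r for r in (r_qrs, r_pqrst) if not np.isnan(r)]
    return bool(rs) and max(rs) > r_threshold


def plausibility_verdict(rr_ms: np.ndarray,
                         rr_min: float = RR_MIN_MS, rr_max: float = RR_MAX_MS,
                         max_dev: float = MAX_DEV) -> bool:
    """Fallback rule: every RR in [rr_min, rr_max] ms and within
    ``max_dev`` relative deviation of the segment median. Empty -> False."""
    rr = np.asarray(rr_ms, dtype=float)
    if len(rr) == 0:
        return False
    if np.any(rr < rr_min) or np.any(rr > rr_max):
        return False
    med = np.median(rr)
    return bool(np.all(np.abs(rr - med) / med <= max_dev))


def segment_template_quality(rec: SignalRecord, peaks: RPeakSeries,
                             segment_s: float = SEGMENT_S,
                             r_threshold: float = R_THRESHOLD,
                             rr_min: float = RR_MIN_MS, rr_max: float = RR_MAX_MS,
                             max_dev: float = MAX_DEV,
                             qrs_window: tuple = QRS_WINDOW_S,
                             pqrst_window: tuple = PQRST_WINDOW_S) -> list[QualitySegment]:
    """Apply the two-route quality algorithm to consecutive segments."""
    n_segments = int(np.ceil(rec.duration / segment_s))
    segments = []
    times = peaks.times
    rr_all = peaks.rr
    for k in range(n_segments):
        start = rec.t0 + k * segment_s
        in_seg = (times >= start) & (times < start + segment_s)
        pts = times[in_seg]
        qrs = _extract_complexes(rec, pts, qrs_window)
        pqrst = _extract_complexes(rec, pts, pqrst_window)
        r_qrs = segment_r(qrs)
        r_pqrst = segment_r(pqrst)
        if correlation_verdict(r_qrs, r_pqrst, r_threshold):
            verdict = "accepted_by_correlation"
        else:
            idx = np.where(in_seg[:-1] & in_seg[1:])[0]  # RR fully inside
            rr_seg = rr_all[idx]
            if plausibility_verdict(rr_seg, rr_min, rr_max, max_dev):
                verdict = "accepted_by_plausibility"
            else:
                verdict = "rejected"
        segments.append(QualitySegment(start=start, duration=segment_s,
                                       r_qrs=r_qrs, r_pqrst=r_pqrst,
                                       verdict=verdict, n_beats=int(in_seg.sum())))
    return segments


def filtered_rr(peaks: RPeakSeries, segments: list[QualitySegment]) -> RPeakSeries:
    """Drop RR intervals whose starting peak lies in a rejected segment.

    Gap positions (dropped stretches) are recorded on the returned series
    so spectral analysis can skip windows that straddle them.
    """
    if len(peaks) < 2:
        return RPeakSeries(times=peaks.times.copy(), source=peaks.source)
    starts = np.array([s.start for s in segments])
    accepted = np.array([s.accepted for s in segments])
    idx = np.clip(np.searchsorted(starts, peaks.times[:-1], side="right") - 1,
                  0, len(segments) - 1)
    keep_interval = accepted[idx]
    if not keep_interval.any():
        warnings.warn("all segments rejected: no RR intervals survive quality filtering")
        return RPeakSeries(times=np.array([]), source=peaks.source,
                           gaps=[(peaks.times[0], peaks.times[-1])])
    # rebuild peak times: a peak survives if it bounds a kept interval
    keep_peak = np.zeros(len(peaks), dtype=bool)
    keep_peak[:-1] |= keep_interval
    keep_peak[1:] |= keep_interval
    orig_idx = np.where(keep_peak)[0]
    kept_times = peaks.times[keep_peak]
    # a difference between consecutive kept peaks is a real RR interval only
    # if the pair was adjacent in the original series and that interval kept
    adjacent = np.diff(orig_idx) == 1
    rr_mask = adjacent & keep_interval[orig_idx[:-1]]
    gaps = [(s.start, s.start + s.duration) for s in segments if not s.accepted]
    return RPeakSeries(times=kept_times, source=peaks.source, gaps=gaps,
                       rr_mask=rr_mask)


def quality_summary(segments: list[QualitySegment]) -> QualitySummary:
    """Whole-night mean/SD of segment r and the accepted fraction."""
    rs = np.array([s.r for s in segments])
    rs = rs[~np.isnan(rs)]
    if len(rs) == 0:
        raise InsufficientDataError("no segment has a defined correlation coefficient")
    accepted = sum(s.accepted for s in segments)
    return QualitySummary(r_mean=float(np.mean(rs)),
                          r_sd=float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
                          fraction_accepted=accepted / len(segments),
                          n_segments=len(segments))


def filter_ecg(rec: SignalRecord, **kwargs):
    """Convenience end-to-end: detect peaks, grade segments, filter RR.

    Returns (filtered RPeakSeries, segments, QualitySummary).
    """
    peaks = detect_r_peaks(rec)
    segments = segment_template_quality(rec, peaks, **kwargs)
    rr = filtered_rr(peaks, segments)
    summary = quality_summary(segments)
    return rr, segments, summary
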