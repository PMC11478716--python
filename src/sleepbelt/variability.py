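"""Time- and frequency-domain variability features for RR or BB series.

Six time-domain features (SDNN, pNN50, rMSSD, IRRR, MADRR, triangular
index) are computed on the whole-night interval series. Band powers
(ULF 0–0.003, VLF 0.003–0.03, LF 0.03–0.15, HF 0.15–0.4 Hz and the LF/HF
ratio) come from short-time Fourier transforms of the cubic-interpolated
interval signal in 300-s windows; ULF, unresolvable inside a 300-s window,
is taken from the whole-night periodogram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

from .types import InsufficientDataError, VariabilityFeatures

BANDS = {"ulf": (0.0, 0.003), "vlf": (0.003, 0.03),
         "lf": (0.03, 0.15), "hf": (0.15, 0.4)}
HRVI_BIN_MS = 7.8125  # 1/128 s histogram bin, Task-Force convention


@dataclass
class SpectralConfig:
    window_s: float = 300.0
    overlap: float = 0.0
    resample_hz: float = 4.0
    bands: dict = None
    max_gap_s: float = 15.0  # windows containing longer gaps are skipped
    ulf_whole_night: bool = True

    def __post_init__(self):
        if self.bands is None:
            self.bands = dict(BANDS)
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        edges = sorted(self.bands.values())
        for (l0, h0), (l1, h1) in zip(edges, edges[1:]):
            if h0 > l1:
                raise ValueError("bands must be non-overlapping and ascending")


def time_domain_features(intervals: np.ndarray,
                         pnn_threshold: float = 50.0,
                         hrvi_bin: float = HRVI_BIN_MS) -> dict:
    """The six time-domain features on an interval series.

    ``pnn_threshold`` and ``hrvi_bin`` are in the units of ``intervals``
    (ms for RR, s for BB — pass 0.05 / a scaled bin for BB).
    """
    x = np.asarray(intervals, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 intervals")
    d = np.diff(x)
    sdnn = float(np.std(x, ddof=1))
    pnn50 = float(np.mean(np.abs(d) > pnn_threshold))
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    irrr = float(np.percentile(x, 75) - np.percentile(x, 25))
    madrr = float(np.median(np.abs(x)))
    edges = np.arange(x.min(), x.max() + hrvi_bin, hrvi_bin)
    if len(edges) < 2:
        edges = np.array([x.min(), x.min() + hrvi_bin])
    counts, _ = np.histogram(x, bins=edges)
    hrvi = float(len(x) / counts.max())
    return {"sdnn": sdnn, "pnn50": pnn50, "rmssd": rmssd,
            "irrr": irrr, "madrr": madrr, "hrvi": hrvi}


def _resample_intervals(times: np.ndarray, intervals: np.ndarray,
                        fs: float) -> tuple:
    """Cubic interpolation of the interval series onto an even grid."""
    if len(times) < 4:
        raise InsufficientDataError("need at least 4 intervals for interpolation")
    t = np.arange(times[0], times[-1], 1.0 / fs)
    cs = CubicSpline(times, intervals)
    return t, cs(t)


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs < hi)
    if not sel.any():
        return 0.0
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    return float(np.sum(psd[sel]) * df)


def band_powers(times: np.ndarray, intervals: np.ndarray,
                cfg: SpectralConfig | None = None) -> dict:
    """STFT band powers of the interval signal, averaged over 300-s windows.

    Windows overlapping a detection gap longer than ``cfg.max_gap_s`` are
    skipped. Returns the four powers (interval-units squared) plus lfhf
    (NaN when hf is zero).
    """
    cfg = cfg or SpectralConfig()
    times = np.asarray(times, dtype=float)
    intervals = np.asarray(intervals, dtype=float)
    span = times[-1] - times[0] if len(times) else 0.0
    if span < cfg.window_s:
        raise InsufficientDataError(
            f"series span {span:.0f}s shorter than one {cfg.window_s:.0f}s window")
    fs = cfg.resample_hz
    t, x = _resample_intervals(times, intervals, fs)
    gap_starts = times[:-1][np.diff(times) > cfg.max_gap_s]
    gap_ends = times[1:][np.diff(times) > cfg.max_gap_s]

    nwin = int(cfg.window_s * fs)
    step = max(int(nwin * (1 - cfg.overlap)), 1)
    powers = {k: [] for k in cfg.bands}
    for lo in range(0, len(x) - nwin + 1, step):
        w_start, w_end = t[lo], t[lo + nwin - 1]
        if any((gs < w_end) and (ge > w_start)
               for gs, ge in zip(gap_starts, gap_ends)):
            continue
        seg = x[lo:lo + nwin]
        freqs, psd = periodogram(seg, fs=fs, window="hann", detrend="constant")
        for name, (b_lo, b_hi) in cfg.bands.items():
            powers[name].append(_band_power(freqs, psd, b_lo, b_hi))
    if not powers[next(iter(cfg.bands))]:
        raise InsufficientDataError("no usable 300-s window (gaps everywhere)")
    out = {name: float(np.mean(vals)) for name, vals in powers.items()}
    if cfg.ulf_whole_night and "ulf" in cfg.bands:
        freqs, psd = periodogram(x, fs=fs, window="hann", detrend="constant")
        out["ulf"] = _band_power(freqs, psd, *cfg.bands["ulf"])
    hf = out.get("hf", 0.0)
    out["lfhf"] = float(out.get("lf", 0.0) / hf) if hf > 0 else float("nan")
    return out


def whole_night_features(times: np.ndarray, intervals: np.ndarray,
                         channel: str = "hrv",
                         cfg: SpectralConfig | None = None,
                         pnn_threshold: float | None = None,
                         hrvi_bin: float | None = None) -> VariabilityFeatures:
    """Assemble the 11-feature whole-night vector for one series.

    The same code path serves HRV (intervals in ms) and BRV (intervals
    in s); defaults for the pNN threshold (50 ms) and the triangular-index
    bin are converted to the series' units and scale for the BRV channel.
    """
    if channel not in ("hrv", "brv"):
        raise ValueError("channel must be 'hrv' or 'brv'")
    x = np.asarray(intervals, dtype=float)
    if pnn_threshold is None:
        pnn_threshold = 50.0 if channel == "hrv" else 0.050  # 50 ms either way
    if hrvi_bin is None:
        if channel == "hrv":
            hrvi_bin = HRVI_BIN_MS
        else:
            # keep the bin the same fraction of the typical interval as the
            # 7.8125 ms bin is of a nominal 800 ms RR
            hrvi_bin = float(np.median(x)) * HRVI_BIN_MS / 800.0 if len(x) else 0.01
    td = time_domain_features(x, pnn_threshold=pnn_threshold, hrvi_bin=hrvi_bin)
    fd = band_powers(times, x, cfg)
    return VariabilityFeatures(channel=channel, **td,
                               ulf=fd["ulf"], vlf=fd["vlf"], lf=fd["lf"],
                               hf=fd["hf"], lfhf=fd["lfhf"])
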