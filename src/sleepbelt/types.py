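"""Shared domain types for the sleepbelt pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHANNELS = ("ecg", "excursion")
DEVICES = ("belt", "psg")


class InsufficientDataError(ValueError):
    """Raised when an operation receives too little data to be meaningful."""


@dataclass
class SignalRecord:
    """One subject-night's raw waveform for a single channel and device.

    Attributes
    ----------
    channel : {"ecg", "excursion"}
    device : {"belt", "psg"}
    fs : float
        Sampling rate in Hz.
    t0 : float
        Start time in seconds (usually 0).
    samples : ndarray
        The waveform values (mV for ECG, arbitrary units for excursion).
    meta : dict
        Free-form metadata (subject_id, night, ...).
    truth : dict
        Optional generator ground truth (e.g. "r_times", "onset_times",
        "rr_ms", "corrupt_mask"); empty for real recordings.
    """

    channel: str
    device: str
    fs: float
    t0: float
    samples: np.ndarray
    meta: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.device not in DEVICES:
            raise ValueError(f"device must be one of {DEVICES}, got {self.device!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class RPeakSeries:
    """Detected R-peak times with derived RR intervals (ms).

    ``rr_mask`` (optional) marks which successive-time differences are true
    RR intervals; differences spanning a quality-filter gap are masked out.
    """

    times: np.ndarray
    source: str = "belt"
    gaps: list = field(default_factory=list)
    rr_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def rr(self) -> np.ndarray:
        """RR intervals in milliseconds; length is len(times) - 1."""
        return np.diff(self.times) * 1000.0

    def valid_rr(self) -> tuple:
        """(interval start times, RR ms) excluding gap-spanning differences."""
        rr = self.rr
        t = self.times[:-1]
        if self.rr_mask is None:
            return t, rr
        m = np.asarray(self.rr_mask, dtype=bool)
        return t[m], rr[m]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class QualitySegment:
    """Verdict for one fixed-length ECG segment.

    ``r_qrs``/``r_pqrst`` are NaN when fewer than three beats fall in the
    segment (correlation undefined; the plausibility rule decides instead).
    """

    start: float
    duration: float
    r_qrs: float
    r_pqrst: float
    verdict: str
    n_beats: int

    VERDICTS = ("accepted_by_correlation", "accepted_by_plausibility", "rejected")

    def __post_init__(self) -> None:
        if self.verdict not in self.VERDICTS:
            raise ValueError(f"verdict must be one of {self.VERDICTS}")

    @property
    def accepted(self) -> bool:
        return self.verdict != "rejected"

    @property
    def r(self) -> float:
        """Best of the two complex correlations (NaN if both undefined)."""
        if np.isnan(self.r_qrs) and np.isnan(self.r_pqrst):
            return float("nan")
        return float(np.nanmax([self.r_qrs, self.r_pqrst]))


@dataclass
class QualitySummary:
    """Whole-night segment-quality roll-up."""

    r_mean: float
    r_sd: float
    fraction_accepted: float
    n_segments: int


@dataclass
class BreathSeries:
    """Detected breathing cycles: onsets, intervals, inhale durations, amplitudes."""

    onset_times: np.ndarray
    inhale_durations: np.ndarray
    amplitudes: np.ndarray
    source: str = "belt"
    gaps: list = field(default_factory=list)
    bb_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.inhale_durations = np.asarray(self.inhale_durations, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.onset_times) > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ValueError("onset times must be strictly increasing")

    @property
    def bb_intervals(self) -> np.ndarray:
        """Breath-to-breath intervals in seconds."""
        return np.diff(self.onset_times)

    def valid_bb(self) -> tuple:
        """(interval start times, BB s) excluding masked-out differences."""
        bb = self.bb_intervals
        t = self.onset_times[:-1]
        if self.bb_mask is None:
            return t, bb
        m = np.asarray(self.bb_mask, dtype=bool)
        return t[m], bb[m]

    def __len__(self) -> int:
        return len(self.onset_times)


@dataclass
class BreathQualitySegment:
    start: float
    duration: float
    r_template: float
    verdict: str
    n_cycles: int

    def __post_init__(self) -> None:
        if self.verdict not in ("accepted", "rejected"):
            raise ValueError("verdict must be 'accepted' or 'rejected'")

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


FEATURE_NAMES = (
    "sdnn", "pnn50", "rmssd", "irrr", "madrr", "hrvi",
    "ulf", "vlf", "lf", "hf", "lfhf",
)


@dataclass
class VariabilityFeatures:
    """The 11 named variability features for one subject-night.

    Units: interval stats in the unit of the input series (ms for HRV,
    s for BRV); powers in that unit squared; pnn50 a proportion;
    hrvi and lfhf unitless.
    """

    sdnn: float
    pnn50: float
    rmssd: float
    irrr: float
    madrr: float
    hrvi: float
    ulf: float
    vlf: float
    lf: float
    hf: float
    lfhf: float
    channel: str = "hrv"

    def as_dict(self, prefix: Optional[str] = None) -> dict:
        p = f"{prefix}_" if prefix else ""
        return {f"{p}{name}": getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class PairedMeans:
    """Whole-night mean rate from both devices for one subject."""

    subject_id: str
    belt_value: float
    psg_value: float
    channel: str  # "hr" or "br"


@dataclass
class BlandAltmanResult:
    bias: float
    bias_ci: tuple
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    sd_diff: float
    n: int

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "bias_ci": list(self.bias_ci),
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "loa_lower_ci": list(self.loa_lower_ci),
            "loa_upper_ci": list(self.loa_upper_ci),
            "sd_diff": self.sd_diff,
            "n": self.n,
        }


@dataclass
class ClassificationResult:
    feature_set: str
    cutoff_quantile: float
    cutoff_value: float
    auc: float
    auc_ci: tuple
    sensitivity: float
    specificity: float
    confusion: tuple  # (tp, tn, fp, fn)
    roc_points: np.ndarray  # columns (fpr, tpr)
    loocv: bool

    def as_dict(self) -> dict:
        tp, tn, fp, fn = self.confusion
        return {
            "feature_set": self.feature_set,
            "cutoff_quantile": self.cutoff_quantile,
            "cutoff_value": self.cutoff_value,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn)},
            "loocv": self.loocv,
        }


@dataclass
class RepeatabilityResult:
    feature: str
    r_pt: float
    ci: tuple
    var_between: float
    var_within: float
    n_subjects: int
    n_nights: float

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "r_pt": self.r_pt,
            "ci": list(self.ci),
            "var_between": self.var_between,
            "var_within": self.var_within,
            "n_subjects": self.n_subjects,
            "n_nights": self.n_nights,
        }
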