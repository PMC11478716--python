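"""Synthetic whole-night cohort generator.

Produces paired belt/PSG ECG and thoracic-excursion waveforms whose
variability structure is driven by a per-subject apnea rate (AHI), plus
artifact injection to exercise the downstream quality filters, and
light-weight feature-level simulators for classifier and repeatability
validation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import SignalRecord

MIN_EVENT_DURATION_S = 10.0


@dataclass
class SubjectSpec:
    """Generative parameters for one virtual subject."""

    subject_id: str
    ahi: float
    n_nights: int = 1
    base_hr: float = 60.0
    base_bf: float = 14.0
    noise_level: float = 0.0
    seed: int = 0
    # per-subject multiplicative effect on variability magnitude; shared
    # across nights so repeatability has a true between-subject component
    subject_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ValueError("ahi must be >= 0")
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        if not 30 <= self.base_hr <= 180:
            raise ValueError("base_hr must be in [30, 180]")
        if not 5 <= self.base_bf <= 50:
            raise ValueError("base_bf must be in [5, 50]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


@dataclass
class ApneaEvent:
    onset: float
    duration: float
    type: str = "obstructive"  # or "central"

    def __post_init__(self) -> None:
        if self.duration < MIN_EVENT_DURATION_S:
            raise ValueError("apnea events are at least 10 s long")
        if self.type not in ("obstructive", "central"):
            raise ValueError("type must be 'obstructive' or 'central'")

    @property
    def end(self) -> float:
        return self.onset + self.duration


def schedule_apneas(spec: SubjectSpec, night_duration: float,
                    rng_seed: int,
                    mean_duration: float = 20.0,
                    central_fraction: float = 0.2) -> list[ApneaEvent]:
    """Draw a non-overlapping apnea event schedule for one night.

    Renewal process: each cycle is an event (duration 10 s + exponential
    tail, mean ``mean_duration``) followed by an exponential gap whose mean
    is chosen so the long-run event rate equals ``spec.ahi`` per hour.
    Events that would run past the end of the night are dropped.
    """
    if night_duration <= 0:
        raise ValueError("night_duration must be positive")
    if spec.ahi <= 0:
        return []
    rng = np.random.default_rng(rng_seed)
    mean_cycle = 3600.0 / spec.ahi
    mean_gap = max(mean_cycle - mean_duration, 2.0)
    events: list[ApneaEvent] = []
    t = rng.exponential(mean_gap)
    while t < night_duration:
        dur = MIN_EVENT_DURATION_S + rng.exponential(mean_duration - MIN_EVENT_DURATION_S)
        if t + dur > night_duration:
            break
        etype = "central" if rng.random() < central_fraction else "obstructive"
        events.append(ApneaEvent(onset=t, duration=dur, type=etype))
        t += dur + rng.exponential(mean_gap)
    return events


# PQRST morphology: (offset_s relative to R, amplitude, gaussian sigma_s)
_ECG_WAVES = (
    (-0.170, 0.12, 0.025),   # P
    (-0.025, -0.12, 0.006),  # Q
    (0.000, 1.00, 0.011),    # R
    (0.028, -0.20, 0.007),   # S
    (0.220, 0.30, 0.045),    # T
)


def _apnea_rr_modulation(t: np.ndarray, events: list[ApneaEvent],
                         gain: float) -> np.ndarray:
    """Multiplicative RR modulation: bradycardia during an event, a
    tachycardia overshoot in the 15 s after it. Magnitude scales with
    event duration (saturating at 60 s)."""
    mod = np.ones_like(t)
    for ev in events:
        g = gain * min(ev.duration, 60.0) / 30.0
        inside = (t >= ev.onset) & (t < ev.end)
        phase = (t[inside] - ev.onset) / ev.duration
        mod[inside] *= 1.0 + g * np.sin(np.pi * phase)
        after = (t >= ev.end) & (t < ev.end + 15.0)
        phase_a = (t[after] - ev.end) / 15.0
        mod[after] *= 1.0 - 0.8 * g * np.sin(np.pi * phase_a)
    return mod


def _rr_ground_truth(spec: SubjectSpec, events: list[ApneaEvent],
                     duration: float, rng: np.random.Generator) -> np.ndarray:
    """Beat times (s) over [0, duration] honouring the 333–2000 ms band."""
    base_rr = 60.0 / spec.base_hr  # seconds
    rsa_amp = 0.035 * spec.subject_factor
    f_resp = spec.base_bf / 60.0
    gain = 0.22 * spec.subject_factor
    # apnea modulation precomputed on a 1-s grid, interpolated per beat
    grid = np.arange(0.0, duration + 1.0, 1.0)
    mod_grid = _apnea_rr_modulation(grid, events, gain)
    times = [0.3]
    while True:
        t = times[-1]
        rr = base_rr * (1.0 + rsa_amp * math.sin(2 * math.pi * f_resp * t))
        rr *= np.interp(t, grid, mod_grid)
        rr += rng.normal(0.0, 0.002)  # beat-to-beat jitter, physiological
        rr = min(max(rr, 0.340), 1.990)  # stay inside the plausibility band
        if t + rr > duration:
            break
        times.append(t + rr)
    return np.asarray(times)


def _render_pqrst(r_times: np.ndarray, fs: float, n: int) -> np.ndarray:
    """Sum-of-Gaussians PQRST complexes evaluated at exact sample times."""
    x = np.zeros(n)
    grid = np.arange(n) / fs
    for rt in r_times:
        lo = max(int((rt - 0.30) * fs), 0)
        hi = min(int((rt + 0.45) * fs) + 1, n)
        if hi <= lo:
            continue
        dt = grid[lo:hi] - rt
        seg = np.zeros(hi - lo)
        for off, amp, sig in _ECG_WAVES:
            seg += amp * np.exp(-0.5 * ((dt - off) / sig) ** 2)
        x[lo:hi] += seg
    return x


def synthesize_ecg(spec: SubjectSpec, events: list[ApneaEvent],
                   fs: float = 250.0, duration: float = 7 * 3600.0,
                   device: str = "belt", rng_seed: int | None = None) -> SignalRecord:
    """Synthesize a whole-night single-channel ECG with PQRST morphology.

    Beat-to-beat intervals follow the base rhythm with respiratory sinus
    arrhythmia plus an apnea-locked cyclic excursion. Ground-truth R times
    and RR intervals are stored in ``rec.truth``.
    """
    if fs < 125:
        raise ValueError("fs must be >= 125 Hz for ECG (template morphology undersampled)")
    seed = spec.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    r_times = _rr_ground_truth(spec, events, duration, rng)
    n = int(round(duration * fs))
    x = _render_pqrst(r_times, fs, n)
    if spec.noise_level > 0:
        dev_scale = 1.0 if device == "belt" else 0.2
        lvl = spec.noise_level * dev_scale
        x = x + rng.normal(0.0, 0.03 * lvl, n)
        t = np.arange(n) / fs
        x = x + 0.1 * lvl * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    return SignalRecord(
        channel="ecg", device=device, fs=fs, t0=0.0, samples=x,
        meta={"subject_id": spec.subject_id},
        truth={"r_times": r_times, "rr_ms": np.diff(r_times) * 1000.0,
               "events": events},
    )


def _breath_cycle_times(spec: SubjectSpec, events: list[ApneaEvent],
                        duration: float, rng: np.random.Generator):
    """Onset times and per-cycle (inhale_frac, amplitude) ground truth."""
    # event effects precomputed on a 1-s grid
    grid = np.arange(0.0, duration + 1.0, 1.0)
    amp_grid = np.ones_like(grid)
    recovery_grid = np.ones_like(grid)
    for ev in events:
        inside = (grid >= ev.onset) & (grid < ev.end)
        amp_grid[inside] = 0.02 if ev.type == "central" else 0.25
        after = (grid >= ev.end) & (grid < ev.end + 10.0)
        recovery_grid[after] = 1.0 + 0.25 * spec.subject_factor  # recovery breaths
    onsets = [0.1]
    amps = []
    inhale_fracs = []
    while True:
        t = onsets[-1]
        bf = spec.base_bf * (1.0 + 0.05 * spec.subject_factor
                             * math.sin(2 * math.pi * t / 90.0))
        idx = min(int(t), len(grid) - 1)
        bf *= recovery_grid[idx]
        bf += rng.normal(0.0, 0.15)
        bf = min(max(bf, 5.5), 48.0)  # stays inside the 5–50 /min band
        cycle = 60.0 / bf
        if t + cycle > duration:
            break
        # a cycle overlapping an event at any point is amplitude-suppressed
        idx_hi = min(int(t + cycle) + 1, len(grid))
        amp = amp_grid[idx:idx_hi].min() if idx_hi > idx else amp_grid[idx]
        onsets.append(t + cycle)
        amps.append(amp)
        inhale_fracs.append(0.40)
    return np.asarray(onsets), np.asarray(amps), np.asarray(inhale_fracs)


def synthesize_excursion(spec: SubjectSpec, events: list[ApneaEvent],
                         fs: float = 25.0, duration: float = 7 * 3600.0,
                         device: str = "belt", rng_seed: int | None = None) -> SignalRecord:
    """Synthesize a thoracic-excursion signal: quasi-sinusoidal breaths with
    distinct inhale/exhale phases, amplitude reduced >=70% in obstructive
    events and to ~0 in central events."""
    if fs < 10:
        raise ValueError("fs must be >= 10 Hz for excursion")
    seed = (spec.seed + 1) if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    onsets, amps, inhale_fracs = _breath_cycle_times(spec, events, duration, rng)
    n = int(round(duration * fs))
    grid = np.arange(n) / fs
    x = np.zeros(n)
    for k in range(len(onsets) - 1):
        t0, t1 = onsets[k], onsets[k + 1]
        amp, frac = amps[k], inhale_fracs[k]
        peak_t = t0 + frac * (t1 - t0)
        lo, hi = int(t0 * fs) + 1, min(int(t1 * fs) + 1, n)
        if hi <= lo:
            continue
        tt = grid[lo:hi]
        seg = np.empty(hi - lo)
        inh = tt <= peak_t
        seg[inh] = 0.5 * amp * (1 - np.cos(np.pi * (tt[inh] - t0) / (peak_t - t0)))
        exh = ~inh
        seg[exh] = 0.5 * amp * (1 + np.cos(np.pi * (tt[exh] - peak_t) / (t1 - peak_t)))
        x[lo:hi] = seg
    if spec.noise_level > 0:
        dev_scale = 1.0 if device == "belt" else 0.3
        x = x + rng.normal(0.0, 0.02 * spec.noise_level * dev_scale, n)
    return SignalRecord(
        channel="excursion", device=device, fs=fs, t0=0.0, samples=x,
        meta={"subject_id": spec.subject_id},
        truth={"onset_times": onsets, "amplitudes": amps,
               "inhale_fracs": inhale_fracs, "events": events},
    )


def inject_artifacts(rec: SignalRecord, fraction_bad: float,
                     rng_seed: int, mean_block_s: float = 30.0) -> SignalRecord:
    """Replace ~``fraction_bad`` of the record with high-amplitude noise and
    baseline wander, drawn as contiguous blocks (geometric-like lengths) the
    way real belt artifacts occur. Returns a new record; the corrupted-sample
    mask is stored in ``truth["corrupt_mask"]``."""
    if not 0 <= fraction_bad <= 1:
        raise ValueError("fraction_bad must be in [0, 1]")
    out = replace(rec, samples=rec.samples.copy(),
                  meta=dict(rec.meta), truth=dict(rec.truth))
    n = len(out.samples)
    if fraction_bad == 0 or n == 0:
        out.truth["corrupt_mask"] = np.zeros(n, dtype=bool)
        return out
    rng = np.random.default_rng(rng_seed)
    mask = np.zeros(n, dtype=bool)
    target = fraction_bad * n
    block_n = max(int(mean_block_s * rec.fs), 1)
    guard = 0
    while mask.sum() < target and guard < 10000:
        guard += 1
        start = rng.integers(0, n)
        length = max(int(rng.exponential(block_n)), int(rec.fs))
        mask[start:start + length] = True
    amp = max(np.ptp(rec.samples), 1.0)
    t = np.arange(n) / rec.fs
    noise = (2.0 * amp * rng.standard_normal(n)
             + 1.5 * amp * np.sin(2 * np.pi * 0.8 * t + rng.uniform(0, 2 * np.pi)))
    out.samples[mask] = noise[mask]
    out.truth["corrupt_mask"] = mask
    return out


@dataclass
class AhiDistribution:
    """Log-normal AHI distribution calibrated by median and IQR."""

    median: float = 33.0
    iqr: tuple = (16.0, 58.0)

    def sigma(self) -> float:
        lo, hi = self.iqr
        z75 = 0.6744897501960817
        return 0.5 * (math.log(hi / self.median) + math.log(self.median / lo)) / z75

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.median), self.sigma(), n))


@dataclass
class Cohort:
    subjects: list[SubjectSpec]
    records: dict = field(default_factory=dict)  # (subject_id, night, channel, device) -> SignalRecord
    events: dict = field(default_factory=dict)   # (subject_id, night) -> list[ApneaEvent]


def generate_cohort(n_subjects: int,
                    ahi_distribution: AhiDistribution | None = None,
                    rng_seed: int = 0,
                    n_nights: int = 1,
                    night_duration: float = 7 * 3600.0,
                    ecg_fs: float = 250.0,
                    excursion_fs: float = 25.0,
                    noise_level: float = 0.0,
                    artifact_fraction: float = 0.0,
                    subject_sd: float = 0.3) -> Cohort:
    """Generate a full cohort of paired belt/PSG recordings.

    Belt and PSG records of one subject-night share the same event schedule
    and the same RR/breath ground truth; only their noise realizations
    differ. ``subject_sd`` is the SD of the per-subject log-scale random
    effect on variability magnitude (gives multi-night recordings a true
    intra-class correlation).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dist = ahi_distribution or AhiDistribution()
    rng = np.random.default_rng(rng_seed)
    ahis = dist.sample(n_subjects, rng)
    factors = np.exp(rng.normal(0.0, subject_sd, n_subjects))
    cohort = Cohort(subjects=[])
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        spec = SubjectSpec(subject_id=sid, ahi=float(ahis[i]),
                           n_nights=n_nights, noise_level=noise_level,
                           seed=int(rng.integers(0, 2**31)),
                           subject_factor=float(factors[i]))
        cohort.subjects.append(spec)
        for night in range(1, n_nights + 1):
            night_seed = spec.seed + 1000 * night
            events = schedule_apneas(spec, night_duration, night_seed)
            cohort.events[(sid, night)] = events
            # shared physiological truth: same rng seed for both devices
            for device in ("belt", "psg"):
                ecg = synthesize_ecg(spec, events, fs=ecg_fs,
                                     duration=night_duration, device=device,
                                     rng_seed=night_seed + 1)
                exc = synthesize_excursion(spec, events, fs=excursion_fs,
                                           duration=night_duration, device=device,
                                           rng_seed=night_seed + 2)
                if artifact_fraction > 0 and device == "belt":
                    ecg = inject_artifacts(ecg, artifact_fraction, night_seed + 3)
                    exc = inject_artifacts(exc, artifact_fraction / 3.0, night_seed + 4)
                for rec in (ecg, exc):
                    rec.meta.update({"night": night, "ahi": spec.ahi})
                cohort.records[(sid, night, ecg.channel, device)] = ecg
                cohort.records[(sid, night, exc.channel, device)] = exc
    return cohort


# --------------------------------------------------------------------------
# Feature-level simulators (fast surrogates for classifier / repeatability
# validation, bypassing waveform synthesis)

def simulate_feature_table(n_subjects: int, n_nights: int, icc: float,
                           seed: int, n_features: int = 1,
                           feature_names: list[str] | None = None):
    """Per-feature nightly values with a known intra-class correlation.

    value_ij = sqrt(icc) * u_i + sqrt(1 - icc) * e_ij with u, e ~ N(0, 1),
    so between-subject variance / total variance = icc exactly.
    """
    import pandas as pd

    if not 0 <= icc <= 1:
        raise ValueError("icc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = feature_names or [f"f{k}" for k in range(n_features)]
    rows = {"subject_id": np.repeat([f"S{i:03d}" for i in range(n_subjects)], n_nights),
            "night": np.tile(np.arange(1, n_nights + 1), n_subjects)}
    for name in names:
        u = rng.standard_normal(n_subjects)
        e = rng.standard_normal((n_subjects, n_nights))
        vals = math.sqrt(icc) * u[:, None] + math.sqrt(1 - icc) * e
        rows[name] = vals.ravel()
    return pd.DataFrame(rows)


def simulate_classification_cohort(n_subjects: int, seed: int,
                                   effect_size: float = 2.0,
                                   n_informative: int = 4,
                                   ahi_distribution: AhiDistribution | None = None):
    """Cohort feature table where AHI drives some HRV and BRV features.

    The first ``n_informative`` features of each channel scale linearly with
    standardized log-AHI (independent noise per channel), so both channels
    carry signal and combining them helps.
    """
    import pandas as pd

    from .types import FEATURE_NAMES

    rng = np.random.default_rng(seed)
    dist = ahi_distribution or AhiDistribution()
    ahi = dist.sample(n_subjects, rng)
    z = (np.log(ahi) - math.log(dist.median)) / dist.sigma()
    data = {"subject_id": [f"S{i:03d}" for i in range(n_subjects)],
            "ahi": ahi, "night": 1, "device": "belt"}
    for prefix in ("hrv", "brv"):
        for k, name in enumerate(FEATURE_NAMES):
            slope = effect_size if k < n_informative else 0.0
            noise = rng.standard_normal(n_subjects)
            data[f"{prefix}_{name}"] = slope * z + noise
    return pd.DataFrame(data)
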