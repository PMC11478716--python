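"""Run configuration: every threshold of the pipeline in one place.

Defaults equal the published analysis constants: 15-s ECG segments with
r > 0.98, RR plausibility 333–2000 ms with 33% max deviation, 32-s
breathing segments with r >= 0.75, the 5–50 breaths/min band, 300-s
spectral windows with band edges 0.003/0.03/0.15/0.4 Hz, and the 50-ms
pNN threshold.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    # cohort simulation
    n_subjects: int = 8
    n_nights: int = 1
    night_duration_s: float = 1800.0
    ecg_fs: float = 250.0
    excursion_fs: float = 25.0
    ahi_median: float = 33.0
    ahi_iqr: tuple = (16.0, 58.0)
    noise_level: float = 0.2
    artifact_fraction: float = 0.0
    subject_sd: float = 0.3
    seed: int = 0
    # ECG quality
    ecg_segment_s: float = 15.0
    ecg_r_threshold: float = 0.98
    rr_min_ms: float = 333.0
    rr_max_ms: float = 2000.0
    rr_max_dev: float = 0.33
    # breathing quality
    breath_segment_s: float = 32.0
    breath_r_threshold: float = 0.75
    min_bpm: float = 5.0
    max_bpm: float = 50.0
    # variability
    spectral_window_s: float = 300.0
    spectral_overlap: float = 0.0
    resample_hz: float = 4.0
    band_edges: tuple = (0.003, 0.03, 0.15, 0.4)
    pnn_threshold_ms: float = 50.0
    # classification
    label_quantile: float = 0.5
    svm_seed: int = 0
    # repeatability
    n_boot: int = 200
    # stage toggles
    run_simulate: bool = True
    run_quality: bool = True
    run_features: bool = True
    run_agreement: bool = True
    run_classify: bool = True
    run_repeatability: bool = True
    write_signals: bool = False

    def bands(self) -> dict:
        e = self.band_edges
        return {"ulf": (0.0, e[0]), "vlf": (e[0], e[1]),
                "lf": (e[1], e[2]), "hf": (e[2], e[3])}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ahi_iqr"] = list(d["ahi_iqr"])
        d["band_edges"] = list(d["band_edges"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "ahi_iqr" in d:
            d["ahi_iqr"] = tuple(d["ahi_iqr"])
        if "band_edges" in d:
            d["band_edges"] = tuple(d["band_edges"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
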