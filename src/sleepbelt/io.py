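"""Plain-text readers/writers: two-column signal CSVs with JSON sidecars,
RR/BB interval CSVs, and cohort metadata tables."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import RPeakSeries, SignalRecord


def write_signal_csv(rec: SignalRecord, path) -> None:
    """time_s,value CSV plus a ``<stem>.json`` sidecar with the metadata."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.times, "value": rec.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "channel": rec.channel, "device": rec.device, "fs": rec.fs,
        "t0": rec.t0, **{k: v for k, v in rec.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_signal_csv(path) -> SignalRecord:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    t = df["time_s"].to_numpy(dtype=float)
    fs = meta.get("fs")
    if fs is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    known = {"channel", "device", "fs", "t0"}
    return SignalRecord(
        channel=meta.get("channel", "ecg"), device=meta.get("device", "belt"),
        fs=float(fs), t0=float(meta.get("t0", t[0] if len(t) else 0.0)),
        samples=df["value"].to_numpy(dtype=float),
        meta={k: v for k, v in meta.items() if k not in known},
    )


def write_rr_csv(peaks: RPeakSeries, segments, path) -> None:
    """t_s,rr_ms,segment_verdict rows, one per RR interval."""
    t, rr = peaks.valid_rr()
    verdicts = []
    starts = np.array([s.start for s in segments]) if segments else np.array([0.0])
    labels = [s.verdict for s in segments] if segments else ["accepted"]
    for ti in t:
        idx = int(np.clip(np.searchsorted(starts, ti, side="right") - 1,
                          0, len(labels) - 1))
        verdicts.append(labels[idx])
    pd.DataFrame({"t_s": t, "rr_ms": rr, "segment_verdict": verdicts}).to_csv(
        path, index=False, float_format="%.6f")


def write_bb_csv(breaths, segments, path) -> None:
    """t_s,bb_s,segment_verdict rows, one per surviving BB interval."""
    t, bb = breaths.valid_bb()
    starts = np.array([s.start for s in segments]) if segments else np.array([0.0])
    labels = [s.verdict for s in segments] if segments else ["accepted"]
    verdicts = []
    for ti in t:
        idx = int(np.clip(np.searchsorted(starts, ti, side="right") - 1,
                          0, len(labels) - 1))
        verdicts.append(labels[idx])
    pd.DataFrame({"t_s": t, "bb_s": bb, "segment_verdict": verdicts}).to_csv(
        path, index=False, float_format="%.6f")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
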