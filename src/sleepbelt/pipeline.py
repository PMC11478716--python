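"""End-to-end orchestration: simulate -> quality filter -> features ->
agreement / classification / repeatability, all from one RunConfig."""
from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import breath as bp
from . import classify as clf
from . import ecg as ep
from . import io as sio
from . import repeatability as rpt
from . import synthetic as syn
from . import variability as var
from .config import RunConfig
from .types import FEATURE_NAMES, InsufficientDataError, PairedMeans

log = logging.getLogger("sleepbelt")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _spectral_cfg(config: RunConfig) -> var.SpectralConfig:
    return var.SpectralConfig(window_s=config.spectral_window_s,
                              overlap=config.spectral_overlap,
                              resample_hz=config.resample_hz,
                              bands=config.bands())


def _night_features(config: RunConfig, ecg_rec, exc_rec):
    """Quality-filter one subject-night and compute its 22-feature row.

    Returns (row dict, mean HR, mean BR); missing pieces are NaN.
    """
    row: dict = {}
    mean_hr = mean_br = float("nan")
    scfg = _spectral_cfg(config)
    try:
        rr_series, segs, summary = ep.filter_ecg(
            ecg_rec, segment_s=config.ecg_segment_s,
            r_threshold=config.ecg_r_threshold,
            rr_min=config.rr_min_ms, rr_max=config.rr_max_ms,
            max_dev=config.rr_max_dev)
        t_rr, rr = rr_series.valid_rr()
        row["ecg_fraction_accepted"] = summary.fraction_accepted
        row["ecg_r_mean"] = summary.r_mean
        if len(rr) >= 2:
            mean_hr = agr.whole_night_mean_rate(rr, unit="ms")
        feats = var.whole_night_features(t_rr, rr, channel="hrv", cfg=scfg,
                                         pnn_threshold=config.pnn_threshold_ms)
        row.update(feats.as_dict(prefix="hrv"))
    except (InsufficientDataError, ValueError) as exc:
        log.warning("HRV features unavailable for %s/%s: %s",
                    ecg_rec.meta.get("subject_id"), ecg_rec.device, exc)
        row.update({f"hrv_{n}": float("nan") for n in FEATURE_NAMES})
    try:
        bb_series, bsegs = bp.filter_breaths(
            exc_rec, min_bpm=config.min_bpm, max_bpm=config.max_bpm)
        t_bb, bb = bb_series.valid_bb()
        if len(bb) >= 2:
            mean_br = agr.whole_night_mean_rate(bb, unit="s")
        feats = var.whole_night_features(t_bb, bb, channel="brv", cfg=scfg,
                                         pnn_threshold=config.pnn_threshold_ms / 1000.0)
        row.update(feats.as_dict(prefix="brv"))
    except (InsufficientDataError, ValueError) as exc:
        log.warning("BRV features unavailable for %s/%s: %s",
                    exc_rec.meta.get("subject_id"), exc_rec.device, exc)
        row.update({f"brv_{n}": float("nan") for n in FEATURE_NAMES})
    return row, mean_hr, mean_br


def run_all(config: RunConfig, out_dir) -> dict:
    """Run every enabled stage; writes CSV/JSON artifacts plus a manifest.

    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "stages": {}, "versions": _versions()}
    config.save(out / "config.yaml")

    t0 = time.perf_counter()
    if not config.run_simulate:
        raise StageError("simulate", ValueError(
            "pipeline currently requires the simulate stage (no external input path)"))
    cohort = syn.generate_cohort(
        n_subjects=config.n_subjects,
        ahi_distribution=syn.AhiDistribution(config.ahi_median, config.ahi_iqr),
        rng_seed=config.seed, n_nights=config.n_nights,
        night_duration=config.night_duration_s,
        ecg_fs=config.ecg_fs, excursion_fs=config.excursion_fs,
        noise_level=config.noise_level,
        artifact_fraction=config.artifact_fraction,
        subject_sd=config.subject_sd)
    meta = pd.DataFrame([
        {"subject_id": s.subject_id, "night": night, "ahi": s.ahi, "seed": s.seed}
        for s in cohort.subjects for night in range(1, config.n_nights + 1)])
    sio.write_table(meta, out / "cohort_metadata.csv")
    if config.write_signals:
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for (sid, night, channel, device), rec in cohort.records.items():
            sio.write_signal_csv(rec, sig_dir / f"{sid}_n{night}_{channel}_{device}.csv")
    _mark(manifest, "simulate", t0)

    if not (config.run_quality and config.run_features):
        if config.run_agreement or config.run_classify or config.run_repeatability:
            raise StageError("features", ValueError(
                "agreement/classification/repeatability need the quality and "
                "feature stages enabled"))
        sio.write_json(manifest, out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    rows = {"belt": [], "psg": []}
    rates: dict = {}
    for s in cohort.subjects:
        for night in range(1, config.n_nights + 1):
            for device in ("belt", "psg"):
                ecg_rec = cohort.records[(s.subject_id, night, "ecg", device)]
                exc_rec = cohort.records[(s.subject_id, night, "excursion", device)]
                row, mean_hr, mean_br = _night_features(config, ecg_rec, exc_rec)
                row.update({"subject_id": s.subject_id, "night": night,
                            "ahi": s.ahi, "device": device,
                            "mean_hr": mean_hr, "mean_br": mean_br})
                rows[device].append(row)
                rates[(s.subject_id, night, device)] = (mean_hr, mean_br)
    tables = {}
    for device in ("belt", "psg"):
        df = pd.DataFrame(rows[device])
        front = ["subject_id", "night", "device", "ahi", "mean_hr", "mean_br"]
        df = df[front + [c for c in df.columns if c not in front]]
        tables[device] = df
        sio.write_table(df, out / f"features_{device}.csv")
    _mark(manifest, "features", t0)

    if config.run_agreement:
        t0 = time.perf_counter()
        try:
            results = {}
            for channel, pos in (("hr", 0), ("br", 1)):
                pairs = []
                for s in cohort.subjects:
                    for night in range(1, config.n_nights + 1):
                        b = rates[(s.subject_id, night, "belt")][pos]
                        p = rates[(s.subject_id, night, "psg")][pos]
                        if np.isfinite(b) and np.isfinite(p):
                            pairs.append(PairedMeans(s.subject_id, b, p, channel))
                results[channel] = agr.bland_altman(pairs).as_dict()
            sio.write_json(results, out / "agreement.json")
        except Exception as exc:
            raise StageError("agreement", exc) from exc
        _mark(manifest, "agreement", t0)

    if config.run_classify:
        t0 = time.perf_counter()
        try:
            results = {}
            for device, df in tables.items():
                complete = df.dropna(subset=[c for c in df.columns
                                             if c.startswith(("hrv_", "brv_"))])
                use_loocv = len(complete) >= 10
                per_set = {}
                for fset in ("ecg", "bf", "combined"):
                    try:
                        res = clf.classify(complete, feature_set=fset,
                                           quantile=config.label_quantile,
                                           loocv=use_loocv, seed=config.svm_seed)
                        d = res.as_dict()
                        np.savetxt(out / f"roc_{device}_{fset}.csv",
                                   res.roc_points, delimiter=",",
                                   header="fpr,tpr", comments="", fmt="%.6f")
                        per_set[fset] = d
                    except (InsufficientDataError, ValueError) as exc:
                        per_set[fset] = {"error": str(exc)}
                results[device] = per_set
            sio.write_json(results, out / "classification.json")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("classify", exc) from exc
        _mark(manifest, "classify", t0)

    if config.run_repeatability:
        t0 = time.perf_counter()
        try:
            results: dict = {}
            if config.n_nights >= 2:
                df = tables["belt"]
                for prefix, channel in (("hrv", "ecg"), ("brv", "bf")):
                    per_feature = []
                    for name in FEATURE_NAMES:
                        col = f"{prefix}_{name}"
                        try:
                            r = rpt.repeatability(df.dropna(subset=[col]), col,
                                                  n_boot=config.n_boot,
                                                  seed=config.seed)
                            per_feature.append(r)
                        except (InsufficientDataError, ValueError) as exc:
                            log.warning("repeatability skipped for %s: %s", col, exc)
                    if per_feature:
                        results[channel] = {
                            "summary": {
                                "median": rpt.summarize_repeatability(per_feature)["median"],
                                "iqr": list(rpt.summarize_repeatability(per_feature)["iqr"]),
                            },
                            "features": [r.as_dict() for r in per_feature],
                        }
            else:
                results["note"] = "repeatability needs n_nights >= 2; skipped"
            sio.write_json(results, out / "repeatability.json")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("repeatability", exc) from exc
        _mark(manifest, "repeatability", t0)

    sio.write_json(manifest, out / "manifest.json")
    return manifest


def _mark(manifest: dict, stage: str, t0: float) -> None:
    dt = time.perf_counter() - t0
    manifest["stages"][stage] = {"seconds": round(dt, 3)}
    log.info("stage %-14s %.2fs", stage, dt)


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {"sleepbelt": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "sklearn": sklearn.__version__}
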