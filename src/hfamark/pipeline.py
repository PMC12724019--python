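"""End-to-end orchestration: simulate -> montage -> detect -> featurize ->
train/score -> outcome -> report.

Every stage is a pure function of (inputs, config, seed); stage seeds are
derived deterministically from the global seed, so rerunning a config
reproduces all outputs bit-identically (verified through the manifest
hashes). Per-detector outputs are kept in separate subdirectories and never
pooled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features as feat, outcome as outc
from .detect import DETECTORS, detect_recording, make_detector
from .montage import Recording, apply_montage
from .simulate import Cohort, SimulationConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "load_cohort"]

log = logging.getLogger("hfamark")


@dataclass
class RunConfig:
    out_dir: str = "hfamark_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detectors: list = field(default_factory=lambda: ["STE", "SLL", "HIL", "MNI"])
    detector_overrides: dict = field(default_factory=dict)
    grid: dict | None = None
    cv_folds: int = 10
    inner_folds: int = 3
    pseudo_null: bool = False
    n_null: int = 5
    seed: int = 0

    def validate(self) -> None:
        unknown = [d for d in self.detectors if d.upper() not in DETECTORS]
        if unknown:
            raise ValueError(f"unknown detectors: {unknown}")
        self.simulation.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_cohort(sim_dir) -> Cohort:
    """Reload a cohort written by the simulate stage (signals as .npy)."""
    sim_dir = Path(sim_dir)
    patients = pd.read_csv(sim_dir / "patients.csv")
    recordings, elec_frames = [], []
    for pid in patients["id"]:
        elec = pd.read_csv(sim_dir / f"{pid}_electrodes.tsv", sep="\t")
        data = np.load(sim_dir / f"{pid}_signals.npy").astype(float)
        recordings.append(
            Recording(
                data=data,
                fs=1000.0,
                channels=elec.drop(columns=["site_class"], errors="ignore"),
                patient=pid,
            )
        )
        elec["patient"] = pid
        elec_frames.append(elec)
    events = pd.read_json(sim_dir / "ground_truth_events.json", orient="records")
    return Cohort(
        recordings=recordings,
        electrodes=pd.concat(elec_frames, ignore_index=True),
        patients=patients,
        true_events=events,
        config=SimulationConfig(),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def _montage_all(cohort: Cohort) -> dict[str, Recording]:
    return {rec.patient: apply_montage(rec) for rec in cohort.recordings}


def _detect_all(cfg: RunConfig, montaged: dict[str, Recording]) -> dict[str, pd.DataFrame]:
    out = {}
    for det_id in cfg.detectors:
        det = make_detector(det_id, **cfg.detector_overrides.get(det_id, {}))
        frames = [detect_recording(rec, det) for rec in montaged.values()]
        out[det_id.upper()] = pd.concat(frames, ignore_index=True)
        log.info("detect[%s]: %d events", det_id, len(out[det_id.upper()]))
    return out


def _featurize_all(cfg: RunConfig, cohort: Cohort, montaged, events_by_det):
    epoch_minutes = cfg.simulation.epoch_minutes
    cohort_meta = {}
    ages = cohort.patients.set_index("id")["age"]
    for pid, rec in montaged.items():
        elec = cohort.electrodes[cohort.electrodes["patient"] == pid].reset_index(drop=True)
        cohort_meta[pid] = {"montaged": rec.channels, "electrodes": elec, "age": float(ages[pid])}

    tables, enriched = {}, {}
    for det_id, events in events_by_det.items():
        parts = []
        for pid, rec in montaged.items():
            ev = events[events["patient"] == pid]
            sig_by_name = dict(zip(rec.channels["name"], rec.data))
            for channel, grp in ev.groupby("channel"):
                ef = feat.event_feature_table(
                    sig_by_name[channel], list(zip(grp["onset"], grp["offset"])), rec.fs
                )
                ef.insert(0, "patient", pid)
                ef.insert(1, "channel", channel)
                ef.insert(2, "detector", det_id)
                parts.append(ef)
        enriched[det_id] = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(
                columns=[
                    "patient", "channel", "detector",
                    "onset", "offset", "duration_ms", "max_power_uv2", "peak_freq_hz", "entropy",
                ]
            )
        )
        tables[det_id] = feat.cohort_feature_table(
            enriched[det_id] if len(enriched[det_id]) else enriched[det_id],
            cohort_meta,
            epoch_minutes,
        ).get(det_id)
        if tables[det_id] is None:  # no events anywhere: emit all-zero-rate rows
            parts = [
                feat.electrode_feature_table(
                    enriched[det_id], m["montaged"], m["electrodes"], epoch_minutes, m["age"], pid, det_id
                )
                for pid, m in cohort_meta.items()
            ]
            tables[det_id] = pd.concat(parts, ignore_index=True)
    return tables, enriched


def _resected_lookup(cohort: Cohort, table: pd.DataFrame) -> pd.Series:
    key = cohort.electrodes.set_index(["patient", "name"])["resected"]
    return pd.Series(
        [bool(key.get((p, c), False)) for p, c in zip(table["patient"], table["channel"])],
        index=table.index,
    )


def _train_detector(cfg: RunConfig, table: pd.DataFrame, seed: int) -> dict:
    """Adaptive nested CV for pipeline runs: folds are capped by the number
    of patients and the rarer class; tiny demo cohorts skip tuning."""
    train = feat.training_table(table)
    labels = train["label"].astype(int).to_numpy()
    if np.unique(labels).size < 2:
        return {"status": "skipped: single-class training data"}
    n_groups = train["patient"].nunique()
    k = int(min(cfg.cv_folds, n_groups, labels.sum(), (1 - labels).sum()))
    if k < 2:
        return {"status": "skipped: too few patients/classes for cross-validation"}
    inner_k = int(min(cfg.inner_folds, n_groups - 1))
    grid = cfg.grid
    if inner_k < 2:
        inner_k = 2  # nested contract needs an inner split; 2 is the floor
        grid = {"max_depth": [4]}  # no real tuning on micro-cohorts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = classify.nested_cv_train(train, labels, grid=grid, k=k, inner_k=inner_k, seed=seed)
        probs, model = classify.fit_full_and_score(train, labels, table, grid=grid, inner_k=inner_k, seed=seed)
        attrib = classify.attribution_summary(model, train)
    return {
        "status": "ok",
        "result": result,
        "train_index": train.index,
        "scores": probs,
        "model": model,
        "attributions": attrib,
        "k": k,
    }


def _outcome_detector(cfg: RunConfig, table: pd.DataFrame, scores, cohort: Cohort) -> dict:
    work = table.copy()
    work["resected"] = _resected_lookup(cohort, work).to_numpy()
    if scores is not None:
        work["soz_probability"] = scores
        value_col = "soz_probability"
    else:
        value_col = "rate"
    summaries = outc.patient_summary_table(work, value_col)
    merged = cohort.patients.merge(summaries, left_on="id", right_on="patient", how="inner")
    out = {"summaries": summaries, "value_column": value_col}
    usable = merged.dropna(subset=["biomarker_difference"])
    if len(usable) >= 10 and usable["ilae_class1"].nunique() == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["logistic"] = outc.standard_care_logistic(
                usable, usable["biomarker_difference"].rename("biomarker_difference")
            )
            out["loo"] = outc.loo_outcome_eval(usable, usable["biomarker_difference"])
    else:
        out["status"] = "skipped: too few complete patients for outcome modelling"
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages and return the run directory.

    Any stage failure aborts with the stage name in the exception; outputs
    and a manifest (sha256 per emitted file, config, seed) land under
    ``cfg.out_dir``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    stage_seed = {s: int(rng.integers(0, 2**31 - 1)) for s in ("simulate", "train", "null")}
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    sim_cfg = dataclasses.replace(cfg.simulation, seed=stage_seed["simulate"])
    cohort = generate_cohort(sim_cfg)
    write_cohort(cohort, out / "simulate")
    report["stages"]["simulate"] = {
        "n_patients": int(len(cohort.patients)),
        "n_electrodes": int(len(cohort.electrodes)),
        "n_true_events": int(len(cohort.true_events)),
    }

    montaged = _montage_all(cohort)
    events_by_det = _detect_all(cfg, montaged)
    for det_id, events in events_by_det.items():
        d = out / "detect" / det_id
        d.mkdir(parents=True, exist_ok=True)
        events.to_csv(d / "events.csv", index=False)
    report["stages"]["detect"] = {d: int(len(e)) for d, e in events_by_det.items()}

    tables, enriched = _featurize_all(cfg, cohort, montaged, events_by_det)
    for det_id in tables:
        d = out / "features" / det_id
        d.mkdir(parents=True, exist_ok=True)
        tables[det_id].to_csv(d / "features.csv", index=False)
        enriched[det_id].to_csv(d / "events_with_features.csv", index=False)
    report["stages"]["featurize"] = {d: int(len(t)) for d, t in tables.items()}

    report["stages"]["train"] = {}
    scores_by_det: dict[str, np.ndarray | None] = {}
    for det_id, table in tables.items():
        d = out / "model" / det_id
        d.mkdir(parents=True, exist_ok=True)
        res = _train_detector(cfg, table, stage_seed["train"])
        if res["status"] != "ok":
            report["stages"]["train"][det_id] = res["status"]
            scores_by_det[det_id] = None
            continue
        table_scores = table[["patient", "channel", "detector"]].copy()
        table_scores["soz_probability"] = res["scores"]
        table_scores.to_csv(d / "scores.csv", index=False)
        res["attributions"].contributions.to_csv(d / "attributions.csv", index=False)
        nested = res["result"]
        entry = {
            "auroc": nested.auroc.value,
            "auroc_ci95": list(nested.auroc.ci95),
            "auprc": nested.auprc.value,
            "outer_folds": res["k"],
            "attribution_ranking": res["attributions"].ranking,
        }
        if cfg.pseudo_null:
            null = classify.pseudo_label_null(
                feat.training_table(table),
                prevalence=cfg.simulation.soz_prevalence,
                n_models=cfg.n_null,
                observed_auroc=nested.auroc.value,
                grid=cfg.grid,
                k=res["k"],
                seed=stage_seed["null"],
            )
            entry["pseudo_null"] = {
                "mean_null_auroc": float(null.null_aurocs.mean()),
                "p_value": null.p_value,
            }
        _write_json(d / "metrics.json", entry)
        report["stages"]["train"][det_id] = entry
        scores_by_det[det_id] = res["scores"]

    report["stages"]["outcome"] = {}
    for det_id, table in tables.items():
        d = out / "outcome" / det_id
        d.mkdir(parents=True, exist_ok=True)
        res = _outcome_detector(cfg, table, scores_by_det.get(det_id), cohort)
        res["summaries"].to_csv(d / "summary_measures.csv", index=False)
        entry = {"value_column": res["value_column"]}
        if "loo" in res:
            entry["loo_auroc_with"] = res["loo"].auroc_with.value
            entry["loo_auroc_without"] = res["loo"].auroc_without.value
            entry["delong_p"] = res["loo"].delong_p
            res["logistic"].table.to_csv(d / "logistic_report.csv")
        else:
            entry["status"] = res.get("status", "ok")
        _write_json(d / "outcome.json", entry)
        report["stages"]["outcome"][det_id] = entry

    _write_json(out / "report" / "report.json", report)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stage_seeds": stage_seed,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(out / "report" / "manifest.json", manifest)
    return out
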