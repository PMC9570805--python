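"""End-to-end orchestration: simulate, train, evaluate, report.

A "run" lives in one output directory: per-combination subdirectories with
per-fold prediction timelines and confusion charts, a tidy per-class
metrics table, a four-row summary table, and a JSON manifest recording the
configuration snapshot, every seed, stage timings and a checksum inventory
of the written files.  A rerun over an existing directory resumes: folds
whose timeline file already exists under an identical configuration are
reloaded instead of retrained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activities import ActivityClass
from .cohort import CohortConfig, Dataset, generate_cohort, read_cohort, write_cohort
from .evaluation import (chart_to_frame, confusion, export_timeline,
                         fold_records, precision_distribution, summarize)
from .loso import FoldResult, LosoResult, TrainingConfig, run_combination
from .preprocessing import SensorCombination

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_digest(obj: dict) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def simulate_cohort(out_dir, config: CohortConfig | None = None,
                    seed: int = 0) -> Dataset:
    """Generate a cohort, write it to disk with a manifest, and return it."""
    config = config or CohortConfig()
    t0 = time.time()
    dataset = generate_cohort(config.n_participants, config, seed)
    out_dir = Path(out_dir)
    write_cohort(dataset, out_dir)
    files = {str(p.relative_to(out_dir)): _sha256(p)
             for p in sorted(out_dir.rglob("*")) if p.is_file()
             and p.name != "manifest.json"}
    manifest = {
        "stage": "simulate",
        "version": __version__,
        "cohort_seed": seed,
        "config": config.to_dict(),
        "elapsed_s": round(time.time() - t0, 2),
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return dataset


def _fold_paths(comb_dir: Path, pid: str):
    return (comb_dir / f"timeline_{pid}.csv",
            comb_dir / f"confusion_{pid}.csv")


def _write_fold(comb_dir: Path, fold: FoldResult) -> None:
    tl_path, cf_path = _fold_paths(comb_dir, fold.val_participant_id)
    export_timeline(fold).to_csv(tl_path, index=False)
    chart_to_frame(confusion(fold.y_true, fold.y_pred)).to_csv(cf_path)


def _load_fold(comb_dir: Path, pid: str, train_ids,
               fold_meta: dict) -> FoldResult:
    tl_path, _ = _fold_paths(comb_dir, pid)
    df = pd.read_csv(tl_path)
    y_true = np.array([int(ActivityClass.from_code(c)) for c in df["true"]])
    y_pred = np.array([int(ActivityClass.from_code(c)) for c in df["pred"]])
    return FoldResult(
        val_participant_id=pid,
        train_participant_ids=tuple(train_ids),
        best_repeat_index=fold_meta.get("best_repeat_index", -1),
        val_accuracy=float(np.mean(y_true == y_pred)),
        y_true=y_true, y_pred=y_pred,
        stopped_at_iter=fold_meta.get("stopped_at_iter", -1),
        repeat_accuracies=tuple(fold_meta.get("repeat_accuracies", ())),
        repeat_seeds=tuple(fold_meta.get("repeat_seeds", ())),
    )


def run_experiment(dataset: Dataset, out_dir,
                   combinations=(SensorCombination.C1, SensorCombination.C2,
                                 SensorCombination.C3, SensorCombination.C4),
                   training: TrainingConfig | None = None,
                   resume: bool = True) -> dict:
    """LOSO-train and evaluate the requested sensor combinations.

    Returns {SensorCombination: LosoResult} and writes all report files.
    """
    training = training or TrainingConfig()
    training.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = _config_digest({"training": training.to_dict(),
                             "cohort_seed": dataset.cohort_seed,
                             "cohort": dataset.config.to_dict()})
    manifest_path = out_dir / "manifest.json"
    manifest = {"stage": "run", "version": __version__,
                "config_digest": digest,
                "cohort_seed": dataset.cohort_seed,
                "training": training.to_dict(),
                "combinations": {}, "timings_s": {}, "files": {}}
    old = {}
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_digest") == digest:
            old = prev.get("combinations", {})

    from .loso import loso_folds  # local import to avoid cycle at module load
    results = {}
    for comb in combinations:
        comb_dir = out_dir / comb.name
        comb_dir.mkdir(exist_ok=True)
        t0 = time.time()
        folds_meta = old.get(comb.name, {}).get("folds", {})
        result = LosoResult(combination=comb)
        pending = []
        for k, (train_ids, val_id) in enumerate(loso_folds(dataset)):
            tl_path, cf_path = _fold_paths(comb_dir, val_id)
            if resume and tl_path.exists() and cf_path.exists() \
                    and val_id in folds_meta:
                result.folds.append(
                    _load_fold(comb_dir, val_id, train_ids, folds_meta[val_id]))
                log.info("%s fold %s: resumed from %s", comb.name, val_id,
                         tl_path.name)
            else:
                pending.append((k, train_ids, val_id))
        if pending:
            fresh = run_combination(
                dataset, comb, training,
                fold_callback=lambda f, d=comb_dir: _write_fold(d, f))
            by_pid = {f.val_participant_id: f for f in fresh.folds}
            done = {f.val_participant_id for f in result.folds}
            result.folds.extend(f for pid, f in by_pid.items()
                                if pid not in done)
        # keep fold order aligned with the cohort
        order = {pid: i for i, pid in enumerate(dataset.participant_ids)}
        result.folds.sort(key=lambda f: order[f.val_participant_id])
        results[comb] = result
        manifest["combinations"][comb.name] = {"folds": {
            f.val_participant_id: {
                "best_repeat_index": f.best_repeat_index,
                "stopped_at_iter": f.stopped_at_iter,
                "val_accuracy": f.val_accuracy,
                "repeat_accuracies": list(f.repeat_accuracies),
                "repeat_seeds": list(f.repeat_seeds),
            } for f in result.folds}}
        manifest["timings_s"][comb.name] = round(time.time() - t0, 2)

    records = pd.concat([fold_records(r) for r in results.values()],
                        ignore_index=True)
    records.to_csv(out_dir / "metrics.csv", index=False)
    summary = summarize(results)
    summary.to_csv(out_dir / "summary.csv", index=False)
    summary.to_json(out_dir / "summary.json", orient="records", indent=2)
    boxes = pd.concat(
        [precision_distribution(records[records.combination == c.name])
         .assign(combination=c.name) for c in results],
        ignore_index=True)
    boxes.to_json(out_dir / "precision_boxes.json", orient="records", indent=2)

    manifest["files"] = {str(p.relative_to(out_dir)): _sha256(p)
                         for p in sorted(out_dir.rglob("*"))
                         if p.is_file() and p.name != "manifest.json"}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return results


def run_all(cohort_dir, out_dir, combinations=None,
            training: TrainingConfig | None = None) -> dict:
    """Load a cohort from disk and run the full ablation experiment."""
    dataset = read_cohort(cohort_dir)
    combos = combinations or (SensorCombination.C1, SensorCombination.C2,
                              SensorCombination.C3, SensorCombination.C4)
    return run_experiment(dataset, out_dir, combos, training)
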