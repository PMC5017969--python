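"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
train -> evaluate, with a manifest recording seeds, hashes and headline
metrics so any stage can be re-run in isolation."""

from __future__ import annotations

import hashlib
import json
import os
import time
import zlib

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    NetworkConfig,
    hidden_size,
    init_network,
    save_model,
    train_scg,
)
from .config import PipelineConfig
from .evaluation import cross_validate, overall_accuracy
from .feature_selection import mrmr_rank
from .features import FEATURE_NAMES, extract_features
from .preprocessing import preprocess_recording
from .signal_io import (
    AnnotationTrack,
    Recording,
    Trial,
    read_annotations,
    read_recording,
    segment_trials,
    write_annotations,
    write_feature_table,
    write_recording,
)
from .synthetic import DatasetMeta, GeneratorConfig, generate_dataset

_GAP_SAMPLES = 200  # quiet spacing between utterances in a built recording


def dataset_to_recordings(
    trials: list[Trial], meta: DatasetMeta, cfg: GeneratorConfig
) -> dict[str, tuple[Recording, AnnotationTrack]]:
    """Concatenate each subject's trials into one continuous recording with
    annotated utterance intervals (quiet gaps in between)."""
    by_subject: dict[str, list[int]] = {}
    for i, rec in enumerate(meta.records):
        by_subject.setdefault(rec["subject_id"], []).append(i)
    out = {}
    for subject_id, indices in by_subject.items():
        key = zlib.crc32(subject_id.encode())  # stable across interpreters
        rng = np.random.default_rng([cfg.seed, 0x6A9, key])
        chunks: list[np.ndarray] = []
        intervals: list[tuple[int, int, int]] = []
        cursor = 0
        for i in indices:
            gap = cfg.dc_offset_mv + cfg.noise_sd_mv * rng.standard_normal(
                _GAP_SAMPLES
            )
            chunks.append(gap)
            cursor += _GAP_SAMPLES
            t = trials[i]
            chunks.append(t.samples)
            intervals.append((cursor, cursor + len(t), t.class_id))
            cursor += len(t)
        chunks.append(
            cfg.dc_offset_mv + cfg.noise_sd_mv * rng.standard_normal(
                _GAP_SAMPLES
            )
        )
        out[subject_id] = (
            Recording(np.concatenate(chunks), fs=cfg.fs,
                      subject_id=subject_id),
            AnnotationTrack(intervals),
        )
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate(cfg: GeneratorConfig, out_dir: str) -> dict:
    """Generate the dataset and write per-subject recordings + sidecars."""
    os.makedirs(out_dir, exist_ok=True)
    trials, meta = generate_dataset(cfg)
    recs = dataset_to_recordings(trials, meta, cfg)
    files = {}
    for subject_id, (rec, ann) in sorted(recs.items()):
        rec_path = os.path.join(out_dir, f"{subject_id}_recording.csv")
        ann_path = os.path.join(out_dir, f"{subject_id}_annotations.csv")
        write_recording(rec, rec_path)
        write_annotations(ann, ann_path)
        files[subject_id] = {"recording": rec_path, "annotations": ann_path}
    manifest = {
        "n_trials": len(trials),
        "subjects": sorted(recs),
        "files": files,
    }
    with open(os.path.join(out_dir, "simulate_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_and_preprocess(config: PipelineConfig, sim_dir: str) -> list[Trial]:
    """Read simulated recordings, filter the continuous signal, segment."""
    with open(os.path.join(sim_dir, "simulate_manifest.json")) as fh:
        manifest = json.load(fh)
    trials: list[Trial] = []
    for subject_id in manifest["subjects"]:
        paths = manifest["files"][subject_id]
        rec = read_recording(paths["recording"], fs=config.generator.fs,
                            subject_id=subject_id)
        ann = read_annotations(paths["annotations"])
        clean = preprocess_recording(rec, config.filter)
        trials.extend(segment_trials(clean, ann))
    return trials


def extract_table(config: PipelineConfig, trials: list[Trial],
                  path: str) -> pd.DataFrame:
    vectors = [extract_features(t, config.feature) for t in trials]
    write_feature_table(
        vectors,
        [t.class_id for t in trials],
        [t.subject_id for t in trials],
        path,
    )
    return pd.read_csv(path)


def select_features(config: PipelineConfig, table: pd.DataFrame,
                    path: str | None = None):
    X = table[list(FEATURE_NAMES)].to_numpy()
    y = table["class_id"].to_numpy()
    result = mrmr_rank(
        X, y, k=config.selection.k, scheme=config.selection.scheme(),
        feature_names=list(FEATURE_NAMES),
    )
    if path:
        payload = {
            "k": result.k,
            "ranked_indices": result.ranked_indices,
            "feature_names": result.feature_names,
            "per_step": [
                {"feature": s.feature, "relevance": s.relevance,
                 "redundancy": s.redundancy, "score": s.score}
                for s in result.per_step
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return result


def train_model(config: PipelineConfig, table: pd.DataFrame,
                selection, model_path: str | None = None,
                metrics_path: str | None = None):
    sel = selection.ranked_indices
    X = table[list(FEATURE_NAMES)].to_numpy()[:, sel]
    y = table["class_id"].to_numpy()
    cfg = NetworkConfig(
        n_inputs=len(sel),
        n_hidden=hidden_size(len(sel)),
        n_outputs=config.generator.n_classes,
        seed=config.seed,
    )
    model = init_network(cfg)
    model.feature_names = [FEATURE_NAMES[i] for i in sel]
    train_scg(model, X, y, config.train)
    if model_path:
        save_model(model, model_path)
    if metrics_path:
        pd.DataFrame(model.history).to_csv(metrics_path, index=False)
    return model


def evaluate(config: PipelineConfig, table: pd.DataFrame, out_dir: str,
             selection=None, make_plots: bool = True):
    X = table[list(FEATURE_NAMES)].to_numpy()
    y = table["class_id"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    fixed = (
        selection.ranked_indices
        if (selection is not None and config.evaluation.fixed_selection)
        else None
    )
    result = cross_validate(
        X, y, subjects=subjects,
        k_folds=config.evaluation.k_folds,
        seed=config.seed,
        n_select=config.selection.k,
        n_classes=config.generator.n_classes,
        scheme=config.selection.scheme(),
        train_config=config.train,
        cv_mode=config.evaluation.cv_mode,
        fixed_selection=fixed,
    )
    os.makedirs(out_dir, exist_ok=True)
    cm = result.pooled_confusion
    pd.DataFrame(
        cm.counts,
        index=[f"true_{n}" for n in cm.class_names],
        columns=[f"pred_{n}" for n in cm.class_names],
    ).to_csv(os.path.join(out_dir, "confusion_matrix.csv"))
    roc_rows = []
    for curve in result.roc:
        for fpr, tpr in zip(curve.fpr, curve.tpr):
            roc_rows.append({"class_id": curve.class_id, "fpr": fpr,
                             "tpr": tpr, "auc": curve.auc})
    pd.DataFrame(roc_rows).to_csv(os.path.join(out_dir, "roc_points.csv"),
                                  index=False)
    summary = {
        "overall_accuracy_pct": overall_accuracy(cm),
        "mean_fold_accuracy_pct": result.mean_accuracy,
        "sd_fold_accuracy_pct": result.sd_accuracy,
        "fold_accuracies_pct": result.fold_accuracies,
        "per_class_accuracy_pct": [
            None if np.isnan(v) else v for v in result.per_class_accuracy
        ],
        "seed": result.seed,
    }
    with open(os.path.join(out_dir, "cv_result.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    if make_plots:
        _plot_confusion(cm, os.path.join(out_dir, "confusion_matrix.png"))
        _plot_roc(result.roc, os.path.join(out_dir, "roc_curves.png"))
    return result


def _plot_confusion(cm, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    ax.set_xticks(range(len(cm.class_names)), cm.class_names)
    ax.set_yticks(range(len(cm.class_names)), cm.class_names)
    for i in range(len(cm.counts)):
        for j in range(len(cm.counts)):
            if cm.counts[i, j]:
                ax.text(j, i, str(cm.counts[i, j]), ha="center",
                        va="center", fontsize=7)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_roc(curves, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for curve in curves:
        if curve.defined:
            ax.plot(curve.fpr, curve.tpr, lw=1,
                    label=f"class {curve.class_id} (AUC {curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(config: PipelineConfig, out_dir: str | None = None,
            make_plots: bool = True) -> dict:
    """Execute every stage in order and return the run manifest."""
    out_dir = out_dir or config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    sim_dir = os.path.join(out_dir, "simulated")
    simulate(config.generator, sim_dir)
    trials = load_and_preprocess(config, sim_dir)
    table_path = os.path.join(out_dir, "features.csv")
    table = extract_table(config, trials, table_path)
    selection_path = os.path.join(out_dir, "selection.json")
    selection = select_features(config, table, selection_path)
    model_path = os.path.join(out_dir, "model.json")
    metrics_path = os.path.join(out_dir, "train_metrics.csv")
    model = train_model(config, table, selection, model_path, metrics_path)
    eval_dir = os.path.join(out_dir, "evaluation")
    result = evaluate(config, table, eval_dir, selection=selection,
                      make_plots=make_plots)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_trials": len(trials),
        "n_features": len(FEATURE_NAMES),
        "n_selected": selection.k,
        "n_hidden": model.config.n_hidden,
        "stopped_epoch": model.stopped_epoch,
        "headline": {
            "pooled_cv_accuracy_pct": overall_accuracy(
                result.pooled_confusion
            ),
            "mean_fold_accuracy_pct": result.mean_accuracy,
        },
        "hashes": {
            "features.csv": _sha256(table_path),
            "selection.json": _sha256(selection_path),
            "model.json": _sha256(model_path),
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
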