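"""End-to-end orchestration of the comparative experiment.

One config drives: synthetic dataset generation -> stain normalization to a
reference image -> fused handcrafted features + classical classifiers under
cross-validation, and in parallel the block-wise fine-tuned network arm ->
a per-(arm, scheme, magnification) comparison table plus the embedding and
Grad-CAM figures for the winning arms.  Completed stages are skipped on
rerun (their outputs are on disk), and a single master seed fans out to
per-stage seeds through a fixed hash, so a rerun with an unchanged config
reproduces the same report.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classify, deep, explain, features as feat, stain, synthetic as syn

__all__ = ["ExperimentConfig", "ComparisonReport", "run_experiment", "select_best"]


@dataclass
class ExperimentConfig:
    """Everything a run needs; JSON round-trip stable.

    ``design`` selects the dataset: preset "binary" (default benign/malignant
    specs) or "subclasses" (the eight tumor sub-classes), with ``per_cell``
    images per (class, magnification).  ``schemes`` chooses the label
    column(s): "binary" -> class, "subclass" -> subclass.
    """

    design: str = "binary"
    per_cell: int = 100
    magnifications: tuple[int, ...] = (40,)
    image_size: int = 64
    reference: str = "auto"             # path, or "auto" = first image
    classifiers: tuple[str, ...] = ("knn", "rf", "mlp", "adaboost", "svm")
    dl_schedules: tuple[str, ...] = ("B6", "B3")
    dl_scale_factor: int = 8
    dl_epochs: int = 15
    dl_pretrain: bool = True
    dl_pretrain_epochs: int = 40
    schemes: tuple[str, ...] = ("binary",)
    cv_folds: int = 10
    feature_resize: int = 224
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src: str | Path) -> "ExperimentConfig":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        for k in ("magnifications", "classifiers", "dl_schedules", "schemes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(np.random.SeedSequence(
        [master, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2 ** 31))


def _design_cells(config: ExperimentConfig) -> list[syn.DesignCell]:
    if config.design == "binary":
        specs = {"benign": syn.default_benign_spec(),
                 "malignant": syn.default_malignant_spec()}
        cells = [syn.DesignCell(spec=s, count=config.per_cell, magnification=m)
                 for s in specs.values() for m in config.magnifications]
    elif config.design == "subclasses":
        parents = {"A": "benign", "F": "benign", "PT": "benign", "TA": "benign",
                   "DC": "malignant", "LC": "malignant", "MC": "malignant",
                   "PC": "malignant"}
        cells = [syn.DesignCell(spec=s, count=config.per_cell, magnification=m,
                                class_label=parents[cid], subclass_label=cid)
                 for cid, s in syn.subclass_specs().items()
                 for m in config.magnifications]
    else:
        raise ValueError(f"unknown design {config.design!r}")
    return cells


_SCHEME_COLUMN = {"binary": "class", "subclass": "subclass"}


@dataclass
class ComparisonReport:
    """The comparison table plus provenance."""

    table: pd.DataFrame     # arm, arm_type, scheme, magnification, metrics, status
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"provenance": self.provenance,
                   "cells": self.table.to_dict(orient="records")}
        s = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, path: str | Path) -> "ComparisonReport":
        d = json.loads(Path(path).read_text())
        return cls(table=pd.DataFrame(d["cells"]), provenance=d["provenance"])

    def summary(self) -> str:
        cols = ["arm", "arm_type", "scheme", "magnification",
                "accuracy", "recall", "precision", "status"]
        return self.table[cols].to_string(index=False,
                                          float_format=lambda v: f"{v:.2f}")


def select_best(report: ComparisonReport | pd.DataFrame, scheme: str,
                magnification: int) -> str:
    """The winning arm of one (scheme, magnification) cell set: highest
    accuracy, ties broken by higher recall, then lexicographic arm id."""
    df = report.table if isinstance(report, ComparisonReport) else report
    sub = df[(df["scheme"] == scheme) & (df["magnification"] == magnification)
             & (df["status"] == "ok")]
    if sub.empty:
        raise ValueError(f"no successful cells for ({scheme}, {magnification})")
    sub = sub.sort_values(["accuracy", "recall", "arm"],
                          ascending=[False, False, True], kind="mergesort")
    return str(sub.iloc[0]["arm"])


def _normalize_stage(out: Path, manifest: pd.DataFrame,
                     config: ExperimentConfig) -> tuple[Path, pd.DataFrame]:
    norm_dir = out / "norm"
    done = norm_dir / "manifest.csv"
    if done.exists():
        return norm_dir, syn.read_manifest(done)
    data_dir = out / "data"
    if config.reference == "auto":
        ref_path = data_dir / manifest["image_path"].iloc[0]
    else:
        ref_path = Path(config.reference)
    ref_px = np.asarray(Image.open(ref_path).convert("RGB"))
    profile = stain.stain_profile(ref_px, seed=_stage_seed(config.seed, "reference"))
    log = []
    for rel in manifest["image_path"]:
        px = np.asarray(Image.open(data_dir / rel).convert("RGB"))
        try:
            out_px = stain.normalize_stains(px, profile)
            status = "normalized"
        except stain.NoTissueError:
            out_px = px  # pass through unchanged
            status = "skipped_no_tissue"
        dst = norm_dir / rel
        dst.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(out_px).save(dst)
        log.append({"image_path": rel, "status": status})
    profile.to_json(norm_dir / "reference_profile.json")
    pd.DataFrame(log).to_csv(norm_dir / "normalization_log.csv", index=False)
    manifest.to_csv(done, index=False)
    return norm_dir, manifest


def _features_stage(out: Path, norm_dir: Path, manifest: pd.DataFrame,
                    config: ExperimentConfig) -> pd.DataFrame:
    fpath = out / "features.csv"
    if fpath.exists():
        return pd.read_csv(fpath, keep_default_na=False)
    table = feat.extract_features_table(manifest, norm_dir,
                                        resize_to=config.feature_resize)
    table.to_csv(fpath, index=False)
    return pd.read_csv(fpath, keep_default_na=False)


def _load_images(norm_dir: Path, manifest: pd.DataFrame) -> np.ndarray:
    return np.stack([
        np.asarray(Image.open(norm_dir / rel).convert("RGB"))
        for rel in manifest["image_path"]])


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> ComparisonReport:
    """Execute every stage; per-cell failures are recorded, not raised."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    # stage 1: dataset
    data_dir = out / "data"
    if not (data_dir / "manifest.csv").exists():
        syn.generate_dataset(_design_cells(config), data_dir,
                             seed=_stage_seed(config.seed, "data"),
                             size=(config.image_size, config.image_size))
    manifest = syn.read_manifest(data_dir / "manifest.csv")

    # stage 2: stain normalization
    norm_dir, manifest = _normalize_stage(out, manifest, config)

    # stage 3: handcrafted features
    table = _features_stage(out, norm_dir, manifest, config)

    # stage 4/5: arms
    report_path = out / "report.json"
    if report_path.exists():
        return ComparisonReport.from_json(report_path)

    rows = []
    images_cache: dict[int, np.ndarray] = {}
    backbone = None
    for mag in config.magnifications:
        sel = table["magnification"] == mag
        sub_table = table[sel].reset_index(drop=True)
        sub_manifest = manifest[manifest["magnification"] == mag].reset_index(drop=True)
        for scheme in config.schemes:
            col = _SCHEME_COLUMN[scheme]
            labels = sub_table[col].to_numpy()
            for kind in config.classifiers:
                row = {"arm": kind, "arm_type": "cml", "scheme": scheme,
                       "magnification": int(mag)}
                try:
                    model = classify.ClassicalClassifierModel(
                        sub_table[feat.feature_column_names()].to_numpy(),
                        labels, classify.ClassifierSpec(kind))
                    res = model.fit(k=config.cv_folds,
                                    seed=_stage_seed(config.seed, f"cml/{kind}"))
                    row.update(accuracy=res.mean_accuracy, recall=res.mean_recall,
                               precision=res.mean_precision, status="ok")
                    (out / f"cml_{kind}_{scheme}_{mag}.json").write_text(res.to_json())
                except Exception as err:  # noqa: BLE001 - cell isolation
                    row.update(accuracy=np.nan, recall=np.nan, precision=np.nan,
                               status="failed", error=str(err))
                rows.append(row)
            if not config.dl_schedules:
                continue
            if mag not in images_cache:
                images_cache[mag] = _load_images(norm_dir, sub_manifest)
            imgs = images_cache[mag]
            dl_labels = sub_manifest[col].to_numpy()
            if backbone is None and config.dl_pretrain:
                backbone, _ = deep.pretrain_backbone(
                    scale_factor=config.dl_scale_factor,
                    input_size=config.image_size,
                    seed=_stage_seed(config.seed, "pretrain"),
                    epochs=config.dl_pretrain_epochs)
            for sched in config.dl_schedules:
                arm = f"vgg19-{'B6' if sched == 'B6' else 'B6-' + sched}"
                row = {"arm": arm, "arm_type": "dl", "scheme": scheme,
                       "magnification": int(mag)}
                try:
                    net = deep.VGG19Network(
                        num_classes=len(set(dl_labels)),
                        scale_factor=config.dl_scale_factor,
                        input_size=config.image_size,
                        seed=_stage_seed(config.seed, f"dl/{sched}/init"))
                    if backbone is not None:
                        deep.transfer_weights(backbone, net)
                    cfg = deep.TrainConfig(
                        epochs=config.dl_epochs,
                        seed=_stage_seed(config.seed, f"dl/{sched}/{scheme}/{mag}"))
                    res = deep.FineTuneModel(net, imgs, dl_labels, cfg,
                                             tune_from=sched).fit()
                    m = res.test_metrics
                    row.update(accuracy=m.accuracy, recall=m.recall,
                               precision=m.precision, status="ok")
                    res.history.to_csv(
                        out / f"dl_{sched}_{scheme}_{mag}_history.csv", index=False)
                    row["_results"] = res  # kept transiently for figures
                except Exception as err:  # noqa: BLE001
                    row.update(accuracy=np.nan, recall=np.nan, precision=np.nan,
                               status="failed", error=str(err))
                rows.append(row)

    full = pd.DataFrame(rows)
    _make_figures(out, full, table, images_cache, manifest, config)
    report = ComparisonReport(
        table=full.drop(columns=["_results"], errors="ignore"),
        provenance={"config": json.loads(config.to_json()), "seed": config.seed})
    report.to_json(report_path)
    report.table.to_csv(out / "report.csv", index=False)
    return report


def _make_figures(out: Path, full: pd.DataFrame, table: pd.DataFrame,
                  images_cache: dict, manifest: pd.DataFrame,
                  config: ExperimentConfig) -> None:
    """Embedding panels for the handcrafted features and Grad-CAM overlays
    for the best network arm of each (scheme, magnification)."""
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for mag in config.magnifications:
        sub = table[table["magnification"] == mag]
        X = sub[feat.feature_column_names()].to_numpy()
        for scheme in config.schemes:
            labels = sub[_SCHEME_COLUMN[scheme]].to_numpy()
            try:
                emb = explain.pca_2d(X, labels=labels)
                explain.plot_embedding(
                    emb, fig_dir / f"pca_handcrafted_{scheme}_{mag}.png",
                    title=f"PCA, handcrafted features, {scheme}, {mag}x")
                emb_k = explain.kpca_2d(X, kernel="rbf", labels=labels)
                explain.plot_embedding(
                    emb_k, fig_dir / f"kpca_rbf_handcrafted_{scheme}_{mag}.png",
                    title=f"KPCA (rbf), handcrafted features, {scheme}, {mag}x")
            except ValueError:
                continue
            dl_rows = full[(full["arm_type"] == "dl") & (full["scheme"] == scheme)
                           & (full["magnification"] == mag)
                           & (full["status"] == "ok")]
            if dl_rows.empty or "_results" not in dl_rows.columns:
                continue
            best = dl_rows.sort_values(["accuracy", "recall", "arm"],
                                       ascending=[False, False, True]).iloc[0]
            res = best["_results"]
            if not isinstance(res, deep.TrainResults):
                continue
            imgs = images_cache[mag]
            for i in res.test_indices[:3]:
                lab = res.class_names[res.network.forward(
                    deep.preprocess_images(imgs[i][None],
                                           res.network.input_stats)).argmax()]
                heat = explain.grad_cam(res.network, imgs[i], lab,
                                        class_names=res.class_names)
                over = explain.overlay(heat, imgs[i])
                Image.fromarray(over).save(
                    fig_dir / f"gradcam_{best['arm']}_{scheme}_{mag}_{i}.png")
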