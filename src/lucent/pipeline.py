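"""End-to-end orchestration: phantom -> preprocess -> segment -> render ->
classify -> evaluate, as one reproducible, configured, logged run.

A run is a pure function of (config, seed): every stage writes its
artifacts under the run directory with a ``.done`` marker, so deleting
downstream artifacts and re-running re-executes only the downstream
stages. Ablation presets reproduce the pipeline variants by configuration
alone:

* ``raw_slices``  — baseline: classify the middle axial slices of the
  preprocessed CT volume (no segmentation, no rendering, no augmentation);
* ``mask_no_aug`` — 12 rendered airway views, augmentation disabled;
* ``views6``      — 6 rendered views with augmentation;
* ``full12``      — the complete pipeline: 12 views with augmentation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from lucent.classifier import (
    AugmentConfig2D,
    ClassifierConfig,
    predict_patient,
    train_classifier,
)
from lucent.evalstats import ClassMetrics, class_metrics, confusion, roc_auc, stratified_kfold
from lucent.phantom import PhantomSpec, make_cohort
from lucent.preprocess import PreprocessConfig, preprocess_volume
from lucent.render import render_viewset
from lucent.segmetrics import seg_report
from lucent.segnet import (
    FocalParams,
    SegAugmentConfig,
    SegNetConfig,
    predict_mask,
    train_segnet,
)
from lucent.serialize import _jsonable

PRESETS = ("raw_slices", "mask_no_aug", "views6", "full12")


@dataclass
class RunConfig:
    out_dir: str | Path = "run"
    seed: int = 0
    # cohort
    n_fba: int = 10
    n_nfba: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    # ablation preset
    preset: str = "full12"
    # segmentation stage (optional; ground-truth masks are used downstream
    # unless use_predicted_masks is set)
    train_segmentation: bool = False
    use_predicted_masks: bool = False
    segnet: SegNetConfig = field(default_factory=SegNetConfig)
    seg_epochs: int = 8
    seg_lr: float = 3e-3
    seg_crop: int = 32
    # rendering
    render_size: int = 64
    camera_radius_mm: float = 150.0
    frame_half_mm: float = 60.0
    # classification
    classifier: ClassifierConfig = field(default_factory=lambda: ClassifierConfig(
        input_size=64, lr0=1e-3, max_epochs=25))
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")

    @property
    def n_views(self) -> int:
        return 6 if self.preset == "views6" else 12

    @property
    def augmented(self) -> bool:
        return self.preset in ("views6", "full12")


@dataclass
class RunRecord:
    config: dict
    config_hash: str
    artifacts: dict
    metrics: dict
    log: list


def _hash_config(cfg_dict: dict) -> str:
    return hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]


def _resize2d(img: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    return resize(img, (size, size), order=1, anti_aliasing=True,
                  preserve_range=True).astype(np.float32)


def _stage(out: Path, name: str):
    d = out / name
    d.mkdir(parents=True, exist_ok=True)
    return d, d / ".done"


def run(config: RunConfig) -> RunRecord:
    """Execute the configured pipeline; see the module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = _jsonable(asdict(config))
    chash = _hash_config(cfg_dict)
    log: list[str] = []
    artifacts: dict[str, str] = {}
    metrics: dict = {}

    def note(msg: str) -> None:
        log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    note(f"run start, config hash {chash}, seed {config.seed}")

    # ---------------------------------------------------------------- phantom
    stage_dir, done = _stage(out, "cohort")
    records = make_cohort(config.n_fba, config.n_nfba, config.phantom, config.seed,
                          out_dir=None if done.exists() else stage_dir)
    done.write_text("ok")
    artifacts["cohort"] = str(stage_dir)
    note(f"cohort: {config.n_fba} FBA + {config.n_nfba} NFBA phantoms")

    # ------------------------------------------------------------- preprocess
    pre = []
    for rec in records:
        v, m = preprocess_volume(rec.volume, rec.mask, config.preprocess)
        pre.append((rec.patient_id, v, m, rec.label))
    note("preprocessing: resample/clip-normalize/crop/smooth")

    # ------------------------------------------------------------------ folds
    ids = [p[0] for p in pre]
    labels = [p[3] for p in pre]
    folds = stratified_kfold(ids, labels, k=config.k_folds, seed=config.seed)
    test_ids = {i for i in ids if folds[i] == 0}
    val_ids = {i for i in ids if folds[i] == 1}
    train_ids = {i for i in ids if folds[i] >= 2}
    note(f"folds: {len(train_ids)} train / {len(val_ids)} val / {len(test_ids)} test")

    # ----------------------------------------------------------- segmentation
    masks = {pid: m for pid, _, m, _ in pre}
    if config.train_segmentation:
        stage_dir, done = _stage(out, "segmentation")
        seg_train = [(v.voxels, m) for pid, v, m, _ in pre if pid in train_ids]
        seg_val = [(v.voxels, m) for pid, v, m, _ in pre if pid in val_ids]
        model, hist = train_segnet(seg_train, config.segnet, FocalParams(),
                                   SegAugmentConfig() if config.augmented
                                   else SegAugmentConfig.disabled(),
                                   val_pairs=seg_val, epochs=config.seg_epochs,
                                   lr=config.seg_lr, crop_size=config.seg_crop,
                                   seed=config.seed)
        rows = []
        for pid, v, m, _ in pre:
            if pid not in test_ids:
                continue
            pm = predict_mask(model, _center_crop(v.voxels, m, config.seg_crop),
                              threshold=config.segnet.threshold)
            rows.append({"patient_id": pid,
                         **seg_report(pm, _center_crop_mask(m, config.seg_crop),
                                      v.spacing_mm).to_row()})
        seg_df = pd.DataFrame(rows)
        seg_df.to_csv(stage_dir / "seg_metrics.csv", index=False)
        done.write_text("ok")
        metrics["segmentation"] = {
            "val_dsc_last": hist["val_dsc"][-1] if hist["val_dsc"] else None,
            "test_dsc_mean": float(seg_df["dsc_pct"].mean()) if len(seg_df) else None,
        }
        artifacts["segmentation"] = str(stage_dir)
        note(f"segmentation: val DSC {metrics['segmentation']['val_dsc_last']}")
        if config.use_predicted_masks:
            for pid, v, m, _ in pre:
                masks[pid] = predict_mask(model, v.voxels,
                                          threshold=config.segnet.threshold)

    # ----------------------------------------------------------------- render
    items = []
    if config.preset == "raw_slices":
        for pid, v, m, lab in pre:
            nz = v.shape[2]
            sl = [_resize2d(v.voxels[:, :, k], config.render_size)
                  for k in range(nz // 2 - 6, nz // 2 + 6)]
            items.append((pid, np.stack(sl), lab))
        note("raw-slice baseline: middle 12 axial slices per patient")
    else:
        stage_dir, done = _stage(out, "views")
        export = not done.exists()
        for pid, v, m, lab in pre:
            vs = render_viewset(masks[pid], v.spacing_mm, n_views=config.n_views,
                                radius_mm=config.camera_radius_mm,
                                size=config.render_size,
                                frame_half_mm=config.frame_half_mm)
            items.append((pid, vs.images, lab))
            if export:
                from lucent.render import save_viewset

                save_viewset(vs, stage_dir, pid)
        done.write_text("ok")
        artifacts["views"] = str(stage_dir)
        note(f"rendered {config.n_views} views per patient at "
             f"{config.render_size}px")

    # --------------------------------------------------------------- classify
    by_split = {
        "train": [i for i in items if i[0] in train_ids],
        "val": [i for i in items if i[0] in val_ids],
        "test": [i for i in items if i[0] in test_ids],
    }
    train_imgs = np.concatenate([i[1].ravel() for i in by_split["train"]])
    ccfg = replace(config.classifier, seed=config.seed,
                   zscore_mean=float(train_imgs.mean()),
                   zscore_sd=float(train_imgs.std() + 1e-6))
    aug = AugmentConfig2D() if config.augmented else AugmentConfig2D.disabled()
    model, hist = train_classifier(by_split["train"], by_split["val"], ccfg, aug)
    note(f"classifier trained {len(hist['val_f1'])} epochs "
         f"(best val F1 {max(hist['val_f1']):.3f})")

    # --------------------------------------------------------------- evaluate
    stage_dir, done = _stage(out, "evaluation")
    rows, truth, pred, score = [], [], [], []
    for pid, views, lab in by_split["test"]:
        pp = predict_patient(model, views, ccfg, pid, lab)
        truth.append(lab == "FBA")
        pred.append(pp.label_pred == "FBA")
        score.append(float(pp.aggregate_prob[1]))
        rows.append({"patient_id": pid, "label_true": lab,
                     "label_pred": pp.label_pred, "p_fba": score[-1]})
    pd.DataFrame(rows).to_csv(stage_dir / "predictions.csv", index=False)
    cc = confusion(truth, pred)
    cm = class_metrics(cc)
    metrics["confusion"] = {"tp": cc.tp, "fn": cc.fn, "tn": cc.tn, "fp": cc.fp}
    metrics["classification"] = cm.rounded()
    metrics["auc"] = roc_auc(score, truth) if (any(truth) and not all(truth)) else None
    metrics["history"] = {k: [float(x) for x in v] for k, v in hist.items()}
    (stage_dir / "report.json").write_text(json.dumps(
        {k: v for k, v in metrics.items() if k != "history"}, indent=2))
    done.write_text("ok")
    artifacts["evaluation"] = str(stage_dir)
    note(f"test metrics: {metrics['classification']}, AUC {metrics['auc']}")

    record = RunRecord(cfg_dict, chash, artifacts, metrics, log)
    (out / "run_record.json").write_text(json.dumps(
        {"config": cfg_dict, "config_hash": chash, "artifacts": artifacts,
         "metrics": {k: v for k, v in metrics.items() if k != "history"},
         "log": log}, indent=2))
    return record


def _center_crop(vol: np.ndarray, mask: np.ndarray, size: int) -> np.ndarray:
    from lucent.segnet import _crop_around

    return _crop_around(vol, mask, size, None)[0]


def _center_crop_mask(mask: np.ndarray, size: int) -> np.ndarray:
    from lucent.segnet import _crop_around

    return _crop_around(mask.astype(np.float32), mask, size, None)[1]


def ablation_suite(base: RunConfig) -> pd.DataFrame:
    """Run all four ablation presets with shared cohort, folds and seed.

    Returns one row per preset with the patient-level metrics, all computed
    on identical test patients.
    """
    rows = []
    for preset in PRESETS:
        cfg = replace(base, preset=preset,
                      out_dir=Path(base.out_dir) / f"ablation_{preset}")
        rec = run(cfg)
        row = {"preset": preset, **rec.metrics["classification"],
               "auc": rec.metrics["auc"], **rec.metrics["confusion"]}
        rows.append(row)
    return pd.DataFrame(rows)
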