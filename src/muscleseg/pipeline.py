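"""End-to-end pipeline driver: phantom -> preprocess -> train -> segment ->
postprocess -> quantify -> evaluate.

:func:`run_experiment` runs the whole study in memory on a synthetic cohort
and is the programmatic entry point; :func:`run_pipeline` is the on-disk
variant behind the CLI, executing enabled stages in order against NIfTI/CSV
artifacts so that stages can be toggled and re-run against prior outputs.

All randomness flows from the experiment seed; in deterministic mode (the
default — there is no nondeterministic path) a config fully determines the
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .evaluate import EvalReport, evaluate_testset
from .phantom import CohortScan, PhantomSpec, generate_cohort
from .postprocess import finalize
from .preprocess import PreprocessConfig, apply_mask, muscle_mask_from_water, split_labels, split_thighs
from .quantify import roi_stats_table
from .segmenter import (
    TrainedModel,
    UnetConfig,
    build_unet,
    load_model,
    make_slice_dataset,
    normalize_channels,
    predict_volume,
    save_model,
    train,
)
from .volumes import FatWaterVolume, MuscleLabelVolume

__all__ = ["ExperimentConfig", "ThighCase", "run_experiment", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Desk-scale end-to-end experiment on a synthetic cohort.

    Defaults match the scaled-down study conditions: 20 training + 5
    held-out bilateral subjects, per-ROI fat fractions drawn uniformly from
    [0.05, 0.4], 3% additive noise, and a depth-3 / 16-filter U-net trained
    with Adam on 64 x 64 thigh slices.
    """

    n_train_subjects: int = 20
    n_test_subjects: int = 5
    repeats: int = 1
    ff_range: Tuple[float, float] = (0.05, 0.4)
    noise_sigma: float = 0.03
    # per-subject anatomical variation (uniform draws), mm
    geometry_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "thigh_radius": (25.0, 30.0),
            "subcut_fat_thickness": (4.0, 7.0),
            "bone_radius": (4.0, 6.0),
        }
    )
    grid_shape: Tuple[int, int, int] = (64, 128, 12)
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 6.0)
    # fixed PhantomSpec field overrides (e.g. smaller radii for small grids)
    phantom_overrides: Dict[str, float] = field(default_factory=dict)
    epochs: int = 25
    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"
    norm: str = "none"
    depth: int = 3
    base_filters: int = 16
    batch_size: int = 6
    val_fraction: float = 0.25
    connectivity: int = 26
    seed: int = 0


@dataclass
class ThighCase:
    """One preprocessed thigh: masked original-intensity channels plus the
    pristine split volume (for fat-fraction work) and ground truth."""

    thigh_id: str
    repeat_id: int
    role: str  # train / test
    masked: FatWaterVolume
    original: FatWaterVolume
    labels: MuscleLabelVolume


def _phantom_spec(cfg: ExperimentConfig) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=tuple(cfg.grid_shape),
        voxel_spacing=tuple(cfg.voxel_spacing),
        noise_sigma=cfg.noise_sigma,
        **cfg.phantom_overrides,
    )


def make_cohort(cfg: ExperimentConfig) -> List[CohortScan]:
    """Training + held-out subjects in one cohort (subjects split by index)."""
    dist: Dict[str, Tuple[float, float]] = {"roi_fat_fraction": cfg.ff_range}
    dist.update(cfg.geometry_ranges)
    return generate_cohort(
        n_subjects=cfg.n_train_subjects + cfg.n_test_subjects,
        repeats=cfg.repeats,
        spec_distribution=dist,
        seed=cfg.seed,
        base_spec=_phantom_spec(cfg),
    )


def preprocess_scan(
    scan: CohortScan, pre_cfg: Optional[PreprocessConfig] = None, role: str = "train"
) -> List[ThighCase]:
    """Split a bilateral scan and derive the muscle-region masked channels."""
    pre_cfg = pre_cfg or PreprocessConfig()
    left, right = split_thighs(scan.volume, pre_cfg)
    lab_left, lab_right = split_labels(scan.labels, pre_cfg)
    out = []
    for side, vol, lab in (("left", left, lab_left), ("right", right, lab_right)):
        mask = muscle_mask_from_water(vol.water, pre_cfg)
        out.append(
            ThighCase(
                thigh_id=f"{scan.subject_id}_{side}",
                repeat_id=scan.repeat_id,
                role=role,
                masked=apply_mask(vol, mask),
                original=vol,
                labels=lab,
            )
        )
    return out


def _mirror_fw(vol: FatWaterVolume) -> FatWaterVolume:
    return FatWaterVolume(
        np.flip(vol.water, axis=1).copy(), np.flip(vol.fat, axis=1).copy(),
        vol.voxel_spacing, side_label=vol.side_label,
    )


def _mirror_lab(lab: MuscleLabelVolume) -> MuscleLabelVolume:
    return MuscleLabelVolume(np.flip(lab.labels, axis=1).copy(), lab.voxel_spacing)


def canonical_input(case: ThighCase) -> Tuple[FatWaterVolume, MuscleLabelVolume]:
    """Normalized network input and labels in canonical (left) chirality.

    Left and right thighs are mirror images; presenting both chiralities
    makes the muscle-group layout ambiguous wherever fat-fraction contrast
    is weak, so right thighs are mirrored in-plane before the network and
    predictions mirrored back (:func:`predict_case`).
    """
    vol = normalize_channels(case.masked)
    lab = case.labels
    if case.thigh_id.endswith("right"):
        vol, lab = _mirror_fw(vol), _mirror_lab(lab)
    return vol, lab


def predict_case(model: TrainedModel, case: ThighCase, unet_cfg=None) -> MuscleLabelVolume:
    """Predict a thigh in canonical chirality and mirror back if needed."""
    vol, _ = canonical_input(case)
    pred = predict_volume(model, vol, unet_cfg)
    if case.thigh_id.endswith("right"):
        pred = _mirror_lab(pred)
    return pred


def run_experiment(
    cfg: ExperimentConfig, pre_cfg: Optional[PreprocessConfig] = None
) -> Tuple[EvalReport, TrainedModel]:
    """Run the full desk-scale study in memory.

    Generates the cohort, preprocesses every scan, trains the U-net on the
    training subjects (volume-level train/validation split), predicts the
    held-out subjects, applies largest-component postprocessing and returns
    the evaluation report plus the trained model.
    """
    t0 = time.time()
    scans = make_cohort(cfg)
    thighs: List[ThighCase] = []
    for scan in scans:
        sidx = int(scan.subject_id[1:])
        role = "train" if sidx < cfg.n_train_subjects else "test"
        thighs.extend(preprocess_scan(scan, pre_cfg, role))
    log.info("pipeline: cohort + preprocessing done in %.1fs", time.time() - t0)

    train_thighs = [t for t in thighs if t.role == "train"]
    test_thighs = [t for t in thighs if t.role == "test"]
    volumes = [canonical_input(t) for t in train_thighs]
    ids = [f"{t.thigh_id}_r{t.repeat_id}" for t in train_thighs]
    subjects = [t.thigh_id.rsplit("_", 1)[0] for t in train_thighs]
    train_set, val_set = make_slice_dataset(
        volumes, split=1.0 - cfg.val_fraction, seed=cfg.seed, volume_ids=ids,
        groups=subjects,
    )

    unet_cfg = UnetConfig(
        depth=cfg.depth,
        base_filters=cfg.base_filters,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        lr_schedule=cfg.lr_schedule,
        norm=cfg.norm,
        seed=cfg.seed,
    )
    model = build_unet(unet_cfg)
    t1 = time.time()
    train(model, train_set, val_set, unet_cfg)
    log.info(
        "pipeline: trained %d epochs on %d slices in %.1fs (final val loss %.4g)",
        cfg.epochs, len(train_set), time.time() - t1,
        model.history["val_loss"][-1] if model.history["val_loss"] else float("nan"),
    )

    pairs = []
    for t in test_thighs:
        pred = predict_case(model, t, unet_cfg)
        pred = finalize(pred, cfg.connectivity)
        pairs.append((t.labels, pred, t.original, t.thigh_id, t.repeat_id))
    report = evaluate_testset(pairs)
    log.info("pipeline: total %.1fs, mean Dice %.4f", time.time() - t0, report.summary["mean_dice"])
    return report, model


# ---------------------------------------------------------------------------
# on-disk staged pipeline (CLI `muscleseg run`)
# ---------------------------------------------------------------------------

ALL_STAGES = ("phantom", "preprocess", "train", "segment", "postprocess", "quantify", "evaluate")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> Dict[str, object]:
    """Execute enabled stages in order against on-disk artifacts.

    ``config`` mirrors :class:`ExperimentConfig` under the key
    ``experiment`` plus an optional ``stages`` list; disabled stages are
    skipped and downstream stages consume whatever artifacts already exist
    under ``out_dir``. A resolved config copy, per-stage logs and a run
    summary (with config hash and produced files) are written next to the
    outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(ALL_STAGES))
    cfg = ExperimentConfig(**config.get("experiment", {}))
    pre_cfg = PreprocessConfig(**config.get("preprocess", {}))
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    produced: List[str] = []

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    def run_stage(name, fn):
        if name not in stages:
            log.info("stage %s: skipped (toggle off)", name)
            return
        t0 = time.time()
        try:
            fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        log.info("stage %s: done in %.1fs", name, time.time() - t0)

    # -- phantom ------------------------------------------------------------
    def do_phantom():
        d = stage_dir("phantom")
        rows = []
        for scan in make_cohort(cfg):
            stem = f"{scan.subject_id}_r{scan.repeat_id}"
            msio.write_fat_water(scan.volume, d / f"{stem}_water.nii.gz", d / f"{stem}_fat.nii.gz")
            msio.write_labels(scan.labels, d / f"{stem}_labels.nii.gz")
            sidx = int(scan.subject_id[1:])
            row = {
                "subject_id": scan.subject_id,
                "repeat_id": scan.repeat_id,
                "role": "train" if sidx < cfg.n_train_subjects else "test",
                "water": f"{stem}_water.nii.gz",
                "fat": f"{stem}_fat.nii.gz",
                "labels": f"{stem}_labels.nii.gz",
            }
            for roi, ff in scan.spec.roi_fat_fraction.items():
                row[f"true_ff_roi{roi}"] = ff
            rows.append(row)
        msio.write_manifest(rows, d / "manifest.csv")
        produced.append(str(d / "manifest.csv"))

    # -- preprocess ---------------------------------------------------------
    def do_preprocess():
        src = out / "phantom"
        d = stage_dir("preprocessed")
        manifest = msio.read_manifest(src / "manifest.csv")
        rows = []
        for _, r in manifest.iterrows():
            vol = msio.read_fat_water(src / r["water"], src / r["fat"])
            labels = msio.read_labels(src / r["labels"])
            scan = CohortScan(vol, labels, r["subject_id"], int(r["repeat_id"]), _phantom_spec(cfg))
            for case in preprocess_scan(scan, pre_cfg, r["role"]):
                stem = f"{case.thigh_id}_r{case.repeat_id}"
                msio.write_fat_water(case.masked, d / f"{stem}_water.nii.gz", d / f"{stem}_fat.nii.gz")
                msio.write_fat_water(case.original, d / f"{stem}_origwater.nii.gz", d / f"{stem}_origfat.nii.gz")
                msio.write_labels(case.labels, d / f"{stem}_labels.nii.gz")
                rows.append(
                    {
                        "thigh_id": case.thigh_id,
                        "repeat_id": case.repeat_id,
                        "role": case.role,
                        "side": case.thigh_id.rsplit("_", 1)[1],
                        "water": f"{stem}_water.nii.gz",
                        "fat": f"{stem}_fat.nii.gz",
                        "orig_water": f"{stem}_origwater.nii.gz",
                        "orig_fat": f"{stem}_origfat.nii.gz",
                        "labels": f"{stem}_labels.nii.gz",
                    }
                )
        msio.write_manifest(rows, d / "manifest.csv")
        produced.append(str(d / "manifest.csv"))

    def _load_cases(roles: Sequence[str]) -> List[ThighCase]:
        d = out / "preprocessed"
        manifest = msio.read_manifest(d / "manifest.csv")
        cases = []
        for _, r in manifest.iterrows():
            if r["role"] not in roles:
                continue
            side = r["side"]
            cases.append(
                ThighCase(
                    thigh_id=r["thigh_id"],
                    repeat_id=int(r["repeat_id"]),
                    role=r["role"],
                    masked=msio.read_fat_water(d / r["water"], d / r["fat"], side),
                    original=msio.read_fat_water(d / r["orig_water"], d / r["orig_fat"], side),
                    labels=msio.read_labels(d / r["labels"]),
                )
            )
        return cases

    def _unet_cfg() -> UnetConfig:
        return UnetConfig(
            depth=cfg.depth,
            base_filters=cfg.base_filters,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            lr_schedule=cfg.lr_schedule,
            norm=cfg.norm,
            seed=cfg.seed,
        )

    # -- train --------------------------------------------------------------
    def do_train():
        d = stage_dir("model")
        cases = _load_cases(("train",))
        volumes = [canonical_input(c) for c in cases]
        ids = [f"{c.thigh_id}_r{c.repeat_id}" for c in cases]
        subjects = [c.thigh_id.rsplit("_", 1)[0] for c in cases]
        train_set, val_set = make_slice_dataset(
            volumes, split=1.0 - cfg.val_fraction, seed=cfg.seed, volume_ids=ids,
            groups=subjects,
        )
        model = build_unet(_unet_cfg())
        train(model, train_set, val_set)
        save_model(model, d / "unet")
        produced.append(str(d / "unet.npz"))

    # -- segment ------------------------------------------------------------
    def do_segment():
        d = stage_dir("predictions")
        model = load_model(out / "model" / "unet")
        rows = []
        for c in _load_cases(("test",)):
            pred = predict_case(model, c)
            stem = f"{c.thigh_id}_r{c.repeat_id}"
            msio.write_labels(pred, d / f"{stem}_pred.nii.gz")
            rows.append({"thigh_id": c.thigh_id, "repeat_id": c.repeat_id, "pred": f"{stem}_pred.nii.gz"})
        msio.write_manifest(rows, d / "manifest.csv")

    # -- postprocess --------------------------------------------------------
    def do_postprocess():
        src = out / "predictions"
        d = stage_dir("postprocessed")
        manifest = msio.read_manifest(src / "manifest.csv")
        rows = []
        for _, r in manifest.iterrows():
            pred = msio.read_labels(src / r["pred"])
            final = finalize(pred, cfg.connectivity)
            msio.write_labels(final, d / r["pred"])
            rows.append(dict(r))
        msio.write_manifest(rows, d / "manifest.csv")

    # -- quantify -----------------------------------------------------------
    def do_quantify():
        d = stage_dir("quantify")
        cases = {(c.thigh_id, c.repeat_id): c for c in _load_cases(("test",))}
        manifest = msio.read_manifest(out / "postprocessed" / "manifest.csv")
        tables = []
        for _, r in manifest.iterrows():
            c = cases[(r["thigh_id"], int(r["repeat_id"]))]
            auto = msio.read_labels(out / "postprocessed" / r["pred"])
            tables.append(roi_stats_table(c.original, auto, f"{c.thigh_id}_r{c.repeat_id}"))
        pd.concat(tables, ignore_index=True).to_csv(d / "roi_stats.csv", index=False)
        produced.append(str(d / "roi_stats.csv"))

    # -- evaluate -----------------------------------------------------------
    def do_evaluate():
        d = stage_dir("evaluation")
        cases = {(c.thigh_id, c.repeat_id): c for c in _load_cases(("test",))}
        manifest = msio.read_manifest(out / "postprocessed" / "manifest.csv")
        pairs = []
        for _, r in manifest.iterrows():
            c = cases[(r["thigh_id"], int(r["repeat_id"]))]
            auto = msio.read_labels(out / "postprocessed" / r["pred"])
            pairs.append((c.labels, auto, c.original, c.thigh_id, c.repeat_id))
        report = evaluate_testset(pairs)
        report.per_scan.to_csv(d / "report_per_scan.csv", index=False)
        report.per_thigh.to_csv(d / "report_per_thigh.csv", index=False)
        (d / "summary.json").write_text(json.dumps(report.summary, indent=2, sort_keys=True))
        produced.append(str(d / "summary.json"))

    for name, fn in zip(
        ALL_STAGES,
        (do_phantom, do_preprocess, do_train, do_segment, do_postprocess, do_quantify, do_evaluate),
    ):
        run_stage(name, fn)

    run_summary = {
        "config_hash": _config_hash(config),
        "stages_run": [s for s in ALL_STAGES if s in stages],
        "experiment": asdict(cfg),
        "produced": produced,
    }
    (out / "run_summary.json").write_text(json.dumps(run_summary, indent=2, sort_keys=True))
    return run_summary
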