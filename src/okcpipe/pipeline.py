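"""End-to-end orchestration of the four classification experiments.

Experiment I   — baseline backbone on augmented whole images.
Experiment II  — second backbone on augmented whole images.
Experiment III — same backbone on region-selected (epithelium-only)
                 images, augmented.
Experiment IV  — the models of II and III combined by averaging their
                 confidence scores.

At desk scale all branches train the numpy ``smallcnn``; the vgg16 /
densenet builders describe the full-scale architectures structurally.
A run is a pure function of its configuration and seed: histories,
reports and ROC tables written twice with the same config are
identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import augment as aug
from . import dataset as ds
from . import evaluate as ev
from . import models as md
from . import regionsel as rs
from . import synthdata as sd

logger = logging.getLogger(__name__)

EXPERIMENTS = ("I", "II", "III", "IV")


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable to the run log."""

    experiment: str = "IV"
    data_root: str | None = None  # per-class image folders; None => synthetic
    synthetic_per_class: int = 100
    out_dir: str | None = None
    seed: int = 0
    fractions: tuple[float, float, float] = ds.DEFAULT_FRACTIONS
    augmentation: aug.AugmentationConfig = field(
        default_factory=aug.AugmentationConfig
    )
    # desk-scale smallcnn training recipe: 30 epochs of Adam at 3e-3,
    # batches of 12 (the full-scale recipes live in ModelSpec defaults)
    branch_a: md.ModelSpec = field(
        default_factory=lambda: md.ModelSpec(epochs=30, learning_rate=3e-3)
    )  # whole image
    branch_b: md.ModelSpec = field(
        default_factory=lambda: md.ModelSpec(epochs=30, learning_rate=3e-3)
    )  # region-selected
    model_input: tuple[int, int, int] = (48, 48, 3)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.experiment == "IV" and (self.branch_a is None or self.branch_b is None):
            raise ValueError("experiment IV requires both branch specs")


@dataclass
class BranchResult:
    name: str
    results: md.TrainingResults
    scores: list[md.PredictionScore]
    report: ev.MetricsReport


@dataclass
class ExperimentResult:
    config: PipelineConfig
    plan: ds.SplitPlan
    branches: dict[str, BranchResult]
    ensemble_scores: list[md.PredictionScore] | None = None
    ensemble_report: ev.MetricsReport | None = None

    @property
    def final_report(self) -> ev.MetricsReport:
        if self.ensemble_report is not None:
            return self.ensemble_report
        return next(iter(self.branches.values())).report


def _load_or_generate(config: PipelineConfig) -> list[sd.LabeledImage]:
    if config.data_root is not None:
        images = ds.load_images(config.data_root, target_size=None)
        if not images:
            raise FileNotFoundError(f"no images found under {config.data_root}")
        return images
    return sd.generate_dataset(config.synthetic_per_class, seed=config.seed)


def _train_branch(
    name: str,
    spec: md.ModelSpec,
    images: list[sd.LabeledImage],
    plan: ds.SplitPlan,
    config: PipelineConfig,
    preprocess=None,
) -> BranchResult:
    """Train one branch and score it on the test split.

    ``preprocess`` (e.g. region selection) is applied to every image
    of every split before augmentation — preprocessing, unlike
    augmentation, is part of the input representation and therefore
    applies to held-out data too.
    """
    t0 = time.time()
    if preprocess is not None:
        images = [
            sd.LabeledImage(
                pixels=preprocess(img.pixels),
                label=img.label,
                tile_truth=img.tile_truth,
                source_id=img.source_id,
            )
            for img in images
        ]

    spec = replace(spec, input_shape=config.model_input)
    model = md.build_model(spec)

    val_images = list(
        aug.augment_split(images, plan, config.augmentation, split=ds.VAL)
    )

    def epoch_data(epoch: int):
        stream = aug.augment_split(
            images, plan, config.augmentation, split=ds.TRAIN, epoch=epoch
        )
        x, y, _ = md.images_to_array(list(stream), spec.input_shape)
        return x, y

    xv, yv, _ = md.images_to_array(val_images, spec.input_shape)
    results = model.fit(
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        validation=(xv, yv),
        data_fn=epoch_data,
    )

    test_images = list(
        aug.augment_split(images, plan, config.augmentation, split=ds.TEST)
    )
    scores = md.predict(model, test_images)
    labels = [1 if img.label == sd.OKC else 0 for img in test_images]
    report = ev.evaluate_scores(labels, scores)
    logger.info(
        "branch %s: %d train / %d val / %d test images, %d epochs, "
        "test accuracy %.3f (%.1f s)",
        name,
        len(plan.train_ids),
        len(val_images),
        len(test_images),
        spec.epochs,
        report.accuracy,
        time.time() - t0,
    )
    return BranchResult(name=name, results=results, scores=scores, report=report)


def run_experiment(config: PipelineConfig) -> ExperimentResult:
    """Run one of the four experiments end to end."""
    images = _load_or_generate(config)
    manifest = [(img.source_id, img.label) for img in images]
    plan = ds.make_split(manifest, config.fractions, seed=config.seed)

    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    branches: dict[str, BranchResult] = {}

    def whole_branch() -> BranchResult:
        spec = replace(config.branch_a, seed=int(seeds[0]))
        return _train_branch("whole_image", spec, images, plan, config)

    def region_branch() -> BranchResult:
        spec = replace(config.branch_b, seed=int(seeds[1]))
        return _train_branch(
            "region_selected",
            spec,
            images,
            plan,
            config,
            preprocess=lambda px: rs.select_region(px).output,
        )

    if config.experiment in ("I", "II"):
        branches["whole_image"] = whole_branch()
    elif config.experiment == "III":
        branches["region_selected"] = region_branch()
    else:  # IV
        branches["whole_image"] = whole_branch()
        branches["region_selected"] = region_branch()

    result = ExperimentResult(config=config, plan=plan, branches=branches)

    if config.experiment == "IV":
        a = branches["whole_image"]
        b = branches["region_selected"]
        result.ensemble_scores = ev.ensemble_average(a.scores, b.scores)
        test_imgs = {img.source_id: img for img in images}
        labels = [
            1 if test_imgs[s.id].label == sd.OKC else 0 for s in result.ensemble_scores
        ]
        result.ensemble_report = ev.evaluate_scores(labels, result.ensemble_scores)
        logger.info("ensemble test accuracy %.3f", result.ensemble_report.accuracy)

    if config.out_dir is not None:
        write_artifacts(result, Path(config.out_dir), images)
    return result


def write_artifacts(
    result: ExperimentResult, out: Path, images: list[sd.LabeledImage]
) -> None:
    """Write histories, reports, ROC tables, and a reproducibility log."""
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    for name, branch in result.branches.items():
        hist = branch.results.history_frame()
        hist.to_csv(out / f"history_{name}.csv", index=False)
        branch.report.to_json(out / f"report_{name}.json")
        (out / f"report_{name}.txt").write_text(branch.report.summary() + "\n")
        _write_roc(branch.report, out / f"roc_{name}.csv")

    if result.ensemble_report is not None:
        result.ensemble_report.to_json(out / "report_ensemble.json")
        (out / "report_ensemble.txt").write_text(result.ensemble_report.summary() + "\n")
        _write_roc(result.ensemble_report, out / "roc_ensemble.csv")

    result.plan.to_tsv(out / "split_plan.tsv")

    if "region_selected" in result.branches:
        preview_dir = out / "region_previews"
        preview_dir.mkdir(exist_ok=True)
        for img in images[:4]:
            sel = rs.select_region(img.pixels)
            Image.fromarray(sel.output.astype(np.uint8)).save(
                preview_dir / f"{img.source_id}.png"
            )

    log = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "fractions": list(cfg.fractions),
        "synthetic_per_class": cfg.synthetic_per_class if cfg.data_root is None else None,
        "data_root": cfg.data_root,
        "model_input": list(cfg.model_input),
        "augmentation": vars(cfg.augmentation) | {},
        "branch_a": {
            "architecture": cfg.branch_a.architecture,
            "epochs": cfg.branch_a.epochs,
            "batch_size": cfg.branch_a.batch_size,
            "learning_rate": cfg.branch_a.learning_rate,
        },
        "branch_b": {
            "architecture": cfg.branch_b.architecture,
            "epochs": cfg.branch_b.epochs,
            "batch_size": cfg.branch_b.batch_size,
            "learning_rate": cfg.branch_b.learning_rate,
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


def _write_roc(report: ev.MetricsReport, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in report.roc_points:
            fh.write(f"{fpr},{tpr}\n")
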