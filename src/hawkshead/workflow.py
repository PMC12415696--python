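"""End-to-end experiment orchestration.

``run_experiment`` composes the full pipeline on a synthetic cohort:

    generate -> cap -> patient-level split -> balance -> stain-normalise
    -> train -> predict on the held-out test patients -> evaluate
    -> whole-slide overlay

The stain profile is fitted once on a training tile and re-used for every
set, and the test split is only touched at the final evaluation stage.
Every run writes its resolved configuration next to its artifacts, so a
run is reconstructible from the config copy plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import cohort_prep, evaluation, stainnorm, synthcohort
from .network import (
    HawksheadSpec,
    TileClassifier,
    TileClassifierResults,
    TrainConfig,
    predict,
    preprocess_tiles,
)
from .overlay import build_overlay, render_overlay, write_geojson
from .records import (
    PredictionRecord,
    TileRecord,
    frame_to_predictions,
    predictions_to_frame,
)
from .tiling import tessellate

logger = logging.getLogger("hawkshead")

NORMALISER_CHOICES = ("reinhard", "macenko", "ruifrok", "vahadane", "none")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, with desk-scale defaults."""

    seed: int = 0
    n_patients_per_class: int = 10
    tiles_per_patient: int = 30
    stain_jitter: synthcohort.StainJitter = field(default_factory=synthcohort.StainJitter)
    normaliser: str = "reinhard"
    split_ratios: tuple[float, float, float] = (0.6, 0.3, 0.1)
    balance: bool = True
    spec: HawksheadSpec = field(default_factory=HawksheadSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    output_dir: str = "hawkshead_run"
    overlay_slide_shape: tuple[int, int] = (1536, 1536)

    def __post_init__(self) -> None:
        if self.normaliser not in NORMALISER_CHOICES:
            raise ValueError(f"normaliser must be one of {NORMALISER_CHOICES}")

    def resolved(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["stain_jitter"] = dataclasses.asdict(self.stain_jitter)
        doc["spec"] = dataclasses.asdict(self.spec)
        doc["train"] = dataclasses.asdict(self.train)
        return doc

    @staticmethod
    def verification_scale(seed: int, output_dir: str = "hawkshead_run") -> "ExperimentConfig":
        """The desk-scale study conditions used by the verification suite.

        Six patients per class with 20 tiles each, Reinhard normalisation,
        eight epochs at batch 16 with learning rate 1e-3 — sized so one run
        trains in about two minutes on a single CPU core with the pure-numpy
        engine while leaving the patient-held-out AUROC criterion intact
        (the learning-rate/batch scaling compensates for the ~100x smaller
        optimisation budget of the original full-cohort setting).
        """
        return ExperimentConfig(
            seed=seed,
            n_patients_per_class=6,
            tiles_per_patient=20,
            normaliser="reinhard",
            train=TrainConfig(learning_rate=1e-3, batch_size=16, max_epochs=8, seed=seed),
            output_dir=output_dir,
        )

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return ExperimentConfig.from_dict(doc)

    @staticmethod
    def from_dict(doc: dict) -> "ExperimentConfig":
        kwargs = dict(doc)
        if "stain_jitter" in kwargs:
            j = kwargs["stain_jitter"]
            kwargs["stain_jitter"] = synthcohort.StainJitter(
                vector_rotation_sd=j.get("vector_rotation_sd", 0.05),
                concentration_scale_range=tuple(j.get("concentration_scale_range", (0.85, 1.15))),
                brightness_scale_range=tuple(j.get("brightness_scale_range", (0.9, 1.1))),
            )
        if "spec" in kwargs:
            s = dict(kwargs["spec"])
            for key in ("conv_filters", "dense_widths"):
                if key in s:
                    s[key] = tuple(s[key])
            kwargs["spec"] = HawksheadSpec(**s)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "split_ratios" in kwargs:
            kwargs["split_ratios"] = tuple(kwargs["split_ratios"])
        if "overlay_slide_shape" in kwargs:
            kwargs["overlay_slide_shape"] = tuple(kwargs["overlay_slide_shape"])
        return ExperimentConfig(**kwargs)


@dataclass
class ExperimentResult:
    """Artifacts and headline numbers of one run."""

    config: ExperimentConfig
    fit: TileClassifierResults
    split: cohort_prep.SplitAssignment
    predictions: pd.DataFrame
    report: evaluation.MetricsReport
    artifact_paths: dict[str, Path]

    @property
    def auroc(self) -> Optional[float]:
        return self.report.auroc


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            start = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - start)
            return out

        return wrapped

    return deco


def _render_rows(cohort: synthcohort.SyntheticCohort, rows: pd.DataFrame) -> list[TileRecord]:
    tiles = []
    for row in rows.itertuples():
        patient = cohort.patient(str(row.patient_id))
        tiles.append(cohort.render_tile(patient, int(row.tile_index)))
    return tiles


def _normalise_tiles(
    tiles: list[TileRecord], normalizer: Optional[stainnorm.StainNormalizer]
) -> list[TileRecord]:
    if normalizer is None:
        return tiles
    return [t.with_pixels(normalizer.transform(t.pixels)) for t in tiles]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline; returns headline results plus artifact paths.

    Artifacts written to ``config.output_dir``: resolved_config.yaml,
    split.csv, history.csv, predictions.csv, metrics.csv, overlay.png and
    overlay.geojson, run.log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    try:
        logger.info("run starts: seed=%d normaliser=%s", config.seed, config.normaliser)
        paths["resolved_config"] = out / "resolved_config.yaml"
        paths["resolved_config"].write_text(yaml.safe_dump(config.resolved()))

        cohort = _stage("generate")(synthcohort.generate_cohort)(
            config.n_patients_per_class,
            config.tiles_per_patient,
            jitter=config.stain_jitter,
            seed=config.seed,
        )
        manifest = cohort.manifest()

        manifest = _stage("cap")(cohort_prep.cap_tiles)(manifest, seed=config.seed)
        split = _stage("split")(cohort_prep.split_patients)(
            manifest, ratios=config.split_ratios, seed=config.seed
        )
        manifest = cohort_prep.assign_tiles(manifest, split)
        labels = {p.patient_id: p.label for p in cohort.patients}
        split.to_frame(labels).to_csv(out / "split.csv", index=False)
        paths["split"] = out / "split.csv"

        train_rows = manifest[manifest["set"] == "train"]
        val_rows = manifest[manifest["set"] == "val"]
        test_rows = manifest[manifest["set"] == "test"]
        if config.balance:
            train_rows = _stage("balance")(cohort_prep.balance_classes)(train_rows, seed=config.seed)
            val_rows = cohort_prep.balance_classes(val_rows, seed=config.seed + 1)

        @_stage("render+normalise")
        def materialise():
            train_tiles = _render_rows(cohort, train_rows)
            val_tiles = _render_rows(cohort, val_rows)
            test_tiles = _render_rows(cohort, test_rows)
            normalizer = None
            if config.normaliser != "none":
                target = train_tiles[0].pixels  # shared target: first training tile
                normalizer = stainnorm.get_normalizer(config.normaliser).fit(target)
            return (
                _normalise_tiles(train_tiles, normalizer),
                _normalise_tiles(val_tiles, normalizer),
                _normalise_tiles(test_tiles, normalizer),
                normalizer,
            )

        train_tiles, val_tiles, test_tiles, normalizer = materialise()

        @_stage("train")
        def fit_model() -> TileClassifierResults:
            classifier = TileClassifier(
                train_tiles,
                val_tiles=val_tiles,
                spec=config.spec,
                config=config.train,
            )
            return classifier.fit()

        fit = fit_model()
        fit.history.to_csv(out / "history.csv", index=False)
        paths["history"] = out / "history.csv"

        @_stage("evaluate")
        def evaluate():
            preds = fit.predict(test_tiles)
            frame = predictions_to_frame(preds)
            frame.to_csv(out / "predictions.csv", index=False)
            counts = evaluation.confusion(preds)
            report = evaluation.metrics(counts)
            report = dataclasses.replace(report, auroc=evaluation.auroc(preds))
            rows = [
                {"metric": name, "value": getattr(report, name)}
                for name in ("accuracy", "precision", "sensitivity", "specificity", "f1", "auroc")
            ]
            pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
            return preds, frame, report

        preds, pred_frame, report = evaluate()
        paths["predictions"] = out / "predictions.csv"
        paths["metrics"] = out / "metrics.csv"

        @_stage("overlay")
        def make_overlay():
            test_patient = cohort.patient(sorted(split.patients_in("test"))[0])
            slide, mask = synthcohort.generate_slide(
                cohort, test_patient, roi="full", slide_shape=config.overlay_slide_shape
            )
            slide_tiles = tessellate(
                slide,
                mask,
                slide_id=test_patient.slide_id,
                patient_id=test_patient.patient_id,
                label=test_patient.label,
            )
            slide_tiles = _normalise_tiles(slide_tiles, normalizer)
            slide_preds = predict(fit.model, slide_tiles, input_size=config.spec.input_size)
            omap = build_overlay(slide_preds)
            rgba = render_overlay(omap, slide)
            Image.fromarray(rgba, mode="RGBA").save(out / "overlay.png")
            write_geojson(omap, out / "overlay.geojson")

        make_overlay()
        paths["overlay_png"] = out / "overlay.png"
        paths["overlay_geojson"] = out / "overlay.geojson"

        logger.info(
            "run done: test AUROC=%s accuracy=%s",
            f"{report.auroc:.4f}" if report.auroc is not None else "undefined",
            f"{report.accuracy:.4f}" if report.accuracy is not None else "undefined",
        )
        return ExperimentResult(
            config=config,
            fit=fit,
            split=split,
            predictions=pred_frame,
            report=report,
            artifact_paths=paths,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def compare_models(
    preds_csv_a: Union[str, Path, pd.DataFrame],
    preds_csv_b: Union[str, Path, pd.DataFrame],
    alpha: float = evaluation.ALPHA_DEFAULT,
) -> tuple[evaluation.PairedTestResult, evaluation.PairedTestResult, str]:
    """DeLong + McNemar comparison of two prediction files, with a verdict report."""
    frame_a = preds_csv_a if isinstance(preds_csv_a, pd.DataFrame) else pd.read_csv(preds_csv_a)
    frame_b = preds_csv_b if isinstance(preds_csv_b, pd.DataFrame) else pd.read_csv(preds_csv_b)
    preds_a = frame_to_predictions(frame_a)
    preds_b = frame_to_predictions(frame_b)
    delong = evaluation.delong_test(preds_a, preds_b, alpha=alpha)
    mcnemar = evaluation.mcnemar_test(preds_a, preds_b, alpha=alpha)

    def verdict(r: evaluation.PairedTestResult) -> str:
        return "significant" if r.significant else "not significant"

    report = (
        f"Paired model comparison (n = {len(preds_a)} tiles, alpha = {alpha})\n"
        f"  DeLong AUROC difference: z = {delong.statistic:.4f}, "
        f"p = {delong.p_value:.4g} -> {verdict(delong)}\n"
        f"  McNemar discordant counts: b = {mcnemar.b} (A wrong, B right), "
        f"c = {mcnemar.c} (A right, B wrong)\n"
        f"  McNemar exact p = {mcnemar.p_value:.4g} -> {verdict(mcnemar)}\n"
    )
    return delong, mcnemar, report
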