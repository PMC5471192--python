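"""End-to-end pipeline: discover -> segment -> profile -> classify.

Every output artefact embeds the configuration hash and seed; reruns with a
fixed seed are byte-identical on the feature table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from .features import build_schema, profile_objects
from .io import DEFAULT_PATTERN, discover_images, read_two_channel
from .segment import SegmentationParams, segment_image

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str = "."
    output_dir: str = "out"
    pattern: str = DEFAULT_PATTERN
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    split_fraction: float = 0.5
    cv_folds: int = 10
    seed: int = 0
    classifiers: Sequence[str] = clf.METHODS
    learning_fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.5)
    learning_repeats: int = 2
    make_figures: bool = True
    blind_dir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"] = asdict(self.segmentation)
        d["classifiers"] = list(self.classifiers)
        d["learning_fractions"] = list(self.learning_fractions)
        return d

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = raw.pop("segmentation", None)
        cfg = cls(**raw)
        if seg:
            if "nucleus_diameter_range" in seg:
                seg["nucleus_diameter_range"] = tuple(
                    seg["nucleus_diameter_range"])
            cfg.segmentation = SegmentationParams(**seg)
        return cfg


def build_feature_table(input_dir: str | Path, params: SegmentationParams,
                        pattern: str = DEFAULT_PATTERN) -> pd.DataFrame:
    """Segment and profile every image pair under ``input_dir``.

    The class column carries the filename-encoded label ("blind" for
    unlabeled sets).
    """
    schema = build_schema()
    records = discover_images(input_dir, pattern)
    frames = []
    n_objects = 0
    for rec in records:
        image = read_two_channel(rec)
        objects = segment_image(image, params, image_id=rec.image_id)
        n_objects += len(objects)
        frames.append(profile_objects(
            objects, image, schema, class_label=rec.label,
            image_id=rec.image_id))
    frames = [f for f in frames if len(f)] or frames[:1]
    table = pd.concat(frames, ignore_index=True)
    log.info("profiled %d cells from %d images (%d segmented objects)",
             len(table), len(records), n_objects)
    return table


def _write_figures(reports: dict[str, clf.EvaluationReport],
                   out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for method, rep in reports.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        cm = rep.cv.confusion_percent
        im = ax.imshow(cm.to_numpy(), cmap="viridis", vmin=0, vmax=100)
        ax.set_xticks(range(len(cm)), cm.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(cm)), cm.index)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{method}: CV confusion (%)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(out_dir / f"confusion_{method}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for method, rep in reports.items():
        for cls, r in rep.roc.items():
            if method == "random_forest":
                ax.plot(r["fpr"], r["tpr"], label=f"{cls} (AUC {r['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "--", color="gray", label="random guess")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title("random forest: one-vs-rest ROC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "roc_random_forest.png", dpi=120)
    plt.close(fig)

    if any(rep.learning for rep in reports.values()):
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, rep in reports.items():
            if rep.learning:
                fr = sorted(rep.learning)
                ax.plot(fr, [rep.learning[f] for f in fr], marker="o",
                        label=method)
        ax.set_xlabel("training fraction")
        ax.set_ylabel("held-out accuracy (%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / "learning_curves.png", dpi=120)
        plt.close(fig)


def train_eval(table: pd.DataFrame, config: RunConfig,
               ) -> dict[str, clf.EvaluationReport]:
    """Run the evaluation protocol for every configured classifier."""
    reports: dict[str, clf.EvaluationReport] = {}
    for method in config.classifiers:
        spec = clf.ClassifierSpec(method=method, rng_seed=config.seed)
        log.info("evaluating %s", method)
        reports[method] = clf.evaluate_classifier(
            spec, table, split_fraction=config.split_fraction,
            cv_folds=config.cv_folds, seed=config.seed,
            learning_fractions=config.learning_fractions,
            learning_repeats=config.learning_repeats)
    return reports


def run_pipeline(config: RunConfig) -> dict[str, clf.EvaluationReport]:
    """Execute the full pipeline and write all artefacts to disk."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = build_schema()

    table = build_feature_table(config.input_dir, config.segmentation,
                                config.pattern)
    table.to_csv(out_dir / "feature_table.csv", index=False)
    schema.to_csv(out_dir / "feature_schema.csv")

    reports = train_eval(table, config)
    report_json = {m: r.to_dict() for m, r in reports.items()}
    provenance = {"config": config.to_dict(), "config_hash": config.hash,
                  "seed": config.seed, "schema_hash": schema.hash,
                  "n_cells": len(table)}
    (out_dir / "report.json").write_text(
        json.dumps({"provenance": provenance, "reports": report_json},
                   indent=2))
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    for method, rep in reports.items():
        rep.cv.confusion_percent.to_csv(out_dir / f"confusion_cv_{method}.csv")
        rep.holdout_confusion.to_csv(out_dir / f"confusion_holdout_{method}.csv")
        for cls, r in rep.roc.items():
            pd.DataFrame({"fpr": r["fpr"], "tpr": r["tpr"]}).to_csv(
                out_dir / f"roc_{method}_{cls}.csv", index=False)

    if config.make_figures:
        _write_figures(reports, out_dir)

    if config.blind_dir:
        blind = build_feature_table(config.blind_dir, config.segmentation,
                                    config.pattern)
        spec = clf.ClassifierSpec(method="random_forest", rng_seed=config.seed)
        model = clf.train_classifier(spec, table)
        preds = clf.predict_blind(model, blind)
        out = pd.concat([blind[["image_id", "object_id"]], preds], axis=1)
        out.to_csv(out_dir / "blind_predictions.csv", index=False)

    return reports
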