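"""End-to-end orchestration: filter -> segment -> features -> select -> learn.

The stages mirror how the tool is used on a wound corpus: photographs are
median-filtered, the wound bed is segmented on the saturation plane,
descriptors are extracted for the labeled tissue regions, screened by
ANOVA F, and the Bayes and SVM classifiers are trained and scored.  Every
run writes a manifest (config echo, package versions, seed) sufficient to
reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import __version__
from .classify import (BayesModel, KernelSpec, SvmModel, fit_bayes, fit_svm,
                       predict_bayes_table, predict_svm_table)
from .evaluation import EvaluationReport, evaluate
from .features import TissueRegion, build_feature_table, write_features
from .io import BinaryMask, RgbImage, median_filter_rgb
from .color import s_channel_8bit
from .segmentation import SegmentationResult, crop_wound, dice, select_threshold
from .selection import DEFAULT_F_THRESHOLD, SelectionResult, anova_f

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline; round-trips through YAML."""

    median_window: int = 5
    selem_radius: int = 0          # 0 = auto-scale with image size
    quantization_bins: int = 256
    f_threshold: float = DEFAULT_F_THRESHOLD
    kernel: str = "poly3"
    svm_c: float = 1.0
    svm_gamma: float = 0.0         # 0 = 1/(n_features * var), the 'scale' rule
    svm_coef0: float = 1.0
    protocol: str = "split"        # "split" (stratified 70/30) or "resubstitution"
    test_fraction: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.median_window % 2 == 0 or self.median_window < 3:
            raise ValueError("median_window must be odd and >= 3")
        if self.quantization_bins != 256:
            raise ValueError("only 256-bin quantization is supported")
        if self.protocol not in ("split", "resubstitution"):
            raise ValueError("protocol must be 'split' or 'resubstitution'")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(
            name=self.kernel,
            C=self.svm_c,
            gamma=self.svm_gamma if self.svm_gamma > 0 else "scale",
            coef0=self.svm_coef0,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    segmentations: dict[str, SegmentationResult]
    dice_scores: dict[str, float]
    features: pd.DataFrame
    selection: SelectionResult
    bayes_model: BayesModel
    svm_model: SvmModel
    bayes_report: EvaluationReport
    svm_report: EvaluationReport
    protocol_used: str


def _split(table: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.protocol == "resubstitution":
        return table, table
    train, test = train_test_split(
        table,
        test_size=config.test_fraction,
        random_state=config.seed,
        stratify=table["label"],
    )
    return train, test


def run_pipeline(
    images: dict[str, RgbImage],
    regions: list[TissueRegion],
    config: PipelineConfig | None = None,
    wound_truth: dict[str, BinaryMask] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on labeled inputs and return models plus reports.

    `wound_truth` (ground-truth wound masks keyed by image id) enables the
    per-image Dice record; segmentation still runs without it.
    """
    config = config or PipelineConfig()
    if not images or not regions:
        raise ValueError("pipeline needs at least one image and one labeled region")
    if any(r.label is None for r in regions):
        raise ValueError("training requires labeled regions")

    stage = "preprocess"
    try:
        filtered = {
            iid: median_filter_rgb(img, config.median_window)
            for iid, img in images.items()
        }

        stage = "segment"
        segmentations: dict[str, SegmentationResult] = {}
        dice_scores: dict[str, float] = {}
        radius = config.selem_radius if config.selem_radius > 0 else None
        for iid, img in filtered.items():
            s8 = s_channel_8bit(img)
            seg = select_threshold(s8, selem_radius=radius)
            crop_wound(img, seg.refined_mask)  # validates a non-empty wound bed
            segmentations[iid] = seg
            if wound_truth and iid in wound_truth:
                dice_scores[iid] = dice(seg.refined_mask, wound_truth[iid])
            log.info("segmented %s: t=%d D=%.3f", iid, seg.threshold, seg.divergence)

        stage = "features"
        table = build_feature_table(filtered, regions)

        stage = "select"
        train_table, test_table = _split(table, config)
        selection = anova_f(train_table, threshold=config.f_threshold)
        log.info("retained %d/675 features (F > %g)", len(selection.retained), config.f_threshold)

        stage = "train"
        bayes_model = fit_bayes(train_table, selection)
        svm_model = fit_svm(train_table, selection, config.kernel_spec())

        stage = "evaluate"
        truth = test_table["label"].to_numpy()
        bayes_report = evaluate(truth, predict_bayes_table(bayes_model, test_table))
        svm_report = evaluate(truth, predict_svm_table(svm_model, test_table))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        config=config,
        segmentations=segmentations,
        dice_scores=dice_scores,
        features=table,
        selection=selection,
        bayes_model=bayes_model,
        svm_model=svm_model,
        bayes_report=bayes_report,
        svm_report=svm_report,
        protocol_used=config.protocol,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def report_dict(result: PipelineResult) -> dict:
    return {
        "protocol": result.protocol_used,
        "n_regions": int(len(result.features)),
        "n_retained_features": len(result.selection.retained),
        "segmentation": {
            iid: {
                "threshold": seg.threshold,
                "divergence": seg.divergence,
                "mask_area": seg.refined_mask.area,
                **({"dice": result.dice_scores[iid]} if iid in result.dice_scores else {}),
            }
            for iid, seg in result.segmentations.items()
        },
        "bayes": result.bayes_report.to_dict(),
        "svm": result.svm_report.to_dict(),
    }


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_features(result.features, out / "features.csv")
    result.selection.write_report(out / "selection.csv")
    result.bayes_model.to_json(out / "bayes_model.json")
    result.svm_model.to_json(out / "svm_model.json")
    (out / "report.json").write_text(json.dumps(report_dict(result), indent=1))
    manifest = {
        "woundbed_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": result.config.seed,
        "config": dataclasses.asdict(result.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
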