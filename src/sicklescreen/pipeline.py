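"""End-to-end orchestration: slides in, diagnoses and reports out.

Two inference routes exist for the decision layer:

* **network mode** — degraded FOV -> enhancement U-net -> segmentation
  U-net -> class probabilities;
* **ground-truth-probability mode** — ideal probability maps derived
  from the generator's label masks, which isolates the counting and
  thresholding rules from network training quality.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import counting
from .counting import SlideDiagnosis, CountResult
from .evaluation import McConfig, SlideCounts, SsimParams
from .nn import TrainConfig, UNetConfig, predict, softmax_probs
from .synthetic import (
    DegradationSpec,
    SlideSpec,
    ideal_probmap,
    render_clean_smear,
)


@dataclass
class SlideRecord:
    """Per-slide result: counts, percentage, call and truth."""

    slide_id: str
    counts: CountResult
    diagnosis: SlideDiagnosis
    positive_truth: bool

    @property
    def correct(self) -> bool:
        return self.diagnosis.positive == self.positive_truth

    def to_counts(self) -> SlideCounts:
        return SlideCounts(self.counts.n_total_cells, self.counts.n_sickle,
                           self.positive_truth)


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline in one auditable place.

    Defaults are the published operating point: cell probability 0.8,
    component size 100 px, sickle probability 0.15, slide threshold
    0.5%, five FOVs per slide.
    """

    slide: SlideSpec = field(default_factory=SlideSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train_enhance: TrainConfig = field(
        default_factory=lambda: TrainConfig(task="enhance"))
    train_segment: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            task="segment", learning_rate=1e-5, batch_size=20,
            iterations=80_000))
    mc: McConfig = field(default_factory=McConfig)
    ssim: SsimParams = field(default_factory=SsimParams)
    cell_prob_threshold: float = counting.CELL_PROB_THRESHOLD
    min_component_pixels: int = counting.MIN_COMPONENT_PIXELS
    sickle_prob_threshold: float = counting.SICKLE_PROB_THRESHOLD
    slide_pct_threshold: float = counting.SLIDE_PCT_THRESHOLD

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        try:
            is_file = isinstance(source, (str, Path)) and Path(source).exists()
        except OSError:  # e.g. a long YAML string is not a valid path
            is_file = False
        data = yaml.safe_load(Path(source).read_text() if is_file else source)
        def _tuples(d):
            return {k: tuple(v) if isinstance(v, list) else v
                    for k, v in d.items()}
        return cls(
            slide=SlideSpec(**data["slide"]),
            degradation=DegradationSpec(**_tuples(data["degradation"])),
            unet=UNetConfig(**data["unet"]),
            train_enhance=TrainConfig(**_tuples(data["train_enhance"])),
            train_segment=TrainConfig(**_tuples(data["train_segment"])),
            mc=McConfig(**_tuples(data["mc"])),
            ssim=SsimParams(**data["ssim"]),
            cell_prob_threshold=data["cell_prob_threshold"],
            min_component_pixels=data["min_component_pixels"],
            sickle_prob_threshold=data["sickle_prob_threshold"],
            slide_pct_threshold=data["slide_pct_threshold"],
        )


# ---------------------------------------------------------------------------
# inference routes

def probmaps_ground_truth(spec: SlideSpec) -> list[np.ndarray]:
    """Ideal class-probability maps from the generator's label masks."""
    return [ideal_probmap(render_clean_smear(spec, fov_id)[1])
            for fov_id in range(spec.n_fov)]


def probmap_from_networks(degraded: np.ndarray, enhance_net, segment_net):
    """Smartphone image -> enhancement -> segmentation -> probabilities."""
    enhanced = np.clip(predict(enhance_net, degraded), 0.0, 1.0)
    logits = predict(segment_net, enhanced)
    return softmax_probs(logits)


def diagnose_slide(probmaps: Sequence[np.ndarray], slide_id: str,
                   positive_truth: bool,
                   cfg: PipelineConfig | None = None) -> SlideRecord:
    """Count cells over the slide's FOVs and apply the percentage rule."""
    cfg = cfg or PipelineConfig()
    per_fov = []
    for p in probmaps:
        mask = counting.cell_pixel_mask(p, cfg.cell_prob_threshold)
        n_total = counting.count_cells(mask, cfg.min_component_pixels)
        n_sickle = counting.count_sickle(
            p, cfg.min_component_pixels, cfg.sickle_prob_threshold)
        per_fov.append((n_total, n_sickle))
    counts = CountResult(
        n_total_cells=sum(t for t, _ in per_fov),
        n_sickle=sum(s for _, s in per_fov),
        per_fov=tuple(per_fov))
    pct = counting.sickle_percentage(counts)
    diag = counting.classify_slide(pct, cfg.slide_pct_threshold)
    return SlideRecord(slide_id, counts, diag, positive_truth)


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic screening cohort: slides at two true prevalence levels."""

    n_negative: int = 20
    n_positive: int = 20
    negative_prevalence: float = 0.0
    positive_prevalence: float = 0.02
    # ~190 cells per FOV, ~960 per slide: at 2% prevalence the expected
    # sickle count (~19) sits far above the >0.5% rule's ~5-cell bar, so
    # a positive slide essentially cannot fall below threshold by chance
    fov_px: int = 384
    n_fov: int = 5
    cell_density: float = 5000.0
    seed: int = 0


def generate_cohort_records(cohort: CohortSpec,
                            cfg: PipelineConfig | None = None
                            ) -> list[SlideRecord]:
    """Ground-truth-probability diagnoses for a synthetic cohort."""
    cfg = cfg or PipelineConfig()
    records = []
    for i in range(cohort.n_negative + cohort.n_positive):
        positive = i >= cohort.n_negative
        prevalence = (cohort.positive_prevalence if positive
                      else cohort.negative_prevalence)
        spec = SlideSpec(
            n_fov=cohort.n_fov, fov_px=cohort.fov_px,
            cell_density=cohort.cell_density, sickle_fraction=prevalence,
            seed=cohort.seed * 100_003 + i)
        probmaps = probmaps_ground_truth(spec)
        records.append(diagnose_slide(
            probmaps, slide_id=f"slide{i:03d}", positive_truth=positive,
            cfg=cfg))
    return records


def cohort_report(records: Sequence[SlideRecord]) -> dict:
    """Confusion, accuracy and ROC/AUC for a diagnosed cohort."""
    calls = [r.diagnosis.positive for r in records]
    truths = [r.positive_truth for r in records]
    conf = counting.confusion_and_accuracy(calls, truths)
    report = {
        "n_slides": len(records),
        "tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn,
        "accuracy_pct": conf.accuracy_pct,
    }
    pcts = [r.diagnosis.sickle_pct for r in records]
    if any(truths) and not all(truths):
        fpr, tpr, thr, auc_val = counting.roc_curve(pcts, truths)
        report["auc"] = auc_val
        report["roc"] = {"fpr": list(map(float, fpr)),
                         "tpr": list(map(float, tpr)),
                         "thresholds": list(map(float, thr))}
    else:
        report["auc"] = None
        report["roc_skipped"] = "single-class cohort"
    return report


def records_to_frame(records: Sequence[SlideRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "slide_id": [r.slide_id for r in records],
        "n_total": [r.counts.n_total_cells for r in records],
        "n_sickle": [r.counts.n_sickle for r in records],
        "pct": [r.diagnosis.sickle_pct for r in records],
        "call": [r.diagnosis.positive for r in records],
        "truth": [r.positive_truth for r in records],
    })


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
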