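"""Cell counting and slide-level diagnosis from class-probability maps.

The decision layer is deliberately simple and threshold-based:

* a pixel belongs to a red blood cell when its normal + sickle
  probability exceeds 0.8 (strict);
* an 8-connected component counts as a cell when it holds more than
  100 such pixels (strict);
* a component counts as a sickle cell when more than 100 of its pixels
  exceed a sickle probability of 0.15 — a deliberately low bar, because
  the segmentation network sees far more healthy than sickle cells;
* a slide is called positive when sickle cells exceed 0.5% (strict) of
  all counted cells pooled over its five fields of view.

All four thresholds are exclusive boundaries ("above", "more than"):
exact equality never counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)

CELL_PROB_THRESHOLD = 0.8
MIN_COMPONENT_PIXELS = 100
SICKLE_PROB_THRESHOLD = 0.15
SLIDE_PCT_THRESHOLD = 0.5


@dataclass(frozen=True)
class CountResult:
    """Total and sickle component counts, with the per-FOV breakdown."""

    n_total_cells: int
    n_sickle: int
    per_fov: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not 0 <= self.n_sickle:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SlideDiagnosis:
    sickle_pct: float
    positive: bool
    threshold_used: float = SLIDE_PCT_THRESHOLD


def _validate_probmap(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 3 or p.shape[-1] != 3:
        raise ValueError("probability map must be H x W x 3")
    if p.min() < -1e-9 or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5):
        raise ValueError("per-pixel class probabilities must sum to 1")
    return p


def cell_pixel_mask(p: np.ndarray,
                    threshold: float = CELL_PROB_THRESHOLD) -> np.ndarray:
    """Pixels whose normal + sickle probability is strictly above threshold."""
    p = _validate_probmap(p)
    return (p[..., 1] + p[..., 2]) > threshold


def count_cells(mask: np.ndarray,
                min_pixels: int = MIN_COMPONENT_PIXELS) -> int:
    """8-connected components with strictly more than ``min_pixels`` pixels."""
    mask = np.asarray(mask).astype(bool)
    labels, n = ndi.label(mask, structure=EIGHT_CONNECTED)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes > min_pixels).sum())


def count_sickle(p: np.ndarray,
                 min_pixels: int = MIN_COMPONENT_PIXELS,
                 p_sickle_thr: float = SICKLE_PROB_THRESHOLD,
                 require_cell_mask: bool = False,
                 cell_threshold: float = CELL_PROB_THRESHOLD) -> int:
    """Components of high-sickle-probability pixels counted as sickle cells.

    By default the sickle count is independent of the 0.8 cell rule;
    ``require_cell_mask=True`` additionally intersects with it.
    """
    p = _validate_probmap(p)
    m = p[..., 2] > p_sickle_thr
    if require_cell_mask:
        m &= cell_pixel_mask(p, cell_threshold)
    return count_cells(m, min_pixels)


def count_fov(p: np.ndarray, **kwargs) -> tuple[int, int]:
    """(total cells, sickle cells) for one field of view."""
    n_total = count_cells(cell_pixel_mask(p), kwargs.get("min_pixels",
                                                         MIN_COMPONENT_PIXELS))
    n_sickle = count_sickle(p, **kwargs)
    return n_total, n_sickle


def sickle_percentage(fovs: Sequence[np.ndarray] | CountResult) -> float:
    """Percent sickle cells pooled over all fields of view of a slide."""
    if isinstance(fovs, CountResult):
        total, sickle = fovs.n_total_cells, fovs.n_sickle
    else:
        counts = [count_fov(p) for p in fovs]
        total = sum(t for t, _ in counts)
        sickle = sum(s for _, s in counts)
    if total == 0:
        raise ValueError("no cells counted; sickle percentage undefined")
    return 100.0 * sickle / total


def count_slide(fovs: Sequence[np.ndarray], **kwargs) -> CountResult:
    per_fov = tuple(count_fov(p, **kwargs) for p in fovs)
    return CountResult(
        n_total_cells=sum(t for t, _ in per_fov),
        n_sickle=sum(s for _, s in per_fov),
        per_fov=per_fov,
    )


def classify_slide(pct: float,
                   threshold: float = SLIDE_PCT_THRESHOLD) -> SlideDiagnosis:
    """Positive iff the sickle percentage strictly exceeds the threshold."""
    if pct < 0:
        raise ValueError("percentage must be >= 0")
    return SlideDiagnosis(sickle_pct=float(pct), positive=pct > threshold,
                          threshold_used=threshold)


@dataclass(frozen=True)
class ConfusionResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy_pct(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / n


def confusion_and_accuracy(diagnoses: Sequence[bool],
                           truths: Sequence[bool]) -> ConfusionResult:
    """Confusion counts and accuracy (%) of slide calls against truth."""
    if len(diagnoses) != len(truths):
        raise ValueError("diagnoses and truths must have equal length")
    d = np.asarray(diagnoses)
    t = np.asarray(truths)
    if d.dtype != bool or t.dtype != bool:
        if not (set(np.unique(d)) <= {0, 1} and set(np.unique(t)) <= {0, 1}):
            raise ValueError("labels must be boolean positive/negative")
        d = d.astype(bool)
        t = t.astype(bool)
    return ConfusionResult(
        tp=int((d & t).sum()), fp=int((d & ~t).sum()),
        tn=int((~d & ~t).sum()), fn=int((~d & t).sum()),
    )


def roc_curve(pcts: Sequence[float], truths: Sequence[bool]):
    """ROC over slide-level sickle-percentage thresholds, with trapezoid AUC.

    Returns (fpr, tpr, thresholds, auc).
    """
    t = np.asarray(truths, dtype=bool)
    s = np.asarray(pcts, dtype=float)
    if t.all() or not t.any():
        raise ValueError("ROC needs both positive and negative slides")
    fpr, tpr, thr = _sk_roc_curve(t, s)
    return fpr, tpr, thr, float(_sk_auc(fpr, tpr))
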