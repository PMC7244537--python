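"""Enhancement quality metrics and the accuracy-vs-cell-count simulation.

SSIM is computed as a single global statistic on the luminance (Y)
channel only: the chroma channels differ between microscope modalities
for reasons unrelated to image quality (staining variability, the
smartphone's blue background), so only brightness structure is compared.

The Monte Carlo analysis asks how diagnostic accuracy degrades when
fewer red blood cells are inspected: cells are removed uniformly at
random from each slide's pooled count (a hypergeometric draw of the
surviving sickle cells), the slide is re-classified at the 0.5% rule,
and accuracy/AUC are averaged over many replicates.  Because the cells
are roughly monodisperse, random cell removal stands in for shrinking
the inspected smear area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# ITU-R BT.601 luma coefficients
_Y_WEIGHTS = (0.299, 0.587, 0.114)


def rgb_to_y(img: np.ndarray) -> np.ndarray:
    """Luminance (Y of YCbCr, BT.601 weights) of a unit-range RGB image."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    r, g, b = _Y_WEIGHTS
    return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]


@dataclass(frozen=True)
class SsimParams:
    """Stabilizers for the SSIM ratio; defaults are the conventional
    (0.01 L)^2 and (0.03 L)^2 for dynamic range L."""

    dynamic_range: float = 1.0
    c1: float | None = None
    c2: float | None = None

    def resolved(self) -> tuple[float, float]:
        c1 = (0.01 * self.dynamic_range) ** 2 if self.c1 is None else self.c1
        c2 = (0.03 * self.dynamic_range) ** 2 if self.c2 is None else self.c2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("c1 and c2 must be positive")
        return c1, c2


def ssim_global(x: np.ndarray, z: np.ndarray,
                params: SsimParams | None = None) -> float:
    """Single-window SSIM between two same-shape luminance grids.

    Uses whole-image means, variances and covariance (population
    normalization); identical inputs score exactly 1.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("images must have the same shape")
    c1, c2 = (params or SsimParams()).resolved()
    mx, mz = x.mean(), z.mean()
    vx, vz = x.var(), z.var()
    cov = ((x - mx) * (z - mz)).mean()
    return float(((2 * mx * mz + c1) * (2 * cov + c2))
                 / ((mx**2 + mz**2 + c1) * (vx + vz + c2)))


def ssim_y(x_rgb: np.ndarray, z_rgb: np.ndarray,
           params: SsimParams | None = None) -> float:
    """SSIM of the Y channels of two RGB images."""
    return ssim_global(rgb_to_y(x_rgb), rgb_to_y(z_rgb), params)


def ssim_report(inputs: Sequence[np.ndarray], outputs: Sequence[np.ndarray],
                truths: Sequence[np.ndarray],
                params: SsimParams | None = None) -> dict:
    """Per-arm mean +- s.d. of Y-channel SSIM against the ground truth.

    Arms: 'input' (degraded vs truth) and 'output' (restored vs truth).
    """
    if not (len(inputs) == len(outputs) == len(truths)):
        raise ValueError("inputs, outputs and truths must be aligned")
    arms = {}
    for name, imgs in (("input", inputs), ("output", outputs)):
        vals = np.array([ssim_y(im, tr, params) for im, tr in zip(imgs, truths)])
        arms[name] = (float(vals.mean()),
                      float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return arms


# ---------------------------------------------------------------------------
# Monte Carlo accuracy vs inspected cell count

@dataclass(frozen=True)
class SlideCounts:
    """Pooled per-slide counts used by the decision layer."""

    n_total: int
    n_sickle: int
    positive_truth: bool

    def __post_init__(self):
        if not 0 <= self.n_sickle <= self.n_total:
            raise ValueError("need 0 <= n_sickle <= n_total")


@dataclass(frozen=True)
class McConfig:
    n_reps: int = 1000
    keep_fractions: tuple[float, ...] = (0.02, 0.05, 0.1, 0.25, 0.5, 1.0)
    threshold_pct: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(not 0 < f <= 1 for f in self.keep_fractions):
            raise ValueError("keep fractions must lie in (0, 1]")


@dataclass
class McCurve:
    keep_fractions: np.ndarray
    mean_cells: np.ndarray  # mean kept cells per slide, by level
    accuracy_mean: np.ndarray
    accuracy_sd: np.ndarray
    auc_mean: np.ndarray
    auc_sd: np.ndarray


def _auc_from_scores(scores: np.ndarray, truths: np.ndarray) -> float:
    # Mann-Whitney formulation: P(score_pos > score_neg) + 0.5 ties
    pos = scores[truths]
    neg = scores[~truths]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def subsample_counts(totals: np.ndarray, sickles: np.ndarray,
                     keep_fraction: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One Monte Carlo draw: kept cells and surviving sickle cells per slide.

    Each slide keeps ``max(1, round(f * n_total))`` cells; the surviving
    sickle count is an exact hypergeometric draw (so its expectation is
    ``kept * n_sickle / n_total`` and the subsampled percentage is an
    unbiased estimator of the full percentage).  ``f >= 1`` reproduces
    the full counts without consuming randomness.
    """
    totals = np.asarray(totals)
    sickles = np.asarray(sickles)
    kept = np.minimum(np.maximum(1, np.round(keep_fraction * totals)
                                 .astype(int)), totals)
    if keep_fraction >= 1.0:
        return kept, sickles.copy()
    return kept, rng.hypergeometric(sickles, totals - sickles, kept)


def mc_subsample_cells(slides: Sequence[SlideCounts], cfg: McConfig) -> McCurve:
    """Accuracy/AUC as the inspected cell count shrinks.

    Per replicate and keep level, each slide keeps
    ``round(f * n_total)`` cells; the surviving sickle count is a
    hypergeometric draw, the slide is re-classified at
    ``cfg.threshold_pct`` and cohort accuracy and AUC recorded.  At
    ``f = 1`` every replicate reproduces the full-count result exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    truths = np.array([s.positive_truth for s in slides])
    totals = np.array([s.n_total for s in slides])
    sickles = np.array([s.n_sickle for s in slides])
    if totals.min() < 1:
        raise ValueError("every slide needs at least one counted cell")

    n_levels = len(cfg.keep_fractions)
    acc = np.empty((n_levels, cfg.n_reps))
    auc = np.empty((n_levels, cfg.n_reps))
    mean_cells = np.empty(n_levels)
    for li, f in enumerate(cfg.keep_fractions):
        kept = np.minimum(np.maximum(1, np.round(f * totals).astype(int)),
                          totals)
        mean_cells[li] = kept.mean()
        for rep in range(cfg.n_reps):
            kept, ks = subsample_counts(totals, sickles, f, rng)
            pct = 100.0 * ks / kept
            calls = pct > cfg.threshold_pct
            acc[li, rep] = (calls == truths).mean()
            auc[li, rep] = _auc_from_scores(pct, truths)
    return McCurve(
        keep_fractions=np.asarray(cfg.keep_fractions, dtype=float),
        mean_cells=mean_cells,
        accuracy_mean=acc.mean(axis=1), accuracy_sd=acc.std(axis=1, ddof=0),
        auc_mean=auc.mean(axis=1), auc_sd=auc.std(axis=1, ddof=0),
    )


def accuracy_vs_area_table(curve: McCurve, cells_per_mm2: float) -> pd.DataFrame:
    """Tabulate the Monte Carlo curves against implied smear area."""
    if cells_per_mm2 <= 0:
        raise ValueError("cells_per_mm2 must be positive")
    return pd.DataFrame({
        "keep_fraction": curve.keep_fractions,
        "mean_cells": curve.mean_cells,
        "area_mm2": curve.mean_cells / cells_per_mm2,
        "accuracy_mean": curve.accuracy_mean,
        "accuracy_sd": curve.accuracy_sd,
        "auc_mean": curve.auc_mean,
        "auc_sd": curve.auc_sd,
    })
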