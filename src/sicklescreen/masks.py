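"""Training-mask construction from clean images and sickle point labels.

Expert annotation marks only a point per sickle cell; the pixel-level
three-class ground truth is built by (1) thresholding the clean image by
color/intensity to find all cells, (2) filling cell-center holes (the
pale biconcave center can match the background), (3) eroding four pixels
to drop noisy edges, and (4) assigning the component under each
annotated point to the sickle class, every other cell component to the
normal class, and everything else — including white blood cells and
platelets — to background.

Connectivity: 8-connected foreground, 4-connected background holes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .counting import EIGHT_CONNECTED
from .synthetic import BACKGROUND, NORMAL, SICKLE

CROSS = ndi.generate_binary_structure(2, 1)  # 3x3 cross element


@dataclass(frozen=True)
class SickleAnnotation:
    """Point annotations of sickle cells within one field of view."""

    fov_id: int
    points: tuple[tuple[float, float], ...]  # (row, col)


@dataclass(frozen=True)
class MaskThresholds:
    """Per-channel color/intensity box defining cell foreground.

    Chosen per slide in the original workflow; the defaults fit the
    synthetic staining palette (red cells have depressed green relative
    to the pale background, while leukocyte purple is excluded by the
    red-channel floor).
    """

    low: tuple[float, float, float] = (0.50, 0.0, 0.0)
    high: tuple[float, float, float] = (0.97, 0.88, 1.0)

    def __post_init__(self):
        if any(lo >= hi for lo, hi in zip(self.low, self.high)):
            raise ValueError("each low threshold must be below its high")


def suggest_thresholds(image: np.ndarray) -> MaskThresholds:
    """Otsu-style starting point for the per-slide manual choice.

    Cells are darker than the background in the green channel; the
    suggested box keeps everything below the green Otsu split.
    """
    g = np.asarray(image, dtype=float)[..., 1]
    return MaskThresholds(low=(0.0, 0.0, 0.0),
                          high=(1.0, float(threshold_otsu(g)), 1.0))


def threshold_cells(clean: np.ndarray, t: MaskThresholds) -> np.ndarray:
    """Binary foreground: pixels inside the color/intensity box."""
    img = np.asarray(clean, dtype=float)
    lo = np.asarray(t.low)
    hi = np.asarray(t.high)
    mask = np.all((img >= lo) & (img <= hi), axis=-1)
    frac = mask.mean()
    if frac > 0.9 or (frac < 0.001 and mask.size > 0):
        warnings.warn(
            f"thresholds select {100 * frac:.2f}% of pixels; "
            "likely miscalibrated for this slide", RuntimeWarning)
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the border."""
    return ndi.binary_fill_holes(np.asarray(mask).astype(bool),
                                 structure=CROSS)


def erode(mask: np.ndarray, n_px: int = 4) -> np.ndarray:
    """Erode by ``n_px`` iterations of the unit cross element."""
    mask = np.asarray(mask).astype(bool)
    if n_px == 0:
        return mask.copy()
    return ndi.binary_erosion(mask, structure=CROSS, iterations=n_px)


def assign_classes(cell_mask: np.ndarray,
                   annotations: SickleAnnotation | Sequence[tuple[float, float]],
                   wbc_regions: np.ndarray | None = None,
                   snap_radius: float = 10.0,
                   on_background: str = "snap") -> np.ndarray:
    """Three-class label mask from foreground components and point labels.

    The component under each annotated point becomes sickle, all other
    foreground becomes normal; ``wbc_regions`` (a boolean mask of
    leukocytes/platelets) is forced to background.  A point that lands
    on background is snapped to the nearest component within
    ``snap_radius`` px (``on_background='snap'``) or dropped
    (``'drop'``), with a warning either way.  Two points on one
    component count once.
    """
    mask = np.asarray(cell_mask).astype(bool)
    if wbc_regions is not None:
        mask = mask & ~np.asarray(wbc_regions).astype(bool)
    labels, n = ndi.label(mask, structure=EIGHT_CONNECTED)
    out = np.where(mask, NORMAL, BACKGROUND).astype(np.uint8)

    points = (annotations.points if isinstance(annotations, SickleAnnotation)
              else tuple(annotations))
    sickle_ids: set[int] = set()
    for (r, c) in points:
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]):
            raise ValueError(f"annotation ({r}, {c}) outside image bounds")
        lab = labels[ri, ci]
        if lab == 0:
            warnings.warn(f"annotation ({r}, {c}) lies on background",
                          RuntimeWarning)
            if on_background == "drop":
                continue
            fg = np.argwhere(mask)
            if len(fg) == 0:
                continue
            d = np.hypot(fg[:, 0] - r, fg[:, 1] - c)
            k = int(np.argmin(d))
            if d[k] > snap_radius:
                continue
            lab = labels[fg[k, 0], fg[k, 1]]
        if lab in sickle_ids:
            warnings.warn("two annotations on one component; counted once",
                          RuntimeWarning)
        sickle_ids.add(int(lab))
    if sickle_ids:
        out[np.isin(labels, sorted(sickle_ids))] = SICKLE
    return out


def build_label_mask(clean: np.ndarray,
                     annotations,
                     thresholds: MaskThresholds | None = None,
                     wbc_regions: np.ndarray | None = None,
                     erode_px: int = 4) -> np.ndarray:
    """Full pipeline: threshold, fill holes, erode, assign classes."""
    t = thresholds or MaskThresholds()
    m = erode(fill_holes(threshold_cells(clean, t)), erode_px)
    return assign_classes(m, annotations, wbc_regions=wbc_regions)


def extract_training_patches(image: np.ndarray, label_mask: np.ndarray,
                             annotations, patch: int = 128):
    """One patch per sickle annotation, centered and clamped inside the image.

    Only the annotated neighborhoods are kept for training; unannotated
    regions of a sickle-labeled slide may contain missed sickle cells
    and are excluded.  Returns a list of (image patch, mask patch,
    (row0, col0)) triples.
    """
    h, w = label_mask.shape
    if h < patch or w < patch:
        raise ValueError("image smaller than the requested patch size")
    points = (annotations.points if isinstance(annotations, SickleAnnotation)
              else tuple(annotations))
    out = []
    for (r, c) in points:
        r0 = int(np.clip(round(r) - patch // 2, 0, h - patch))
        c0 = int(np.clip(round(c) - patch // 2, 0, w - patch))
        out.append((image[r0:r0 + patch, c0:c0 + patch],
                    label_mask[r0:r0 + patch, c0:c0 + patch], (r0, c0)))
    return out
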