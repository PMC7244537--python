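"""Synthetic thin blood smear generator with per-cell ground truth.

Emulates the feathered edge of a Wright-Giemsa stained thin smear, where
red blood cells lie in a monolayer: healthy cells render as biconcave
discs (pink rim, pale center), sickled cells as dense crescents.  White
blood cells and platelets are drawn but, like the slide background, carry
the background label — only red blood cells are segmentation targets.

A paired degradation model produces the "smartphone microscope"
counterpart of each clean field of view: radially increasing defocus
blur, a blue color cast, exposure jitter, a smooth geometric warp
(stored, so registration has ground truth) and sensor noise.

All randomness flows from a single integer seed expanded into
independent per-FOV, per-stage streams, so generation is bit-reproducible
and adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

# Label classes for the segmentation ground truth.
BACKGROUND, NORMAL, SICKLE = 0, 1, 2

# Default staining palette (unit-range RGB).
BG_COLOR = (0.94, 0.93, 0.95)
RBC_RIM = (0.78, 0.45, 0.48)
RBC_CENTER = (0.90, 0.72, 0.72)
SICKLE_COLOR = (0.60, 0.28, 0.36)
WBC_COLOR = (0.48, 0.38, 0.66)
PLT_COLOR = (0.46, 0.36, 0.68)


class DensityError(RuntimeError):
    """Requested cell density could not be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not place {requested} non-overlapping cells "
            f"(achieved {achieved}); lower cell_density or allow overlap"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class CellSpec:
    """Geometry and appearance of one rendered cell."""

    center: tuple[float, float]  # (row, col) px
    kind: str  # normal | sickle | wbc | platelet
    radius: float  # px
    orientation: float  # radians
    stain_color: tuple[float, float, float]

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.kind not in ("normal", "sickle", "wbc", "platelet"):
            raise ValueError(f"unknown cell kind {self.kind!r}")


@dataclass(frozen=True)
class SlideSpec:
    """One virtual slide: a set of fields of view at controlled prevalence.

    Defaults mirror the imaging conditions of a five-FOV smartphone
    screen: 0.51 mm x 0.51 mm per FOV at 1000 px, ~1.25 mm^2 total, and
    a density giving roughly 9630 red blood cells over the five FOVs.
    """

    n_fov: int = 5
    fov_px: int = 1000
    mm_per_px: float = 0.51 / 1000.0
    cell_density: float = 7700.0  # red blood cells per mm^2
    sickle_fraction: float = 0.0
    wbc_fraction: float = 0.01  # per red blood cell
    platelet_fraction: float = 0.05
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self):
        if self.n_fov < 1:
            raise ValueError("n_fov must be >= 1")
        if not 0.0 <= self.sickle_fraction <= 1.0:
            raise ValueError("sickle_fraction must lie in [0, 1]")
        if self.fov_px < 32:
            raise ValueError("fov_px too small")

    @property
    def fov_area_mm2(self) -> float:
        return (self.fov_px * self.mm_per_px) ** 2


@dataclass(frozen=True)
class DegradationSpec:
    """Smartphone-microscope degradation model.

    A spec of all zeros (and unit chroma gains) is the identity.
    """

    blur_sigma_center: float = 1.0
    blur_sigma_edge: float = 2.5
    chroma_gains: tuple[float, float, float] = (0.92, 0.97, 1.12)
    intensity_gain_jitter: float = 0.05
    warp_amplitude: float = 2.0
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("blur_sigma_center", "blur_sigma_edge",
                     "intensity_gain_jitter", "warp_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def is_identity(self) -> bool:
        return (
            self.blur_sigma_center == 0 and self.blur_sigma_edge == 0
            and tuple(self.chroma_gains) == (1.0, 1.0, 1.0)
            and self.intensity_gain_jitter == 0
            and self.warp_amplitude == 0 and self.noise_sigma == 0
        )


IDENTITY_DEGRADATION = DegradationSpec(0.0, 0.0, (1.0, 1.0, 1.0), 0.0, 0.0, 0.0)


@dataclass
class DegradationResult:
    """Degraded image plus the geometric warp ground truth."""

    image: np.ndarray  # H x W x 3 in [0, 1]
    field: np.ndarray  # H x W x 2 (row, col) displacement, sampling clean at degraded coords


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# cell geometry

def _cell_radius(kind: str, spec: SlideSpec, rng: np.random.Generator) -> float:
    px_per_um = 1e-3 / spec.mm_per_px
    if kind == "normal":
        base = 3.9 * px_per_um  # RBC radius ~3.9 um
        return max(3.0, base * (1 + 0.05 * rng.standard_normal()))
    if kind == "sickle":
        base = 5.4 * px_per_um  # bounding radius of the crescent
        return max(3.5, base * (1 + 0.05 * rng.standard_normal()))
    if kind == "wbc":
        return 5.0 * px_per_um * (1 + 0.08 * rng.standard_normal())
    return 1.0 * px_per_um * (1 + 0.2 * rng.standard_normal())  # platelet


def _max_bounding_radius_px(spec: SlideSpec) -> float:
    # worst-case lattice-cell bounding radius (sickle crescent, +3 s.d. jitter)
    return 5.4 * 1e-3 / spec.mm_per_px * 1.15


def _render_cell(img: np.ndarray, mask: np.ndarray, cell: CellSpec) -> None:
    """Composite one cell into the image and label mask in place."""
    h, w = mask.shape
    r0, c0 = cell.center
    R = cell.radius
    lo_r = max(0, int(r0 - R - 3))
    hi_r = min(h, int(r0 + R + 4))
    lo_c = max(0, int(c0 - R - 3))
    hi_c = min(w, int(c0 + R + 4))
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dy = rr - r0
    dx = cc - c0
    r = np.hypot(dy, dx)

    if cell.kind == "sickle":
        # crescent: outer disc minus an offset inner disc
        off = 0.60 * R
        r_in = 0.75 * R
        u = (math.cos(cell.orientation), math.sin(cell.orientation))
        di = np.hypot(dy - off * u[0], dx - off * u[1])
        inside = np.minimum(R - r, di - r_in)  # >0 inside crescent
        alpha = np.clip(inside / 1.2, 0.0, 1.0)
        color = np.array(cell.stain_color)
        colmap = np.broadcast_to(color, alpha.shape + (3,))
        label_val = SICKLE
    elif cell.kind == "normal":
        alpha = np.clip((R - r) / 1.2, 0.0, 1.0)
        # biconcave central pallor: pale center, saturated rim
        rn = np.clip(r / R, 0.0, 1.2)
        pallor = np.exp(-((rn / 0.45) ** 2))
        colmap = (
            np.multiply.outer(pallor, np.array(RBC_CENTER))
            + np.multiply.outer(1 - pallor, np.asarray(cell.stain_color))
        )
        label_val = NORMAL
    else:  # wbc / platelet: textured purple blob, background class
        alpha = np.clip((R - r) / 1.2, 0.0, 1.0)
        colmap = np.broadcast_to(np.asarray(cell.stain_color), alpha.shape + (3,))
        label_val = BACKGROUND

    a3 = alpha[..., None]
    img[lo_r:hi_r, lo_c:hi_c] = (1 - a3) * img[lo_r:hi_r, lo_c:hi_c] + a3 * colmap
    if label_val != BACKGROUND:
        mask[lo_r:hi_r, lo_c:hi_c][alpha > 0.5] = label_val


def _hex_sites(side: int, margin: float, spacing: float,
               rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Jittered hexagonal lattice sites inside [margin, side - margin]^2."""
    row_step = spacing * math.sqrt(3) / 2
    rows = np.arange(margin, side - margin, row_step)
    sites = []
    for i, r in enumerate(rows):
        offset = 0.0 if i % 2 == 0 else spacing / 2
        cols = np.arange(margin + offset, side - margin, spacing)
        sites.extend((r, c) for c in cols)
    sites = np.asarray(sites, dtype=float)
    if jitter > 0 and len(sites):
        sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
        np.clip(sites, margin, side - margin, out=sites)
    return sites


def _place_cells(spec: SlideSpec, fov_id: int) -> list[CellSpec]:
    """Place cells as a monolayer.

    Red and white cells sit on a jittered hexagonal lattice whose spacing
    matches the requested density (a near-packed monolayer, as at the
    smear's feathered edge, cannot be reached by rejection sampling);
    platelets are squeezed into the remaining gaps by rejection sampling.
    """
    rng_kind = _rng(spec.seed, fov_id, 0)
    rng_geom = _rng(spec.seed, fov_id, 1)
    rng_place = _rng(spec.seed, fov_id, 2)

    side = spec.fov_px
    n_rbc = int(round(spec.cell_density * spec.fov_area_mm2))
    n_wbc = int(round(n_rbc * spec.wbc_fraction))
    n_plt = int(round(n_rbc * spec.platelet_fraction))
    kinds = ["sickle" if rng_kind.random() < spec.sickle_fraction else "normal"
             for _ in range(n_rbc)] + ["wbc"] * n_wbc
    palette = {"normal": RBC_RIM, "sickle": SICKLE_COLOR,
               "wbc": WBC_COLOR, "platelet": PLT_COLOR}

    cells: list[CellSpec] = []
    placed: list[tuple[float, float, float]] = []  # row, col, bounding radius

    if spec.allow_overlap:
        for kind in kinds:
            radius = _cell_radius(kind, spec, rng_geom)
            theta = rng_geom.random() * 2 * math.pi
            r0 = rng_place.uniform(radius + 3, side - radius - 3)
            c0 = rng_place.uniform(radius + 3, side - radius - 3)
            placed.append((r0, c0, radius))
            cells.append(CellSpec((r0, c0), kind, radius, theta, palette[kind]))
    else:
        rbound = _max_bounding_radius_px(spec)
        margin = rbound + 3
        inner = max(side - 2 * margin, 1.0)
        spacing = math.sqrt(inner**2 / (max(len(kinds), 1) * math.sqrt(3) / 2))
        spacing *= 0.99  # a few spare sites so rounding never under-supplies
        # below one normal-RBC diameter per site the monolayer is
        # physically impossible: cells would merge, not just touch
        floor_spacing = 2 * 3.9e-3 / spec.mm_per_px + 1
        if spacing < floor_spacing:
            capacity = len(_hex_sites(side, margin, floor_spacing,
                                      rng_place, 0.0))
            raise DensityError(n_rbc, capacity)
        # jitter bounded so even two worst-case cells cannot touch; at
        # near-packed densities (spacing under the worst-case sickle
        # bounding diameter) jitter is zero and rare tangency is allowed,
        # as at the feathered edge of a real smear
        jitter = max(0.0, (spacing - (2 * rbound + 1)) / (2 * math.sqrt(2)))
        sites = _hex_sites(side, margin, spacing, rng_place, jitter)
        if len(sites) < len(kinds):
            raise DensityError(n_rbc, len(sites))
        chosen = sites[rng_place.permutation(len(sites))[: len(kinds)]]
        for kind, (r0, c0) in zip(kinds, chosen):
            radius = _cell_radius(kind, spec, rng_geom)
            theta = rng_geom.random() * 2 * math.pi
            placed.append((r0, c0, radius))
            cells.append(CellSpec((r0, c0), kind, radius, theta, palette[kind]))

    # platelets: tiny, fitted into gaps; unplaceable ones are dropped
    placed_arr = np.asarray(placed) if placed else np.empty((0, 3))
    for _ in range(n_plt):
        radius = _cell_radius("platelet", spec, rng_geom)
        for _ in range(60):
            r0 = rng_place.uniform(radius + 2, side - radius - 2)
            c0 = rng_place.uniform(radius + 2, side - radius - 2)
            if spec.allow_overlap or placed_arr.shape[0] == 0 or np.all(
                np.hypot(placed_arr[:, 0] - r0, placed_arr[:, 1] - c0)
                > placed_arr[:, 2] + radius + 1
            ):
                placed_arr = np.vstack([placed_arr, [r0, c0, radius]])
                cells.append(CellSpec(
                    (r0, c0), "platelet", radius,
                    rng_geom.random() * 2 * math.pi, palette["platelet"]))
                break
    return cells


def render_clean_smear(
    spec: SlideSpec, fov_id: int = 0
) -> tuple[np.ndarray, np.ndarray, list[CellSpec]]:
    """Render one clean (benchtop-quality) field of view.

    Returns the RGB image in [0, 1], the three-class label mask
    (0 background, 1 normal RBC, 2 sickle) and the list of placed cells.
    Identical (spec, fov_id) produce bit-identical output.
    """
    cells = _place_cells(spec, fov_id)
    side = spec.fov_px
    rng_bg = _rng(spec.seed, fov_id, 3)
    img = np.empty((side, side, 3))
    img[:] = BG_COLOR
    # faint illumination mottle so the background is not exactly constant
    mottle = ndi.gaussian_filter(rng_bg.standard_normal((side, side)), side / 16.0)
    sd = mottle.std()
    if sd > 0:
        img += (0.008 * mottle / sd)[..., None]
    mask = np.zeros((side, side), dtype=np.uint8)
    for cell in cells:
        _render_cell(img, mask, cell)
    np.clip(img, 0.0, 1.0, out=img)
    return img, mask, cells


def annotation_point(cell: CellSpec) -> tuple[float, float]:
    """A point on the rendered cell body (where an expert would click).

    A crescent's geometric center lies inside its cut-out, so for sickle
    cells the point sits on the thick limb, opposite the opening.
    """
    if cell.kind != "sickle":
        return cell.center
    u = (math.cos(cell.orientation), math.sin(cell.orientation))
    r = 0.55 * cell.radius
    return (cell.center[0] - r * u[0], cell.center[1] - r * u[1])


def render_slide(spec: SlideSpec):
    """Render every FOV of the slide; yields (image, mask, cells) triples."""
    return [render_clean_smear(spec, fov_id) for fov_id in range(spec.n_fov)]


# ---------------------------------------------------------------------------
# degradation

def _smooth_warp_field(shape, amplitude, rng) -> np.ndarray:
    h, w = shape
    fld = rng.standard_normal((h, w, 2))
    sigma = max(h, w) / 8.0
    for k in range(2):
        fld[..., k] = ndi.gaussian_filter(fld[..., k], sigma)
    mag = np.hypot(fld[..., 0], fld[..., 1]).max()
    if mag > 0:
        fld *= amplitude / mag
    return fld


def degrade_to_smartphone(clean: np.ndarray, d: DegradationSpec) -> DegradationResult:
    """Produce the smartphone-like counterpart of a clean FOV.

    The degraded image samples the clean image at ``coords + field``; the
    returned field is the registration ground truth (max magnitude equals
    ``warp_amplitude`` by construction).
    """
    clean = np.asarray(clean, dtype=float)
    h, w = clean.shape[:2]
    if d.is_identity():
        return DegradationResult(clean.copy(), np.zeros((h, w, 2)))

    rng = _rng(d.seed, 101)
    out = clean

    # geometric warp (lens distortion / mechanical shift surrogate)
    if d.warp_amplitude > 0:
        fld = _smooth_warp_field((h, w), d.warp_amplitude, rng)
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        coords = [rows + fld[..., 0], cols + fld[..., 1]]
        out = np.stack(
            [ndi.map_coordinates(out[..., c], coords, order=1, mode="nearest")
             for c in range(out.shape[2])], axis=-1)
    else:
        fld = np.zeros((h, w, 2))

    # radially increasing defocus: blend a center-blur and an edge-blur
    if d.blur_sigma_center > 0 or d.blur_sigma_edge > 0:
        bc = (ndi.gaussian_filter(out, (d.blur_sigma_center,) * 2 + (0,))
              if d.blur_sigma_center > 0 else out)
        be = (ndi.gaussian_filter(out, (d.blur_sigma_edge,) * 2 + (0,))
              if d.blur_sigma_edge > 0 else out)
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        rad = np.hypot(rows - (h - 1) / 2, cols - (w - 1) / 2)
        wgt = (rad / rad.max()) ** 2 if rad.max() > 0 else rad
        out = (1 - wgt[..., None]) * bc + wgt[..., None] * be

    # blue cast + exposure jitter
    gains = np.asarray(d.chroma_gains, dtype=float)
    gain = 1.0 + d.intensity_gain_jitter * rng.standard_normal()
    out = out * gains * gain

    if d.noise_sigma > 0:
        out = out + d.noise_sigma * rng.standard_normal(out.shape)

    return DegradationResult(np.clip(out, 0.0, 1.0), fld)


# ---------------------------------------------------------------------------
# probability-map fixtures for the counting rules

def generate_probmap_fixture(
    blobs: Sequence[tuple[int, float, float]],
    shape: tuple[int, int] | None = None,
    gap: int = 3,
) -> np.ndarray:
    """Build a class-probability map with connected blobs of exact pixel counts.

    Each ``(n_pixels, p_cell, p_sickle)`` blob becomes one connected
    region whose pixels carry probabilities (background, normal, sickle)
    = (1 - p_cell, p_cell - p_sickle, p_sickle); everywhere else the
    background probability is 1.  Blobs never touch, so the component
    structure is exactly the blob list.
    """
    for n_px, p_cell, p_sickle in blobs:
        if n_px < 1:
            raise ValueError("blob pixel count must be >= 1")
        if not (0.0 <= p_sickle <= p_cell <= 1.0):
            raise ValueError(
                "need 0 <= p_sickle <= p_cell <= 1 so class probabilities sum to 1"
            )

    sides = [int(math.ceil(math.sqrt(n))) for n, _, _ in blobs]
    width = sum(sides) + gap * (len(blobs) + 1)
    height = (max(sides) if sides else 8) + 2 * gap
    if shape is None:
        shape = (max(height, 8), max(width, 8))
    h, w = shape
    if h < height or w < width:
        raise ValueError("blobs do not fit in the requested canvas")

    p = np.zeros((h, w, 3))
    p[..., 0] = 1.0
    col = gap
    for (n_px, p_cell, p_sickle), side in zip(blobs, sides):
        probs = (1.0 - p_cell, p_cell - p_sickle, p_sickle)
        # fill row-major inside a side x side block: always 4-connected
        idx = np.arange(n_px)
        rr = gap + idx // side
        cc = col + idx % side
        p[rr, cc, :] = probs
        col += side + gap
    return p


def ideal_probmap(mask: np.ndarray,
                  p_cell: float = 0.95,
                  p_sickle_hi: float = 0.90) -> np.ndarray:
    """Ground-truth-derived class probabilities for decision-layer tests.

    Encodes a confident, correct segmentation of ``mask``: cell pixels get
    cell probability ``p_cell`` (split so normal pixels stay far below the
    0.15 sickle threshold and sickle pixels far above it).
    """
    p = np.empty(mask.shape + (3,))
    p[...] = (0.98, 0.01, 0.01)
    p_lo = p_cell - p_sickle_hi
    p[mask == NORMAL] = (1 - p_cell, p_sickle_hi, p_lo)
    p[mask == SICKLE] = (1 - p_cell, p_lo, p_sickle_hi)
    return p
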