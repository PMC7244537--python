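"""Three-stage co-registration of smartphone FOVs to benchtop images.

The training-pair construction aligns each smartphone field of view to
the benchtop whole-slide scan in three steps:

1. **Locate** — normalized cross-correlation of the FOV against the
   (bicubically down-sampled) whole-slide image; the correlation peak
   gives the crop position.
2. **Affine** — a six-parameter affine transform (shift, rotation,
   anisotropic scale, shear) fitted by direct optimization of a
   normalized-correlation metric on smoothed luminance, which is
   insensitive to the gain/offset and color-cast differences between
   the modalities.
3. **Elastic pyramidal** — coarse-to-fine block matching: the image is
   tiled into progressively smaller blocks, each block's residual shift
   is found as a cross-correlation peak with parabolic subpixel
   refinement, and the block shifts are bilinearly interpolated into a
   dense displacement field composed across levels.

Convention: coordinates are (row, col), 0-based; a displacement field
``F`` means the warped moving image samples ``moving`` at ``x + F(x)``
for each fixed-image pixel ``x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .evaluation import rgb_to_y


@dataclass
class AffineTransform:
    """2x3 matrix mapping fixed-image (row, col) to moving-image coords."""

    matrix: np.ndarray  # shape (2, 3)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        det = np.linalg.det(self.matrix[:, :2])
        if abs(det) < 1e-8:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map (..., 2) row/col coordinates."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.matrix[:, :2].T + self.matrix[:, 2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2].copy()


@dataclass
class AffineFitResult:
    transform: AffineTransform
    metric: float  # final 1 - NCC (lower is better)
    converged: bool


@dataclass
class DisplacementField:
    """Dense (H, W, 2) row/col displacement field."""

    field: np.ndarray
    levels: int = 1

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 3 or self.field.shape[2] != 2:
            raise ValueError("field must be (H, W, 2)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.field[..., 0], self.field[..., 1])


def _lum(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return rgb_to_y(img) if img.ndim == 3 else img


# ---------------------------------------------------------------------------
# stage 0: bicubic down-sampling

def downsample_to_match(hi: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Bicubic down-sampling to ``target_hw`` (refuses to upsample)."""
    hi = np.asarray(hi, dtype=float)
    th, tw = target_hw
    if th > hi.shape[0] or tw > hi.shape[1]:
        raise ValueError("target larger than source: use for down-sampling only")
    out_shape = (th, tw) + hi.shape[2:]
    return resize(hi, out_shape, order=3, anti_aliasing=False,
                  preserve_range=True, mode="edge")


# ---------------------------------------------------------------------------
# stage 1: locate the FOV in the whole-slide image

def locate_fov(whole_slide: np.ndarray, fov: np.ndarray,
               min_correlation: float = 0.2) -> tuple[int, int] | None:
    """Offset (row, col) of the best-matching crop, or None if no match.

    Uses the normalized cross-correlation matrix between the FOV and the
    whole-slide luminance; a zero-variance template or a peak below
    ``min_correlation`` yields None.
    """
    ws = _lum(whole_slide)
    f = _lum(fov)
    if f.shape[0] > ws.shape[0] or f.shape[1] > ws.shape[1]:
        raise ValueError("fov must be smaller than the whole-slide image")
    if f.std() == 0 or ws.std() == 0:
        return None
    corr = match_template(ws, f, pad_input=False)
    peak = float(corr.max())
    if peak < min_correlation:
        return None
    idx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    return int(idx[0]), int(idx[1])


# ---------------------------------------------------------------------------
# warping

def warp(image: np.ndarray,
         transform: "DisplacementField | AffineTransform") -> np.ndarray:
    """Resample ``image`` through a displacement field or affine transform.

    Bilinear interpolation; samples outside the image take the border
    value.  A zero field (or identity affine) returns the image unchanged.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if isinstance(transform, AffineTransform):
        coords = transform.apply(np.stack([rows, cols], axis=-1))
        sample = [coords[..., 0], coords[..., 1]]
    else:
        fld = transform.field
        if fld.shape[:2] != (h, w):
            raise ValueError("field shape does not match image")
        sample = [rows + fld[..., 0], cols + fld[..., 1]]

    def _warp_plane(plane):
        return ndi.map_coordinates(plane, sample, order=1, mode="nearest")

    if image.ndim == 2:
        return _warp_plane(image)
    return np.stack([_warp_plane(image[..., c])
                     for c in range(image.shape[2])], axis=-1)


# ---------------------------------------------------------------------------
# stage 2: affine refinement

def _affine_from_params(p, center) -> AffineTransform:
    dy, dx, theta, log_sy, log_sx, shear = p
    cy, cx = center
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shear_m = np.array([[1.0, shear], [0.0, 1.0]])
    scale = np.diag([np.exp(log_sy), np.exp(log_sx)])
    lin = rot @ shear_m @ scale
    c = np.array([cy, cx])
    trans = c + np.array([dy, dx]) - lin @ c
    return AffineTransform(np.column_stack([lin, trans]))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def fit_affine(moving: np.ndarray, fixed: np.ndarray,
               smooth_sigma: float = 2.0, max_iter: int = 400,
               extra_starts: int = 2) -> AffineFitResult:
    """Fit shift, rotation, scale and shear between same-size images.

    Minimizes ``1 - NCC`` of Gaussian-smoothed luminance over the six
    affine parameters (Powell), multi-started from the identity and from
    a phase-correlation translation estimate.  Non-convergence within the
    iteration cap returns the best-so-far transform with
    ``converged=False``.
    """
    m = ndi.gaussian_filter(_lum(moving), smooth_sigma)
    f = ndi.gaussian_filter(_lum(fixed), smooth_sigma)
    if m.shape != f.shape:
        raise ValueError("fit_affine expects same-size images (locate+crop first)")
    h, w = f.shape
    mr = int(0.1 * h)
    mc = int(0.1 * w)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    def cost(p):
        t = _affine_from_params(p, center)
        warped = warp(m, t)
        return 1.0 - _ncc(warped[mr:h - mr, mc:w - mc], f[mr:h - mr, mc:w - mc])

    starts = [np.zeros(6)]
    try:
        shift, _, _ = phase_cross_correlation(f, m, normalization=None)
        init = np.zeros(6)
        # phase correlation returns the shift applied to moving to match
        # fixed; our transform samples moving at fixed coords + t
        init[0], init[1] = -shift[0], -shift[1]
        starts.append(init)
    except Exception:  # pragma: no cover - degenerate inputs
        pass
    rng = np.random.default_rng(0)
    for _ in range(extra_starts):
        p = np.zeros(6)
        p[:2] = rng.uniform(-5, 5, size=2)
        starts.append(p)

    best = None
    converged = False
    for p0 in starts:
        res = optimize.minimize(cost, p0, method="Powell",
                                options={"maxiter": max_iter, "xtol": 1e-4,
                                         "ftol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        warnings.warn("affine fit did not converge; returning best-so-far",
                      RuntimeWarning)
    return AffineFitResult(_affine_from_params(best.x, center),
                           float(best.fun), converged)


# ---------------------------------------------------------------------------
# stage 3: elastic pyramidal registration

def _block_shift(fixed_block: np.ndarray, moving_block: np.ndarray,
                 max_shift: int, min_std: float = 0.0
                 ) -> tuple[float, float] | None:
    """Residual shift of the moving block via a cross-correlation peak.

    Returns the displacement to *add to the sampling position* of the
    moving image, with parabolic subpixel refinement (clipped to +-0.5
    px around the integer peak), or None for blocks whose contrast is at
    or below ``min_std`` (their correlation peak carries no signal).
    """
    if fixed_block.std() <= min_std or moving_block.std() <= min_std:
        return None
    h, w = fixed_block.shape
    # Hann taper suppresses spectral leakage from content sliding in
    # at block edges, which otherwise biases the peak toward zero
    taper = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    f = (fixed_block - fixed_block.mean()) * taper
    m = (moving_block - moving_block.mean()) * taper
    # full cross-correlation via FFT
    corr = np.fft.irfft2(np.fft.rfft2(f) * np.conj(np.fft.rfft2(m)),
                         s=(h, w))
    corr = np.fft.fftshift(corr)
    c0 = (h // 2, w // 2)
    s = max_shift
    win = corr[c0[0] - s:c0[0] + s + 1, c0[1] - s:c0[1] + s + 1]
    pk = np.unravel_index(int(np.argmax(win)), win.shape)
    if (pk[0] in (0, win.shape[0] - 1)) or (pk[1] in (0, win.shape[1] - 1)):
        # peak pinned to the search boundary: aliased / unrefinable match
        return None

    def _parabolic(vals):
        denom = vals[0] + vals[2] - 2 * vals[1]
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (vals[0] - vals[2]) / denom, -0.5, 0.5))

    dr = float(pk[0] - s)
    dc = float(pk[1] - s)
    if 0 < pk[0] < win.shape[0] - 1:
        dr += _parabolic(win[pk[0] - 1:pk[0] + 2, pk[1]])
    if 0 < pk[1] < win.shape[1] - 1:
        dc += _parabolic(win[pk[0], pk[1] - 1:pk[1] + 2])
    # with m(x) = f(x + d) the peak sits at +d; sampling m at x - d
    # aligns it with f, so the returned displacement is -d
    return -dr, -dc


def _fill_invalid(shifts: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Invalid (featureless) blocks inherit their valid neighbors' mean."""
    sh = shifts.copy()
    if valid.all():
        return sh
    if not valid.any():
        sh[:] = 0.0
        return sh
    valid = valid.copy()
    for _ in range(max(sh.shape[:2])):
        missing = ~valid
        if not missing.any():
            break
        filled = valid.astype(float)
        den = ndi.uniform_filter(filled, 3)
        fillable = missing & (den > 1e-9)
        for k in range(2):
            num = ndi.uniform_filter(np.where(valid, sh[..., k], 0.0), 3)
            sh[..., k][fillable] = (num / np.maximum(den, 1e-9))[fillable]
        valid = valid | fillable
    return sh


def _interpolate_block_field(shifts: np.ndarray,
                             centers_r: np.ndarray, centers_c: np.ndarray,
                             shape: tuple[int, int]) -> np.ndarray:
    """Bilinear interpolation of per-block shifts to a dense field.

    Outside the grid of block centers the field is linearly extrapolated
    but clamped to the range actually observed among the blocks, so a
    steep gradient between the outermost centers cannot launch the
    corners beyond any measured displacement.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    out = np.empty((h, w, 2))
    for k in range(2):
        interp = RegularGridInterpolator(
            (centers_r, centers_c), sh_k := shifts[..., k],
            bounds_error=False, fill_value=None, method="linear")
        dense = interp(np.stack([rows.ravel(), cols.ravel()], axis=-1)
                       ).reshape(h, w)
        out[..., k] = np.clip(dense, sh_k.min(), sh_k.max())
    return out


def _block_pass(f: np.ndarray, mw: np.ndarray, block: int,
                smooth: float) -> np.ndarray:
    """One block-matching pass: residual shift field between f and mw."""
    h, w = f.shape
    step = max(4, block // 2)  # 50% block overlap
    r0s = list(range(0, h - block + 1, step))
    c0s = list(range(0, w - block + 1, step))
    if r0s[-1] != h - block:
        r0s.append(h - block)
    if c0s[-1] != w - block:
        c0s.append(w - block)
    centers_r = np.array([r + (block - 1) / 2 for r in r0s])
    centers_c = np.array([c + (block - 1) / 2 for c in c0s])
    shifts = np.zeros((len(r0s), len(c0s), 2))
    valid = np.zeros((len(r0s), len(c0s)), dtype=bool)
    max_shift = max(2, block // 4)
    # blocks well below the image's own contrast are featureless
    # background: exclude them and inherit their neighbors' motion
    min_std = 0.1 * float(f.std())
    for i, r0 in enumerate(r0s):
        for j, c0 in enumerate(c0s):
            res = _block_shift(f[r0:r0 + block, c0:c0 + block],
                               mw[r0:r0 + block, c0:c0 + block], max_shift,
                               min_std)
            if res is not None:
                shifts[i, j] = res
                valid[i, j] = True
    # vector-median outlier rejection: overlapping blocks see mostly the
    # same motion, so a block that disagrees sharply with its neighbors
    # has locked onto the wrong cell (a smear is near-periodic); treat it
    # like a featureless block and inherit the neighborhood's motion
    if valid.any():
        med = np.stack([ndi.median_filter(shifts[..., k], size=3,
                                          mode="nearest")
                        for k in range(2)], axis=-1)
        dev = np.hypot(*(shifts - med).transpose(2, 0, 1))
        valid &= dev <= 2.0
    shifts = _fill_invalid(shifts, valid)
    if smooth > 0:
        for k in range(2):
            shifts[..., k] = ndi.gaussian_filter(shifts[..., k], smooth)
    return _interpolate_block_field(shifts, centers_r, centers_c, (h, w))


def elastic_pyramidal_register(moving: np.ndarray, fixed: np.ndarray,
                               levels: int = 3, min_block: int = 32,
                               inner_iterations: int = 5,
                               smooth: float = 0.7,
                               field_smooth: float = 0.25
                               ) -> DisplacementField:
    """Coarse-to-fine block-matching estimate of a dense displacement field.

    The first level tiles the image into 50%-overlapping blocks of side
    ``side // 4``; each subsequent level halves the block side, stopping
    at ``min_block``.  Within a level, warp-and-correlate is repeated
    ``inner_iterations`` times: a single correlation pass under-reports
    fractional shifts (interpolation broadens the peak), but re-warping
    with the running estimate shrinks the residual geometrically.

    Two safeguards keep near-periodic content (a smear is a field of
    near-identical cells) from locking onto the wrong cell: each
    incremental field is Gaussian-smoothed at ``field_smooth * block``
    pixels — the estimator targets smooth warps, and iteration restores
    whatever amplitude the smoothing removes, while spatially incoherent
    wrong-cell matches cannot accumulate — and an increment is accepted
    only if it reduces the photometric residual.  Inputs should already
    be affine-aligned.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    m = _lum(moving)
    f = _lum(fixed)
    if m.shape != f.shape:
        raise ValueError("inputs must have the same shape")
    h, w = f.shape
    total = np.zeros((h, w, 2))
    block = max(min_block, min(h, w) // 4)
    err = float(np.abs(m - f).mean())
    for level in range(levels):
        for _ in range(inner_iterations):
            mw = warp(m, DisplacementField(total))
            delta = _block_pass(f, mw, block, smooth)
            if field_smooth > 0:
                sigma = field_smooth * block
                for k in range(2):
                    delta[..., k] = ndi.gaussian_filter(delta[..., k], sigma)
            cand = total + delta
            cand_err = float(np.abs(warp(m, DisplacementField(cand))
                                    - f).mean())
            # accept only residual-reducing increments: a spurious block
            # peak (low-texture region) must not cascade across iterations
            if cand_err >= err:
                break
            total, err = cand, cand_err
        if block // 2 >= min_block:
            block //= 2
    return DisplacementField(total, levels=levels)
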