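"""Registration: locate, affine, warp and elastic pyramidal recovery."""

import dataclasses

import numpy as np
import pytest

from sicklescreen import registration as reg
from sicklescreen import synthetic as syn


# ---------------------------------------------------------------------------
# downsample / locate

def test_downsample_shape_and_refusal(textured_image):
    lo = reg.downsample_to_match(textured_image, (64, 64))
    assert lo.shape == (64, 64, 3)
    with pytest.raises(ValueError):
        reg.downsample_to_match(lo, (128, 128))


def test_downsample_preserves_smooth_ramp():
    ramp = np.linspace(0, 1, 200)[None, :] * np.ones((200, 1))
    lo = reg.downsample_to_match(ramp, (50, 50))
    # interior of a linear ramp is reproduced by bicubic interpolation
    expect = np.linspace(0, 1, 200)[::4]
    np.testing.assert_allclose(lo[25, 5:45], expect[5:45], atol=0.02)


def test_locate_fov_exact_on_crop(textured_image):
    crop = textured_image[40:104, 24:88]
    assert reg.locate_fov(textured_image, crop) == (40, 24)


def test_locate_fov_none_on_flat_or_poor_match(textured_image):
    flat = np.zeros((32, 32))
    assert reg.locate_fov(textured_image, flat) is None
    rng = np.random.default_rng(0)
    noise = rng.random((64, 64))
    assert reg.locate_fov(textured_image, noise,
                          min_correlation=0.9) is None
    with pytest.raises(ValueError):
        reg.locate_fov(np.zeros((16, 16)), np.ones((32, 32)))


def test_locate_matches_bruteforce_ncc(textured_image):
    """Peak position agrees with a direct NCC scan over all offsets."""
    from sicklescreen.evaluation import rgb_to_y

    ws = rgb_to_y(textured_image)[:48, :48]
    tpl = ws[10:34, 19:43].copy()
    best, best_pos = -2.0, None
    th, tw = tpl.shape
    t0 = tpl - tpl.mean()
    for r in range(ws.shape[0] - th + 1):
        for c in range(ws.shape[1] - tw + 1):
            win = ws[r:r + th, c:c + tw]
            w0 = win - win.mean()
            denom = np.sqrt((w0 * w0).sum() * (t0 * t0).sum())
            ncc = (w0 * t0).sum() / denom if denom else 0.0
            if ncc > best:
                best, best_pos = ncc, (r, c)
    assert best_pos == (10, 19)
    assert reg.locate_fov(ws, tpl) == best_pos


# ---------------------------------------------------------------------------
# warp + transforms

def test_affine_identity_and_validation():
    ident = reg.AffineTransform.identity()
    pts = np.array([[1.0, 2.0], [3.0, 4.0]])
    np.testing.assert_allclose(ident.apply(pts), pts)
    with pytest.raises(ValueError):
        reg.AffineTransform(np.zeros((2, 3)))  # singular
    with pytest.raises(ValueError):
        reg.AffineTransform(np.zeros((3, 3)))


def test_warp_zero_field_is_identity(textured_image):
    h, w = textured_image.shape[:2]
    fld = reg.DisplacementField(np.zeros((h, w, 2)))
    np.testing.assert_allclose(reg.warp(textured_image, fld),
                               textured_image, atol=1e-12)
    np.testing.assert_allclose(
        reg.warp(textured_image, reg.AffineTransform.identity()),
        textured_image, atol=1e-12)


def test_warp_integer_shift(textured_image):
    """A constant (+2, +3) field shifts content by (-2, -3) in the output."""
    h, w = textured_image.shape[:2]
    fld = np.zeros((h, w, 2))
    fld[..., 0] = 2
    fld[..., 1] = 3
    out = reg.warp(textured_image, reg.DisplacementField(fld))
    np.testing.assert_allclose(out[:-2, :-3], textured_image[2:, 3:],
                               atol=1e-12)


def test_displacement_field_validation():
    with pytest.raises(ValueError):
        reg.DisplacementField(np.zeros((4, 4)))
    bad = np.zeros((4, 4, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        reg.DisplacementField(bad)
    mag = reg.DisplacementField(np.full((2, 2, 2), 3.0)).magnitude
    np.testing.assert_allclose(mag, np.hypot(3, 3))


# ---------------------------------------------------------------------------
# affine fitting

def test_fit_affine_recovers_translation(textured_image):
    shift = reg.AffineTransform(np.array([[1.0, 0, 5.0], [0, 1.0, -3.0]]))
    moved = reg.warp(textured_image, shift)
    fit = reg.fit_affine(moved, textured_image)
    # composing the fit with the shift should cancel: t_fit = -t_shift
    np.testing.assert_allclose(fit.transform.translation, [-5.0, 3.0],
                               atol=0.5)
    assert fit.metric < 0.02


def test_fit_affine_recovers_rotation(textured_image):
    theta = np.deg2rad(2.0)
    h, w = textured_image.shape[:2]
    c = np.array([(h - 1) / 2, (w - 1) / 2])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    t = c - rot @ c
    moved = reg.warp(textured_image,
                     reg.AffineTransform(np.column_stack([rot, t])))
    fit = reg.fit_affine(moved, textured_image)
    lin = fit.transform.matrix[:, :2]
    est_theta = np.rad2deg(np.arctan2(lin[1, 0], lin[0, 0]))
    assert abs(est_theta - (-2.0)) < 0.2
    assert fit.metric < 0.05


def test_fit_affine_shape_check(textured_image):
    with pytest.raises(ValueError):
        reg.fit_affine(textured_image[:64], textured_image)


# ---------------------------------------------------------------------------
# elastic pyramidal

def _sinusoid_field(h, w, amp):
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    fld = np.empty((h, w, 2))
    fld[..., 0] = amp * np.sin(2 * np.pi * rows / h) * np.cos(np.pi * cols / w)
    fld[..., 1] = amp * np.cos(np.pi * rows / h) * np.sin(2 * np.pi * cols / w)
    return fld


def _interior_rms(est, truth, margin=16):
    d = (est - truth)[margin:-margin, margin:-margin]
    return float(np.sqrt((d ** 2).sum(axis=-1).mean()))


def test_elastic_identity_recovers_zero(textured_image):
    fld = reg.elastic_pyramidal_register(textured_image, textured_image)
    assert np.abs(fld.field).max() < 0.15


def test_elastic_recovers_smooth_warp(textured_image):
    truth = _sinusoid_field(*textured_image.shape[:2], amp=2.0)
    degraded = reg.warp(textured_image, reg.DisplacementField(truth))
    est = reg.elastic_pyramidal_register(textured_image, degraded)
    assert _interior_rms(est.field, truth) < 0.5
    full = float(np.sqrt(((est.field - truth) ** 2).sum(axis=-1).mean()))
    assert full < 1.0  # border ring: displacement partly unobservable


def test_elastic_improves_alignment(textured_image):
    truth = _sinusoid_field(*textured_image.shape[:2], amp=2.0)
    degraded = reg.warp(textured_image, reg.DisplacementField(truth))
    est = reg.elastic_pyramidal_register(textured_image, degraded)
    before = np.abs(textured_image - degraded).mean()
    after = np.abs(reg.warp(textured_image, est) - degraded).mean()
    assert after < 0.35 * before


def test_elastic_validation(textured_image):
    with pytest.raises(ValueError):
        reg.elastic_pyramidal_register(textured_image,
                                       textured_image[:64, :64])
    with pytest.raises(ValueError):
        reg.elastic_pyramidal_register(textured_image, textured_image,
                                       levels=0)


def test_elastic_registers_degradation_warp(small_slide_spec):
    """End-to-end: recover the stored degradation field (interior RMS)."""
    img, _, _ = syn.render_clean_smear(small_slide_spec)
    d = syn.DegradationSpec(blur_sigma_center=0, blur_sigma_edge=0,
                            chroma_gains=(1, 1, 1), intensity_gain_jitter=0,
                            warp_amplitude=2.0, noise_sigma=0, seed=4)
    res = syn.degrade_to_smartphone(img, d)
    est = reg.elastic_pyramidal_register(img, res.image)
    assert _interior_rms(est.field, res.field) < 0.5
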