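"""Synthetic smear generator: determinism, ground truth, degradation."""

import dataclasses

import numpy as np
import pytest

from sicklescreen import counting
from sicklescreen import synthetic as syn


def test_render_is_deterministic(small_slide_spec):
    a_img, a_mask, a_cells = syn.render_clean_smear(small_slide_spec)
    b_img, b_mask, b_cells = syn.render_clean_smear(small_slide_spec)
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_mask, b_mask)
    assert a_cells == b_cells


def test_fovs_differ_and_seeds_differ(small_slide_spec):
    img0, _, _ = syn.render_clean_smear(small_slide_spec, fov_id=0)
    img1, _, _ = syn.render_clean_smear(small_slide_spec, fov_id=1)
    assert not np.array_equal(img0, img1)
    other = dataclasses.replace(small_slide_spec, seed=small_slide_spec.seed + 1)
    img0b, _, _ = syn.render_clean_smear(other, fov_id=0)
    assert not np.array_equal(img0, img0b)


def test_output_ranges_and_shapes(small_fov, small_slide_spec):
    img, mask, cells = small_fov
    side = small_slide_spec.fov_px
    assert img.shape == (side, side, 3)
    assert mask.shape == (side, side)
    assert img.min() >= 0.0 and img.max() <= 1.0
    assert set(np.unique(mask)) <= {syn.BACKGROUND, syn.NORMAL, syn.SICKLE}


def test_mask_component_count_matches_cells(small_fov):
    """Each red blood cell is one labeled component of > 100 px."""
    _, mask, cells = small_fov
    n_rbc = sum(c.kind in ("normal", "sickle") for c in cells)
    assert counting.count_cells(mask > 0, min_pixels=100) == n_rbc
    n_sickle = sum(c.kind == "sickle" for c in cells)
    assert counting.count_cells(mask == syn.SICKLE, min_pixels=100) == n_sickle


def test_zero_prevalence_has_no_sickle_label(small_slide_spec):
    spec = dataclasses.replace(small_slide_spec, sickle_fraction=0.0)
    _, mask, cells = syn.render_clean_smear(spec)
    assert not (mask == syn.SICKLE).any()
    assert all(c.kind != "sickle" for c in cells)


def test_wbc_and_platelets_are_background():
    spec = syn.SlideSpec(n_fov=1, fov_px=128, cell_density=1500.0,
                         wbc_fraction=0.1, platelet_fraction=0.3, seed=5)
    _, mask, cells = syn.render_clean_smear(spec)
    assert any(c.kind == "wbc" for c in cells)
    assert any(c.kind == "platelet" for c in cells)
    for c in cells:
        if c.kind in ("wbc", "platelet"):
            r, col = int(round(c.center[0])), int(round(c.center[1]))
            assert mask[r, col] == syn.BACKGROUND


def test_cells_do_not_overlap(small_fov):
    _, _, cells = small_fov
    big = [c for c in cells if c.kind != "platelet"]
    for i in range(len(big)):
        for j in range(i + 1, len(big)):
            d = np.hypot(big[i].center[0] - big[j].center[0],
                         big[i].center[1] - big[j].center[1])
            assert d > big[i].radius + big[j].radius


def test_prevalence_matches_request_over_many_slides():
    """Empirical sickle fraction within 3 binomial s.d. of the request."""
    frac = 0.2
    n_sickle = n_rbc = 0
    for s in range(50):
        spec = syn.SlideSpec(n_fov=1, fov_px=128, cell_density=2000.0,
                             sickle_fraction=frac, wbc_fraction=0.0,
                             platelet_fraction=0.0, seed=1000 + s)
        cells = syn._place_cells(spec, 0)
        n_rbc += len(cells)
        n_sickle += sum(c.kind == "sickle" for c in cells)
    sd = np.sqrt(frac * (1 - frac) / n_rbc)
    assert abs(n_sickle / n_rbc - frac) <= 3 * sd


def test_density_error_when_unplaceable():
    spec = syn.SlideSpec(n_fov=1, fov_px=64, cell_density=60000.0, seed=0)
    with pytest.raises(syn.DensityError) as exc:
        syn.render_clean_smear(spec)
    assert exc.value.requested > exc.value.achieved


def test_cellspec_validation():
    with pytest.raises(ValueError):
        syn.CellSpec((0, 0), "normal", -1.0, 0.0, (1, 0, 0))
    with pytest.raises(ValueError):
        syn.CellSpec((0, 0), "mystery", 5.0, 0.0, (1, 0, 0))
    with pytest.raises(ValueError):
        syn.SlideSpec(sickle_fraction=1.5)


def test_render_slide_yields_n_fov(small_slide_spec):
    spec = dataclasses.replace(small_slide_spec, n_fov=2)
    fovs = syn.render_slide(spec)
    assert len(fovs) == 2
    np.testing.assert_array_equal(
        fovs[0][0], syn.render_clean_smear(spec, fov_id=0)[0])


# ---------------------------------------------------------------------------
# degradation

def test_identity_degradation_is_exact(textured_image):
    res = syn.degrade_to_smartphone(textured_image, syn.IDENTITY_DEGRADATION)
    np.testing.assert_array_equal(res.image, textured_image)
    assert not res.field.any()


def test_degradation_deterministic_and_distinct(textured_image):
    d = syn.DegradationSpec(seed=7)
    a = syn.degrade_to_smartphone(textured_image, d)
    b = syn.degrade_to_smartphone(textured_image, d)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.field, b.field)
    c = syn.degrade_to_smartphone(textured_image, syn.DegradationSpec(seed=8))
    assert not np.array_equal(a.image, c.image)


def test_degradation_blue_cast(textured_image):
    d = syn.DegradationSpec(intensity_gain_jitter=0.0, noise_sigma=0.0,
                            warp_amplitude=0.0, seed=3)
    res = syn.degrade_to_smartphone(textured_image, d)
    rel_blue = res.image[..., 2].mean() / textured_image[..., 2].mean()
    rel_red = res.image[..., 0].mean() / textured_image[..., 0].mean()
    assert rel_blue > 1.05 and rel_red < 0.97


def test_warp_field_amplitude_bound(textured_image):
    amp = 1.5
    d = syn.DegradationSpec(blur_sigma_center=0, blur_sigma_edge=0,
                            chroma_gains=(1, 1, 1), intensity_gain_jitter=0,
                            warp_amplitude=amp, noise_sigma=0, seed=2)
    res = syn.degrade_to_smartphone(textured_image, d)
    mag = np.hypot(res.field[..., 0], res.field[..., 1])
    assert mag.max() == pytest.approx(amp)
    # warp ground truth: degraded samples clean at x + field
    from scipy import ndimage as ndi
    h, w = textured_image.shape[:2]
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    expect = np.stack([
        ndi.map_coordinates(textured_image[..., c],
                            [rows + res.field[..., 0],
                             cols + res.field[..., 1]],
                            order=1, mode="nearest")
        for c in range(3)], axis=-1)
    np.testing.assert_allclose(res.image, np.clip(expect, 0, 1), atol=1e-12)


def test_degradation_spec_validation():
    with pytest.raises(ValueError):
        syn.DegradationSpec(noise_sigma=-0.1)
    assert syn.IDENTITY_DEGRADATION.is_identity()
    assert not syn.DegradationSpec().is_identity()


def test_annotation_point_lies_on_cell_body(small_fov):
    _, mask, cells = small_fov
    for c in cells:
        if c.kind in ("normal", "sickle"):
            r, col = syn.annotation_point(c)
            want = syn.NORMAL if c.kind == "normal" else syn.SICKLE
            assert mask[int(round(r)), int(round(col))] == want


def test_ideal_probmap_is_valid_and_confident(small_fov):
    _, mask, _ = small_fov
    p = syn.ideal_probmap(mask)
    np.testing.assert_allclose(p.sum(axis=-1), 1.0)
    assert (p[mask == syn.NORMAL][:, 1] > 0.8).all()
    assert (p[mask == syn.SICKLE][:, 2] > 0.8).all()
    assert (p[mask == syn.BACKGROUND][:, 0] > 0.9).all()
    # normal cells stay below the 0.15 sickle-probability bar
    assert (p[mask == syn.NORMAL][:, 2] < 0.15).all()
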