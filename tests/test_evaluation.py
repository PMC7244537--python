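"""SSIM and Monte Carlo accuracy-vs-cell-count behavior."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from sicklescreen import evaluation as ev


# ---------------------------------------------------------------------------
# luminance + SSIM

def test_rgb_to_y_weights():
    img = np.zeros((1, 3, 3))
    img[0, 0] = (1, 0, 0)
    img[0, 1] = (0, 1, 0)
    img[0, 2] = (0, 0, 1)
    np.testing.assert_allclose(ev.rgb_to_y(img)[0], [0.299, 0.587, 0.114])
    with pytest.raises(ValueError):
        ev.rgb_to_y(np.zeros((4, 4)))


def _ssim_oracle(x, z, c1, c2):
    mx, mz = x.mean(), z.mean()
    vx = ((x - mx) ** 2).mean()
    vz = ((z - mz) ** 2).mean()
    cov = ((x - mx) * (z - mz)).mean()
    return ((2 * mx * mz + c1) * (2 * cov + c2)) / (
        (mx * mx + mz * mz + c1) * (vx + vz + c2))


def test_ssim_identity_is_one(rng):
    x = rng.random((16, 16))
    assert ev.ssim_global(x, x) == pytest.approx(1.0, abs=1e-12)


def test_ssim_symmetry_and_range(rng):
    x = rng.random((12, 12))
    z = rng.random((12, 12))
    s = ev.ssim_global(x, z)
    assert s == pytest.approx(ev.ssim_global(z, x), abs=1e-14)
    assert -1.0 <= s <= 1.0


def test_ssim_matches_oracle(rng):
    params = ev.SsimParams()
    c1, c2 = params.resolved()
    assert (c1, c2) == (0.01 ** 2, 0.03 ** 2)
    for _ in range(20):
        x = rng.random((8, 8))
        z = rng.random((8, 8))
        np.testing.assert_allclose(ev.ssim_global(x, z, params),
                                   _ssim_oracle(x, z, c1, c2),
                                   rtol=1e-12, atol=0)


def test_ssim_custom_stabilizers_and_validation():
    x = np.zeros((4, 4))
    # both images constant-zero: SSIM collapses to 1 by the stabilizers
    assert ev.ssim_global(x, x, ev.SsimParams(c1=1.0, c2=1.0)) == 1.0
    with pytest.raises(ValueError):
        ev.SsimParams(c1=-1.0).resolved()
    with pytest.raises(ValueError):
        ev.ssim_global(np.zeros((4, 4)), np.zeros((5, 4)))


def test_ssim_y_uses_luminance_only():
    rng = np.random.default_rng(0)
    base = rng.random((16, 16, 3))
    # pure chroma change with identical Y: swap R and B weighted to keep Y
    y = ev.rgb_to_y(base)
    other = np.stack([y, y, y], axis=-1)
    same_y = np.stack([y, y, y], axis=-1)
    assert ev.ssim_y(other, same_y) == pytest.approx(1.0, abs=1e-12)


def test_ssim_degrades_with_blur(small_fov):
    from scipy import ndimage as ndi

    img = small_fov[0]
    blurred = np.stack([ndi.gaussian_filter(img[..., c], 3.0)
                        for c in range(3)], axis=-1)
    assert ev.ssim_y(blurred, img) < ev.ssim_y(img, img) - 0.05


def test_ssim_report_two_arms(small_fov, rng):
    truth = small_fov[0]
    noisy = np.clip(truth + 0.1 * rng.standard_normal(truth.shape), 0, 1)
    close = np.clip(truth + 0.01 * rng.standard_normal(truth.shape), 0, 1)
    report = ev.ssim_report([noisy, noisy], [close, close], [truth, truth])
    assert set(report) == {"input", "output"}
    assert report["output"][0] > report["input"][0]
    for mean, sd in report.values():
        assert 0 <= mean <= 1 and sd >= 0
    with pytest.raises(ValueError):
        ev.ssim_report([truth], [], [truth])


# ---------------------------------------------------------------------------
# Monte Carlo subsampling

def _cohort():
    return ([ev.SlideCounts(400, 0, False) for _ in range(10)]
            + [ev.SlideCounts(400, 8, True) for _ in range(10)])


def test_mc_keep_one_reproduces_full_counts_exactly():
    curve = ev.mc_subsample_cells(_cohort(),
                                  ev.McConfig(n_reps=50,
                                              keep_fractions=(1.0,), seed=1))
    assert curve.accuracy_mean[0] == 1.0
    assert curve.accuracy_sd[0] == 0.0
    assert curve.auc_mean[0] == 1.0
    assert curve.auc_sd[0] == 0.0
    assert curve.mean_cells[0] == 400


def test_mc_deterministic_under_seed():
    cfg = ev.McConfig(n_reps=40, keep_fractions=(0.1, 0.5, 1.0), seed=9)
    a = ev.mc_subsample_cells(_cohort(), cfg)
    b = ev.mc_subsample_cells(_cohort(), cfg)
    np.testing.assert_array_equal(a.accuracy_mean, b.accuracy_mean)
    np.testing.assert_array_equal(a.auc_mean, b.auc_mean)


def test_mc_accuracy_matches_hypergeometric_closed_form():
    """Expected accuracy through the module equals the closed form.

    Cohort: one always-correct negative slide (0 sickle) and one positive
    slide (8/400).  The positive slide is called positive iff its kept
    sickle count exceeds 0.5% of kept cells, whose probability is a
    hypergeometric tail.
    """
    slides = [ev.SlideCounts(400, 0, False), ev.SlideCounts(400, 8, True)]
    cfg = ev.McConfig(n_reps=1000, keep_fractions=(0.25,), seed=4)
    curve = ev.mc_subsample_cells(slides, cfg)
    kept = round(0.25 * 400)
    bar = int(np.floor(0.005 * kept))  # call positive iff ks > bar
    p_pos = float(hypergeom(400, 8, kept).sf(bar))
    expect = (1.0 + p_pos) / 2.0
    se = curve.accuracy_sd[0] / np.sqrt(cfg.n_reps)
    assert abs(curve.accuracy_mean[0] - expect) <= 3 * max(se, 1e-3)


def test_mc_subsampled_percentage_unbiased():
    """Mean subsampled sickle pct equals the full pct within 3 MC s.e."""
    n_total, n_sickle = 500, 10
    full_pct = 100.0 * n_sickle / n_total
    rng = np.random.default_rng(11)
    for f in (0.1, 0.5):
        pcts = np.empty(1000)
        for rep in range(1000):
            kept, ks = ev.subsample_counts(np.array([n_total]),
                                           np.array([n_sickle]), f, rng)
            pcts[rep] = 100.0 * ks[0] / kept[0]
        se = pcts.std(ddof=1) / np.sqrt(len(pcts))
        assert abs(pcts.mean() - full_pct) <= 3 * se
        # and the draw respects the hypergeometric support
        kept_n = round(f * n_total)
        assert pcts.min() >= 0 and pcts.max() <= 100.0 * n_sickle / kept_n


def test_mc_accuracy_non_increasing_with_fewer_cells():
    cfg = ev.McConfig(n_reps=400, keep_fractions=(0.02, 0.1, 0.5, 1.0),
                      seed=2)
    curve = ev.mc_subsample_cells(_cohort(), cfg)
    acc = curve.accuracy_mean  # ordered smallest keep first
    assert np.all(np.diff(acc) >= -0.02)  # larger keep never clearly worse
    assert acc[-1] > acc[0]  # and full counts are genuinely better


def test_mc_validation():
    with pytest.raises(ValueError):
        ev.McConfig(n_reps=0)
    with pytest.raises(ValueError):
        ev.McConfig(keep_fractions=(0.0, 1.0))
    with pytest.raises(ValueError):
        ev.SlideCounts(5, 6, True)
    with pytest.raises(ValueError):
        ev.mc_subsample_cells([ev.SlideCounts(0, 0, False)], ev.McConfig())


def test_accuracy_vs_area_table():
    curve = ev.mc_subsample_cells(_cohort(),
                                  ev.McConfig(n_reps=20,
                                              keep_fractions=(0.5, 1.0)))
    df = ev.accuracy_vs_area_table(curve, cells_per_mm2=7700.0)
    assert list(df.columns) == ["keep_fraction", "mean_cells", "area_mm2",
                                "accuracy_mean", "accuracy_sd",
                                "auc_mean", "auc_sd"]
    np.testing.assert_allclose(df["area_mm2"], df["mean_cells"] / 7700.0)
    with pytest.raises(ValueError):
        ev.accuracy_vs_area_table(curve, 0.0)
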