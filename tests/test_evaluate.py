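"""Metric suite: PSNR, SSIM, MAE, air mismatch, ROIs, CNR, width trend."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cbctshade.evaluate import (
    MetricsReport,
    air_mismatch_mask,
    cnr,
    extract_rois,
    mae_hu,
    psnr,
    roi_hu_difference,
    ssim,
    volume_metrics,
    width_vs_mae,
)
from cbctshade.phantom import generate_phantom
from cbctshade.volume import LabelMap


# ---------------------------------------------------------------------------
# PSNR


def test_psnr_identical_images_is_infinite():
    a = np.random.default_rng(0).uniform(size=(32, 32))
    assert psnr(a, a) == float("inf")


def test_psnr_closed_form_20db():
    ref = np.zeros((10, 10))
    test = np.full((10, 10), 0.1)  # MSE 0.01, peak 1 -> 20 dB
    assert psnr(ref, test) == pytest.approx(20.0)


def test_psnr_matches_definitional_oracle():
    rng = np.random.default_rng(1)
    a, b = rng.uniform(size=(64, 64)), rng.uniform(size=(64, 64))
    manual = 10 * np.log10(1.0 / np.mean((a - b) ** 2))
    assert psnr(a, b) == pytest.approx(manual, abs=1e-9)


# ---------------------------------------------------------------------------
# SSIM


def test_ssim_self_similarity_is_one():
    a = np.random.default_rng(2).uniform(size=(64, 64))
    assert ssim(a, a) == pytest.approx(1.0)


def test_ssim_distinct_constants_closed_form():
    """For constant images only the stabilized luminance term survives."""
    a = np.full((32, 32), 0.2)
    b = np.full((32, 32), 0.6)
    c1 = (0.01 * 1.0) ** 2
    expected = (2 * 0.2 * 0.6 + c1) / (0.2**2 + 0.6**2 + c1)
    assert ssim(a, b) == pytest.approx(expected, abs=1e-9)


def test_ssim_bounded():
    rng = np.random.default_rng(3)
    for _ in range(5):
        v = ssim(rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32)))
        assert -1.0 <= v <= 1.0


def _ssim_oracle(ref, test, sigma=1.5, win=11, k1=0.01, k2=0.03, L=1.0):
    """Independent definitional SSIM: Gaussian window, population covariance."""
    half = win // 2
    g = np.exp(-0.5 * (np.arange(win) - half) ** 2 / sigma**2)
    kernel = np.outer(g, g)
    kernel /= kernel.sum()

    from scipy.signal import convolve2d

    def filt(x):
        return convolve2d(x, kernel, mode="valid")

    mu1, mu2 = filt(ref), filt(test)
    s11 = filt(ref * ref) - mu1**2
    s22 = filt(test * test) - mu2**2
    s12 = filt(ref * test) - mu1 * mu2
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    m = ((2 * mu1 * mu2 + c1) * (2 * s12 + c2)) / ((mu1**2 + mu2**2 + c1) * (s11 + s22 + c2))
    return float(m.mean())


def test_ssim_matches_independent_oracle():
    rng = np.random.default_rng(4)
    for _ in range(3):
        a = gaussian_filter(rng.uniform(size=(64, 64)), 2)
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        assert ssim(a, b) == pytest.approx(_ssim_oracle(a, b), abs=1e-6)


# ---------------------------------------------------------------------------
# air mismatch + MAE


def test_air_mismatch_rules():
    ct = np.array([[[20.0, -800.0, -800.0]]])
    cbct = np.array([[[25.0, -750.0, 10.0]]])
    mask = air_mismatch_mask(ct, cbct, air_threshold=-300.0)
    # matching tissue kept, matching air kept, mismatch dropped
    np.testing.assert_array_equal(mask[0, 0], [True, True, False])


def test_air_mismatch_no_subthreshold_keeps_all():
    ct = np.full((2, 4, 4), 100.0)
    assert air_mismatch_mask(ct, ct + 50.0).all()


def test_constructed_pocket_is_excluded():
    """Two phantoms differing only in rectal air pocket state: the excluded
    voxels are exactly the pocket (modulo the partial-volume shell)."""
    base = generate_phantom(300.0, 6, seed=101, grid_size=384)  # no pocket (seeded)
    with_pocket = base.copy()
    cz, cy, cx = 3, 250, 192
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in base.shape], indexing="ij")
    pocket = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= 6**2
    with_pocket.values[pocket] = -1000.0
    mask = air_mismatch_mask(base.values, with_pocket.values)
    excluded = ~mask
    assert excluded.sum() == pocket.sum()
    assert np.array_equal(excluded, pocket)


def test_mae_closed_forms():
    ref = np.random.default_rng(5).uniform(-500, 500, (4, 16, 16))
    assert mae_hu(ref, ref) == 0.0
    assert mae_hu(ref, ref + 50.0) == pytest.approx(50.0)


def test_mae_empty_mask_rejected():
    ref = np.zeros((2, 4, 4))
    with pytest.raises(ValueError, match="empty"):
        mae_hu(ref, ref, mask=np.zeros_like(ref, dtype=bool))


def test_masking_out_corruption_lowers_mae():
    rng = np.random.default_rng(6)
    ref = rng.uniform(0, 100, (2, 32, 32))
    test = ref.copy()
    test[:, :8, :8] += 500.0  # corrupted corner
    mask = np.ones_like(ref, dtype=bool)
    mask[:, :8, :8] = False
    assert mae_hu(ref, test, mask) < mae_hu(ref, test)


# ---------------------------------------------------------------------------
# ROIs


def test_extract_rois_containment_and_determinism(phantom_300):
    rois = extract_rois(phantom_300.labels, "muscle", 4, edge=8, seed=3)
    assert len(rois) == 4
    for r in rois:
        cube = phantom_300.labels.codes[r.slices()]
        assert cube.shape == (8, 8, 8)
        assert np.all(cube == cube.flat[0])
        assert phantom_300.labels.table[int(cube.flat[0])] == "muscle"
    again = extract_rois(phantom_300.labels, "muscle", 4, edge=8, seed=3)
    assert [r.corner for r in rois] == [r.corner for r in again]


def test_extract_rois_too_small_region_raises(phantom_300):
    with pytest.raises(ValueError, match="cortical_bone"):
        extract_rois(phantom_300.labels, "cortical_bone", 1, edge=8, seed=0)


def test_extract_rois_unknown_tissue(phantom_300):
    with pytest.raises(KeyError):
        extract_rois(phantom_300.labels, "bone_marrow", 1)


def test_roi_hu_difference_closed_forms(phantom_300):
    rois = extract_rois(phantom_300.labels, "fat", 3, edge=8, seed=1)
    same = roi_hu_difference(phantom_300.values, phantom_300.values, rois)
    assert np.allclose(same["abs_difference"], 0.0)
    shifted = roi_hu_difference(phantom_300.values, phantom_300.values - 100.0, rois)
    assert np.allclose(shifted["abs_difference"], 100.0)
    agg = shifted.groupby("tissue")["abs_difference"].agg(["mean", "std"])
    assert agg.loc["fat", "mean"] == pytest.approx(100.0)


def test_roi_hu_difference_empty_set_rejected(phantom_300):
    from cbctshade.evaluate import ROISet

    with pytest.raises(ValueError):
        roi_hu_difference(phantom_300.values, phantom_300.values, ROISet([]))


# ---------------------------------------------------------------------------
# CNR


def _two_rois():
    from cbctshade.evaluate import ROI

    return ROI((0, 0, 0), 4, "ctv"), ROI((0, 0, 8), 4, "muscle")


def test_cnr_closed_form_and_antisymmetry():
    fg, bg = _two_rois()
    rng = np.random.default_rng(7)
    img = np.zeros((4, 4, 16))
    img[:, :, :4] = 100.0 + rng.normal(0, 10, (4, 4, 4))
    img[:, :, 8:12] = rng.normal(0, 10, (4, 4, 4))
    v = cnr(img, fg, bg)
    sd = np.sqrt((img[fg.slices()].var() + img[bg.slices()].var()) / 2)
    assert v == pytest.approx((img[fg.slices()].mean() - img[bg.slices()].mean()) / sd)
    assert cnr(img, bg, fg) == pytest.approx(-v)


def test_cnr_equal_means_is_zero():
    fg, bg = _two_rois()
    rng = np.random.default_rng(8)
    img = rng.normal(50, 5, (4, 4, 16))
    img[bg.slices()] = img[fg.slices()]
    assert cnr(img, fg, bg) == pytest.approx(0.0)


def test_cnr_zero_sd_rejected():
    fg, bg = _two_rois()
    img = np.zeros((4, 4, 16))
    with pytest.raises(ValueError):
        cnr(img, fg, bg)


def test_cnr_same_tissue_rois_near_zero(phantom_300):
    """Two ROIs of the same tissue share a mean, so their CNR is ~0; a truly
    noise-free (constant) volume instead triggers the zero-SD guard."""
    rois = extract_rois(phantom_300.labels, "muscle", 2, edge=8, seed=5)
    fg, bg = rois.rois
    assert abs(cnr(phantom_300.values, fg, bg)) < 0.5
    with pytest.raises(ValueError):
        cnr(np.full((4, 4, 16), 45.0), *_two_rois())


# ---------------------------------------------------------------------------
# reports


def test_volume_metrics_shapes_and_tags(simulated_pair):
    cbct, ct = simulated_pair
    rep = volume_metrics(ct.values, cbct.values, "Base", fold_id=0, phantom_width=300.0)
    assert rep.model_tag == "Base"
    assert rep.mae_median > 0
    assert -1 <= rep.ssim_median <= 1


def test_width_vs_mae_rows_and_partition():
    reports = [
        MetricsReport("Base", 0, 260.0, mae_median=80.0),
        MetricsReport("Base", 1, 300.0, mae_median=120.0),
        MetricsReport("Base", 2, 340.0, mae_median=150.0),
        MetricsReport("FT2", 0, 260.0, mae_median=40.0),
    ]
    df, corr = width_vs_mae(reports)
    assert len(df) == 4
    assert set(df["model_tag"]) == {"Base", "FT2"}
    assert corr["Base"] == pytest.approx(1.0)  # perfectly increasing
    assert np.isnan(corr["FT2"])  # too few points for a rank correlation


def test_width_vs_mae_single_report():
    df, _ = width_vs_mae([MetricsReport("Base", 0, 300.0, mae_median=100.0)])
    assert len(df) == 1


def test_base_mae_increases_with_pelvis_width(desk_geometry):
    """Wider bodies suffer more truncation, so uncorrected (Base) HU error
    grows with pelvis width: positive rank correlation."""
    from cbctshade.phantom import generate_phantom
    from cbctshade.pipeline import _center_crop
    from cbctshade.simulator import PhysicsConfig, simulate_cbct

    reports = []
    for i, w in enumerate([250.0, 300.0, 350.0, 400.0]):
        ct = generate_phantom(w, 1, seed=50 + i, grid_size=512)
        cbct = simulate_cbct(ct, desk_geometry, PhysicsConfig(), seed=50 + i)
        reports.append(
            volume_metrics(_center_crop(ct, 220).values, cbct.values, "Base", i, w)
        )
    _, corr = width_vs_mae(reports)
    assert corr["Base"] > 0.5
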