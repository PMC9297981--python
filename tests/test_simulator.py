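"""Simulator: attenuation mapping, projector, physics, Ohnesorge, FBP."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from cbctshade.phantom import uniform_ellipse_phantom
from cbctshade.simulator import (
    Geometry,
    PhysicsConfig,
    Sinogram,
    apply_physics,
    attenuation_to_hu,
    forward_project,
    hu_to_attenuation,
    ohnesorge_correct,
    parker_weights,
    reconstruct_fbp,
    simulate_cbct,
)
from cbctshade.volume import Volume


# ---------------------------------------------------------------------------
# HU <-> attenuation


@pytest.mark.parametrize(
    "hu,mu",
    [(-1000.0, 0.0), (0.0, 1000.0 / 2**16), (3100.0, 4100.0 / 2**16)],
)
def test_hu_to_attenuation_values(hu, mu):
    vol = Volume(np.full((1, 4, 4), hu, dtype=np.float32))
    out = hu_to_attenuation(vol)
    np.testing.assert_allclose(out.values, mu, atol=1e-12)


def test_hu_below_air_clipped():
    vol = Volume(np.full((1, 2, 2), -1000.0))
    vol.values[...] = -1500.0  # bypass constructor check deliberately
    assert hu_to_attenuation(vol).values.min() == 0.0


def test_attenuation_roundtrip():
    hu = np.linspace(-1000, 3100, 64)
    np.testing.assert_allclose(attenuation_to_hu((hu + 1000) / 2**16), hu, atol=1e-9)


# ---------------------------------------------------------------------------
# geometry


def test_geometry_defaults_give_208mm_fov():
    g = Geometry()
    assert abs(g.fov_mm - 208.0) < 0.5
    assert g.min_arc_degrees < 220.0


def test_geometry_invalid_distances_rejected():
    with pytest.raises(ValueError):
        Geometry(source_to_isocenter=1700.0, source_to_detector=1672.0)


def test_geometry_short_scan_minimum_enforced():
    with pytest.raises(ValueError, match="short-scan"):
        Geometry(arc_degrees=170.0)


# ---------------------------------------------------------------------------
# forward projection


def test_uniform_disk_central_chord(desk_geometry):
    """Central bin of a centred disk = diameter x mu at every view."""
    n = 256
    x = np.arange(n) - (n - 1) / 2.0
    yy, xx = np.meshgrid(x, x, indexing="ij")
    sl = np.where(xx**2 + yy**2 <= 50.0**2, 0.01, 0.0)
    sino = forward_project(sl, desk_geometry, 1.0)
    central = sino.values[:, sino.values.shape[1] // 2]
    np.testing.assert_allclose(central, 1.0, rtol=0.01)


def test_zero_slice_projects_to_zero(desk_geometry):
    sino = forward_project(np.zeros((64, 64)), desk_geometry, 1.0)
    assert np.all(sino.values == 0.0)


def test_projector_matches_brute_force_oracle():
    """Ray-driven integrals vs an independent 10x-oversampled oracle."""
    g = Geometry(n_views=30, detector_pitch=0.776, active_width=120.0)
    rng = np.random.default_rng(4)
    rel = []
    for _ in range(3):
        sl = rng.uniform(0.0, 0.02, (32, 32))
        sino = forward_project(sl, g, 1.0)  # default step: 0.5 x spacing
        oracle = _oracle_project(sl, g, 1.0, step=0.05)
        rel.append(np.linalg.norm(sino.values - oracle) / np.linalg.norm(oracle))
    assert max(rel) < 0.01


def _oracle_project(sl, g, spacing, step):
    """Brute-force fan-beam line integrals (independent implementation)."""
    n = sl.shape[0]
    half = (n - 1) / 2.0
    angles = np.radians(g.view_angles_deg)
    s = g.bin_centers_mm
    r_max = half * spacing * np.sqrt(2.0)
    out = np.zeros((len(angles), len(s)))
    for v, beta in enumerate(angles):
        nvec = np.array([np.cos(beta), np.sin(beta)])
        tvec = np.array([-np.sin(beta), np.cos(beta)])
        src = g.source_to_isocenter * nvec
        det = src - g.source_to_detector * nvec
        pts = det[None, :] + s[:, None] * tvec[None, :]
        d = pts - src[None, :]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        t0 = g.source_to_isocenter - r_max
        t1 = g.source_to_isocenter + r_max
        ts = np.arange(t0, t1, step)
        # sample points: (nbins, nsamples, 2)
        p = src[None, None, :] + ts[None, :, None] * d[:, None, :]
        gx = p[..., 0] / spacing + half
        gy = p[..., 1] / spacing + half
        vals = map_coordinates(sl, [gy.ravel(), gx.ravel()], order=1, cval=0.0)
        out[v] = vals.reshape(len(s), len(ts)).sum(axis=1) * step
    return out


def test_degenerate_geometry_rejected():
    g = Geometry(n_views=10)
    with pytest.raises(ValueError, match="degenerate"):
        forward_project(np.zeros((4096, 4096)), g, 1.0)


# ---------------------------------------------------------------------------
# physics


def test_identity_physics_is_bit_exact(disk_sinogram):
    _, sino = disk_sinogram
    out = apply_physics(sino, PhysicsConfig(0.0, 1.0, 0.0), seed=0)
    assert np.array_equal(out.values, sino.values)


def test_scatter_only_reduces_attenuation(disk_sinogram):
    _, sino = disk_sinogram
    out = apply_physics(
        sino, PhysicsConfig(scatter_factor=0.001, beam_hardening_factor=1.0, noise_factor=0.0), seed=0
    )
    assert np.all(out.values <= sino.values + 1e-12)


def test_physics_seeded_determinism(disk_sinogram):
    _, sino = disk_sinogram
    cfg = PhysicsConfig()
    a = apply_physics(sino, cfg, seed=5)
    b = apply_physics(sino, cfg, seed=5)
    c = apply_physics(sino, cfg, seed=6)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_physics_config_validation():
    with pytest.raises(ValueError):
        PhysicsConfig(scatter_factor=-0.1)
    with pytest.raises(ValueError):
        PhysicsConfig(beam_hardening_factor=0.9)


# ---------------------------------------------------------------------------
# Ohnesorge truncation handling


def test_untruncated_rows_pass_through(disk_sinogram):
    _, sino = disk_sinogram
    out = ohnesorge_correct(sino, 0.30)
    np.testing.assert_allclose(out.values, sino.values, atol=1e-9)
    left, right = out.extension
    assert np.all(left == 0.0) and np.all(right == 0.0)


def test_truncated_row_extension_continuous_and_decaying(desk_geometry):
    ph = uniform_ellipse_phantom(340.0, 1, hu=45.0, grid_size=448)
    sino = forward_project(hu_to_attenuation(ph).values[0], desk_geometry, 1.0)
    out = ohnesorge_correct(sino, 0.30)
    left, right = out.extension
    row = out.values[0]
    # continuity: first extension sample within 1% of the edge value
    assert abs(right[0, 0] - row[-1]) <= 0.01 * abs(row[-1])
    assert abs(left[0, -1] - row[0]) <= 0.01 * abs(row[0])
    # rolloff reaches zero at the far end
    assert right[0, -1] == 0.0 and left[0, 0] == 0.0


def test_extension_fraction_must_be_positive(disk_sinogram):
    _, sino = disk_sinogram
    with pytest.raises(ValueError):
        ohnesorge_correct(sino, 0.0)


# ---------------------------------------------------------------------------
# FBP


def test_parker_weights_conjugate_pairs_sum_to_one(desk_geometry):
    """Defining property of short-scan redundancy weighting."""
    g = desk_geometry
    arc = np.radians(g.arc_degrees)
    gamma = np.linspace(-g.half_fan_angle, g.half_fan_angle, 41)
    betas = np.radians(g.view_angles_deg)
    w = parker_weights(g, gamma)

    def weight_at(beta, gam):
        # continuous evaluation by re-deriving from the same formula
        delta = (arc - np.pi) / 2.0
        if beta < 2 * (delta + gam):
            return np.sin(np.pi / 4 * beta / (delta + gam)) ** 2
        if beta > np.pi + 2 * gam:
            return np.sin(np.pi / 4 * (arc - beta) / (delta - gam)) ** 2
        return 1.0

    rng = np.random.default_rng(0)
    for _ in range(200):
        gam = float(rng.uniform(-g.half_fan_angle, g.half_fan_angle))
        beta = float(rng.uniform(0, 2 * ((arc - np.pi) / 2 + gam)))
        conj = beta + np.pi - 2 * gam
        if 0 <= conj <= arc:
            total = weight_at(beta, gam) + weight_at(conj, -gam)
            assert abs(total - 1.0) < 1e-6
    assert w.shape == (g.n_views, gamma.size)
    assert np.all((w >= -1e-12) & (w <= 1 + 1e-12))


def test_zero_sinogram_reconstructs_to_air(desk_geometry):
    sino = Sinogram(
        np.zeros((desk_geometry.n_views, desk_geometry.detector_bins)),
        desk_geometry,
        desk_geometry.view_angles_deg,
    )
    rec = reconstruct_fbp(sino, desk_geometry, 128, 1.0)
    np.testing.assert_allclose(rec, -1000.0, atol=1e-6)


def test_fbp_recovers_uniform_disk(disk_sinogram, desk_geometry):
    """Physics-free untruncated 0-HU disk: small interior bias and RMSE."""
    _, sino = disk_sinogram
    rec = reconstruct_fbp(sino, desk_geometry, 220, 1.0)
    n = 220
    x = np.arange(n) - (n - 1) / 2.0
    yy, xx = np.meshgrid(x, x, indexing="ij")
    interior = xx**2 + yy**2 <= 60.0**2
    assert abs(rec[interior].mean()) < 20.0
    assert np.sqrt((rec[interior] ** 2).mean()) < 50.0


def test_truncation_correction_reduces_edge_error(desk_geometry):
    """Paired reconstruction of a truncated body: corrected beats uncorrected
    in the outer 5-mm annulus of the FOV."""
    ph = uniform_ellipse_phantom(340.0, 1, hu=45.0, grid_size=448)
    sino = forward_project(hu_to_attenuation(ph).values[0], desk_geometry, 1.0)
    rec_raw = reconstruct_fbp(sino, desk_geometry, 220, 1.0)
    rec_cor = reconstruct_fbp(ohnesorge_correct(sino, 0.30), desk_geometry, 220, 1.0)
    n = 220
    x = np.arange(n) - (n - 1) / 2.0
    yy, xx = np.meshgrid(x, x, indexing="ij")
    r = np.sqrt(xx**2 + yy**2)
    fov_r = desk_geometry.fov_mm / 2.0
    annulus = (r >= fov_r - 5.0) & (r <= fov_r)
    truth = np.where((xx / 170.0) ** 2 + (yy / (0.68 * 170.0)) ** 2 <= 1.0, 45.0, -1000.0)
    err_raw = np.abs(rec_raw - truth)[annulus].mean()
    err_cor = np.abs(rec_cor - truth)[annulus].mean()
    assert err_cor < err_raw


def test_simulate_cbct_shape_and_determinism(desk_geometry):
    ph = uniform_ellipse_phantom(250.0, 2, hu=45.0, grid_size=384)
    a = simulate_cbct(ph, desk_geometry, PhysicsConfig(), seed=3, out_size=220)
    b = simulate_cbct(ph, desk_geometry, PhysicsConfig(), seed=3, out_size=220)
    assert a.shape == (2, 220, 220)
    assert a.spacing == 1.0
    assert np.array_equal(a.values, b.values)


def test_closed_loop_physics_off(desk_geometry):
    """Identity physics + untruncated body: CBCT ~ CT inside the body."""
    ph = uniform_ellipse_phantom(190.0, 1, hu=45.0, grid_size=384)
    out = simulate_cbct(ph, desk_geometry, PhysicsConfig(0.0, 1.0, 0.0), seed=0, out_size=220)
    n = 220
    x = np.arange(n) - (n - 1) / 2.0
    yy, xx = np.meshgrid(x, x, indexing="ij")
    inside = (xx / 85.0) ** 2 + (yy / (0.68 * 85.0)) ** 2 <= 1.0
    mae = np.abs(out.values[0][inside] - 45.0).mean()
    assert mae < 50.0
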