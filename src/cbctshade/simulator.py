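"""Narrow-FOV CBCT simulation: projection, physics corruption, reconstruction.

The simulator turns a CT-like HU volume into an artifact-bearing CBCT volume:

1. HU -> linear-attenuation-like units ("CTmu"),
2. per-axial-slice fan-beam forward projection under the treatment-room
   geometry (the central cone-beam plane is exactly a fan beam, and training
   and evaluation are axial-slice based, so 2D fan beam per slice stands in
   for the 3D cone),
3. a parametric scatter / beam-hardening / noise model applied to the
   projections in intensity space,
4. detector-limited truncation (the detector simply ends: the sinogram only
   ever contains the active bins) with optional Ohnesorge-style mirrored
   cosine extrapolation used during filtering,
5. short-scan filtered backprojection (cosine pre-weighting, generalized
   Parker redundancy weighting for a 220-degree arc, Ram-Lak filtering,
   distance-weighted backprojection).

Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit, prange
from scipy.ndimage import gaussian_filter1d

from .volume import Volume

HU_SCALE = 2.0**16  # CTmu = (HU + 1000) / 2^16


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class Geometry:
    """Fan-beam acquisition geometry (distances in mm, angles in degrees)."""

    source_to_isocenter: float = 1172.0
    source_to_detector: float = 1672.0
    arc_degrees: float = 220.0
    n_views: int = 500
    detector_pitch: float = 0.388
    detector_bins: int | None = None
    active_width: float | None = None

    def __post_init__(self) -> None:
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise ValueError("need source_to_detector > source_to_isocenter > 0")
        if self.active_width is None:
            # collimated so the FOV diameter at isocenter is 208 mm
            self.active_width = 208.0 * self.source_to_detector / self.source_to_isocenter
        if self.detector_bins is None:
            self.detector_bins = int(np.ceil(self.active_width / self.detector_pitch - 1e-9))
        if self.active_width > self.detector_bins * self.detector_pitch + 1e-6:
            raise ValueError("active_width exceeds physical detector span")
        if self.arc_degrees < self.min_arc_degrees - 1e-9:
            raise ValueError(
                f"arc {self.arc_degrees} deg below short-scan minimum "
                f"{self.min_arc_degrees:.2f} deg"
            )

    @property
    def half_fan_angle(self) -> float:
        """Half fan angle in radians (to the edge of the active detector)."""
        return float(np.arctan(0.5 * self.active_width / self.source_to_detector))

    @property
    def min_arc_degrees(self) -> float:
        return 180.0 + 2.0 * np.degrees(self.half_fan_angle)

    @property
    def fov_mm(self) -> float:
        """FOV diameter at isocenter implied by the active detector width."""
        return self.active_width * self.source_to_isocenter / self.source_to_detector

    @property
    def view_angles_deg(self) -> np.ndarray:
        return np.linspace(0.0, self.arc_degrees, self.n_views, endpoint=False)

    @property
    def bin_centers_mm(self) -> np.ndarray:
        """Physical detector coordinates of the active bin centres."""
        n = self.detector_bins
        return (np.arange(n) - (n - 1) / 2.0) * self.detector_pitch


@dataclass
class PhysicsConfig:
    """Parametric projection-domain corruption model.

    ``(scatter_factor, beam_hardening_factor, noise_factor) = (0, 1, 0)`` is
    the exact identity.  The model is a documented stand-in: scatter is an
    additive low-frequency intensity term, beam hardening a compressive power
    law on post-log attenuation, noise additive Gaussian in intensity space.
    """

    scatter_factor: float = 0.001
    beam_hardening_factor: float = 1.005
    noise_factor: float = 0.001
    scatter_kernel_width: float = 300.0
    scatter_gain: float = 25.0
    intensity_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.scatter_factor < 0 or self.noise_factor < 0:
            raise ValueError("scatter_factor and noise_factor must be >= 0")
        if self.beam_hardening_factor < 1.0:
            raise ValueError("beam_hardening_factor < 1 is not a no-op-or-more")

    @property
    def is_identity(self) -> bool:
        return (
            self.scatter_factor == 0.0
            and self.beam_hardening_factor == 1.0
            and self.noise_factor == 0.0
        )


@dataclass
class Sinogram:
    """views x detector-bins grid of post-log line integrals."""

    values: np.ndarray
    geometry: Geometry
    view_angles_deg: np.ndarray
    extension: tuple[np.ndarray, np.ndarray] | None = None  # (left, right)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != self.geometry.n_views:
            raise ValueError("sinogram row count must equal geometry.n_views")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")


@dataclass
class AttenuationVolume:
    """3D grid of linear-attenuation-like units (per mm)."""

    values: np.ndarray
    spacing: float = 1.0


# ---------------------------------------------------------------------------
# HU <-> attenuation


def hu_to_attenuation(ct: Volume) -> AttenuationVolume:
    """Map HU to attenuation-like units: CTmu = (HU + 1000) / 2^16.

    HU below -1000 are clipped (air is the physical floor).
    """
    hu = np.maximum(ct.values, -1000.0)
    return AttenuationVolume((hu + 1000.0) / HU_SCALE, ct.spacing)


def attenuation_to_hu(mu: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hu_to_attenuation` on raw arrays."""
    return mu * HU_SCALE - 1000.0


# ---------------------------------------------------------------------------
# forward projection (ray-driven, numba)


@njit(cache=True, fastmath=True)
def _project_kernel(img, spacing, n_grid, sid, sdd, angles, s_coords, step, out):
    half = (n_grid - 1) / 2.0
    # circle circumscribing the grid: rays are integrated only inside it
    r_grid = half * spacing * 1.4143
    for v in range(angles.shape[0]):
        beta = angles[v]
        nx_, ny_ = np.cos(beta), np.sin(beta)
        tx, ty = -np.sin(beta), np.cos(beta)
        sx_, sy_ = sid * nx_, sid * ny_
        for j in range(s_coords.shape[0]):
            # detector bin centre in world coordinates
            px = sx_ - sdd * nx_ + s_coords[j] * tx
            py = sy_ - sdd * ny_ + s_coords[j] * ty
            dx, dy = px - sx_, py - sy_
            norm = np.sqrt(dx * dx + dy * dy)
            dx /= norm
            dy /= norm
            # ray / circle intersection: |S + t d|^2 = r_grid^2
            b_half = sx_ * dx + sy_ * dy
            c = sx_ * sx_ + sy_ * sy_ - r_grid * r_grid
            disc = b_half * b_half - c
            if disc <= 0.0:
                out[v, j] = 0.0
                continue
            sq = np.sqrt(disc)
            t0 = -b_half - sq
            t1 = -b_half + sq
            acc = 0.0
            n_steps = int((t1 - t0) / step) + 1
            for k in range(n_steps):
                t = t0 + (k + 0.5) * step
                if t > t1:
                    break
                wx = sx_ + t * dx
                wy = sy_ + t * dy
                gx = wx / spacing + half
                gy = wy / spacing + half
                ix = int(np.floor(gx))
                iy = int(np.floor(gy))
                if ix < 0 or iy < 0 or ix >= n_grid - 1 or iy >= n_grid - 1:
                    continue
                fx = gx - ix
                fy = gy - iy
                v00 = img[iy, ix]
                v01 = img[iy, ix + 1]
                v10 = img[iy + 1, ix]
                v11 = img[iy + 1, ix + 1]
                acc += (
                    v00 * (1 - fx) * (1 - fy)
                    + v01 * fx * (1 - fy)
                    + v10 * (1 - fx) * fy
                    + v11 * fx * fy
                )
            out[v, j] = acc * step


def forward_project(
    slice_mu: np.ndarray,
    geometry: Geometry,
    spacing: float = 1.0,
    step: float | None = None,
) -> Sinogram:
    """Fan-beam line integrals of a 2D attenuation slice.

    Each sinogram entry is the integral of attenuation (per mm) along the ray
    from the source to the detector-bin centre, in dimensionless attenuation
    units.  Bins beyond the active width simply do not exist, so truncation
    arises naturally when the object exceeds the FOV.

    ``step`` is the ray sampling step in mm (default: half the voxel spacing).
    """
    slice_mu = np.ascontiguousarray(slice_mu, dtype=np.float64)
    if slice_mu.ndim != 2 or slice_mu.shape[0] != slice_mu.shape[1]:
        raise ValueError("forward_project expects a square 2D slice")
    n_grid = slice_mu.shape[0]
    if n_grid * spacing / 2.0 * np.sqrt(2.0) >= geometry.source_to_isocenter:
        raise ValueError("degenerate geometry: source inside the object grid")
    if step is None:
        step = 0.5 * spacing
    angles = np.radians(geometry.view_angles_deg)
    out = np.empty((geometry.n_views, geometry.detector_bins), dtype=np.float64)
    _project_kernel(
        slice_mu,
        float(spacing),
        n_grid,
        geometry.source_to_isocenter,
        geometry.source_to_detector,
        angles,
        geometry.bin_centers_mm,
        float(step),
        out,
    )
    return Sinogram(out, geometry, geometry.view_angles_deg.copy())


# ---------------------------------------------------------------------------
# physics corruption


def apply_physics(sino: Sinogram, physics: PhysicsConfig, seed: int) -> Sinogram:
    """Apply scatter, beam hardening and noise to a sinogram (seeded).

    Work happens in intensity space with I0 = 1: beam hardening compresses
    post-log attenuation (p -> p^(1/f), unchanged at p = 1), scatter adds a
    low-frequency term ``scatter_factor * smooth(I)`` (Gaussian smoothing of
    width ``scatter_kernel_width`` mm along the detector), and Gaussian noise
    of SD ``noise_factor`` is added in intensity.  The identity configuration
    (0, 1, 0) returns the input bit-identically.
    """
    if physics.is_identity:
        return Sinogram(
            sino.values.copy(), sino.geometry, sino.view_angles_deg.copy(), sino.extension
        )
    p = sino.values
    if physics.beam_hardening_factor != 1.0:
        p = np.sign(p) * np.abs(p) ** (1.0 / physics.beam_hardening_factor)
    intensity = np.exp(-p)
    if physics.scatter_factor > 0.0:
        # S = sf * gain * smooth(I): the kernel width (default 300 mm) is much
        # larger than the detector so the scatter background is genuinely
        # low-frequency, and the gain fixes the scatter-to-primary ratio at
        # the order-one level a pelvis shadow produces for the default factor
        sigma_bins = physics.scatter_kernel_width / sino.geometry.detector_pitch
        smooth = gaussian_filter1d(intensity, sigma_bins, axis=1, mode="nearest")
        intensity = intensity + physics.scatter_factor * physics.scatter_gain * smooth
    if physics.noise_factor > 0.0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, physics.noise_factor, size=intensity.shape)
    intensity = np.maximum(intensity, physics.intensity_floor)
    return Sinogram(-np.log(intensity), sino.geometry, sino.view_angles_deg.copy())


# ---------------------------------------------------------------------------
# Ohnesorge-style truncation correction


def ohnesorge_correct(
    sino: Sinogram, extension_fraction: float = 0.30, edge_threshold: float = 0.02
) -> Sinogram:
    """Extend truncated rows with a mirrored, cosine-weighted rolloff.

    Each row whose edge value exceeds ``edge_threshold`` (attenuation units)
    is extended on that side by ``extension_fraction`` of the active detector
    width; the extension mirrors the row about the edge and decays with a
    cosine from the edge value to zero.  The extension is stored as metadata
    and used only during ramp filtering; the returned sinogram keeps the
    original bin support.  Untruncated rows pass through unchanged (their
    extensions are zero).
    """
    if extension_fraction <= 0:
        raise ValueError("extension_fraction must be > 0")
    vals = sino.values
    n_views, n_bins = vals.shape
    n_ext = int(round(extension_fraction * n_bins))
    left = np.zeros((n_views, n_ext))
    right = np.zeros((n_views, n_ext))
    k = np.arange(1, n_ext + 1)
    taper = np.cos(np.pi * k / (2.0 * n_ext))
    taper[-1] = 0.0  # exact zero at the extension end
    # mirror about the edge sample itself (half-sample shift) so the first
    # extension sample is continuous with the measured edge value
    for v in range(n_views):
        row = vals[v]
        if row[0] > edge_threshold:
            mirror = row[np.minimum(k - 1, n_bins - 1)]
            left[v] = (mirror * taper)[::-1]
        if row[-1] > edge_threshold:
            mirror = row[n_bins - 1 - np.minimum(k - 1, n_bins - 1)]
            right[v] = mirror * taper
    return Sinogram(vals.copy(), sino.geometry, sino.view_angles_deg.copy(), (left, right))


# ---------------------------------------------------------------------------
# short-scan filtered backprojection


def parker_weights(geometry: Geometry, gamma: np.ndarray) -> np.ndarray:
    """Generalized Parker redundancy weights for an over-complete short scan.

    ``gamma`` is the signed fan angle of each detector coordinate.  For arc
    A = pi + 2*delta, rays measured twice receive smooth sin^2 weights whose
    conjugate pairs sum to one; singly-measured rays get weight one.
    Returns an ``(n_views, len(gamma))`` array.
    """
    arc = np.radians(geometry.arc_degrees)
    delta = (arc - np.pi) / 2.0
    beta = np.radians(geometry.view_angles_deg)[:, None]
    g = gamma[None, :]
    w = np.ones((beta.shape[0], gamma.shape[0]))
    start = beta < 2.0 * (delta + g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ws = np.sin(np.pi / 4.0 * beta / (delta + g)) ** 2
        we = np.sin(np.pi / 4.0 * (arc - beta) / (delta - g)) ** 2
    end = beta > np.pi + 2.0 * g
    w = np.where(start, ws, w)
    w = np.where(end, we, w)
    return w


def _ramp_kernel(n: int, tau: float, apodize: bool) -> np.ndarray:
    """FFT of the band-limited (Shepp-Logan-free) Ram-Lak kernel, length n."""
    k = np.concatenate([np.arange(0, n // 2 + 1), np.arange(n // 2 - 1, 0, -1)])
    h = np.zeros(n)
    h[0] = 1.0 / (4.0 * tau * tau)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * tau) ** 2
    H = np.real(np.fft.fft(h))
    if apodize:
        f = np.fft.fftfreq(n, d=tau)
        f_nyq = 1.0 / (2.0 * tau)
        H = H * np.cos(np.pi * f / (2.0 * f_nyq))
    return H


@njit(parallel=False, cache=True, fastmath=True)
def _backproject_kernel(filtered, angles, u_coords, sid, n_out, out_spacing, fov_radius, out):
    half = (n_out - 1) / 2.0
    n_views = filtered.shape[0]
    n_u = u_coords.shape[0]
    u0 = u_coords[0]
    du = u_coords[1] - u_coords[0]
    dbeta = angles[1] - angles[0] if n_views > 1 else 2 * np.pi
    for iy in range(n_out):
        py = (iy - half) * out_spacing
        for ix in range(n_out):
            px = (ix - half) * out_spacing
            if px * px + py * py > fov_radius * fov_radius:
                out[iy, ix] = np.nan
                continue
            acc = 0.0
            for v in range(n_views):
                beta = angles[v]
                nx_, ny_ = np.cos(beta), np.sin(beta)
                tx, ty = -np.sin(beta), np.cos(beta)
                denom = sid - (px * nx_ + py * ny_)
                u = sid * (px * tx + py * ty) / denom
                uu = (u - u0) / du
                i0 = int(np.floor(uu))
                if i0 < 0 or i0 >= n_u - 1:
                    continue
                fu = uu - i0
                val = filtered[v, i0] * (1 - fu) + filtered[v, i0 + 1] * fu
                big_u = denom / sid
                acc += val / (big_u * big_u)
            out[iy, ix] = acc * dbeta


def reconstruct_fbp(
    sino: Sinogram,
    geometry: Geometry | None = None,
    out_size: int = 220,
    out_spacing: float = 1.0,
    apodize: bool = True,
) -> np.ndarray:
    """Short-scan fan-beam FBP of one sinogram onto a centred HU grid.

    Pipeline: rebin to the virtual detector at the isocenter, cosine
    pre-weighting, generalized Parker redundancy weighting, Ram-Lak ramp
    filtering (with optional cosine apodization; Ohnesorge extensions, when
    present, take part in the filtering only), distance-weighted
    backprojection, and inversion of the HU -> attenuation mapping.  Voxels
    outside the FOV circle are set to -1000 HU.
    """
    geometry = geometry or sino.geometry
    if geometry.arc_degrees < geometry.min_arc_degrees - 1e-9:
        raise ValueError("arc below the short-scan minimum")
    sid, sdd = geometry.source_to_isocenter, geometry.source_to_detector
    mag = sid / sdd
    tau = geometry.detector_pitch * mag
    u = geometry.bin_centers_mm * mag  # virtual detector at isocenter
    n_bins = u.shape[0]

    if sino.extension is not None:
        left, right = sino.extension
        n_ext = left.shape[1]
        vals = np.concatenate([left, sino.values, right], axis=1)
        u_full = (np.arange(n_bins + 2 * n_ext) - (n_bins + 2 * n_ext - 1) / 2.0) * tau
    else:
        n_ext = 0
        vals = sino.values
        u_full = u

    gamma = np.arctan(u_full / sid)
    cosw = sid / np.sqrt(sid**2 + u_full**2)
    parker = parker_weights(geometry, gamma)
    weighted = vals * cosw[None, :] * parker

    n_fft = 1
    while n_fft < 2 * weighted.shape[1]:
        n_fft *= 2
    H = _ramp_kernel(n_fft, tau, apodize)
    filt = np.real(np.fft.ifft(np.fft.fft(weighted, n=n_fft, axis=1) * H[None, :], axis=1))
    filt = filt[:, : weighted.shape[1]] * tau
    if n_ext:
        filt = filt[:, n_ext : n_ext + n_bins]  # extension used only during filtering

    out = np.empty((out_size, out_size), dtype=np.float64)
    _backproject_kernel(
        np.ascontiguousarray(filt),
        np.radians(sino.view_angles_deg),
        u,
        sid,
        out_size,
        out_spacing,
        geometry.fov_mm / 2.0,
        out,
    )
    hu = attenuation_to_hu(out)
    hu[~np.isfinite(hu)] = -1000.0
    return hu


# ---------------------------------------------------------------------------
# orchestration


def simulate_cbct(
    ct: Volume,
    geometry: Geometry | None = None,
    physics: PhysicsConfig | None = None,
    seed: int = 0,
    out_size: int = 220,
    out_spacing: float = 1.0,
    truncation_correction: float | None = 0.30,
    projection_step: float | None = None,
) -> Volume:
    """Simulate a narrow-FOV CBCT volume from a CT-like volume.

    Per axial slice: HU -> attenuation -> fan-beam projection -> physics
    corruption -> (optional) Ohnesorge truncation handling -> short-scan FBP
    onto an ``out_size`` x ``out_size`` grid at ``out_spacing`` mm.  The output
    volume keeps the input's slice count and is voxel-aligned with it (both
    are centred on the isocenter).
    """
    geometry = geometry or Geometry()
    physics = physics or PhysicsConfig()
    mu = hu_to_attenuation(ct)
    n_slices = mu.values.shape[0]
    rng = np.random.default_rng(seed)
    slice_seeds = rng.integers(0, 2**31 - 1, size=n_slices)
    out = np.empty((n_slices, out_size, out_size), dtype=np.float32)
    for k in range(n_slices):
        sino = forward_project(mu.values[k], geometry, mu.spacing, step=projection_step)
        sino = apply_physics(sino, physics, int(slice_seeds[k]))
        if truncation_correction is not None:
            sino = ohnesorge_correct(sino, truncation_correction)
        out[k] = reconstruct_fbp(sino, geometry, out_size, out_spacing)
    z0 = -(n_slices - 1) / 2.0 * ct.spacing
    half = (out_size - 1) / 2.0 * out_spacing
    return Volume(out, out_spacing, (z0, -half, -half))
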