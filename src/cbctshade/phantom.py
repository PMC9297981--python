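"""Seeded digital pelvis phantoms.

The generator emulates the gross anatomy of a pelvic CT at the level the
shading-correction method cares about: a body ellipse with a subcutaneous fat
layer over a muscle background, two femoral heads of spongy bone wrapped in a
thin cortical shell, an anterior bladder, a posterior rectum tube whose lumen
may contain seeded air pockets, and a central clinical target volume (CTV).
Anatomical realism is deliberately coarse - geometric primitives with seeded
Gaussian HU texture - because the correction network is anatomy-agnostic at
this level; what matters downstream is that the body can exceed the 208-mm
reconstruction FOV (variable pelvis width) and that every tissue has a known
nominal HU for ROI analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import TISSUE_CODES, LabelMap, Volume

_NAME_TO_CODE = {name: code for code, name in TISSUE_CODES.items()}

AIR_HU = -1000.0


def _default_means() -> dict[str, float]:
    # standard radiology ranges; configurable, never asserted against any source
    return {
        "air": AIR_HU,
        "fat": -100.0,
        "muscle": 45.0,
        "spongy_bone": 300.0,
        "cortical_bone": 700.0,
        "bladder": 15.0,
        "ctv": 50.0,
    }


def _default_sds() -> dict[str, float]:
    return {
        "air": 0.0,
        "fat": 12.0,
        "muscle": 12.0,
        "spongy_bone": 20.0,
        "cortical_bone": 20.0,
        "bladder": 10.0,
        "ctv": 12.0,
    }


@dataclass
class TissueConfig:
    """Nominal HU mean/SD per tissue plus air-pocket and width settings."""

    means: dict[str, float] = field(default_factory=_default_means)
    sds: dict[str, float] = field(default_factory=_default_sds)
    air_pocket_probability: float = 0.5
    air_pocket_size_mm: tuple[float, float] = (8.0, 18.0)
    width_range_mm: tuple[float, float] = (250.0, 400.0)

    def __post_init__(self) -> None:
        for name, mu in self.means.items():
            if not (-1000.0 <= mu <= 3100.0):
                raise ValueError(f"nominal HU for {name} outside [-1000, 3100]")
        if self.means["air"] != AIR_HU:
            raise ValueError("air nominal HU must be exactly -1000")
        lo, hi = self.width_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid pelvis width range")


def _ellipsoid(zz, yy, xx, center, semi) -> np.ndarray:
    cz, cy, cx = center
    sz, sy, sx = semi
    return (
        ((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2
    ) <= 1.0


def generate_phantom(
    width_mm: float,
    n_slices: int,
    seed: int,
    config: TissueConfig | None = None,
    grid_size: int = 512,
    spacing: float = 1.0,
) -> Volume:
    """Generate one seeded pelvis phantom.

    The body is an elliptic cylinder of lateral extent ``width_mm`` centred in
    a ``grid_size`` x ``grid_size`` axial grid (anterior-posterior extent is 68%
    of the width); interior organs scale with the body so every width in the
    configured range produces valid anatomy.  Voxels outside the body are air
    at exactly -1000 HU; all other voxels get their tissue nominal plus seeded
    Gaussian texture.

    Raises
    ------
    ValueError
        If ``width_mm`` is outside the configured range or larger than the grid.
    """
    config = config or TissueConfig()
    lo, hi = config.width_range_mm
    if not (lo <= width_mm <= hi):
        raise ValueError(f"width {width_mm} mm outside configured range [{lo}, {hi}]")
    if width_mm > grid_size * spacing:
        raise ValueError(
            f"width {width_mm} mm exceeds grid extent {grid_size * spacing} mm"
        )
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")

    rng = np.random.default_rng(seed)
    half = (grid_size - 1) / 2.0
    x = (np.arange(grid_size) - half) * spacing
    z = (np.arange(n_slices) - (n_slices - 1) / 2.0) * spacing
    zz, yy, xx = np.meshgrid(z, x, x, indexing="ij")

    a = width_mm / 2.0          # lateral semi-axis
    b = 0.68 * a                # anterior-posterior semi-axis
    big = 1e9                   # elliptic cylinder: no z bound

    labels = np.zeros((n_slices, grid_size, grid_size), dtype=np.int16)

    body = _ellipsoid(zz, yy, xx, (0, 0, 0), (big, b, a))
    fat_inner = _ellipsoid(zz, yy, xx, (0, 0, 0), (big, b - 10.0, a - 10.0))
    labels[body] = _NAME_TO_CODE["fat"]
    labels[fat_inner] = _NAME_TO_CODE["muscle"]

    # femoral heads: spongy spheres in a thin cortical shell, lateral placement
    r_head = 0.16 * a
    z_extent = max(n_slices * spacing / 2.0, r_head + 1)
    for sx in (-1.0, 1.0):
        c = (0.0, 0.08 * b, sx * 0.55 * a)
        shell = _ellipsoid(
            zz, yy, xx, c, (min(z_extent, r_head + 2.5), r_head + 2.5, r_head + 2.5)
        )
        core = _ellipsoid(zz, yy, xx, c, (min(z_extent, r_head), r_head, r_head))
        labels[shell] = _NAME_TO_CODE["cortical_bone"]
        labels[core] = _NAME_TO_CODE["spongy_bone"]

    # bladder (anterior), CTV (central), rectum tube (posterior)
    bladder = _ellipsoid(zz, yy, xx, (0, -0.38 * b, 0), (big, 0.26 * b, 0.24 * a))
    labels[bladder] = _NAME_TO_CODE["bladder"]
    ctv = _ellipsoid(zz, yy, xx, (0, 0.05 * b, 0), (big, 0.18 * b, 0.14 * a))
    labels[ctv] = _NAME_TO_CODE["ctv"]
    r_rect = min(14.0, 0.12 * a)
    rect_c = (0, 0.55 * b, 0)
    rectum = _ellipsoid(zz, yy, xx, rect_c, (big, r_rect, r_rect))
    labels[rectum] = _NAME_TO_CODE["muscle"]

    # seeded rectal air pockets (the CT/CBCT mismatch scenario)
    if rng.uniform() < config.air_pocket_probability:
        lo_p, hi_p = config.air_pocket_size_mm
        d = rng.uniform(lo_p, hi_p)
        r = min(d / 2.0, r_rect - 1.0)
        cz = rng.uniform(-0.25, 0.25) * n_slices * spacing
        pocket = _ellipsoid(zz, yy, xx, (cz, rect_c[1], 0), (max(r, 1.0),) * 3)
        labels[pocket] = _NAME_TO_CODE["air"]

    hu = np.full(labels.shape, AIR_HU, dtype=np.float32)
    for name, code in _NAME_TO_CODE.items():
        m = labels == code
        if not m.any():
            continue
        if name == "air":
            hu[m] = AIR_HU
        else:
            hu[m] = config.means[name] + rng.normal(
                0.0, config.sds[name], size=int(m.sum())
            ).astype(np.float32)
    np.clip(hu, -1000.0, 3100.0, out=hu)
    hu[labels == _NAME_TO_CODE["air"]] = AIR_HU

    return Volume(hu, spacing, (float(z[0]), float(x[0]), float(x[0])), LabelMap(labels))


def uniform_ellipse_phantom(
    width_mm: float,
    n_slices: int = 1,
    hu: float = 45.0,
    grid_size: int = 512,
    spacing: float = 1.0,
    ap_ratio: float = 0.68,
) -> Volume:
    """A single-tissue elliptic phantom (no organs, no texture).

    Useful for isolating physics artifacts: any centre/periphery HU difference
    inside the body is then attributable to the simulation, not to anatomy.
    """
    half = (grid_size - 1) / 2.0
    x = (np.arange(grid_size) - half) * spacing
    yy, xx = np.meshgrid(x, x, indexing="ij")
    a = width_mm / 2.0
    body2d = (yy / (ap_ratio * a)) ** 2 + (xx / a) ** 2 <= 1.0
    sl = np.where(body2d, np.float32(hu), np.float32(AIR_HU))
    vol = np.repeat(sl[None], n_slices, axis=0)
    labels = np.where(body2d, _NAME_TO_CODE["muscle"], 0).astype(np.int16)
    labels = np.repeat(labels[None], n_slices, axis=0)
    z0 = -(n_slices - 1) / 2.0 * spacing
    return Volume(vol, spacing, (z0, float(x[0]), float(x[0])), LabelMap(labels))


def sample_cohort(
    n: int,
    width_range: tuple[float, float],
    seed: int,
    config: TissueConfig | None = None,
    n_slices: int = 8,
    grid_size: int = 512,
) -> list[Volume]:
    """Draw ``n`` phantoms with widths uniform over ``width_range``.

    Per-phantom seeds are derived deterministically from the master seed, so a
    cohort is reproducible as a whole and every member individually.
    """
    config = config or TissueConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = width_range
    clo, chi = config.width_range_mm
    if not (clo <= lo <= hi <= chi):
        raise ValueError("width_range must be non-empty and within config limits")
    rng = np.random.default_rng(seed)
    widths = rng.uniform(lo, hi, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        generate_phantom(float(w), n_slices, int(s), config, grid_size=grid_size)
        for w, s in zip(widths, seeds)
    ]


def write_cohort(cohort: list[Volume], out_dir: str | Path, widths=None) -> Path:
    """Write a cohort as NIfTI volumes plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, vol in enumerate(cohort):
        path = out_dir / f"phantom_{i:03d}.nii.gz"
        vol.save(path)
        width = None
        if widths is not None:
            width = float(widths[i])
        elif vol.labels is not None:
            body = vol.labels.codes[vol.shape[0] // 2] > 0
            cols = np.where(body.any(axis=0))[0]
            width = float((cols[-1] - cols[0] + 1) * vol.spacing) if cols.size else 0.0
        entries.append({"index": i, "path": path.name, "width_mm": width})
    manifest = out_dir / "cohort.json"
    manifest.write_text(json.dumps({"phantoms": entries}, indent=2))
    return manifest
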