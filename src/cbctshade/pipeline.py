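"""End-to-end desk-scale orchestration of the full correction pipeline.

``run_demo`` exercises the whole method on generated data at a scale a
single CPU handles in minutes: synthetic-pretraining cohort and target
cohort generation, CBCT simulation with default physics, dataset assembly,
Synth pretraining, FT2 fine-tuning, a noFT baseline, and the Base/noFT/FT2
metric comparison on held-out target phantoms.

The reductions relative to the full-scale protocol (fewer views, fewer
slices per phantom, a 2-block/8-filter network, tens of epochs) preserve the
structure of the experiment - truncated, scatter-corrupted inputs against
clean CT labels - while shrinking runtime; they are documented in the
methods note.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .evaluate import MetricsReport, volume_metrics
from .model import NetworkSpec
from .phantom import TissueConfig, generate_phantom
from .preprocess import build_dataset
from .simulator import Geometry, PhysicsConfig, simulate_cbct
from .train import TrainConfig, _apply_volume, run_protocol
from .volume import Volume

#: reduced geometry for desk-scale cohorts: coarser detector and fewer views,
#: same distances, arc and 208-mm FOV as the full geometry
DESK_GEOMETRY = dict(n_views=200, detector_pitch=0.776)


def simulate_cohort(
    widths: list[float],
    seeds: list[int],
    geometry: Geometry,
    physics: PhysicsConfig,
    n_slices: int = 4,
    grid_size: int = 384,
    config: TissueConfig | None = None,
    out_size: int = 220,
) -> list[tuple[Volume, Volume, float]]:
    """Generate phantoms and their simulated CBCTs; returns (cbct, ct, width)."""
    out = []
    for w, s in zip(widths, seeds):
        ct = generate_phantom(w, n_slices, s, config, grid_size=grid_size)
        cbct = simulate_cbct(ct, geometry, physics, seed=s, out_size=out_size)
        # CT cropped to the CBCT grid for voxel-aligned pairs
        ct_c = _center_crop(ct, out_size)
        out.append((cbct, ct_c, w))
    return out


def _center_crop(v: Volume, size: int) -> Volume:
    ny, nx = v.shape[1:]
    top = (ny - size) // 2
    left = (nx - size) // 2
    vals = v.values[:, top : top + size, left : left + size]
    labels = None
    if v.labels is not None:
        from .volume import LabelMap

        labels = LabelMap(v.labels.codes[:, top : top + size, left : left + size],
                          dict(v.labels.table))
    half = (size - 1) / 2.0 * v.spacing
    return Volume(vals.copy(), v.spacing, (v.origin[0], -half, -half), labels)


def run_demo(
    seed: int,
    out_dir: str | Path | None = None,
    n_synth: int = 12,
    n_target: int = 6,
    n_slices: int = 4,
    width_range: tuple[float, float] = (250.0, 340.0),
    spec: NetworkSpec | None = None,
    cfg: TrainConfig | None = None,
) -> dict:
    """One-command desk-scale demonstration of the FTx training pattern.

    Returns a dict with per-tag :class:`MetricsReport` lists on the held-out
    target phantoms and the training histories; writes CSV/JSON artifacts
    when ``out_dir`` is given.
    """
    rng = np.random.default_rng(seed)
    geometry = Geometry(**DESK_GEOMETRY)
    physics = PhysicsConfig()
    spec = spec or NetworkSpec(n_blocks=2, first_filters=8)
    cfg = cfg or TrainConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        pretrain_epochs=10, finetune_epochs=5, epochs=15,
        steps_per_epoch=15, max_val_slices=8,
    )

    def draw(n):
        widths = rng.uniform(*width_range, size=n)
        seeds = rng.integers(0, 2**31 - 1, size=n)
        return [float(w) for w in widths], [int(s) for s in seeds]

    synth = simulate_cohort(*draw(n_synth), geometry, physics, n_slices)
    target = simulate_cohort(*draw(n_target), geometry, physics, n_slices)

    ds_synth = build_dataset([(c, t) for c, t, _ in synth], seed=seed, split_level="volume")
    ds_target = build_dataset([(c, t) for c, t, _ in target], seed=seed + 1, split_level="volume")

    ft2, hist_ft = run_protocol("ft2", ds_synth, ds_target, cfg=cfg, spec=spec)
    noft, hist_no = run_protocol("noft", None, ds_target, cfg=cfg, spec=spec)

    # held-out evaluation: target phantoms whose slices landed in the test split
    test_ids = sorted({p.phantom_id for p in ds_target.test})
    reports: list[MetricsReport] = []
    for pid in test_ids:
        cbct, ct, width = target[pid]
        reports.append(volume_metrics(ct.values, cbct.values, "Base", pid, width))
        reports.append(volume_metrics(ct.values, _apply_volume(noft, cbct), "noFT", pid, width))
        reports.append(volume_metrics(ct.values, _apply_volume(ft2, cbct), "FT2", pid, width))

    result = {
        "reports": reports,
        "histories": {"FT2": hist_ft, "noFT": hist_no},
        "test_phantoms": test_ids,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame([r.to_dict() for r in reports]).to_csv(out_dir / "metrics.csv", index=False)
        summary = {
            tag: {
                "psnr_median": float(np.median([r.psnr_median for r in reports if r.model_tag == tag])),
                "mae_median": float(np.median([r.mae_median for r in reports if r.model_tag == tag])),
            }
            for tag in ("Base", "noFT", "FT2")
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return result
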