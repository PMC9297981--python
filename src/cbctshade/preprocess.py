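"""CT/CBCT pair preprocessing and slice-pair dataset assembly.

Mirrors the deployment pipeline: FOV masking of the CT so it matches the
narrow-FOV CBCT, isotropic resampling, HU clipping to [-1000, 3100] with
linear rescaling to [0, 1], zero padding of axial slices to 256 x 256, and
seeded 60/20/20 train/validation/test splitting at slice or volume level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume

HU_MIN = -1000.0
HU_MAX = 3100.0


def apply_fov_mask(ct: Volume, fov_diameter: float = 208.0) -> Volume:
    """Set voxels with in-plane radius > fov_diameter/2 to -1000 HU."""
    if fov_diameter <= 0:
        raise ValueError("fov_diameter must be > 0")
    nz, ny, nx = ct.shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * ct.spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * ct.spacing
    yy, xx = np.meshgrid(y, x, indexing="ij")
    outside = (yy**2 + xx**2) > (fov_diameter / 2.0) ** 2
    out = ct.copy()
    out.values[:, outside] = HU_MIN
    return out


def resample_isotropic(v: Volume, spacing: float = 1.0) -> Volume:
    """Trilinear resampling onto an isotropic grid of the given spacing.

    The world-coordinate extent is preserved to within one voxel; a volume
    already at the target spacing is returned unchanged (copied).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if abs(v.spacing - spacing) < 1e-12:
        return v.copy()
    scale = v.spacing / spacing
    new_shape = tuple(max(1, int(round(s * scale))) for s in v.shape)
    coords = np.meshgrid(
        *[np.arange(n) / scale for n in new_shape], indexing="ij"
    )
    vals = map_coordinates(v.values, coords, order=1, mode="nearest").astype(np.float32)
    return Volume(vals, spacing, v.origin)


def normalize_hu(values: np.ndarray) -> np.ndarray:
    """Clip HU to [-1000, 3100] and rescale linearly to [0, 1]."""
    return (np.clip(values, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN)


def denormalize_hu(values: np.ndarray) -> np.ndarray:
    """Map [0, 1] back to HU in [-1000, 3100]; out-of-range input is clipped."""
    values = np.asarray(values)
    if values.size and (values.min() < -1e-9 or values.max() > 1 + 1e-9):
        warnings.warn("denormalize_hu input outside [0, 1]; clipping", stacklevel=2)
        values = np.clip(values, 0.0, 1.0)
    return values * (HU_MAX - HU_MIN) + HU_MIN


def pad_slice(s: np.ndarray, size: int = 256) -> np.ndarray:
    """Zero-pad a 2D slice to ``size`` x ``size``, centred.

    Zero is normalized air, so the padding literally extends the background.
    """
    h, w = s.shape
    if size < h or size < w:
        raise ValueError(f"pad size {size} smaller than slice {s.shape}")
    top = (size - h) // 2
    left = (size - w) // 2
    out = np.zeros((size, size), dtype=s.dtype)
    out[top : top + h, left : left + w] = s
    return out


def crop_slice(s: np.ndarray, size: int) -> np.ndarray:
    """Centre-crop a 2D slice to ``size`` x ``size`` (inverse of pad_slice)."""
    h, w = s.shape
    top = (h - size) // 2
    left = (w - size) // 2
    return s[top : top + size, left : left + size]


@dataclass
class SlicePair:
    """A normalized (CBCT input, CT label) axial slice pair with provenance."""

    input_slice: np.ndarray
    label_slice: np.ndarray
    phantom_id: int
    slice_index: int

    def __post_init__(self) -> None:
        if self.input_slice.shape != self.label_slice.shape:
            raise ValueError("input and label slices must share a shape")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test lists of slice pairs."""

    train: list[SlicePair]
    validation: list[SlicePair]
    test: list[SlicePair]
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    split_level: str = "volume"

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")

    def __len__(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def preprocess_pair(
    cbct: Volume, ct: Volume, fov_diameter: float = 208.0, pad: int = 256,
    phantom_id: int = 0,
) -> list[SlicePair]:
    """Turn one aligned (CBCT, CT) volume pair into normalized slice pairs."""
    if cbct.shape[0] != ct.shape[0]:
        raise ValueError("CBCT and CT must have the same number of axial slices")
    ct = apply_fov_mask(ct, fov_diameter)
    pairs = []
    for k in range(cbct.shape[0]):
        inp = pad_slice(normalize_hu(cbct.values[k]).astype(np.float32), pad)
        lab = pad_slice(normalize_hu(_center_to(ct.values[k], cbct.shape[1])), pad)
        pairs.append(SlicePair(inp, lab.astype(np.float32), phantom_id, k))
    return pairs


def _center_to(sl: np.ndarray, size: int) -> np.ndarray:
    """Centre-crop or pad a slice so CT matches the CBCT in-plane extent."""
    if sl.shape[0] > size:
        return crop_slice(sl, size)
    if sl.shape[0] < size:
        return pad_slice(sl, size)
    return sl


def build_dataset(
    pairs: list[tuple[Volume, Volume]],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    split_level: str = "volume",
    fov_diameter: float = 208.0,
    pad: int = 256,
) -> DatasetSplit:
    """Assemble preprocessed slice pairs and split them 60/20/20 (default).

    ``split_level='volume'`` keeps all slices of a phantom in the same subset
    (no leakage between adjacent slices); ``'slice'`` shuffles individual
    slices.  The shuffle is seeded and deterministic.
    """
    if split_level not in ("volume", "slice"):
        raise ValueError("split_level must be 'volume' or 'slice'")
    all_pairs: list[SlicePair] = []
    for pid, (cbct, ct) in enumerate(pairs):
        all_pairs.extend(preprocess_pair(cbct, ct, fov_diameter, pad, phantom_id=pid))
    rng = np.random.default_rng(seed)
    if split_level == "slice":
        order = rng.permutation(len(all_pairs))
        items = [all_pairs[i] for i in order]
        n = len(items)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        split = (items[:n_train], items[n_train : n_train + n_val], items[n_train + n_val :])
    else:
        ids = sorted({p.phantom_id for p in all_pairs})
        order = rng.permutation(len(ids))
        ids = [ids[i] for i in order]
        n = len(ids)
        n_train = max(1, int(round(ratios[0] * n)))
        n_val = int(round(ratios[1] * n))
        groups = (set(ids[:n_train]), set(ids[n_train : n_train + n_val]), set(ids[n_train + n_val :]))
        split = tuple(
            [p for p in all_pairs if p.phantom_id in g] for g in groups
        )
    return DatasetSplit(*split, ratios=ratios, seed=seed, split_level=split_level)


# ---------------------------------------------------------------------------
# serialization


def save_dataset(split: DatasetSplit, path) -> None:
    """Write a DatasetSplit as an HDF5 container of slice stacks."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["ratios"] = split.ratios
        f.attrs["seed"] = split.seed
        f.attrs["split_level"] = split.split_level
        for name in ("train", "validation", "test"):
            pairs = getattr(split, name)
            g = f.create_group(name)
            if pairs:
                g.create_dataset("inputs", data=np.stack([p.input_slice for p in pairs]))
                g.create_dataset("labels", data=np.stack([p.label_slice for p in pairs]))
                g.create_dataset("phantom_ids", data=[p.phantom_id for p in pairs])
                g.create_dataset("slice_indices", data=[p.slice_index for p in pairs])


def load_dataset(path) -> DatasetSplit:
    """Read a DatasetSplit written by :func:`save_dataset`."""
    import h5py

    subsets = {}
    with h5py.File(path, "r") as f:
        ratios = tuple(float(r) for r in f.attrs["ratios"])
        seed = int(f.attrs["seed"])
        level = str(f.attrs["split_level"])
        for name in ("train", "validation", "test"):
            g = f[name]
            pairs = []
            if "inputs" in g:
                inputs = g["inputs"][...]
                labels = g["labels"][...]
                pids = g["phantom_ids"][...]
                sidx = g["slice_indices"][...]
                pairs = [
                    SlicePair(inputs[i], labels[i], int(pids[i]), int(sidx[i]))
                    for i in range(inputs.shape[0])
                ]
            subsets[name] = pairs
    return DatasetSplit(
        subsets["train"], subsets["validation"], subsets["test"],
        ratios=ratios, seed=seed, split_level=level,
    )
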