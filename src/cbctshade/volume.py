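"""In-memory container for HU volumes and tissue label maps, with NIfTI I/O.

Axis convention: arrays are indexed ``(z, y, x)``; axial slices are ``values[k]``.
World coordinates are millimetres, ``origin`` is the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: canonical tissue code table shared by the phantom generator and ROI analysis
TISSUE_CODES = {
    0: "air",
    1: "fat",
    2: "muscle",
    3: "spongy_bone",
    4: "cortical_bone",
    5: "bladder",
    6: "ctv",
}


@dataclass
class LabelMap:
    """Integer tissue codes per voxel plus the code -> tissue-name table."""

    codes: np.ndarray
    table: dict[int, str] = field(default_factory=lambda: dict(TISSUE_CODES))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        present = np.unique(self.codes)
        missing = [int(c) for c in present if int(c) not in self.table]
        if missing:
            raise ValueError(f"label codes {missing} missing from code table")

    def mask(self, tissue: str) -> np.ndarray:
        """Boolean mask of voxels carrying the given tissue name."""
        codes = [c for c, name in self.table.items() if name == tissue]
        if not codes:
            raise KeyError(f"tissue {tissue!r} not in code table")
        return np.isin(self.codes, codes)


@dataclass
class Volume:
    """A 3D scalar grid in Hounsfield units with isotropic spacing.

    Parameters
    ----------
    values
        HU values, shape ``(nz, ny, nx)``.
    spacing
        Isotropic voxel edge length in mm.
    origin
        World-coordinate (z, y, x) of the centre of voxel (0, 0, 0), mm.
    labels
        Optional tissue label map of identical shape.
    """

    values: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: LabelMap | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("Volume expects a 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        if self.labels is not None and self.labels.codes.shape != self.values.shape:
            raise ValueError("label map shape does not match volume shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "Volume":
        labels = None
        if self.labels is not None:
            labels = LabelMap(self.labels.codes.copy(), dict(self.labels.table))
        return Volume(self.values.copy(), self.spacing, self.origin, labels)

    # -- I/O -----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the volume (and, if present, labels) as NIfTI.

        Labels go to ``<stem>_labels.nii.gz`` next to the volume.
        """
        path = Path(path)
        affine = np.diag([self.spacing, self.spacing, self.spacing, 1.0])
        affine[:3, 3] = self.origin[::-1]
        # nibabel expects (x, y, z) ordering
        nib.save(nib.Nifti1Image(np.ascontiguousarray(self.values.T), affine), str(path))
        if self.labels is not None:
            stem = path.name
            for suf in (".nii.gz", ".nii", ".mha"):
                if stem.endswith(suf):
                    stem = stem[: -len(suf)]
                    break
            lab_path = path.parent / f"{stem}_labels.nii.gz"
            nib.save(
                nib.Nifti1Image(np.ascontiguousarray(self.labels.codes.T.astype(np.int16)), affine),
                str(lab_path),
            )

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).T.astype(np.float32)
        spacing = float(img.header.get_zooms()[0])
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
        return cls(data, spacing, origin)
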