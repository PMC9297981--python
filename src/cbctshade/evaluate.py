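"""HU-recovery metric suite: PSNR, SSIM, MAE, ROI differences and CNR.

Conventions (documented defaults, configurable):

* PSNR and SSIM are computed on the normalized [0, 1] representation with
  peak / data range 1.0 (equivalent to the HU-scale values up to a constant).
* SSIM uses the standard Gaussian-window formulation (11x11 window, sigma
  1.5, K1 = 0.01, K2 = 0.03), delegated to scikit-image.
* MAE is reported in HU over an inclusion mask; mismatching air pockets
  between the two volumes are excluded with a -300 HU threshold by default.
* CNR is signed, (mean_fg - mean_bg) / pooled SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from skimage.metrics import structural_similarity

from .preprocess import denormalize_hu, normalize_hu
from .volume import LabelMap, Volume

AIR_THRESHOLD_HU = -300.0


def _arr(v) -> np.ndarray:
    return v.values if isinstance(v, Volume) else np.asarray(v)


def psnr(ref, test, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs."""
    ref, test = _arr(ref), _arr(test)
    if ref.shape != test.shape:
        raise ValueError("psnr requires equal shapes")
    mse = float(np.mean((ref.astype(np.float64) - test.astype(np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(ref, test, data_range: float = 1.0) -> float:
    """Mean structural similarity (Gaussian 11x11 window, sigma 1.5)."""
    ref, test = _arr(ref), _arr(test)
    if ref.shape != test.shape:
        raise ValueError("ssim requires equal shapes")
    return float(
        structural_similarity(
            ref.astype(np.float64),
            test.astype(np.float64),
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def air_mismatch_mask(ct, cbct, air_threshold: float = AIR_THRESHOLD_HU) -> np.ndarray:
    """Inclusion mask: exclude voxels that are air in exactly one volume.

    Matching air and matching tissue are kept; only disagreements about air
    (e.g. a rectal gas pocket present in one scan only) are dropped.
    """
    ct, cbct = _arr(ct), _arr(cbct)
    a = ct < air_threshold
    b = cbct < air_threshold
    return ~(a ^ b)


def mae_hu(ref, test, mask: np.ndarray | None = None) -> float:
    """Mean absolute HU difference over included voxels."""
    ref, test = _arr(ref).astype(np.float64), _arr(test).astype(np.float64)
    if ref.shape != test.shape:
        raise ValueError("mae_hu requires equal shapes")
    diff = np.abs(ref - test)
    if mask is not None:
        if mask.shape != ref.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty inclusion mask")
        diff = diff[mask]
    return float(diff.mean())


# ---------------------------------------------------------------------------
# ROI analysis


@dataclass(frozen=True)
class ROI:
    """A cubic region: corner voxel index (z, y, x), edge length, tissue tag."""

    corner: tuple[int, int, int]
    edge: int
    tissue: str

    def slices(self) -> tuple[slice, slice, slice]:
        z, y, x = self.corner
        e = self.edge
        return (slice(z, z + e), slice(y, y + e), slice(x, x + e))


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)


def extract_rois(
    labels: LabelMap, tissue: str, n: int, edge: int = 8, seed: int = 0
) -> ROISet:
    """Place ``n`` non-overlapping seeded cubes fully inside a tissue region."""
    mask = labels.mask(tissue)
    # integral image -> cube sums at every corner
    cs = np.cumsum(np.cumsum(np.cumsum(mask.astype(np.int64), 0), 1), 2)
    cs = np.pad(cs, ((1, 0), (1, 0), (1, 0)))
    e = edge
    nz, ny, nx = mask.shape
    if nz < e or ny < e or nx < e:
        raise ValueError(f"{tissue} region grid smaller than ROI edge {e}")
    full = (
        cs[e:, e:, e:]
        - cs[:-e, e:, e:] - cs[e:, :-e, e:] - cs[e:, e:, :-e]
        + cs[:-e, :-e, e:] + cs[:-e, e:, :-e] + cs[e:, :-e, :-e]
        - cs[:-e, :-e, :-e]
    )
    corners = np.argwhere(full == e**3)
    if corners.shape[0] == 0:
        raise ValueError(f"no {e}^3 cube fits inside tissue {tissue!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(corners.shape[0])
    chosen: list[ROI] = []
    for idx in order:
        c = tuple(int(v) for v in corners[idx])
        if all(max(abs(c[d] - r.corner[d]) for d in range(3)) >= e for r in chosen):
            chosen.append(ROI(c, e, tissue))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError(
            f"only {len(chosen)} non-overlapping {e}^3 cubes fit in tissue {tissue!r}"
        )
    return ROISet(chosen)


def roi_hu_difference(ct, cbct, rois: ROISet) -> pd.DataFrame:
    """Per-ROI mean HU in each volume and the absolute difference of means.

    Returns a DataFrame with one row per ROI; aggregate per tissue with
    ``df.groupby('tissue')['abs_difference'].agg(['mean', 'std'])``.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI set")
    ct, cbct = _arr(ct), _arr(cbct)
    rows = []
    for r in rois:
        sl = r.slices()
        m_ct = float(ct[sl].mean())
        m_cb = float(cbct[sl].mean())
        rows.append(
            {
                "tissue": r.tissue,
                "corner": r.corner,
                "ct_mean": m_ct,
                "cbct_mean": m_cb,
                "abs_difference": abs(m_ct - m_cb),
            }
        )
    return pd.DataFrame(rows)


def cnr(image, fg: ROI, bg: ROI, denominator: str = "pooled") -> float:
    """Signed contrast-to-noise ratio between two ROIs of one image.

    ``pooled``: (mean_fg - mean_bg) / sqrt((var_fg + var_bg) / 2);
    ``background``: divide by the background SD alone.
    """
    img = _arr(image)
    a = img[fg.slices()].astype(np.float64)
    b = img[bg.slices()].astype(np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    if denominator == "pooled":
        sd = np.sqrt((a.var() + b.var()) / 2.0)
    elif denominator == "background":
        sd = b.std()
    else:
        raise ValueError("denominator must be 'pooled' or 'background'")
    if sd == 0.0:
        raise ValueError("zero denominator SD in CNR")
    return float((a.mean() - b.mean()) / sd)


# ---------------------------------------------------------------------------
# reports


@dataclass
class MetricsReport:
    """Per-volume (or per-fold) metric summary with provenance."""

    model_tag: str
    fold_id: int | None = None
    phantom_width: float | None = None
    psnr_median: float = float("nan")
    psnr_iqr: float = float("nan")
    ssim_median: float = float("nan")
    ssim_iqr: float = float("nan")
    mae_median: float = float("nan")
    mae_iqr: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _median_iqr(vals: list[float]) -> tuple[float, float]:
    a = np.asarray(vals, dtype=np.float64)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan"), float("nan")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return float(med), float(q3 - q1)


def volume_metrics(
    ct_hu: np.ndarray,
    test_hu: np.ndarray,
    model_tag: str,
    fold_id: int | None = None,
    phantom_width: float | None = None,
    air_threshold: float = AIR_THRESHOLD_HU,
) -> MetricsReport:
    """Slice-wise PSNR/SSIM (normalized scale) and MAE (HU), median and IQR.

    Mismatching air voxels are excluded from the MAE via
    :func:`air_mismatch_mask`.
    """
    ct_hu, test_hu = _arr(ct_hu), _arr(test_hu)
    if ct_hu.ndim == 2:
        ct_hu, test_hu = ct_hu[None], test_hu[None]
    psnrs, ssims, maes = [], [], []
    for k in range(ct_hu.shape[0]):
        ref_n = normalize_hu(ct_hu[k])
        test_n = normalize_hu(test_hu[k])
        psnrs.append(psnr(ref_n, test_n))
        ssims.append(ssim(ref_n, test_n))
        m = air_mismatch_mask(ct_hu[k], test_hu[k], air_threshold)
        maes.append(mae_hu(ct_hu[k], test_hu[k], m))
    rep = MetricsReport(model_tag, fold_id, phantom_width)
    rep.psnr_median, rep.psnr_iqr = _median_iqr(psnrs)
    rep.ssim_median, rep.ssim_iqr = _median_iqr(ssims)
    rep.mae_median, rep.mae_iqr = _median_iqr(maes)
    return rep


def width_vs_mae(reports: list[MetricsReport]) -> tuple[pd.DataFrame, dict[str, float]]:
    """(width, MAE) rows per model tag plus per-tag Spearman rank correlation.

    A positive correlation for the uncorrected (Base) tag means wider pelves
    - hence more truncation - produce larger HU errors.
    """
    rows = [
        {"model_tag": r.model_tag, "width_mm": r.phantom_width, "mae_hu": r.mae_median}
        for r in reports
    ]
    df = pd.DataFrame(rows)
    corr: dict[str, float] = {}
    for tag, grp in df.groupby("model_tag"):
        if len(grp) >= 3 and grp["width_mm"].notna().all():
            rho = spearmanr(grp["width_mm"], grp["mae_hu"]).statistic
            corr[tag] = float(rho)
        else:
            corr[tag] = float("nan")
    return df, corr
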