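"""Masked image-quality metrics, ROI statistics and cohort analyses.

Global map-vs-reference quality is assessed slice by slice with PSNR,
SSIM, mean percentage error (MPE) and the Pearson correlation
coefficient, always over voxels outside the bladder and extreme-value
masks — a metric must be blind to whatever happens under an exclusion
mask.  Regional analysis reduces T2 maps to per-ROI means (tumor vs
non-tumor peripheral zone), compared with paired/unpaired t-tests and
Bland-Altman limits of agreement.  For two-timepoint surveillance
cohorts, deltaT2 (timepoint 2 minus timepoint 1, per tumor ROI) is the
progression marker, summarized by the Mann-Whitney/rank AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps
from skimage.metrics import structural_similarity

from .io_core import ImageVolume

__all__ = [
    "SliceMetrics", "ROIStats", "RegionStat", "PSNRResult",
    "psnr", "ssim", "mpe", "pearson",
    "roi_mean_t2", "paired_ttest", "unpaired_ttest",
    "bland_altman", "delta_t2", "roc_auc", "evaluate_slices",
]

#: Sentinel reported when RMSE is exactly zero (identical images).
PSNR_CAP_DB = 300.0


class PSNRResult(NamedTuple):
    value: float
    capped: bool


class TTestResult(NamedTuple):
    t: float
    p: float
    significant: bool


class BlandAltman(NamedTuple):
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class SliceMetrics:
    slice_index: int
    psnr_db: float
    psnr_capped: bool
    ssim: float
    mpe_percent: float
    pearson_r: float
    n_voxels: int


@dataclass(frozen=True)
class RegionStat:
    mean: float   # ms
    sd: float     # ms
    n: int


@dataclass
class ROIStats:
    subject_id: str
    regions: dict[str, RegionStat]


def _check(est: np.ndarray, ref: np.ndarray, mask: np.ndarray | None):
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {ref.shape}")
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != est.shape:
        raise ValueError("mask shape mismatch")
    return est, ref, mask


def psnr(est, ref, mask=None, data_range: float = 400.0) -> PSNRResult:
    """Peak signal-to-noise ratio, 20*log10(range/RMSE), over unmasked voxels.

    The dynamic range is fixed (default 400 ms, the T2 scaling constant)
    rather than per-slice, so values are comparable across slices.
    Identical inputs are reported as a 300 dB sentinel with
    ``capped=True``.
    """
    est, ref, mask = _check(est, ref, mask)
    if not mask.any():
        raise ValueError("empty metric mask")
    rmse = float(np.sqrt(np.mean((est[mask] - ref[mask]) ** 2)))
    if rmse == 0.0:
        return PSNRResult(PSNR_CAP_DB, True)
    return PSNRResult(min(20.0 * np.log10(data_range / rmse), PSNR_CAP_DB),
                      False)


def ssim(est, ref, mask=None, data_range: float = 400.0) -> float:
    """Masked structural similarity of one slice.

    Standard windowed SSIM (11x11 Gaussian window, sigma 1.5, K1=0.01,
    K2=0.03), averaged over windows that lie fully inside the slice and
    whose center voxel is unmasked.  Masked-out voxels are zero-filled in
    both images before the windowed pass, so the metric is strictly
    blind to whatever values they held.
    """
    est, ref, mask = _check(est, ref, mask)
    if est.ndim != 2:
        raise ValueError("ssim operates on 2D slices")
    if min(est.shape) < 11:
        raise ValueError("slice smaller than the 11x11 SSIM window")
    est = np.where(mask, est, 0.0)
    ref = np.where(mask, ref, 0.0)
    _, smap = structural_similarity(
        ref, est, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=data_range, full=True)
    pad = 5  # (win-1)//2: keep fully-interior windows only
    inner = (slice(pad, -pad), slice(pad, -pad))
    keep = mask[inner]
    if not keep.any():
        raise ValueError("no unmasked interior window centers")
    return float(smap[inner][keep].mean())


def mpe(est, ref, mask=None, floor: float = 1.0) -> float:
    """Mean percentage error: mean of |est - ref| / ref * 100.

    Computed over unmasked voxels whose reference exceeds ``floor`` (ms),
    which keeps near-zero references from blowing up the average.
    """
    est, ref, mask = _check(est, ref, mask)
    sel = mask & (ref > floor)
    if not sel.any():
        raise ValueError("no unmasked voxels above the reference floor")
    return float(np.mean(np.abs(est[sel] - ref[sel]) / ref[sel]) * 100.0)


def pearson(est, ref, mask=None) -> float:
    """Product-moment correlation over unmasked voxels; NaN if degenerate."""
    est, ref, mask = _check(est, ref, mask)
    a, b = est[mask], ref[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_slices(
    est: ImageVolume,
    ref: ImageVolume,
    excluded: np.ndarray,
    data_range: float = 400.0,
    mpe_floor: float = 1.0,
) -> list[SliceMetrics]:
    """All global metrics, slice by slice, outside the excluded mask."""
    if est.shape != ref.shape:
        raise ValueError("estimate/reference shape mismatch")
    rows = []
    for k in range(est.n_slices):
        m = ~excluded[:, :, k]
        p = psnr(est.data[:, :, k], ref.data[:, :, k], m, data_range)
        rows.append(SliceMetrics(
            slice_index=k,
            psnr_db=p.value,
            psnr_capped=p.capped,
            ssim=ssim(est.data[:, :, k], ref.data[:, :, k], m, data_range),
            mpe_percent=mpe(est.data[:, :, k], ref.data[:, :, k], m, mpe_floor),
            pearson_r=pearson(est.data[:, :, k], ref.data[:, :, k], m),
            n_voxels=int(m.sum()),
        ))
    return rows


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------

def roi_mean_t2(
    t2map: ImageVolume,
    rois: dict[str, np.ndarray],
    exclude: np.ndarray | None = None,
    subject_id: str = "",
) -> ROIStats:
    """Per-region mean/sd/count of a T2 map (ms).

    ``rois`` maps region name to a boolean mask; regions must be
    pairwise disjoint.  Voxels under ``exclude`` (e.g. the extreme-value
    mask) are dropped; an empty region is an error.
    """
    names = list(rois)
    overlap = np.zeros(t2map.shape, dtype=int)
    for name in names:
        m = np.asarray(rois[name], dtype=bool)
        if m.shape != t2map.shape:
            raise ValueError(f"ROI {name!r} geometry mismatch")
        overlap += m
    if (overlap > 1).any():
        raise ValueError("ROIs overlap")
    keep = ~exclude if exclude is not None else np.ones(t2map.shape, bool)
    regions = {}
    for name in names:
        vals = t2map.data[np.asarray(rois[name], bool) & keep]
        if vals.size == 0:
            raise ValueError(f"ROI {name!r} is empty after exclusion")
        regions[name] = RegionStat(float(vals.mean()), float(vals.std(ddof=1))
                                   if vals.size > 1 else 0.0, int(vals.size))
    return ROIStats(subject_id=subject_id, regions=regions)


def paired_ttest(a, b, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test; identical samples give t=0, p=1."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == d[0]) and d[0] == 0:
        return TTestResult(0.0, 1.0, False)
    t, p = sps.ttest_rel(a, b)
    return TTestResult(float(t), float(p), bool(p < alpha))


def unpaired_ttest(a, b, alpha: float = 0.05) -> TTestResult:
    """Two-sided Welch t-test (unequal variances)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return TTestResult(0.0, 1.0, False)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p), bool(p < alpha))


def bland_altman(pairs, percent: bool = False) -> BlandAltman:
    """Mean difference and ±1.96 sd limits of agreement.

    In percent mode differences are 100*(a-b)/mean(a,b); pairs with a
    zero mean are dropped (with at least 2 pairs required afterwards).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (a, b) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if percent:
        m = (a + b) / 2.0
        keep = m != 0
        if keep.sum() < 2:
            raise ValueError("fewer than 2 usable pairs in percent mode")
        d = 100.0 * (a[keep] - b[keep]) / m[keep]
    else:
        d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd, int(d.size))


def delta_t2(stats_tp1: list[ROIStats], stats_tp2: list[ROIStats],
             region: str = "tumor") -> dict[str, float]:
    """Per-subject deltaT2 (ms): timepoint-2 ROI mean minus timepoint-1.

    Subjects must match one-to-one between timepoints.
    """
    s1 = {s.subject_id: s for s in stats_tp1}
    s2 = {s.subject_id: s for s in stats_tp2}
    if set(s1) != set(s2):
        raise ValueError(f"subject mismatch: {sorted(set(s1) ^ set(s2))}")
    return {sid: s2[sid].regions[region].mean - s1[sid].regions[region].mean
            for sid in sorted(s1)}


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
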