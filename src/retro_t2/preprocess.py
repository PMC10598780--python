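"""Preprocessing chain for retrospective T2 estimation.

The stages, in pipeline order: resample weighted images onto the T2-map
grid, crop the field of view, deformable-register the weighted images
to the multi-echo echo whose TE is closest to the T2-weighted TE,
generate a bladder mask from the T1-weighted image, normalize each
weighted volume by (mean + 3*sd) of its non-bladder voxels, scale
reference T2 maps by 400 ms into dimensionless network targets, and
build extreme-value masks (T2 strictly above 400 ms) that exclude
spurious high-T2 pixels (urine) from training loss and evaluation.

Registration is pluggable; the default is per-slice multi-resolution
symmetric-forces demons (diffeomorphic intensity registration).  For
pairs with inverted contrast (T1-weighted vs. a late spin echo, where
urine flips from dark to bright) a gradient-magnitude channel is
available, since edge locations are shared across contrasts even when
intensity order is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .io_core import ImageVolume

__all__ = [
    "MaskSet",
    "NormalizationRecord",
    "resample_to_grid",
    "crop_fov",
    "make_bladder_mask",
    "register_deformable",
    "select_registration_target",
    "normalize_weighted",
    "scale_t2",
    "unscale_t2",
    "extreme_mask",
]


@dataclass
class MaskSet:
    """Per-subject exclusion masks, geometry-matched to the subject grid."""

    bladder: np.ndarray   # bool
    extreme: np.ndarray   # bool, reference T2 > threshold

    def __post_init__(self):
        self.bladder = np.asarray(self.bladder, dtype=bool)
        self.extreme = np.asarray(self.extreme, dtype=bool)
        if self.bladder.shape != self.extreme.shape:
            raise ValueError("bladder and extreme masks must share a grid")

    @property
    def excluded(self) -> np.ndarray:
        return self.bladder | self.extreme


@dataclass
class NormalizationRecord:
    """Per-subject intensity normalization bookkeeping."""

    divisor: float        # mean + 3*sd over non-bladder voxels, a.u.
    scale_t2: float = 400.0

    def __post_init__(self):
        if self.divisor <= 0:
            raise ValueError(f"divisor must be > 0, got {self.divisor}")
        if self.scale_t2 <= 0:
            raise ValueError(f"scale_t2 must be > 0, got {self.scale_t2}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def resample_to_grid(vol: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Linearly interpolate ``vol`` onto the grid of ``target``.

    Grids are aligned at the physical origin (index 0); target
    coordinates outside the source extent take the nearest edge value.
    """
    if min(target.shape) < 1 or min(target.spacing) <= 0:
        raise ValueError("degenerate target geometry")
    if vol.shape == target.shape and vol.spacing == target.spacing:
        return vol.with_data(vol.data.copy())
    axes = [np.arange(n) * ts / ss
            for n, ts, ss in zip(target.shape, target.spacing, vol.spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.data, np.stack(coords), order=1, mode="nearest")
    return ImageVolume(out, spacing=target.spacing, units=vol.units)


def crop_fov(vol: ImageVolume, margins: tuple[tuple[int, int], ...]) -> ImageVolume:
    """Crop by (low, high) voxel margins per axis; (0, 0) margins are identity.

    The same margins must be applied to every volume of a subject so the
    grids stay aligned.
    """
    if len(margins) != 3:
        raise ValueError("margins must be ((lo,hi),)*3")
    sl = []
    for ax, (lo, hi) in enumerate(margins):
        n = vol.data.shape[ax]
        if lo < 0 or hi < 0 or lo + hi >= n:
            raise ValueError(f"empty crop on axis {ax}: ({lo},{hi}) of {n}")
        sl.append(slice(lo, n - hi))
    return vol.with_data(vol.data[tuple(sl)].copy())


# ---------------------------------------------------------------------------
# bladder mask
# ---------------------------------------------------------------------------

def make_bladder_mask(
    t1w: ImageVolume,
    opening_radius: int = 2,
    min_size_voxels: int = 50,
    dark_urine: bool = True,
) -> np.ndarray:
    """Morphological bladder segmentation from the T1-weighted image.

    Urine is dark on a short-TR spoiled gradient echo (long T1), so the
    pipeline thresholds the low-intensity mode (Otsu), opens, fills
    holes, and keeps the largest connected component whose in-plane
    centroid lies in the anterior half of the image.  Returns an empty
    mask when no candidate component reaches ``min_size_voxels`` —
    a valid result for subjects without a (filled) bladder.  Set
    ``dark_urine=False`` for protocols where urine is bright.
    """
    data = t1w.data
    finite = data[np.isfinite(data)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return np.zeros(data.shape, dtype=bool)
    thr = threshold_otsu(finite)
    lo = finite[finite < thr]
    hi = finite[finite >= thr]
    if lo.size == 0 or hi.size == 0:
        return np.zeros(data.shape, dtype=bool)
    # bimodality guard: without a genuinely dark (urine) mode, Otsu just
    # splits tissue noise — refuse to segment in that case
    if (hi.mean() - lo.mean()) < 0.2 * hi.mean():
        return np.zeros(data.shape, dtype=bool)
    cand = data < thr if dark_urine else data > thr
    if opening_radius > 0:
        selem = morphology.disk(opening_radius)
        for k in range(data.shape[2]):
            cand[:, :, k] = morphology.opening(cand[:, :, k], selem)
            cand[:, :, k] = ndimage.binary_fill_holes(cand[:, :, k])
    lab = measure.label(cand, connectivity=1)
    if lab.max() == 0:
        return np.zeros(data.shape, dtype=bool)
    ny = data.shape[1]
    best, best_size = 0, 0
    for region in measure.regionprops(lab):
        if region.area < min_size_voxels:
            continue
        cy = region.centroid[1]
        if cy >= ny / 2:          # bladder lies anterior (low y) of the prostate
            continue
        if region.area > best_size:
            best, best_size = region.label, region.area
    if best == 0:
        return np.zeros(data.shape, dtype=bool)
    return lab == best


# ---------------------------------------------------------------------------
# deformable registration
# ---------------------------------------------------------------------------

def select_registration_target(mese_te_list, t2w_te: float) -> tuple[int, float]:
    """Pick the echo whose TE is closest to the T2-weighted TE.

    Registering the weighted images to this echo exploits their similar
    contrast.  Ties break toward the larger TE (closer to a heavily
    T2-weighted contrast).  Returns ``(index, te)``.
    """
    tes = list(mese_te_list)
    if not tes:
        raise ValueError("empty echo-time list")
    best = max(range(len(tes)), key=lambda i: (-abs(tes[i] - t2w_te), tes[i]))
    return best, tes[best]


def _gradient_channel(sl: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    sm = ndimage.gaussian_filter(sl, sigma)
    gx, gy = np.gradient(sm)
    g = np.hypot(gx, gy)
    m = g.max()
    return (g / m if m > 0 else g).astype(np.float64)


def _demons_slice(mov: np.ndarray, fix: np.ndarray, iterations: int,
                  smooth_sd: float) -> np.ndarray:
    """Multi-resolution symmetric-forces demons on one slice.

    Returns the displacement field, shape (2, X, Y), voxel units, such
    that sampling the moving slice at ``x - u(x)`` aligns it to fixed.
    """
    m = sitk.GetImageFromArray(mov.astype(np.float32))
    f = sitk.GetImageFromArray(fix.astype(np.float32))
    d = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    d.SetNumberOfIterations(iterations)
    d.SetSmoothDisplacementField(True)
    d.SetStandardDeviations(smooth_sd)
    fld = None
    for shrink in (4, 2, 1):
        fs = sitk.Shrink(f, [shrink] * 2)
        ms = sitk.Shrink(m, [shrink] * 2)
        if fld is None:
            fld = d.Execute(fs, ms)
        else:
            fld = sitk.Cast(sitk.Resample(fld, fs, sitk.Transform(), sitk.sitkLinear),
                            sitk.sitkVectorFloat64)
            fld = d.Execute(fs, ms, fld)
    fld = sitk.Cast(sitk.Resample(fld, f, sitk.Transform(), sitk.sitkLinear),
                    sitk.sitkVectorFloat64)
    arr = sitk.GetArrayFromImage(fld)           # (X, Y, 2); components (axis1, axis0)
    return np.stack([arr[..., 1], arr[..., 0]])


def register_deformable(
    moving: ImageVolume,
    fixed: ImageVolume,
    channel: str = "intensity",
    iterations: int = 60,
    smooth_sd: float = 2.0,
    presmooth_sigma: float = 1.0,
) -> tuple[ImageVolume, np.ndarray, bool]:
    """Per-slice deformable registration of ``moving`` onto ``fixed``.

    ``channel="intensity"`` histogram-matches the moving slice to the
    fixed slice first (appropriate for similar contrasts);
    ``channel="gradient"`` registers gradient-magnitude images instead
    (robust when the intensity order differs between contrasts).

    Returns ``(warped, field, converged)`` where ``field`` has shape
    (2, X, Y, Z) in mm (same convention as the phantom's ground-truth
    deformation fields).  If registration increases the mean squared
    difference on some slice, that slice's field is zeroed and the
    moving slice passed through; ``converged`` is False in that case.
    """
    if moving.shape != fixed.shape:
        raise ValueError(f"grids differ: {moving.shape} vs {fixed.shape}")
    if channel not in ("intensity", "gradient"):
        raise ValueError(f"unknown channel {channel!r}")
    out = np.empty_like(moving.data, dtype=float)
    field = np.zeros((2,) + moving.shape)
    converged = True
    xx, yy = np.meshgrid(np.arange(moving.shape[0], dtype=float),
                         np.arange(moving.shape[1], dtype=float), indexing="ij")
    for k in range(moving.n_slices):
        msl = moving.data[:, :, k].astype(float)
        fsl = fixed.data[:, :, k].astype(float)
        if presmooth_sigma > 0:   # suppress independent acquisition noise
            msm = ndimage.gaussian_filter(msl, presmooth_sigma)
            fsm = ndimage.gaussian_filter(fsl, presmooth_sigma)
        else:
            msm, fsm = msl, fsl
        if channel == "gradient":
            mreg, freg = _gradient_channel(msm), _gradient_channel(fsm)
        else:
            mi = sitk.GetImageFromArray(msm.astype(np.float32))
            fi = sitk.GetImageFromArray(fsm.astype(np.float32))
            mreg = sitk.GetArrayFromImage(sitk.HistogramMatching(mi, fi))
            freg = fsm
        u = _demons_slice(mreg, freg, iterations, smooth_sd)
        warped = ndimage.map_coordinates(msl, np.stack([xx - u[0], yy - u[1]]),
                                         order=1, mode="nearest")
        if np.mean((warped - fsl) ** 2) > np.mean((msl - fsl) ** 2) and \
                channel == "intensity":
            out[:, :, k] = msl
            converged = False
            continue
        out[:, :, k] = warped
        field[0, :, :, k] = u[0] * moving.spacing[0]
        field[1, :, :, k] = u[1] * moving.spacing[1]
    return moving.with_data(out), field, converged


# ---------------------------------------------------------------------------
# intensity normalization and scaling
# ---------------------------------------------------------------------------

def normalize_weighted(
    vol: ImageVolume, bladder: np.ndarray | None = None
) -> tuple[ImageVolume, NormalizationRecord]:
    """Divide by (mean + 3*sd) of the whole volume, excluding bladder voxels.

    The standard deviation is the population (n-denominator) form.
    Bladder exclusion makes the divisor insensitive to bladder filling —
    arbitrarily bright urine cannot rescale the prostate.
    """
    data = vol.data
    if bladder is None:
        bladder = np.zeros(data.shape, dtype=bool)
    keep = ~np.asarray(bladder, dtype=bool)
    if not keep.any():
        raise ValueError("no voxels outside the bladder mask")
    vals = data[keep]
    divisor = float(vals.mean() + 3.0 * vals.std())  # population sd
    if divisor <= 0:
        raise ValueError(f"non-positive normalization divisor {divisor}")
    rec = NormalizationRecord(divisor=divisor)
    return vol.with_data(data / divisor), rec


def scale_t2(t2map: ImageVolume, scale: float = 400.0) -> ImageVolume:
    """Scale a T2 map (ms) into the dimensionless [~0, 1] network range."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if t2map.units != "ms":
        raise ValueError("scale_t2 expects a map in ms")
    return t2map.with_data(t2map.data / scale, units="arbitrary")


def unscale_t2(scaled: ImageVolume, scale: float = 400.0) -> ImageVolume:
    """Inverse of :func:`scale_t2`: dimensionless map back to ms."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return scaled.with_data(scaled.data * scale, units="ms")


def extreme_mask(t2map: ImageVolume, threshold: float = 400.0) -> np.ndarray:
    """True where reference T2 is strictly above ``threshold`` (ms).

    These voxels (urine, cysts) are excluded from the training loss and
    from every evaluation metric.
    """
    if t2map.units != "ms":
        raise ValueError("extreme_mask expects a map in ms")
    return t2map.data > threshold
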