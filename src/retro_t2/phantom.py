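"""Digital pelvic phantom and MR signal simulation.

The phantom stands in for a clinical prostate cohort: each synthetic
subject is a multi-slice label map of nested elliptical structures
(body/muscle, transition zone, peripheral zone, a tumor inside the
peripheral zone, and a bladder), paired with ground-truth proton
density, T1 and T2 property maps.  Three acquisitions are simulated
from the property maps with standard steady-state signal equations:

* FLASH (spoiled gradient echo, T1-weighted):
  ``S = PD * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-TE/T2)``
  with ``E1 = exp(-TR/T1)`` (the Ernst equation),
* TSE (T2-weighted) and each echo of a multi-echo spin-echo train:
  ``S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)``.

Mono-exponential decay is assumed throughout; stimulated-echo and B1
effects are not modelled (the downstream reference fit drops the first
echo, as is common practice to mitigate exactly those effects in real
data).  Magnitude images are corrupted with Rician noise, and
inter-acquisition patient motion is emulated by smooth random in-plane
deformation fields whose ground truth is returned for registration
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PhantomConfig, SequenceConfig
from .io_core import ImageVolume, LabelVolume

__all__ = [
    "TissueProperties",
    "PhantomSubject",
    "ASCohortSpec",
    "LABELS",
    "generate_phantom",
    "simulate_flash",
    "simulate_tse",
    "simulate_mese",
    "add_noise",
    "apply_deformation",
    "generate_as_cohort",
]

#: Integer codes of the anatomy labels (0 = background tissue).
LABELS = {
    "background": 0,
    "muscle": 1,
    "transition_zone": 2,
    "peripheral_zone": 3,
    "tumor": 4,
    "bladder": 5,
}

ROI_LEGEND = {1: "tumor", 2: "non_tumor_pz"}


@dataclass(frozen=True)
class TissueProperties:
    """Relaxometry properties of one tissue class."""

    pd: float   # relative proton density, a.u.
    t1: float   # ms
    t2: float   # ms

    def __post_init__(self):
        if self.pd <= 0:
            raise ValueError(f"PD must be > 0, got {self.pd}")
        if not (self.t1 >= self.t2 > 0):
            raise ValueError(f"need T1 >= T2 > 0, got T1={self.t1}, T2={self.t2}")


@dataclass
class PhantomSubject:
    """One synthetic subject: anatomy labels plus ground-truth property maps."""

    subject_id: str
    labels: LabelVolume
    pd_map: ImageVolume
    t1_map: ImageVolume
    t2_map: ImageVolume          # units: ms
    roi_labels: LabelVolume      # 1 = tumor, 2 = non-tumor peripheral zone
    timepoint: int = 1


@dataclass
class ASCohortSpec:
    """Two-timepoint active-surveillance cohort specification.

    Per-arm tumor delta-T2 distributions default to the progressor /
    non-progressor statistics observed in serial prostate MRI:
    -10.7 +/- 14.2 ms for progressors and 3.4 +/- 14.5 ms for
    non-progressors, about 12 months apart.
    """

    n_progressors: int = 11
    n_nonprogressors: int = 31
    delta_mean: tuple[float, float] = (-10.7, 3.4)   # (progressor, non-progressor) ms
    delta_sd: tuple[float, float] = (14.2, 14.5)     # ms
    interval_months: float = 12.0                     # metadata only

    def __post_init__(self):
        if self.n_progressors < 1 or self.n_nonprogressors < 1:
            raise ValueError("arm counts must be >= 1")
        if any(s <= 0 for s in self.delta_sd):
            raise ValueError("delta sds must be > 0")


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def _ellipse(nx: int, ny: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Zero-mean smooth random scalar field normalized to unit max |value|."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def generate_phantom(
    cfg: PhantomConfig,
    seed: int,
    subject_id: str = "sub-000",
    timepoint: int = 1,
    t2_overrides: dict[str, float] | None = None,
) -> PhantomSubject:
    """Generate one synthetic subject, deterministically under ``seed``.

    Anatomy is nested per-slice ellipses with per-subject random axes
    and centers.  Per-voxel property values are the tissue-class mean
    times ``(1 + Gaussian jitter)`` times a smooth multiplicative bias
    field; with jitter and bias disabled the maps are piecewise
    constant at exactly the class means.

    Parameters
    ----------
    t2_overrides
        Optional per-tissue T2 class-mean replacements (ms), used by the
        active-surveillance cohort generator to shift tumor T2 between
        timepoints.

    Raises
    ------
    ValueError
        If the in-plane grid is not divisible by 16 (the estimation
        network downsamples 4 times; pad or crop the grid to a multiple
        of 16).
    """
    nx, ny, nz = cfg.grid
    if nx % 16 or ny % 16:
        raise ValueError(
            f"in-plane grid {nx}x{ny} not divisible by 16; "
            "pad (or crop) the grid to a multiple of 16"
        )
    if nz < 1:
        raise ValueError("need at least one slice")

    tissues = {k: list(v) for k, v in cfg.tissues.items()}
    for name, t2 in (t2_overrides or {}).items():
        tissues[name][2] = float(t2)

    rng = np.random.default_rng(seed)
    lab = np.zeros((nx, ny, nz), dtype=np.int32)

    # per-subject anatomical variation
    body_ax = nx * rng.uniform(0.40, 0.46)
    body_ay = ny * rng.uniform(0.36, 0.42)
    pz_cx = nx * rng.uniform(0.48, 0.52)
    pz_cy = ny * rng.uniform(0.58, 0.64)      # prostate posterior (high y)
    pz_ax = nx * rng.uniform(0.16, 0.20)
    pz_ay = ny * rng.uniform(0.12, 0.15)
    bl_cy = ny * rng.uniform(0.26, 0.32)      # bladder anterior (low y)
    bl_ax = nx * rng.uniform(0.12, 0.16)
    bl_ay = ny * rng.uniform(0.10, 0.14)
    tu_theta = rng.uniform(0.15, 0.85) * math.pi  # tumor azimuth within PZ ring
    tu_r = rng.uniform(0.10, 0.14) * min(nx, ny)

    mid = (nz - 1) / 2.0
    for k in range(nz):
        # structures taper away from the central slice
        taper = 1.0 - 0.35 * abs(k - mid) / max(mid, 1.0)
        body = _ellipse(nx, ny, nx / 2, ny / 2, body_ax, body_ay * (0.9 + 0.1 * taper))
        sl = np.zeros((nx, ny), dtype=np.int32)
        sl[body] = LABELS["muscle"]

        pz = _ellipse(nx, ny, pz_cx, pz_cy, pz_ax * taper, pz_ay * taper)
        tz = _ellipse(nx, ny, pz_cx, pz_cy - 0.15 * pz_ay, pz_ax * taper * 0.55,
                      pz_ay * taper * 0.55)
        sl[pz & body] = LABELS["peripheral_zone"]
        sl[tz & pz & body] = LABELS["transition_zone"]

        # tumor: small ellipse constrained to the peripheral zone
        tcx = pz_cx + 0.62 * pz_ax * taper * math.cos(tu_theta)
        tcy = pz_cy + 0.62 * pz_ay * taper * math.sin(tu_theta)
        tumor = _ellipse(nx, ny, tcx, tcy, tu_r * taper * 0.45, tu_r * taper * 0.38)
        sl[tumor & (sl == LABELS["peripheral_zone"])] = LABELS["tumor"]

        if cfg.include_bladder:
            bl = _ellipse(nx, ny, nx / 2, bl_cy, bl_ax * (0.7 + 0.3 * taper),
                          bl_ay * (0.7 + 0.3 * taper))
            sl[bl & body & (sl == LABELS["muscle"])] = LABELS["bladder"]
        lab[:, :, k] = sl

    # property maps: class mean x (1 + jitter) x (1 + bias)
    pd_map = np.empty(lab.shape)
    t1_map = np.empty(lab.shape)
    t2_map = np.empty(lab.shape)
    for name, code in LABELS.items():
        if name not in tissues:
            continue
        pd, t1, t2 = tissues[name]
        m = lab == code
        pd_map[m], t1_map[m], t2_map[m] = pd, t1, t2

    if cfg.jitter_sd > 0:
        for arr in (pd_map, t1_map, t2_map):
            arr *= 1.0 + cfg.jitter_sd * rng.standard_normal(lab.shape)
    if cfg.bias_field_amplitude > 0:
        bias = cfg.bias_field_amplitude * _smooth_field(
            lab.shape, cfg.bias_field_smoothness, rng)
        for arr in (pd_map, t1_map, t2_map):
            arr *= 1.0 + bias
    np.clip(pd_map, 1e-3, None, out=pd_map)
    np.clip(t2_map, 1.0, None, out=t2_map)
    np.maximum(t1_map, t2_map, out=t1_map)   # preserve T1 >= T2

    spacing = tuple(cfg.spacing_mm)
    legend = {v: k for k, v in LABELS.items() if v != 0}
    roi = np.zeros_like(lab)
    roi[lab == LABELS["tumor"]] = 1
    # non-tumor ROI: peripheral zone away from the tumor margin
    pz_mask = lab == LABELS["peripheral_zone"]
    near_tumor = ndimage.binary_dilation(lab == LABELS["tumor"], iterations=2)
    roi[pz_mask & ~near_tumor] = 2

    return PhantomSubject(
        subject_id=subject_id,
        labels=LabelVolume(lab, spacing=spacing, legend=legend),
        pd_map=ImageVolume(pd_map, spacing=spacing, units="arbitrary"),
        t1_map=ImageVolume(t1_map, spacing=spacing, units="ms"),
        t2_map=ImageVolume(t2_map, spacing=spacing, units="ms"),
        roi_labels=LabelVolume(roi, spacing=spacing, legend=dict(ROI_LEGEND)),
        timepoint=timepoint,
    )


# ---------------------------------------------------------------------------
# signal models
# ---------------------------------------------------------------------------

def flash_signal(pd, t1, t2, te: float, tr: float, flip_deg: float):
    """Ernst-equation spoiled gradient-echo signal (elementwise)."""
    a = math.radians(flip_deg)
    e1 = np.exp(-tr / np.asarray(t1, dtype=float))
    return pd * math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1) * np.exp(-te / t2)


def spin_echo_signal(pd, t1, t2, te: float, tr: float):
    """Saturation-recovery spin-echo signal (elementwise)."""
    return pd * (1.0 - np.exp(-tr / np.asarray(t1, dtype=float))) * np.exp(-te / t2)


def _props(subject: PhantomSubject):
    return subject.pd_map.data, subject.t1_map.data, subject.t2_map.data


def simulate_flash(subject: PhantomSubject, params: SequenceConfig) -> ImageVolume:
    """Noiseless T1-weighted FLASH image of a phantom subject."""
    if params.sequence != "FLASH":
        raise ValueError(f"expected FLASH params, got {params.sequence}")
    _validate_seq(params)
    pd, t1, t2 = _props(subject)
    s = flash_signal(pd, t1, t2, params.te, params.tr, params.flip_angle)
    return subject.pd_map.with_data(s, units="arbitrary")


def simulate_tse(subject: PhantomSubject, params: SequenceConfig) -> ImageVolume:
    """Noiseless T2-weighted TSE image of a phantom subject."""
    if params.sequence != "TSE":
        raise ValueError(f"expected TSE params, got {params.sequence}")
    _validate_seq(params)
    pd, t1, t2 = _props(subject)
    s = spin_echo_signal(pd, t1, t2, params.te, params.tr)
    return subject.pd_map.with_data(s, units="arbitrary")


def simulate_mese(subject: PhantomSubject, params: SequenceConfig) -> list[ImageVolume]:
    """Noiseless multi-echo spin-echo train: one image per echo time."""
    if params.sequence != "MESE":
        raise ValueError(f"expected MESE params, got {params.sequence}")
    tes = list(params.echo_times)
    if not tes or any(b <= a for a, b in zip(tes, tes[1:])):
        raise ValueError("MESE echo_times must be non-empty and strictly increasing")
    if tes[-1] >= params.tr:
        raise ValueError("echo times must be below TR")
    pd, t1, t2 = _props(subject)
    return [subject.pd_map.with_data(spin_echo_signal(pd, t1, t2, te, params.tr),
                                     units="arbitrary")
            for te in tes]


def _validate_seq(p: SequenceConfig) -> None:
    if not (0 < p.te < p.tr):
        raise ValueError(f"need 0 < TE < TR, got TE={p.te}, TR={p.tr}")
    if not (0 < p.flip_angle <= 180):
        raise ValueError(f"flip angle must be in (0, 180], got {p.flip_angle}")


def add_noise(vol: ImageVolume, sigma: float, seed: int) -> ImageVolume:
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), n1,n2 ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return vol
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, vol.data.shape)
    n2 = rng.normal(0.0, sigma, vol.data.shape)
    return vol.with_data(np.hypot(vol.data + n1, n2))


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def apply_deformation(
    vol: ImageVolume,
    amplitude_mm: float,
    smoothness: float,
    seed: int,
    field_mm: np.ndarray | None = None,
) -> tuple[ImageVolume, np.ndarray]:
    """Warp a volume by a smooth random in-plane displacement field.

    The field is a Gaussian-filtered white-noise vector field (in-plane
    components only, smooth through-plane as well) scaled so the maximum
    displacement magnitude equals ``amplitude_mm``.  Warping uses linear
    interpolation.  Returns the warped volume and the true field, shape
    ``(2, X, Y, Z)`` in mm, so registration accuracy can be measured
    against ground truth.  Pass ``field_mm`` to reuse a known field
    (e.g. to warp several acquisitions consistently).
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    shape = vol.data.shape
    if field_mm is None:
        if amplitude_mm == 0:
            field_mm = np.zeros((2,) + shape)
        else:
            rng = np.random.default_rng(seed)
            fx = ndimage.gaussian_filter(rng.standard_normal(shape),
                                         sigma=(smoothness, smoothness, 1.0))
            fy = ndimage.gaussian_filter(rng.standard_normal(shape),
                                         sigma=(smoothness, smoothness, 1.0))
            field_mm = np.stack([fx, fy])
            mag = np.sqrt(fx ** 2 + fy ** 2).max()
            if mag > 0:
                field_mm *= amplitude_mm / mag
    if np.allclose(field_mm, 0):
        return vol.with_data(vol.data.copy()), field_mm

    sx, sy, _ = vol.spacing
    xx, yy, zz = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    # pull-back warp: sample the input at x - u(x)
    coords = np.stack([xx - field_mm[0] / sx, yy - field_mm[1] / sy, zz])
    warped = ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest")
    return vol.with_data(warped), field_mm


# ---------------------------------------------------------------------------
# active-surveillance cohorts
# ---------------------------------------------------------------------------

def generate_as_cohort(
    spec: ASCohortSpec,
    seed: int,
    phantom_cfg: PhantomConfig | None = None,
) -> list[dict]:
    """Generate a two-timepoint cohort of phantom subjects.

    For each subject the timepoint-2 tumor T2 class mean equals the
    timepoint-1 value plus a draw from the arm's Normal(delta_mean,
    delta_sd^2), truncated so T2 stays above 10 ms.  Anatomy is shared
    between timepoints but independently re-deformed downstream (each
    timepoint is simulated as its own acquisition session).

    Returns one record per subject:
    ``{"subject_id", "arm", "delta_ms", "timepoint1", "timepoint2"}``
    with ``arm`` in {"progressor", "non-progressor"}.
    """
    phantom_cfg = phantom_cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    base_t2 = phantom_cfg.tissues["tumor"][2]
    records = []
    arms = [("progressor", spec.n_progressors, spec.delta_mean[0], spec.delta_sd[0]),
            ("non-progressor", spec.n_nonprogressors, spec.delta_mean[1], spec.delta_sd[1])]
    idx = 0
    for arm, n, mu, sd in arms:
        for _ in range(n):
            sid = f"as-{idx:03d}"
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            delta = float(rng.normal(mu, sd))
            delta = max(delta, 10.0 - base_t2 + 1e-9)  # keep T2 > 10 ms
            tp1 = generate_phantom(phantom_cfg, sub_seed, subject_id=sid, timepoint=1)
            tp2 = generate_phantom(phantom_cfg, sub_seed, subject_id=sid, timepoint=2,
                                   t2_overrides={"tumor": base_t2 + delta})
            records.append({"subject_id": sid, "arm": arm, "delta_ms": delta,
                            "timepoint1": tp1, "timepoint2": tp2})
            idx += 1
    return records


def sample_deltas(spec: ASCohortSpec, seed: int,
                  n_per_arm: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject tumor delta-T2 values (ms) for both arms.

    Returns ``(deltas, labels)`` with ``labels`` 1 for progressors.
    ``n_per_arm`` overrides both arm counts (used for large-n
    classification analyses where no imaging is needed).
    """
    rng = np.random.default_rng(seed)
    n_p = n_per_arm or spec.n_progressors
    n_n = n_per_arm or spec.n_nonprogressors
    d_p = rng.normal(spec.delta_mean[0], spec.delta_sd[0], n_p)
    d_n = rng.normal(spec.delta_mean[1], spec.delta_sd[1], n_n)
    deltas = np.concatenate([d_p, d_n])
    labels = np.concatenate([np.ones(n_p, dtype=int), np.zeros(n_n, dtype=int)])
    return deltas, labels
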