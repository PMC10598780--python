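"""Reference T2 mapping by mono-exponential fitting of a multi-echo train.

Per voxel the model is ``S(TE) = S0 * exp(-TE/T2)``.  The primary fitter
is log-linear weighted least squares with weights ``S^2``, which undoes
the noise distortion introduced by taking the logarithm and is exact on
noiseless data; an optional vectorized Gauss-Newton polish refines the
estimate in the signal domain.  The first echo can be dropped before
fitting — standard practice with multi-echo spin-echo data, where the
first echo is biased by stimulated-echo/B1 effects that the later
echoes share more uniformly.

Voxels with any non-positive retained echo are excluded (the log is
undefined and such voxels are background): their ``fit_mask`` is false
and T2 is reported as 0.  No upper clamp is applied to fitted T2 —
extreme values (urine) are handled downstream by the extreme-value
mask, preserving the pipeline order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ImageVolume

__all__ = ["FitResult", "fit_t2"]


@dataclass
class FitResult:
    t2_map: ImageVolume      # ms; 0 where the fit failed
    s0_map: ImageVolume      # a.u.
    rsq_map: np.ndarray      # coefficient of determination per voxel
    fit_mask: np.ndarray     # True where fitting succeeded


def fit_t2(
    echoes: list[ImageVolume],
    te_list: list[float] | np.ndarray,
    drop_first: bool = True,
    nonlinear_polish: bool = False,
    polish_iters: int = 8,
) -> FitResult:
    """Fit a mono-exponential T2 decay voxelwise.

    Parameters
    ----------
    echoes
        One image per echo, identical geometry.
    te_list
        Echo times in ms, strictly increasing, same length as ``echoes``.
    drop_first
        Remove the first echo before fitting (default, recommended for
        multi-echo spin-echo references).
    nonlinear_polish
        Refine the log-linear solution with Gauss-Newton iterations on
        ``(log S0, 1/T2)`` in the signal domain.
    """
    te = np.asarray(te_list, dtype=float)
    if len(echoes) != te.size:
        raise ValueError(f"{len(echoes)} echoes but {te.size} echo times")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if drop_first:
        echoes = echoes[1:]
        te = te[1:]
    if len(echoes) < 3:
        raise ValueError("need at least 3 echoes after dropping the first")

    ref = echoes[0]
    sig = np.stack([e.data for e in echoes], axis=0).astype(float)  # (E, X, Y, Z)
    usable = np.all(sig > 0, axis=0)

    t2 = np.zeros(ref.shape, dtype=float)
    s0 = np.zeros(ref.shape, dtype=float)
    rsq = np.full(ref.shape, -np.inf)
    mask = np.zeros(ref.shape, dtype=bool)
    if usable.any():
        s = sig[:, usable]                       # (E, N)
        tec = te[:, None]
        y = np.log(s)
        w = s ** 2
        sw = w.sum(0)
        swx = (w * tec).sum(0)
        swy = (w * y).sum(0)
        swxx = (w * tec ** 2).sum(0)
        swxy = (w * tec * y).sum(0)
        denom = sw * swxx - swx ** 2
        slope = (sw * swxy - swx * swy) / denom
        intercept = (swy - slope * swx) / sw
        ok = slope < 0                           # decaying signal only
        r2v = np.where(ok, -slope, 0.0)          # decay rate 1/T2
        ls0 = intercept

        if nonlinear_polish:
            r2v, ls0 = _gauss_newton(s, te, r2v, ls0, ok, polish_iters)

        t2v = np.zeros_like(slope)
        t2v[ok] = 1.0 / r2v[ok]
        s0v = np.exp(ls0)
        pred = s0v[None, :] * np.exp(-tec * r2v[None, :])
        ss_res = ((s - pred) ** 2).sum(0)
        ss_tot = ((s - s.mean(0)) ** 2).sum(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2stat = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

        t2[usable] = np.where(ok, t2v, 0.0)
        s0[usable] = np.where(ok, s0v, 0.0)
        rsq[usable] = np.where(ok, r2stat, -np.inf)
        m = np.zeros(ok.shape, dtype=bool)
        m[:] = ok
        mask[usable] = m

    return FitResult(
        t2_map=ref.with_data(t2, units="ms"),
        s0_map=ref.with_data(s0, units="arbitrary"),
        rsq_map=rsq,
        fit_mask=mask,
    )


def _gauss_newton(s, te, r2v, ls0, ok, iters):
    """Vectorized Gauss-Newton on residual S - exp(ls0 - TE*r2) (active voxels only)."""
    r2v = r2v.copy()
    ls0 = ls0.copy()
    tec = te[:, None]
    act = np.where(ok)[0]
    a_r2, a_ls0 = r2v[act], ls0[act]
    sa = s[:, act]
    for _ in range(iters):
        pred = np.exp(a_ls0[None, :] - tec * a_r2[None, :])
        res = sa - pred
        # Jacobian columns: d pred/d ls0 = pred; d pred/d r2 = -TE*pred
        j11 = (pred * pred).sum(0)
        j12 = (-tec * pred * pred).sum(0)
        j22 = (tec ** 2 * pred * pred).sum(0)
        g1 = (pred * res).sum(0)
        g2 = (-tec * pred * res).sum(0)
        det = j11 * j22 - j12 ** 2
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        d_ls0 = (j22 * g1 - j12 * g2) / det
        d_r2 = (-j12 * g1 + j11 * g2) / det
        a_ls0 += np.clip(d_ls0, -1.0, 1.0)
        a_r2 += np.clip(d_r2, -0.05, 0.05)
        np.clip(a_r2, 1e-6, None, out=a_r2)
    r2v[act], ls0[act] = a_r2, a_ls0
    return r2v, ls0
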