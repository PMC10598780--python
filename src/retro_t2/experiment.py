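"""End-to-end desk-scale recovery experiment.

Orchestrates the full study on synthetic subjects: simulate a cohort
(three acquisitions per subject, with Rician noise and per-acquisition
deformation), fit reference T2 maps from the multi-echo series
(dropping the first echo), run the preprocessing chain (registration to
the TE=84 ms echo, bladder masking, mean+3sd normalization, 400 ms
scaling, extreme-value masks), train the U-Net on the training split,
and evaluate the held-out test subjects with masked global metrics and
tumor / non-tumor ROI statistics.  Everything is a pure function of
(config, seed).

The optional active-surveillance analysis classifies progressors from
non-progressors by per-subject tumor deltaT2 using the rank AUC; at
desk scale the deltas come from ground-truth tumor means of generated
two-timepoint phantoms, and for large-n analyses directly from the
arm-level delta distributions (no imaging required).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as mx
from .config import RunConfig
from .estimator import NetworkSpec, build_network, make_splits, predict, train
from .io_core import ImageVolume
from .phantom import (ASCohortSpec, PhantomSubject, add_noise, apply_deformation,
                      generate_as_cohort, generate_phantom, sample_deltas,
                      simulate_flash, simulate_mese, simulate_tse)
from .preprocess import (extreme_mask, make_bladder_mask, normalize_weighted,
                         register_deformable, scale_t2, select_registration_target)
from .t2fit import fit_t2

__all__ = ["SubjectData", "ExperimentReport", "simulate_subject",
           "preprocess_subject", "run_recovery_experiment", "run_as_analysis"]


@dataclass
class SubjectData:
    """Everything the pipeline knows about one simulated subject."""

    subject: PhantomSubject
    echoes: list[ImageVolume]
    t1w: ImageVolume
    t2w: ImageVolume
    true_fields: dict[str, np.ndarray]
    # filled by preprocess_subject:
    ref_t2: ImageVolume | None = None
    t1w_norm: ImageVolume | None = None
    t2w_norm: ImageVolume | None = None
    bladder: np.ndarray | None = None
    extreme: np.ndarray | None = None
    target_scaled: ImageVolume | None = None


@dataclass
class ExperimentReport:
    config_hash: str
    seed: int
    folds: list[dict] = field(default_factory=list)
    slice_metrics: pd.DataFrame | None = None
    roi_table: pd.DataFrame | None = None
    tumor_vs_nontumor: mx.TTestResult | None = None
    est_vs_gt_tumor_ttest: mx.TTestResult | None = None
    mean_abs_tumor_error_ms: float = float("nan")
    pearson_pooled: float = float("nan")
    pearson_slice_mean: float = float("nan")
    as_analysis: dict | None = None
    loss_history: dict | None = None


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(n)]


def simulate_subject(cfg: RunConfig, seed: int, subject_id: str) -> SubjectData:
    """Simulate one subject's three acquisitions with noise and motion."""
    s = _spawn_seeds(seed, 6)
    sub = generate_phantom(cfg.phantom, s[0], subject_id=subject_id)
    acq = cfg.acquisition

    echoes = simulate_mese(sub, acq.mese)
    echoes = [add_noise(e, acq.noise_sigma, s[1] + k) for k, e in enumerate(echoes)]

    # each weighted acquisition suffers its own motion relative to the T2 scan
    t1w, fld1 = apply_deformation(simulate_flash(sub, acq.flash),
                                  acq.deform_amplitude_mm, acq.deform_smoothness, s[2])
    t2w, fld2 = apply_deformation(simulate_tse(sub, acq.tse),
                                  acq.deform_amplitude_mm, acq.deform_smoothness, s[3])
    t1w = add_noise(t1w, acq.noise_sigma, s[4])
    t2w = add_noise(t2w, acq.noise_sigma, s[5])
    return SubjectData(subject=sub, echoes=echoes, t1w=t1w, t2w=t2w,
                       true_fields={"t1w": fld1, "t2w": fld2})


def preprocess_subject(data: SubjectData, cfg: RunConfig,
                       register: bool = True) -> SubjectData:
    """Reference fit + the preprocessing chain, in place."""
    acq, ev = cfg.acquisition, cfg.evaluation
    fit = fit_t2(data.echoes, acq.mese.echo_times, drop_first=True)
    data.ref_t2 = fit.t2_map

    idx, _ = select_registration_target(acq.mese.echo_times, acq.tse.te)
    target = data.echoes[idx]
    if register:
        # T1w has inverted urine contrast vs a late echo -> gradient channel
        t1w_reg, _, _ = register_deformable(data.t1w, target, channel="gradient")
        t2w_reg, _, _ = register_deformable(data.t2w, target, channel="intensity")
    else:
        t1w_reg, t2w_reg = data.t1w, data.t2w

    data.bladder = make_bladder_mask(t1w_reg)
    data.t1w_norm, _ = normalize_weighted(t1w_reg, data.bladder)
    data.t2w_norm, _ = normalize_weighted(t2w_reg, data.bladder)
    data.extreme = extreme_mask(data.ref_t2, ev.extreme_threshold_ms)
    data.target_scaled = scale_t2(data.ref_t2, ev.scale_t2_ms)
    return data


def _slice_samples(data: SubjectData, exclude_bladder: bool) -> list:
    samples = []
    loss_keep = ~data.extreme
    if exclude_bladder:
        loss_keep = loss_keep & ~data.bladder
    for k in range(data.subject.t2_map.n_slices):
        x = np.stack([data.t1w_norm.data[:, :, k],
                      data.t2w_norm.data[:, :, k]], axis=-1)
        t = data.target_scaled.data[:, :, k][..., None]
        m = loss_keep[:, :, k][..., None]
        samples.append((x.astype(np.float32), t.astype(np.float32),
                        m.astype(np.float32)))
    return samples


def run_recovery_experiment(cfg: RunConfig) -> ExperimentReport:
    """Simulate, fit, preprocess, train and evaluate; fully seeded."""
    ex, tr, ev = cfg.experiment, cfg.training, cfg.evaluation
    report = ExperimentReport(config_hash=cfg.hash(), seed=cfg.seed)
    seeds = _spawn_seeds(cfg.seed, ex.n_subjects + 3)

    ids = [f"sub-{i:03d}" for i in range(ex.n_subjects)]
    subjects = {}
    for i, sid in enumerate(ids):
        d = simulate_subject(cfg, seeds[i], sid)
        subjects[sid] = preprocess_subject(d, cfg, register=ex.registration)

    plan = make_splits(ids, k=max(ex.folds) + 1,
                       sizes=(ex.n_train, ex.n_val, ex.n_test),
                       seed=seeds[-3])

    slice_rows, roi_rows = [], []
    pooled_est, pooled_ref = [], []
    hist_by_fold = {}
    for fold in ex.folds:
        roles = plan.folds[fold]
        train_s = [s for sid in roles["train"]
                   for s in _slice_samples(subjects[sid], tr.exclude_bladder_from_loss)]
        val_s = [s for sid in roles["val"]
                 for s in _slice_samples(subjects[sid], tr.exclude_bladder_from_loss)]
        spec = NetworkSpec(base_width=ex.base_width, upsample=tr.upsample)
        model = build_network(spec, seed=seeds[-2] + fold)
        tcfg = type(tr)(**{**tr.__dict__, "epochs": ex.epochs})
        model, hist = train(model, train_s, val_s, tcfg, seed=seeds[-1] + fold)
        hist_by_fold[fold] = {"train": hist.train_loss, "val": hist.val_loss,
                              "best_epoch": hist.best_epoch}

        for sid in roles["test"]:
            d = subjects[sid]
            est = predict(model, d.t1w_norm, d.t2w_norm, ev.scale_t2_ms)
            excluded = d.bladder | d.extreme
            pooled_est.append(est.data[~excluded])
            pooled_ref.append(d.ref_t2.data[~excluded])
            for sm in mx.evaluate_slices(est, d.ref_t2, excluded,
                                         ev.psnr_range_ms, ev.mpe_floor_ms):
                slice_rows.append({"fold": fold, "subject": sid, **sm.__dict__})
            rois = {"tumor": d.subject.roi_labels.data == 1,
                    "non_tumor": d.subject.roi_labels.data == 2}
            est_stats = mx.roi_mean_t2(est, rois, exclude=d.extreme, subject_id=sid)
            ref_stats = mx.roi_mean_t2(d.ref_t2, rois, exclude=d.extreme,
                                       subject_id=sid)
            gt_stats = mx.roi_mean_t2(d.subject.t2_map, rois, exclude=d.extreme,
                                      subject_id=sid)
            for region in rois:
                roi_rows.append({
                    "fold": fold, "subject": sid, "region": region,
                    "est_mean_ms": est_stats.regions[region].mean,
                    "ref_mean_ms": ref_stats.regions[region].mean,
                    "gt_mean_ms": gt_stats.regions[region].mean,
                    "est_sd_ms": est_stats.regions[region].sd,
                    "n_voxels": est_stats.regions[region].n,
                })
        report.folds.append({"fold": fold, **roles})

    report.slice_metrics = pd.DataFrame(slice_rows)
    report.roi_table = pd.DataFrame(roi_rows)
    report.loss_history = hist_by_fold

    roi = report.roi_table
    tum = roi[roi.region == "tumor"].sort_values("subject")
    non = roi[roi.region == "non_tumor"].sort_values("subject")
    if len(tum) >= 2:
        report.tumor_vs_nontumor = mx.paired_ttest(
            tum.est_mean_ms.values, non.est_mean_ms.values, ev.alpha)
        report.est_vs_gt_tumor_ttest = mx.paired_ttest(
            tum.est_mean_ms.values, tum.gt_mean_ms.values, ev.alpha)
    report.mean_abs_tumor_error_ms = float(
        np.abs(tum.est_mean_ms.values - tum.gt_mean_ms.values).mean())
    sm = report.slice_metrics
    report.pearson_slice_mean = float(sm.pearson_r.mean())
    report.pearson_pooled = mx.pearson(np.concatenate(pooled_est),
                                       np.concatenate(pooled_ref))

    if ex.as_cohort:
        spec = ASCohortSpec(n_progressors=ex.as_n_progressors,
                            n_nonprogressors=ex.as_n_nonprogressors,
                            delta_mean=tuple(ex.as_delta_mean),
                            delta_sd=tuple(ex.as_delta_sd))
        report.as_analysis = run_as_analysis(spec, seeds[-1], cfg=cfg)
    return report


def run_as_analysis(
    spec: ASCohortSpec,
    seed: int,
    n_per_arm: int | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """Active-surveillance deltaT2 analysis.

    With ``n_per_arm`` set, deltas are drawn directly from the arm
    distributions (large-n classification study, no imaging).  Otherwise
    two-timepoint phantoms are generated and the deltas measured from
    ground-truth tumor ROI means.  Progression scores are the negated
    deltas (progressors lose T2), summarized by the rank AUC plus a
    Welch t-test between arms.
    """
    if n_per_arm is not None:
        deltas, labels = sample_deltas(spec, seed, n_per_arm)
    else:
        phantom_cfg = cfg.phantom if cfg is not None else None
        records = generate_as_cohort(spec, seed, phantom_cfg)
        stats1, stats2, labels_l = [], [], []
        for rec in records:
            rois = {"tumor": rec["timepoint1"].roi_labels.data == 1}
            stats1.append(mx.roi_mean_t2(rec["timepoint1"].t2_map, rois,
                                         subject_id=rec["subject_id"]))
            rois2 = {"tumor": rec["timepoint2"].roi_labels.data == 1}
            stats2.append(mx.roi_mean_t2(rec["timepoint2"].t2_map, rois2,
                                         subject_id=rec["subject_id"]))
            labels_l.append(1 if rec["arm"] == "progressor" else 0)
        dmap = mx.delta_t2(stats1, stats2)
        deltas = np.array([dmap[s.subject_id] for s in stats1])
        labels = np.array(labels_l)

    auc = mx.roc_auc(-deltas, labels)
    tt = mx.unpaired_ttest(deltas[labels == 1], deltas[labels == 0])
    return {
        "n_progressors": int((labels == 1).sum()),
        "n_nonprogressors": int((labels == 0).sum()),
        "delta_mean_progressor_ms": float(deltas[labels == 1].mean()),
        "delta_mean_nonprogressor_ms": float(deltas[labels == 0].mean()),
        "auc": float(auc),
        "ttest_t": tt.t,
        "ttest_p": tt.p,
        "significant": tt.significant,
    }
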