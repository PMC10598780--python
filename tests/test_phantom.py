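import numpy as np
import pytest

from retro_t2.config import PhantomConfig, SequenceConfig
from retro_t2.io_core import ImageVolume, LabelVolume
from retro_t2.phantom import (ASCohortSpec, PhantomSubject, add_noise,
                              apply_deformation, flash_signal, generate_as_cohort,
                              generate_phantom, sample_deltas, simulate_flash,
                              simulate_mese, simulate_tse)


def uniform_subject(pd=100.0, t1=1000.0, t2=80.0, shape=(4, 4, 2)):
    """Hand-built subject with spatially constant properties."""
    lab = np.ones(shape, dtype=np.int32)
    mk = lambda v, u: ImageVolume(np.full(shape, v), units=u)
    return PhantomSubject(
        subject_id="uniform",
        labels=LabelVolume(lab, legend={1: "muscle"}),
        pd_map=mk(pd, "arbitrary"), t1_map=mk(t1, "ms"), t2_map=mk(t2, "ms"),
        roi_labels=LabelVolume(np.zeros(shape, dtype=np.int32)),
    )


class TestGeneratePhantom:
    def test_tumor_t2_near_class_mean(self):
        cfg = PhantomConfig(grid=[128, 128, 6])
        sub = generate_phantom(cfg, seed=1)
        tumor = sub.roi_labels.data == 1
        assert tumor.sum() > 20
        mean_t2 = sub.t2_map.data[tumor].mean()
        # 3% jitter + 5% bias around the 80.4 ms class mean
        assert mean_t2 == pytest.approx(80.4, rel=0.08)

    def test_piecewise_constant_without_jitter(self):
        cfg = PhantomConfig(grid=[64, 64, 3], jitter_sd=0.0,
                            bias_field_amplitude=0.0)
        sub = generate_phantom(cfg, seed=2)
        pz = sub.labels.mask("peripheral_zone")
        assert np.unique(sub.t2_map.data[pz]).tolist() == [106.8]
        assert np.unique(sub.t2_map.data[sub.labels.mask("tumor")]).tolist() == [80.4]

    def test_deterministic_under_seed(self):
        cfg = PhantomConfig(grid=[64, 64, 3])
        a = generate_phantom(cfg, seed=9)
        b = generate_phantom(cfg, seed=9)
        np.testing.assert_array_equal(a.labels.data, b.labels.data)
        np.testing.assert_array_equal(a.t2_map.data, b.t2_map.data)

    def test_tumor_inside_peripheral_zone(self, small_subject):
        tumor = small_subject.labels.mask("tumor")
        pz = small_subject.labels.mask("peripheral_zone")
        grown = tumor | pz
        # tumor voxels were carved out of the PZ ellipse
        assert tumor.any() and not (tumor & pz).any()
        assert small_subject.t2_map.data[tumor].mean() < \
            small_subject.t2_map.data[pz].mean()

    def test_grid_not_divisible_by_16(self):
        with pytest.raises(ValueError, match="pad"):
            generate_phantom(PhantomConfig(grid=[100, 100, 2]), seed=0)

    def test_t1_at_least_t2(self, small_subject):
        assert (small_subject.t1_map.data >= small_subject.t2_map.data).all()


class TestSignalModels:
    def test_flash_matches_independent_calculator(self):
        sub = uniform_subject(pd=100, t1=1000, t2=80)
        img = simulate_flash(sub, SequenceConfig(
            sequence="FLASH", te=2.03, tr=250, flip_angle=48.0))
        assert img.data[0, 0, 0] == pytest.approx(33.46644747754667, rel=1e-9)

    def test_flash_limit_long_tr_90deg(self):
        sub = uniform_subject(pd=50, t1=800, t2=60)
        img = simulate_flash(sub, SequenceConfig(
            sequence="FLASH", te=30.0, tr=1e7, flip_angle=90.0))
        assert img.data[0, 0, 0] == pytest.approx(50 * np.exp(-30 / 60), rel=1e-9)

    def test_flash_vanishes_at_zero_flip(self):
        # sin(alpha) factor: signal -> 0 as alpha -> 0
        s = flash_signal(100.0, 1000.0, 80.0, te=2.03, tr=250.0, flip_deg=1e-7)
        assert abs(s) < 1e-6

    def test_tse_closed_form(self):
        sub = uniform_subject(pd=100, t1=100, t2=80)
        img = simulate_tse(sub, SequenceConfig(
            sequence="TSE", te=80.0, tr=1e7, flip_angle=140.0))
        assert img.data[0, 0, 0] == pytest.approx(100 * np.exp(-1.0), rel=1e-9)

    def test_tse_monotone_in_t2(self):
        lo = uniform_subject(t2=80.4)
        hi = uniform_subject(t2=106.8)
        p = SequenceConfig(sequence="TSE", te=108.0, tr=3000.0, flip_angle=140.0)
        assert simulate_tse(lo, p).data[0, 0, 0] < simulate_tse(hi, p).data[0, 0, 0]

    def test_mese_echo_count_and_values(self):
        sub = uniform_subject(pd=100, t1=1000, t2=80)
        p = SequenceConfig(sequence="MESE", tr=4980.0, flip_angle=180.0,
                           echo_times=[10.5, 21.0, 31.5, 42.0, 52.5, 63.0,
                                       73.5, 84.0])
        echoes = simulate_mese(sub, p)
        assert len(echoes) == 8
        e1 = np.exp(-4980.0 / 1000.0)
        # S(84) for PD*(1-E1) = 100
        scale = 100.0 / (100.0 * (1 - e1))
        assert echoes[-1].data[0, 0, 0] * scale == pytest.approx(
            34.99377491111553, rel=1e-9)
        # echo ratio depends only on T2
        ratio = echoes[1].data[0, 0, 0] / echoes[3].data[0, 0, 0]
        assert ratio == pytest.approx(np.exp(21.0 / 80.0), rel=1e-12)

    def test_mese_strictly_decreasing(self, small_cfg, small_subject):
        echoes = simulate_mese(small_subject, small_cfg.acquisition.mese)
        stack = np.stack([e.data for e in echoes])
        assert (np.diff(stack, axis=0) < 0).all()

    def test_signals_nonnegative_finite(self, small_cfg, small_subject):
        for img in [simulate_flash(small_subject, small_cfg.acquisition.flash),
                    simulate_tse(small_subject, small_cfg.acquisition.tse),
                    *simulate_mese(small_subject, small_cfg.acquisition.mese)]:
            assert np.isfinite(img.data).all() and (img.data >= 0).all()


class TestNoise:
    def test_sigma_zero_identity(self, small_subject):
        out = add_noise(small_subject.pd_map, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, small_subject.pd_map.data)

    def test_rayleigh_mean_on_zero_signal(self):
        vol = ImageVolume(np.zeros((100, 100, 100)))
        out = add_noise(vol, 1.0, seed=3)
        expect = np.sqrt(np.pi / 2)
        se = np.sqrt((2 - np.pi / 2) / vol.data.size)
        assert abs(out.data.mean() - expect) < 3 * se

    def test_deterministic(self, small_subject):
        a = add_noise(small_subject.pd_map, 2.0, seed=5)
        b = add_noise(small_subject.pd_map, 2.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_sigma_rejected(self, small_subject):
        with pytest.raises(ValueError):
            add_noise(small_subject.pd_map, -1.0, seed=0)


class TestDeformation:
    def test_zero_amplitude_identity(self, rng):
        vol = ImageVolume(rng.random((32, 32, 2)))
        out, field = apply_deformation(vol, 0.0, 8.0, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)
        assert not field.any()

    def test_known_translation(self):
        # checkerboard shifted by a constant integer field
        base = np.indices((32, 32))[0] // 4 % 2 ^ (np.indices((32, 32))[1] // 4 % 2)
        vol = ImageVolume(np.repeat(base[..., None], 2, axis=2).astype(float))
        field = np.zeros((2, 32, 32, 2))
        field[0] = 2.0  # 2 mm = 2 voxels at unit spacing, along axis 0
        out, _ = apply_deformation(vol, 2.0, 8.0, seed=0, field_mm=field)
        np.testing.assert_allclose(out.data[4:, :, 0], vol.data[2:-2, :, 0])

    def test_amplitude_bound(self, rng):
        vol = ImageVolume(rng.random((64, 64, 3)))
        _, field = apply_deformation(vol, 3.0, 12.0, seed=4)
        mag = np.sqrt(field[0] ** 2 + field[1] ** 2)
        assert mag.max() <= 3.0 + 1e-9


class TestASCohort:
    def test_arm_counts_and_delta_sign(self):
        spec = ASCohortSpec(n_progressors=3, n_nonprogressors=4)
        cfg = PhantomConfig(grid=[64, 64, 2])
        recs = generate_as_cohort(spec, seed=11, phantom_cfg=cfg)
        assert sum(r["arm"] == "progressor" for r in recs) == 3
        assert sum(r["arm"] == "non-progressor" for r in recs) == 4
        for r in recs:
            tum1 = r["timepoint1"].roi_labels.data == 1
            tum2 = r["timepoint2"].roi_labels.data == 1
            m1 = r["timepoint1"].t2_map.data[tum1].mean()
            m2 = r["timepoint2"].t2_map.data[tum2].mean()
            assert m2 - m1 == pytest.approx(r["delta_ms"], abs=6.0)

    def test_delta_distribution_mean(self):
        spec = ASCohortSpec()
        deltas, labels = sample_deltas(spec, seed=2, n_per_arm=10_000)
        prog = deltas[labels == 1]
        se = 14.2 / np.sqrt(prog.size)
        assert abs(prog.mean() - (-10.7)) < 3 * se

    def test_zero_sd_equal_timepoints(self):
        # degenerate arms: no drift at all
        spec = ASCohortSpec(n_progressors=1, n_nonprogressors=1,
                            delta_mean=(0.0, 0.0), delta_sd=(1e-12, 1e-12))
        cfg = PhantomConfig(grid=[64, 64, 2], jitter_sd=0.0,
                            bias_field_amplitude=0.0)
        recs = generate_as_cohort(spec, seed=3, phantom_cfg=cfg)
        for r in recs:
            t1 = r["timepoint1"].t2_map.data[r["timepoint1"].roi_labels.data == 1]
            t2 = r["timepoint2"].t2_map.data[r["timepoint2"].roi_labels.data == 1]
            np.testing.assert_allclose(t1.mean(), t2.mean(), rtol=1e-9)
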