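import numpy as np
import pytest
from scipy import stats as sps

from retro_t2.io_core import ImageVolume
from retro_t2.metrics import (bland_altman, delta_t2, evaluate_slices, mpe,
                              paired_ttest, pearson, psnr, roc_auc,
                              roi_mean_t2, ssim, unpaired_ttest)


class TestPSNR:
    def test_constant_offset_closed_form(self):
        ref = np.zeros((32, 32))
        est = ref + 4.0
        res = psnr(est, ref, data_range=400.0)
        assert res.value == pytest.approx(40.0, abs=1e-9)   # 20*log10(400/4)
        assert not res.capped

    def test_identical_images_capped(self, rng):
        a = rng.random((16, 16))
        res = psnr(a, a.copy())
        assert res.capped and res.value == 300.0

    def test_matches_independent_formula(self, rng):
        est, ref = rng.random((20, 20)) * 100, rng.random((20, 20)) * 100
        mask = rng.random((20, 20)) > 0.3
        expected = 20 * np.log10(
            400.0 / np.sqrt(np.mean((est[mask] - ref[mask]) ** 2)))
        assert psnr(est, ref, mask).value == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_rejected(self, rng):
        a = rng.random((8, 8))
        with pytest.raises(ValueError, match="empty"):
            psnr(a, a, np.zeros((8, 8), bool))


class TestSSIM:
    def test_identical_is_one(self, rng):
        a = rng.random((32, 32)) * 400
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    def test_constant_images_luminance_only(self):
        # structure/contrast terms are 1 for constants; SSIM reduces to
        # the luminance term (2*mu_x*mu_y + C1)/(mu_x^2 + mu_y^2 + C1)
        a = np.full((32, 32), 100.0)
        b = np.full((32, 32), 150.0)
        c1 = (0.01 * 400.0) ** 2
        lum = (2 * 100 * 150 + c1) / (100 ** 2 + 150 ** 2 + c1)
        assert ssim(a, b) == pytest.approx(lum, rel=1e-9)

    def test_symmetric(self, rng):
        a, b = rng.random((32, 32)) * 400, rng.random((32, 32)) * 400
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_small_slice_rejected(self):
        a = np.ones((8, 8))
        with pytest.raises(ValueError, match="window"):
            ssim(a, a)


class TestMPE:
    def test_identical_zero(self, rng):
        a = rng.random((16, 16)) * 100 + 10
        assert mpe(a, a.copy()) == 0.0

    def test_ten_percent_scale(self, rng):
        ref = rng.random((16, 16)) * 100 + 10
        assert mpe(1.1 * ref, ref) == pytest.approx(10.0, rel=1e-9)

    def test_floor_excludes_near_zero_refs(self, rng):
        ref = rng.random((16, 16)) * 100 + 10
        est = ref.copy()
        ref[0, :4] = 0.0          # would divide by zero without the floor
        assert np.isfinite(mpe(est, ref, floor=1.0))


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.random((16, 16))
        assert pearson(x, x.copy()) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        a, b = rng.random(300), rng.random(300)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert pearson(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_missing(self):
        assert np.isnan(pearson(np.ones(10), np.arange(10.0)))


class TestMaskingInvariance:
    """No global metric may see voxels under the exclusion mask."""

    @pytest.mark.parametrize("fn", [
        lambda e, r, m: psnr(e, r, m).value,
        lambda e, r, m: ssim(e, r, m),
        lambda e, r, m: mpe(e, r, m),
        lambda e, r, m: pearson(e, r, m),
    ], ids=["psnr", "ssim", "mpe", "pearson"])
    def test_invariant_to_masked_voxels(self, fn, rng):
        est = rng.random((32, 32)) * 200 + 20
        ref = rng.random((32, 32)) * 200 + 20
        excluded = rng.random((32, 32)) < 0.25
        keep = ~excluded
        base = fn(est, ref, keep)
        est2, ref2 = est.copy(), ref.copy()
        est2[excluded] = rng.random(excluded.sum()) * 1e5
        ref2[excluded] = rng.random(excluded.sum()) * 1e5 + 1
        assert fn(est2, ref2, keep) == pytest.approx(base, rel=1e-9)


class TestROIStats:
    def test_uniform_region(self):
        t2 = ImageVolume(np.full((8, 8, 2), 80.0), units="ms")
        roi = np.zeros((8, 8, 2), bool)
        roi[2:5, 2:5, :] = True
        st = roi_mean_t2(t2, {"tumor": roi})
        assert st.regions["tumor"].mean == 80.0
        assert st.regions["tumor"].sd == 0.0
        assert st.regions["tumor"].n == 18

    def test_overlap_rejected(self):
        t2 = ImageVolume(np.ones((4, 4, 1)), units="ms")
        roi = np.ones((4, 4, 1), bool)
        with pytest.raises(ValueError, match="overlap"):
            roi_mean_t2(t2, {"a": roi, "b": roi})

    def test_extreme_voxels_excluded(self):
        data = np.full((4, 4, 1), 80.0)
        data[0, 0, 0] = 800.0
        t2 = ImageVolume(data, units="ms")
        roi = np.ones((4, 4, 1), bool)
        st = roi_mean_t2(t2, {"r": roi}, exclude=data > 400)
        assert st.regions["r"].mean == 80.0
        assert st.regions["r"].n == 15

    def test_empty_region_rejected(self):
        t2 = ImageVolume(np.ones((4, 4, 1)), units="ms")
        with pytest.raises(ValueError, match="empty"):
            roi_mean_t2(t2, {"r": np.zeros((4, 4, 1), bool)})


class TestTTests:
    def test_paired_identical(self):
        r = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0 and not r.significant

    def test_paired_matches_formula(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(11, 2, 12)
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_expect = 2 * sps.t.sf(abs(t_expect), d.size - 1)
        r = paired_ttest(a, b)
        assert r.t == pytest.approx(t_expect, rel=1e-12)
        assert r.p == pytest.approx(p_expect, rel=1e-12)

    def test_paired_symmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert paired_ttest(a, b).p == pytest.approx(paired_ttest(b, a).p)

    def test_unpaired_identical(self):
        r = unpaired_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p == 1.0

    def test_unpaired_detects_two_sigma_shift(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        assert unpaired_ttest(a, b).significant

    def test_unpaired_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        r1, r2 = unpaired_ttest(a, b), unpaired_ttest(5 * a, 5 * b)
        assert r1.t == pytest.approx(r2.t, rel=1e-12)


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([(5.0, 5.0), (7.0, 7.0), (9.0, 9.0)])
        assert ba.mean_diff == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_percent_mode_oracle(self):
        ba = bland_altman([(100.0, 90.0), (110.0, 100.0)], percent=True)
        assert ba.mean_diff == pytest.approx(10.025062656641605, rel=1e-12)
        assert ba.loa_low == pytest.approx(8.635659858520668, rel=1e-9)
        assert ba.loa_high == pytest.approx(11.414465454762542, rel=1e-9)

    def test_antisymmetry(self, rng):
        pairs = rng.random((10, 2)) * 100
        fwd = bland_altman(pairs)
        rev = bland_altman(pairs[:, ::-1])
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff, rel=1e-12)

    def test_limits_cover_95_percent_gaussian(self, rng):
        a = rng.normal(100, 10, 20_000)
        b = a + rng.normal(0, 5, 20_000)
        ba = bland_altman(np.column_stack([a, b]))
        d = a - b
        frac = ((d >= ba.loa_low) & (d <= ba.loa_high)).mean()
        assert frac == pytest.approx(0.95, abs=0.01)


class TestDeltaT2:
    def _stats(self, means, sid_prefix="s"):
        from retro_t2.metrics import RegionStat, ROIStats
        return [ROIStats(f"{sid_prefix}{i}", {"tumor": RegionStat(m, 1.0, 10)})
                for i, m in enumerate(means)]

    def test_equal_timepoints_zero(self):
        s = self._stats([80.0, 90.0])
        assert all(v == 0.0 for v in delta_t2(s, self._stats([80.0, 90.0])).values())

    def test_reported_arm_means(self):
        # progressor arm: 82.1 ms at timepoint 1, 71.4 ms at timepoint 2
        d = delta_t2(self._stats([82.1]), self._stats([71.4]))
        assert d["s0"] == pytest.approx(-10.7, abs=1e-12)

    def test_linearity(self):
        s1, s2 = self._stats([80.0, 90.0]), self._stats([85.0, 95.0])
        shifted = self._stats([95.0, 105.0])
        d1 = delta_t2(s1, s2)
        d2 = delta_t2(s1, shifted)
        assert all(d2[k] - d1[k] == pytest.approx(10.0) for k in d1)

    def test_subject_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_t2(self._stats([80.0]), self._stats([80.0], sid_prefix="x"))


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_null_near_half(self, rng):
        n = 10_000
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        se = np.sqrt(1 / 12) / np.sqrt(n / 4)  # rough null SE
        assert abs(roc_auc(scores, labels) - 0.5) < 3 * se

    def test_matches_pairwise_count(self, rng):
        scores = rng.integers(0, 20, 200).astype(float)  # many ties
        labels = rng.integers(0, 2, 200)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        brute = (wins + 0.5 * ties) / (pos.size * neg.size)
        assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestEvaluateSlices:
    def test_rows_complete_and_masked(self, rng):
        est = ImageVolume(rng.random((32, 32, 3)) * 200, units="ms")
        ref = ImageVolume(rng.random((32, 32, 3)) * 200, units="ms")
        excluded = rng.random((32, 32, 3)) < 0.2
        rows = evaluate_slices(est, ref, excluded)
        assert len(rows) == 3
        for r in rows:
            assert np.isfinite([r.psnr_db, r.ssim, r.mpe_percent]).all()
            assert r.n_voxels == int((~excluded[:, :, r.slice_index]).sum())
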