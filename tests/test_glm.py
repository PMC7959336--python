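"""First-level design construction, OLS fitting and contrasts."""
import numpy as np
import pytest
from scipy import stats
from scipy.stats import gamma as gamma_dist

from affectphysio import (
    BoldDataset,
    build_first_level_design,
    build_trial_schedule,
    canonical_hrf,
    contrast_weights,
    f_contrast,
    fit_first_level,
    t_contrast,
)
from affectphysio.glm import (
    build_group_design,
    condition_effect_map,
    covariate_slope_map,
    group_effect_map,
)


class TestHrf:
    def test_zero_at_origin(self):
        assert canonical_hrf(0.1)[0] == 0.0

    def test_peak_near_five_seconds(self):
        dt = 0.01
        h = canonical_hrf(dt)
        t_peak = np.argmax(h) * dt
        # mode of the closed-form double gamma
        tt = np.arange(0, 32, 1e-4)
        ref = gamma_dist.pdf(tt, 6) - gamma_dist.pdf(tt, 16) / 6
        assert abs(t_peak - tt[np.argmax(ref)]) <= dt
        assert t_peak == pytest.approx(5.0, abs=2 * dt)

    def test_tail_below_one_percent_of_peak(self):
        h = canonical_hrf(0.05)
        assert abs(h[-1]) < 0.01  # kernel is unit peak


class TestDesign:
    def test_study_schedule_has_14_columns_with_motion(self, study_schedule):
        motion = np.zeros((340, 6))
        X = build_first_level_design(study_schedule, 340, motion)
        assert len(X.names) == 14
        assert X.names[-1] == "intercept"
        assert len(X.condition_names) == 7  # 5 emotions + mosaic + fixation

    def test_empty_schedule_gives_nuisance_only(self):
        from affectphysio import TrialSchedule
        X = build_first_level_design(TrialSchedule([]), 40, np.zeros((40, 6)))
        assert X.names == [f"motion_{i}" for i in range(1, 7)] + ["intercept"]

    def test_motion_columns_mean_centred(self, study_schedule, rng):
        motion = rng.normal(size=(340, 6)) + 3.0
        X = build_first_level_design(study_schedule, 340, motion)
        for j in range(1, 7):
            assert X.column(f"motion_{j}").mean() == pytest.approx(0.0, abs=1e-12)

    def test_regressor_equals_fine_grid_convolution_oracle(self):
        # independent oracle: explicit discrete convolution sum on the fine grid
        sch = build_trial_schedule(5, 0, 0, seed=0)
        tr_s, n_vols, ov = sch.tr_s, 20, 16
        X = build_first_level_design(sch, n_vols)
        col = X.column("facial_" + sch.trials[0].emotion)

        dt = tr_s / ov
        n_fine = n_vols * ov
        box = np.zeros(n_fine)
        for t in sch.trials:
            if t.emotion != sch.trials[0].emotion:
                continue
            for i in range(n_fine):
                ti = i * dt
                if t.onset_s <= ti < t.onset_s + t.duration_s:
                    box[i] = 1.0
        h = canonical_hrf(dt)
        oracle = np.zeros(n_fine)
        for i in range(n_fine):
            for j in range(max(0, i - h.size + 1), i + 1):
                oracle[i] += box[j] * h[i - j] * dt
        assert np.max(np.abs(col - oracle[::ov])) < 1e-9

    def test_trial_past_scan_end_rejected(self):
        sch = build_trial_schedule(5, 0, 0, seed=0)
        with pytest.raises(ValueError, match="past scan end"):
            build_first_level_design(sch, 4)


def _noiseless_dataset(rng, shape=(6, 6, 4), n_vols=60):
    sch = build_trial_schedule(5, 5, 5, seed=2)
    X = build_first_level_design(sch, n_vols)
    p = X.matrix.shape[1]
    b = rng.normal(size=(p,) + shape)
    b[-1] += 100.0  # intercept column carries the baseline
    vols = np.einsum("tp,pxyz->xyzt", X.matrix, b)
    return BoldDataset(vols, tr_s=sch.tr_s), X, b


class TestFit:
    def test_noiseless_recovery_exact(self, rng):
        bold, X, b = _noiseless_dataset(rng)
        fit = fit_first_level(bold, X)
        assert fit.mask.all()
        recovered = np.stack([fit.unmask(fit.betas[j])
                              for j in range(b.shape[0])])
        assert np.max(np.abs(recovered - b)) < 1e-8

    def test_zero_voxel_outside_mask(self, rng):
        bold, X, _ = _noiseless_dataset(rng)
        vols = bold.volumes.copy()
        vols[0, 0, 0, :] = 0.0
        fit = fit_first_level(BoldDataset(vols, bold.tr_s), X)
        assert not fit.mask[0, 0, 0]

    def test_residuals_orthogonal_to_design(self, rng):
        bold, X, _ = _noiseless_dataset(rng)
        noisy = BoldDataset(bold.volumes + rng.normal(size=bold.volumes.shape),
                            bold.tr_s)
        fit = fit_first_level(noisy, X)
        Y = noisy.volumes[fit.mask].T
        resid = Y - X.matrix @ fit.betas
        assert np.max(np.abs(X.matrix.T @ resid)) < 1e-6 * np.abs(Y).max()

    def test_t_statistic_null_distribution(self, rng):
        # white-noise data: intercept-removed contrast t follows Student-t(df)
        n_vox, n_vols = 4000, 60
        sch = build_trial_schedule(5, 5, 5, seed=2)
        X = build_first_level_design(sch, n_vols)
        vols = 100.0 + rng.normal(size=(n_vox, 1, 1, n_vols))
        fit = fit_first_level(BoldDataset(vols, sch.tr_s), X)
        w = contrast_weights(X, "facial_gt_mosaic")
        tm = t_contrast(fit, w).values
        t = tm[np.isfinite(tm)]
        ks = stats.kstest(t, "t", args=(fit.df_resid,))
        assert ks.pvalue > 0.01
        assert abs(t.mean()) < 0.05


class TestContrasts:
    @pytest.fixture()
    def fit(self, rng):
        bold, X, _ = _noiseless_dataset(rng)
        noisy = BoldDataset(bold.volumes + rng.normal(size=bold.volumes.shape),
                            bold.tr_s)
        return fit_first_level(noisy, X)

    def test_facial_gt_mosaic_weights(self, fit):
        w = contrast_weights(fit.design, "facial_gt_mosaic")
        names = fit.design.names
        for n, wi in zip(names, w):
            if n.startswith("facial_"):
                assert wi == pytest.approx(0.2)
            elif n == "mosaic":
                assert wi == -1.0
            else:
                assert wi == 0.0
        assert w.sum() == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_weights_rejected(self, fit):
        with pytest.raises(ValueError, match="zero"):
            t_contrast(fit, np.zeros(len(fit.design.names)))

    def test_f_of_single_row_equals_t_squared(self, fit):
        w = contrast_weights(fit.design, "facial_gt_fixation")
        t = t_contrast(fit, w).values
        F = f_contrast(fit, w[None, :]).values
        ok = np.isfinite(t)
        assert np.max(np.abs(F[ok] - t[ok] ** 2)
                      / np.maximum(np.abs(F[ok]), 1e-12)) < 1e-10

    def test_valence_maps_antisymmetric(self, fit):
        a = t_contrast(fit, contrast_weights(fit.design, "positive_gt_negative"))
        b = t_contrast(fit, contrast_weights(fit.design, "negative_gt_positive"))
        ok = np.isfinite(a.values)
        assert np.allclose(a.values[ok], -b.values[ok], atol=1e-10)

    def test_estimable_contrast_stable_under_pseudoinverse(self, rng):
        # duplicate a column: weights in the row space give identical effects
        bold, X, _ = _noiseless_dataset(rng)
        from affectphysio.glm import DesignMatrix
        M = np.column_stack([X.matrix, X.matrix[:, 0]])
        X2 = DesignMatrix(M, X.names + ["dup"], X.condition_names)
        fit2 = fit_first_level(bold, X2)
        fit1 = fit_first_level(bold, X)
        w1 = contrast_weights(X, "facial_gt_mosaic")
        # only beta_0 + beta_dup is estimable: give both columns w1[0]
        w2 = np.concatenate([w1, [w1[0]]])
        e1 = w1 @ fit1.betas
        e2 = w2 @ fit2.betas
        assert np.allclose(e1, e2, atol=1e-7)


class TestGroupLevel:
    def _maps(self, rng, n=12, shape=(8, 8, 4), offset=0.0):
        return [rng.normal(size=shape) + offset for _ in range(n)]

    def test_identical_masks_reproduced(self, rng):
        maps = self._maps(rng, n=6)
        gd = build_group_design(maps, ["control"] * 3 + ["bvFTD"] * 3)
        assert gd.mask.all()

    def test_majority_rule_boundary(self, rng):
        maps = self._maps(rng, n=22)
        for m in maps[:10]:
            m[0, 0, 0] = np.nan  # defined in 12/22 -> retained
        for m in maps[:11]:
            m[1, 0, 0] = np.nan  # defined in 11/22 -> dropped
        gd = build_group_design(maps, ["control"] * 11 + ["bvFTD"] * 11)
        assert gd.mask[0, 0, 0]
        assert not gd.mask[1, 0, 0]

    def test_grid_mismatch_names_subjects(self, rng):
        maps = self._maps(rng, n=3) + [rng.normal(size=(4, 4, 2))]
        with pytest.raises(ValueError, match="sub-03"):
            build_group_design(maps, ["control"] * 2 + ["bvFTD"] * 2)

    def test_identical_subject_maps_masked_out(self, rng):
        m = rng.normal(size=(6, 6, 3))
        gd = build_group_design([m.copy() for _ in range(8)],
                                ["control"] * 4 + ["bvFTD"] * 4)
        F = group_effect_map(gd)
        assert np.all(np.isnan(F.values))

    def test_group_with_one_subject_rejected(self, rng):
        maps = self._maps(rng, n=3)
        gd = build_group_design(maps, ["control", "control", "bvFTD"])
        with pytest.raises(ValueError, match="bvFTD"):
            group_effect_map(gd)

    def test_permuted_labels_give_unit_mean_f(self, rng):
        # under exchangeability E[F] = df2/(df2-2) ~ 1
        maps = self._maps(rng, n=24)
        gd = build_group_design(maps, ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        F = group_effect_map(gd)
        vals = F.values[np.isfinite(F.values)]
        expect = 21.0 / 19.0
        assert abs(vals.mean() - expect) < 0.1

    def test_planted_offset_detected_with_analytic_power(self, rng):
        # two groups, mean offset d at unit SD: voxel rejection rate at
        # p<0.005 should match non-central F power
        n, d = 15, 1.0
        n_vox = 3000
        a = rng.normal(size=(n, n_vox))
        b = rng.normal(size=(n, n_vox)) + d
        maps = [row.reshape(n_vox, 1, 1) for row in np.concatenate([a, b])]
        gd = build_group_design(maps, ["a"] * n + ["b"] * n)
        F = group_effect_map(gd)
        df1, df2 = F.df
        crit = stats.f.ppf(1 - 0.005, df1, df2)
        rate = np.mean(F.values[np.isfinite(F.values)] > crit)
        lam = n * d ** 2 / 2  # noncentrality for balanced two-group design
        power = 1 - stats.ncf.cdf(crit, df1, df2, lam)
        assert abs(rate - power) < 0.05


class TestCovariateSlopes:
    def _design_with_cov(self, rng, n=12, amp=None):
        import pandas as pd
        cov = rng.normal(size=n)
        shape = (8, 8, 4)
        region = np.zeros(shape, dtype=bool)
        region[2:5, 2:5, 1:3] = True
        maps = []
        for i in range(n):
            m = rng.normal(size=shape)
            if amp is not None:
                m[region] += amp * cov[i]
            maps.append(m)
        subjects = [f"sub-{i:02d}" for i in range(n)]
        table = pd.DataFrame({"score": cov, "nuis": rng.normal(size=n),
                              "const": 1.0, "same": cov},
                             index=subjects)
        gd = build_group_design(maps, ["control"] * n, covariates=table,
                                subjects=subjects)
        return gd, region

    def test_uncorrelated_covariate_slope_near_zero(self, rng):
        gd, _ = self._design_with_cov(rng)
        t = covariate_slope_map(gd, "score")
        vals = t.values[np.isfinite(t.values)]
        assert abs(vals.mean()) < 0.1

    def test_planted_slope_recovered_and_sign_flips(self, rng):
        gd, region = self._design_with_cov(rng, amp=3.0)
        t = covariate_slope_map(gd, "score", nuisance="nuis")
        assert np.nanmean(t.values[region]) > 3.0
        gd.covariates["score"] *= -1
        t2 = covariate_slope_map(gd, "score", nuisance="nuis")
        assert np.allclose(t2.values[region], -t.values[region], atol=1e-9)

    def test_constant_covariate_rejected(self, rng):
        gd, _ = self._design_with_cov(rng)
        with pytest.raises(ValueError, match="constant"):
            covariate_slope_map(gd, "const")

    def test_collinear_nuisance_rejected(self, rng):
        gd, _ = self._design_with_cov(rng)
        with pytest.raises(ValueError, match="collinear"):
            covariate_slope_map(gd, "score", nuisance="same")


def test_condition_effect_one_sample_t(rng):
    maps = [rng.normal(size=(6, 6, 3)) + 0.5 for _ in range(10)]
    gd = build_group_design(maps, ["control"] * 10)
    t = condition_effect_map(gd)
    data = np.stack(maps)
    expect = data.mean(0) / (data.std(0, ddof=1) / np.sqrt(10))
    assert np.allclose(t.values, expect, atol=1e-10)
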