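"""Regression layer: MLR, LMM, LRT, ICC, VIF, diagnostics, effect curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mhrv.models import (HRVLinearModel, HRVMixedModel, ModelFrame,
                         build_frame, chd_screen, diagnostics, effect_curve,
                         fit_lmm, fit_mlr, frame_from_simulation,
                         icc_from_variances, lrt, remove_influential, vif)
from mhrv.simulate import (DEFAULT_EFFECTS, CohortConfig, sample_cohort,
                           simulate_features)


def _repeated_cohort(seed=0, n_subjects=29, n_visits=8):
    schedule = (14, 18, 22, 26, 30, 34, 38, 40)[:n_visits]
    cfg = CohortConfig.dataset2_like(seed=seed, dropout_prob=0.0,
                                     ga_schedule=schedule)
    cfg = CohortConfig(**{**cfg.__dict__, "n_subjects": n_subjects})
    return sample_cohort(cfg)


def _sim_frame(dv="rmssd", seed=0, cohort=None, effects=None):
    cohort = _repeated_cohort() if cohort is None else cohort
    effects = DEFAULT_EFFECTS[dv] if effects is None else effects
    sim, truth = simulate_features(cohort, effects, seed=seed)
    return frame_from_simulation(sim, dv), truth


class TestBuildFrame:
    def _tables(self):
        features = pd.DataFrame({
            "subject_id": ["A", "A", "B"],
            "measurement_id": ["A_1", "A_2", "B_1"],
            "sdnn": [50.0, 55.0, 40.0],
            "rmssd": [25.0, 30.0, 20.0],
            "sampen": [1.2, 1.3, 1.1],
            "median_hr": [78.0, 80.0, 75.0],
            "median_br": [14.0, 15.0, 13.0],
            "usable": [True, False, True],
        })
        cohort = pd.DataFrame({
            "subject_id": ["A", "A", "B"],
            "measurement_id": ["A_1", "A_2", "B_1"],
            "age": [30.0, 30.0, 33.0],
            "bmi": [22.0, 22.0, 25.0],
            "ga": [20.0, 24.0, 21.0],
            "parity": [0, 0, 2],
            "chd": [0, 0, 1],
        })
        return features, cohort

    def test_unusable_dropped(self):
        features, cohort = self._tables()
        frame = build_frame(features, cohort, "sdnn")
        assert frame.n == 2
        assert frame.n_dropped_unusable == 1

    def test_parity_binary_coding(self):
        features, cohort = self._tables()
        frame = build_frame(features, cohort, "sdnn")
        assert set(frame.X["parity"]) == {0.0, 1.0}

    def test_parity_numeric_mode(self):
        features, cohort = self._tables()
        frame = build_frame(features, cohort, "sdnn", parity_numeric=True)
        assert 2.0 in set(frame.X["parity"])

    def test_dv_transformed(self):
        features, cohort = self._tables()
        frame = build_frame(features, cohort, "rmssd")
        assert frame.y.iloc[0] == pytest.approx(np.log(25.0))
        frame_sq = build_frame(features, cohort, "sampen")
        assert frame_sq.y.iloc[0] == pytest.approx(1.2**2)

    def test_join_mismatch_error(self):
        features, cohort = self._tables()
        with pytest.raises(KeyError):
            build_frame(features, cohort.assign(measurement_id="zzz"), "sdnn")


class TestVIF:
    def test_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        out = vif(X)
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_duplicated_column_infinite(self):
        x = np.arange(10.0)
        out = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_near_collinear_closed_form(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        x2 = x1 + rng.normal(scale=0.05, size=200)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        out = vif(X)
        # closed form from the pairwise correlation
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert out["x2"] == pytest.approx(1 / (1 - r2), rel=1e-6)
        assert out["x2"] > 5


class TestMLR:
    def test_exact_linear_recovery(self):
        x = np.linspace(0, 10, 30)
        frame = ModelFrame(
            dv_name="sdnn",
            y=pd.Series(2 + 3 * x),
            X=pd.DataFrame({"x": x, "z": np.sin(x)}),
            subject_ids=pd.Series([str(i) for i in range(30)]),
        )
        fit = fit_mlr(frame)
        assert fit.beta["const"] == pytest.approx(2.0, abs=1e-8)
        assert fit.beta["x"] == pytest.approx(3.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_adjusted_r2_closed_form(self):
        frame, _ = _sim_frame(seed=1)
        fit = fit_mlr(frame)
        n, p = fit.n, frame.X.shape[1]
        expected = 1 - (1 - fit.r2) * (n - 1) / (n - p - 1)
        assert fit.r2_adjusted == pytest.approx(expected, rel=1e-12)

    def test_f_statistic_formula_oracle(self):
        frame, _ = _sim_frame(seed=2)
        fit = fit_mlr(frame)
        y = frame.y.to_numpy()
        n, p = fit.n, frame.X.shape[1]
        rss = float(np.sum(fit.residuals**2))
        ess = float(np.sum((fit.fitted - y.mean()) ** 2))
        f_ref = (ess / p) / (rss / (n - p - 1))
        assert fit.f_statistic == pytest.approx(f_ref, rel=1e-9)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(20.0)
        frame = ModelFrame(
            dv_name="sdnn",
            y=pd.Series(x + 1),
            X=pd.DataFrame({"a": x, "b": 2 * x}),
            subject_ids=pd.Series([str(i) for i in range(20)]),
        )
        with pytest.raises(ValueError, match="rank"):
            fit_mlr(frame)

    def test_leverage_trace_identity(self):
        frame, _ = _sim_frame(seed=3)
        fit = fit_mlr(frame)
        assert np.sum(fit.leverage) == pytest.approx(frame.X.shape[1] + 1)


class TestLMM:
    def test_icc_ratio_definition(self):
        assert icc_from_variances(1.0, 3.0) == 0.25
        assert icc_from_variances(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            icc_from_variances(-1.0, 1.0)

    def test_zero_between_subject_variance(self):
        effects = DEFAULT_EFFECTS["rmssd"].with_icc(0.0)
        cohort = _repeated_cohort(seed=4)
        iccs = []
        for seed in range(10):
            frame, _ = _sim_frame(cohort=cohort, effects=effects, seed=seed)
            iccs.append(fit_lmm(frame).icc)
        assert np.mean(iccs) < 0.05

    def test_icc_against_anova_oracle(self):
        # balanced one-way design with no fixed effects: compare against the
        # classical one-way random-effects ANOVA estimator
        rng = np.random.default_rng(5)
        n_sub, n_rep = 40, 8
        s2b, s2e = 1.0, 2.0
        b = rng.normal(0, np.sqrt(s2b), n_sub)
        y = (b[:, None] + rng.normal(0, np.sqrt(s2e), (n_sub, n_rep))).ravel()
        subj = np.repeat([f"S{i}" for i in range(n_sub)], n_rep)
        frame = ModelFrame(
            dv_name="rmssd",
            y=pd.Series(y),
            X=pd.DataFrame({"x": rng.normal(size=n_sub * n_rep)}),
            subject_ids=pd.Series(subj),
        )
        fit = fit_lmm(frame)
        ym = y.reshape(n_sub, n_rep).mean(axis=1)
        msb = n_rep * np.var(ym, ddof=1)
        msw = np.mean(np.var(y.reshape(n_sub, n_rep), axis=1, ddof=1))
        icc_anova = (msb - msw) / (msb + (n_rep - 1) * msw)
        assert fit.icc == pytest.approx(icc_anova, abs=0.03)

    def test_blups_one_per_subject(self):
        frame, truth = _sim_frame(seed=6)
        fit = fit_lmm(frame)
        assert len(fit.blups) == frame.subject_ids.nunique()
        # BLUPs track the generating random intercepts
        b_true = pd.Series(truth["b_by_subject"])
        r = np.corrcoef(fit.blups[b_true.index], b_true)[0, 1]
        assert r > 0.9

    def test_conditional_r2_is_one_when_residuals_vanish(self):
        # zero residual variance: conditional fits reproduce y exactly
        effects = DEFAULT_EFFECTS["rmssd"]
        effects = type(effects)(**{**effects.__dict__, "sigma2_e": 1e-12})
        frame, _ = _sim_frame(effects=effects, seed=7)
        fit = fit_lmm(frame)
        assert fit.r2_adjusted == pytest.approx(1.0, abs=1e-6)


class TestLRT:
    def test_identical_loglik(self):
        frame, _ = _sim_frame(seed=8)
        mlr = fit_mlr(frame)
        lmm = fit_lmm(frame)
        fake = type(lmm)(**{**lmm.__dict__, "loglik": mlr.loglik})
        out = lrt(fake, mlr)
        assert out.stat == 0.0 and out.p_mixture == 1.0

    def test_mixture_closed_form(self):
        frame, _ = _sim_frame(seed=9)
        mlr = fit_mlr(frame)
        lmm = fit_lmm(frame)
        fake = type(lmm)(**{**lmm.__dict__,
                            "loglik": mlr.loglik + 3.841 / 2})
        out = lrt(fake, mlr)
        assert out.stat == pytest.approx(3.841)
        assert out.p_mixture == pytest.approx(
            0.5 * stats.chi2.sf(3.841, 1), rel=1e-9)
        assert out.p_mixture == pytest.approx(0.025, abs=0.001)

    def test_nesting_stat_nonnegative(self):
        for seed in range(5):
            frame, _ = _sim_frame(seed=seed)
            out = lrt(fit_lmm(frame), fit_mlr(frame))
            assert out.stat >= 0.0


class TestEffectCurve:
    def test_grid_endpoints_and_medians(self):
        frame, _ = _sim_frame(seed=10)
        fit = fit_mlr(frame)
        c = effect_curve(fit, frame, "median_hr")
        lo, hi = np.percentile(frame.X["median_hr"], [5, 95])
        assert c.grid[0] == pytest.approx(lo)
        assert c.grid[-1] == pytest.approx(hi)

    def test_slope_equals_coefficient(self):
        frame, _ = _sim_frame(seed=11)
        fit = fit_mlr(frame)
        c = effect_curve(fit, frame, "age")
        slope = (c.yhat[-1] - c.yhat[0]) / (c.grid[-1] - c.grid[0])
        assert slope == pytest.approx(fit.beta["age"], rel=1e-9)

    def test_median_point_consistency(self):
        frame, _ = _sim_frame(seed=12)
        fit = fit_mlr(frame)
        med = frame.X.median()
        for iv in frame.X.columns:
            c = effect_curve(fit, frame, iv)
            # prediction with the swept IV at its own median = all-median fit
            x_all_med = np.concatenate([[1.0], med[frame.X.columns].to_numpy()])
            y_all_med = float(x_all_med @ fit.beta.to_numpy())
            if set(np.unique(frame.X[iv])).issubset({0.0, 1.0}):
                continue
            k = np.argmin(np.abs(c.grid - med[iv]))
            yhat_interp = np.interp(med[iv], c.grid, c.yhat)
            assert yhat_interp == pytest.approx(y_all_med, rel=1e-6)

    def test_binary_grid(self):
        frame, _ = _sim_frame(seed=13)
        fit = fit_mlr(frame)
        c = effect_curve(fit, frame, "parity")
        assert list(c.grid) == [0.0, 1.0]

    def test_zero_coefficient_flat_with_cover(self):
        rng = np.random.default_rng(14)
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        y = pd.Series(1.0 + 2.0 * X["x"] + rng.normal(0, 0.5, n))
        frame = ModelFrame("sdnn", y, X,
                           pd.Series([str(i) for i in range(n)]))
        fit = fit_mlr(frame)
        c = effect_curve(fit, frame, "z")
        assert np.ptp(c.yhat) < 0.2
        flat = np.full_like(c.yhat, c.yhat.mean())
        assert np.all(c.ci_low <= flat) and np.all(flat <= c.ci_high)
        assert not c.annotate

    def test_unknown_iv(self):
        frame, _ = _sim_frame(seed=15)
        with pytest.raises(ValueError):
            effect_curve(fit_mlr(frame), frame, "shoe_size")


class TestDiagnosticsAndRemoval:
    def test_centroid_duplicate_near_zero_cooks(self):
        rng = np.random.default_rng(16)
        n = 50
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = pd.Series(2 + X["x"] + rng.normal(0, 0.3, n))
        # append a point exactly at the centroid with the mean response
        X2 = pd.concat([X, pd.DataFrame({"x": [X["x"].mean()]})],
                       ignore_index=True)
        y2 = pd.concat([y, pd.Series([y.mean()])], ignore_index=True)
        frame = ModelFrame("sdnn", y2, X2,
                           pd.Series([str(i) for i in range(n + 1)]))
        fit = fit_mlr(frame)
        assert fit.cooks_d[-1] < np.median(fit.cooks_d) + 1e-3

    def test_planted_outlier_has_max_cooks(self):
        rng = np.random.default_rng(17)
        n = 60
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + rng.normal(0, 0.2, n)
        x[-1], y[-1] = 8.0, -20.0  # extreme leverage + extreme residual
        frame = ModelFrame("sdnn", pd.Series(y), pd.DataFrame({"x": x}),
                           pd.Series([str(i) for i in range(n)]))
        fit = fit_mlr(frame)
        assert np.argmax(fit.cooks_d) == n - 1

    def test_bundle_contents(self):
        frame, _ = _sim_frame(seed=18)
        mlr = fit_mlr(frame)
        bundle = diagnostics(mlr, frame)
        assert len(bundle.qq_theoretical) == frame.n
        assert bundle.cooks_d is not None
        lmm = fit_lmm(frame)
        bundle2 = diagnostics(lmm, frame)
        assert bundle2.blups is not None and len(bundle2.blups) == 29

    def test_clean_data_zero_removals(self):
        frame, _ = _sim_frame(seed=19)
        fit = fit_mlr(frame)
        new_frame, new_fit, report = remove_influential(frame, fit)
        assert report.removed_ids == []
        assert new_frame is frame and new_fit is fit

    def test_planted_outliers_removed_and_reported(self):
        rng = np.random.default_rng(20)
        n = 80
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + rng.normal(0, 0.2, n)
        x[0], y[0] = 9.0, -30.0
        x[1], y[1] = -9.0, 30.0
        frame = ModelFrame("sdnn", pd.Series(y), pd.DataFrame({"x": x}),
                           pd.Series([str(i) for i in range(n)]))
        fit = fit_mlr(frame)
        new_frame, new_fit, report = remove_influential(frame, fit)
        assert sorted(report.removed_ids) == [0, 1]
        assert len(report.removed_cooks_d) == 2
        assert all(d > report.threshold for d in report.removed_cooks_d)
        assert new_frame.n == n - 2


class TestCHDScreen:
    def _features_cohort(self, chd_effect=0.0, seed=0):
        from mhrv.features import inverse_transform_dv

        cfg = CohortConfig(n_subjects=200, design="single", seed=seed)
        cohort = sample_cohort(cfg)
        rng = np.random.default_rng(seed + 1)
        # one HR/BR draw shared by all three DVs
        cohort = cohort.assign(
            median_hr=rng.normal(78, 9, len(cohort)),
            median_br=rng.normal(14, 1.5, len(cohort)),
        )
        feats = cohort[["subject_id", "measurement_id",
                        "median_hr", "median_br"]].copy()
        for i, dv in enumerate(("sdnn", "rmssd", "sampen")):
            sim, _ = simulate_features(cohort, DEFAULT_EFFECTS[dv],
                                       seed=seed + 31 * i)
            y = sim["y"] + chd_effect * cohort["chd"].to_numpy()
            y = np.maximum(y, 0.01)  # keep raw values invertible
            feats[dv] = [inverse_transform_dv(v, dv) for v in y]
        cohort = cohort.drop(columns=["median_hr", "median_br"])
        return feats, cohort

    def test_null_effect_dropped(self):
        feats, cohort = self._features_cohort(chd_effect=0.0, seed=21)
        out = chd_screen(feats, cohort)
        assert not out["skipped"]
        assert out["rmssd"]["decision"] == "drop"

    def test_planted_effect_kept(self):
        feats, cohort = self._features_cohort(chd_effect=1.0, seed=22)
        out = chd_screen(feats, cohort)
        assert out["rmssd"]["decision"] == "keep"

    def test_constant_chd_skipped(self):
        feats, cohort = self._features_cohort(seed=23)
        out = chd_screen(feats, cohort.assign(chd=0))
        assert out["skipped"]

    def test_missing_chd_skipped(self):
        feats, cohort = self._features_cohort(seed=24)
        out = chd_screen(feats, cohort.drop(columns="chd"))
        assert out["skipped"]


class TestSklearnAPI:
    def test_linear_model_fit_predict(self):
        frame, _ = _sim_frame(seed=25)
        est = HRVLinearModel(dv_name="rmssd").fit(frame.X, frame.y)
        pred = est.predict(frame.X)
        np.testing.assert_allclose(pred, est.result_.fitted, rtol=1e-9)
        assert est.get_params() == {"dv_name": "rmssd"}

    def test_mixed_model_attributes(self):
        frame, truth = _sim_frame(seed=26)
        est = HRVMixedModel(dv_name="rmssd").fit(
            frame.X, frame.y, groups=frame.subject_ids)
        assert 0 <= est.icc_ <= 1
        assert est.sigma2_b_ >= 0 and est.sigma2_e_ > 0
        from sklearn.base import clone
        clone(est)  # get_params/set_params contract
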