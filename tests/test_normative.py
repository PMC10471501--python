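"""Normative model: Box–Cox, split rules, partial pooling, deviation scoring,
fit metrics and the site-leakage diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hetmap as h
from hetmap.normative import (boxcox_fit_apply, boxcox_transform, fit_metrics,
                              predict_normative)


class TestBoxCox:
    def test_fixed_lambda_values(self):
        assert boxcox_transform(np.array([3.0]), 1.0)[0] == pytest.approx(2.0)
        assert boxcox_transform(np.array([np.e]), 0.0)[0] == pytest.approx(1.0)

    def test_lognormal_recovers_log_transform(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(1.0, 1.0, size=10_000))
        lam, _ = boxcox_fit_apply(x)
        assert -0.1 < lam < 0.1

    def test_nonpositive_rejected_naming_region(self):
        with pytest.raises(ValueError, match="region 17"):
            boxcox_fit_apply(np.array([1.0, 0.0, 2.0]), name="17")


class TestSplit:
    @staticmethod
    def _cohort(scheme, spec, seed=0):
        return h.make_cohort(scheme, spec, seed=seed)

    def test_small_site_contributes_no_test_controls(self, small_scheme):
        c = self._cohort(small_scheme, [("big", 40, 0), ("small", 29, 0)])
        train, test = h.split_train_test(c, seed=1)
        small_train = (train.subjects["site"] == "small").sum()
        assert small_train == 29
        assert (test.subjects["site"] == "small").sum() == 0

    def test_ten_percent_held_out(self, small_scheme):
        c = self._cohort(small_scheme, [("a", 40, 0), ("b", 40, 0)])
        train, test = h.split_train_test(c, seed=2)
        assert (test.subjects["site"] == "a").sum() == 4
        assert (train.subjects["site"] == "a").sum() == 36

    def test_small_sex_cell_dropped_entirely(self, small_scheme):
        c = self._cohort(small_scheme, [("a", 40, 0), ("b", 40, 0)])
        # shrink one (site, sex) cell below 10 controls
        sub = c.subjects
        males_b = sub[(sub["site"] == "b") & (sub["sex"] == "M")].index[9:]
        keep = ~sub.index.isin(males_b)
        c2 = c.select(keep)
        c2.subjects.loc[(c2.subjects["site"] == "b")
                        & (c2.subjects["sex"] == "M"), "sex"] = "M"
        # now site b has 9 male HCs -> the whole (b, M) cell must vanish
        sub_b_m = c2.subjects[(c2.subjects["site"] == "b") & (c2.subjects["sex"] == "M")]
        assert len(sub_b_m) == 9
        train, test = h.split_train_test(c2, seed=3)
        for part in (train, test):
            cell = part.subjects[(part.subjects["site"] == "b")
                                 & (part.subjects["sex"] == "M")]
            assert cell.empty

    def test_deterministic(self, small_cohort):
        a = h.split_train_test(small_cohort, seed=9)[0]
        b = h.split_train_test(small_cohort, seed=9)[0]
        assert a.subjects.index.equals(b.subjects.index)


class TestFit:
    def test_identical_batches_shrink_to_pooled(self, small_scheme):
        c = h.make_cohort(small_scheme, [("a", 60, 0), ("b", 60, 0)],
                          effects=dict(site_offsets={"a": 0.0, "b": 0.0},
                                       site_noise_scales={"a": 0.1, "b": 0.1},
                                       sex_offset=0.0),
                          seed=5)
        fit = h.fit_normative(c, min_batch=5)
        # oracle: pooled OLS per region on the transformed phenotype
        age_c = c.subjects["age"].to_numpy() - fit.age_center
        X = np.column_stack([np.ones(len(age_c)), age_c])
        for j in range(0, len(fit.region_ids), 7):
            y = boxcox_transform(c.phenotype.to_numpy()[:, j], fit.lambdas[j])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            s2 = res[0] / (len(y) - 2)
            pooled_se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
            assert np.all(np.abs(fit.intercept[j] - beta[0]) < 0.5 * pooled_se)

    def test_noise_free_linear_data_fits_exactly(self, small_scheme):
        c = h.make_cohort(small_scheme, [("a", 30, 0), ("b", 30, 0)],
                          effects=dict(site_noise_scales={"a": 1e-12, "b": 1e-12}),
                          seed=6)
        fit = h.fit_normative(c, min_batch=5)
        assert fit.sigma.max() < 1e-4
        pred = predict_normative(fit, c)
        # exact up to Box–Cox curvature over the age range
        assert np.abs(pred.y.to_numpy() - pred.y_hat.to_numpy()).max() < 1e-4

    def test_degenerate_batch_error_names_batch(self, small_scheme):
        c = h.make_cohort(small_scheme, [("a", 20, 0), ("b", 20, 0)], seed=7)
        rows = (c.subjects["site"] == "b").to_numpy()
        c.phenotype.loc[rows, :] = 1.0
        with pytest.raises(ValueError, match="b"):
            h.fit_normative(c, min_batch=5)

    def test_site_offset_recovery(self, leakage_bundle):
        """Generator site/sex offsets fall inside the fitted 95% intervals in
        >=90% of (region, batch) cells (truth mapped through the fitted
        Box–Cox lambda)."""
        fit, cohort = leakage_bundle["fit"], leakage_bundle["cohort"]
        gp = cohort.gen_params
        baselines = gp["baselines"]
        inside = total = 0
        for j, rid in enumerate(fit.region_ids):
            for b, (site, sex) in enumerate(fit.batches):
                eta = (baselines[rid] + gp["site_offsets"][site]
                       + (gp["sex_offset"] if sex == "M" else 0.0)
                       + gp["age_slope"] * fit.age_center)
                truth = boxcox_transform(np.exp(np.array([eta])), fit.lambdas[j])[0]
                lo = fit.intercept[j, b] - 1.96 * fit.se_intercept[j, b]
                hi = fit.intercept[j, b] + 1.96 * fit.se_intercept[j, b]
                inside += lo <= truth <= hi
                total += 1
        assert inside / total >= 0.90


class TestDeviationZ:
    def test_printed_equation(self):
        assert h.deviation_z(2.0, 0.0, 1.2, 0.9) == pytest.approx(2.0 / np.sqrt(2.25))
        assert h.deviation_z(5.0, 5.0, 1.0, 1.0) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            h.deviation_z(1.0, 0.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(d=st.floats(-10, 10), s1=st.floats(0, 5), s2=st.floats(0.01, 5),
           c=st.floats(0.01, 100))
    def test_scale_equivariance_and_antisymmetry(self, d, s1, s2, c):
        z = h.deviation_z(d, 0.0, s1, s2)
        assert h.deviation_z(c * d, 0.0, c * s1, c * s2) == pytest.approx(z, rel=1e-9)
        assert h.deviation_z(-d, 0.0, s1, s2) == pytest.approx(-z, rel=1e-9)

    def test_heldout_controls_are_calibrated(self, leakage_bundle):
        z = leakage_bundle["dmap"].z.to_numpy()
        assert abs(z.mean()) < 0.1
        assert 0.85 < z.std() < 1.15

    def test_extreme_indicators_roundtrip(self, small_fit):
        dmap = small_fit["dmap"]
        pos, neg = h.threshold_extremes(dmap.z, dmap.z_thr)
        assert pos.equals(dmap.pos_extreme)
        assert neg.equals(dmap.neg_extreme)
        assert not (pos.to_numpy() & neg.to_numpy()).any()


class TestFitMetrics:
    def test_perfect_and_trivial_predictors(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(40, 3))
        mu, var = y.mean(axis=0), y.var(axis=0, ddof=0)
        perfect = fit_metrics(y, y, np.full_like(y, 1e-12), mu, var)
        assert np.allclose(perfect["EV"], 1.0)
        assert np.allclose(perfect["SMSE"], 0.0)
        trivial = fit_metrics(y, np.tile(mu, (40, 1)), np.tile(var, (40, 1)), mu, var)
        assert np.allclose(trivial["SMSE"], 1.0)
        assert np.allclose(trivial["MSLL"], 0.0, atol=1e-12)

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(20, 3))
        yh = y + rng.normal(scale=0.5, size=(20, 3))
        pv = rng.uniform(0.5, 2.0, size=(20, 3))
        mu, var = rng.normal(size=3), rng.uniform(0.5, 2.0, size=3)
        got = fit_metrics(y, yh, pv, mu, var)
        for j in range(3):
            ev = 1 - np.var(y[:, j] - yh[:, j]) / np.var(y[:, j])
            smse = np.mean((y[:, j] - yh[:, j])**2) / np.mean((y[:, j] - mu[j])**2)
            ll = np.mean([0.5 * np.log(2 * np.pi * pv[i, j])
                          + (y[i, j] - yh[i, j])**2 / (2 * pv[i, j]) for i in range(20)])
            ll0 = np.mean([0.5 * np.log(2 * np.pi * var[j])
                           + (y[i, j] - mu[j])**2 / (2 * var[j]) for i in range(20)])
            assert got["EV"][j] == pytest.approx(ev, abs=1e-10)
            assert got["SMSE"][j] == pytest.approx(smse, abs=1e-10)
            assert got["MSLL"][j] == pytest.approx(ll - ll0, abs=1e-10)

    def test_zero_variance_flagged(self):
        y = np.ones((5, 2))
        out = fit_metrics(y, y, np.ones((5, 2)), np.zeros(2), np.ones(2))
        assert out["flagged"].all()
        assert out["EV"].isna().all()


class TestSiteLeakage:
    def test_constant_offset_is_separable(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(120, 20))
        sites = np.repeat(["a", "b", "c"], 40)
        z[sites == "a"] += 3.0
        res = h.site_leakage_score(z, sites, n_repeats=3, seed=0)
        assert res["per_site"]["a"] > 0.9

    def test_shuffled_labels_are_chance_level(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(200, 20))
        sites = rng.permutation(np.repeat(["a", "b", "c", "d"], 50))
        res = h.site_leakage_score(z, sites, n_repeats=5, seed=1)
        assert 0.4 < res["mean"] < 0.6

    def test_tiny_site_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(41, 5))
        sites = np.array(["a"] * 20 + ["b"] * 20 + ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            res = h.site_leakage_score(z, sites, n_repeats=2, seed=2)
        assert "tiny" not in res["per_site"]


class TestCrossval:
    def test_every_subject_predicted_once(self, small_scheme):
        c = h.make_cohort(small_scheme, [("a", 50, 0), ("b", 50, 0)], seed=8)
        res = h.crossval_evaluate(c, k=5, seed=0, min_batch=2)
        assert sorted(res["fold_of"].unique()) == [0, 1, 2, 3, 4]
        assert sum(len(m) for m in res["metrics"]) == 5 * len(c.region_ids)

    def test_small_batches_fall_back_with_warning(self, small_scheme):
        c = h.make_cohort(small_scheme, [("a", 6, 0), ("b", 6, 0)], seed=9)
        with pytest.warns(UserWarning, match="pooled random"):
            h.crossval_evaluate(c, k=4, seed=0, min_batch=1)

    def test_ev_tracks_generator_signal_fraction(self, small_scheme):
        # age explains a known share of log-variance: slope^2 var(age) /
        # (slope^2 var(age) + noise^2)
        slope, noise = -0.01, 0.08
        c = h.make_cohort(
            small_scheme, [("a", 100, 0), ("b", 100, 0)],
            effects=dict(age_slope=slope, sex_offset=0.0,
                         site_offsets={"a": 0.0, "b": 0.0},
                         site_noise_scales={"a": noise, "b": noise}),
            seed=10)
        var_age = np.var(c.subjects["age"])
        r2 = slope**2 * var_age / (slope**2 * var_age + noise**2)
        res = h.crossval_evaluate(c, k=5, seed=0, min_batch=2)
        ev = np.median(np.concatenate([m["EV"].to_numpy() for m in res["metrics"]]))
        assert ev == pytest.approx(r2, abs=0.05)
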