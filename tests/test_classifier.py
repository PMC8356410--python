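"""Weighted logistic machinery: IRLS, model comparison, metrics, draws."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from demprev import synthetic_data as sd
from demprev.classifier import (
    auc,
    classification_metrics,
    compare_models,
    crossval,
    fit_weighted_logistic,
    hosmer_lemeshow,
    lrt,
    metric_uncertainty,
    or_table,
    order_statistic_interval,
    percent_change_from_or,
    stratified_folds,
)
from demprev.config import ScenarioConfig


def _fixture(n=20, seed=3, k=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    eta = 0.3 + X.to_numpy() @ np.linspace(0.8, -0.6, k)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestIRLS:
    def test_matches_statsmodels_oracle_unit_weights(self):
        X, y = _fixture()
        fit = fit_weighted_logistic(X, y, cov_type="model")
        oracle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), oracle.params.to_numpy(), atol=1e-8)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_duplicated_row_equals_weight_two(self):
        X, y = _fixture(n=25)
        X2 = pd.concat([X, X.iloc[[4]]], ignore_index=True)
        y2 = np.append(y, y[4])
        w = np.ones(len(y))
        w[4] = 2.0
        a = fit_weighted_logistic(X2, y2, cov_type="model")
        b = fit_weighted_logistic(X, y, weights=w, cov_type="model")
        np.testing.assert_allclose(a.coef.to_numpy(), b.coef.to_numpy(), atol=1e-8)

    def test_intercept_only_recovers_weighted_mean(self):
        y = np.array([1.0, 0, 0, 1, 0])
        w = np.array([2.0, 1, 1, 3, 1])
        fit = fit_weighted_logistic(
            pd.DataFrame(index=range(5)), y, weights=w, terms=[], cov_type="model"
        )
        p = 1 / (1 + np.exp(-fit.coef["intercept"]))
        assert p == pytest.approx(np.average(y, weights=w), abs=1e-10)

    def test_uniform_weight_rescaling_leaves_coefficients(self):
        X, y = _fixture(n=40)
        a = fit_weighted_logistic(X, y, weights=np.ones(40), cov_type="model")
        b = fit_weighted_logistic(X, y, weights=np.full(40, 17.0), cov_type="model")
        np.testing.assert_allclose(a.coef.to_numpy(), b.coef.to_numpy(), atol=1e-8)

    def test_perfect_separation_names_column(self):
        X = pd.DataFrame({"sep": [-2.0, -1.0, 1.0, 2.0], "z": [0.1, -0.2, 0.15, 0.05]})
        y = np.array([0.0, 0, 1, 1])
        with pytest.raises(ValueError, match="sep"):
            fit_weighted_logistic(X, y)

    def test_cluster_sandwich_positive_semidefinite(self):
        X, y = _fixture(n=60)
        psu = np.arange(60) // 6
        strata = np.arange(60) // 20
        fit = fit_weighted_logistic(X, y, psu=psu, strata=strata)
        eig = np.linalg.eigvalsh(fit.cov.to_numpy())
        assert np.all(eig >= -1e-10)


class TestModelComparison:
    def _fake(self, label, loglik, terms, n=100):
        from demprev.classifier import ClassifierFit

        idx = ["intercept"] + terms
        return ClassifierFit(
            coef=pd.Series(0.0, index=idx),
            cov=pd.DataFrame(np.eye(len(idx)), index=idx, columns=idx),
            loglik=loglik,
            n=n,
            label=label,
        )

    def test_aic_formula(self):
        fit = self._fake("m", -100.0, ["a", "b"])
        assert fit.aic == pytest.approx(206.0)

    def test_identical_nested_fits_give_null_lrt(self):
        small = self._fake("s", -50.0, ["a"])
        big = self._fake("b", -50.0, ["a", "b"])
        out = lrt(big, small)
        assert out["statistic"] == 0.0 and out["p_value"] == pytest.approx(1.0)

    def test_non_nested_pair_rejected(self):
        f1 = self._fake("f1", -10.0, ["a"])
        f2 = self._fake("f2", -10.0, ["b"])
        with pytest.raises(ValueError):
            lrt(f1, f2)

    def test_statistic_equals_deviance_difference(self):
        X, y = _fixture(n=80, k=3)
        small = fit_weighted_logistic(X[["x0"]], y, label="small", cov_type="model")
        big = fit_weighted_logistic(X, y, label="big", cov_type="model")
        out = lrt(big, small)
        d_small = sm.GLM(y, sm.add_constant(X[["x0"]]), family=sm.families.Binomial()).fit().deviance
        d_big = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit().deviance
        assert out["statistic"] == pytest.approx(d_small - d_big, abs=1e-6)
        table = compare_models([small, big])
        assert len(table.attrs["lrt"]) == 1


class TestHosmerLemeshow:
    def _calibrated(self):
        # within each of 10 prediction blocks, observed events equal expected
        rows_p, rows_y = [], []
        for k in range(1, 11):
            p = k / 11
            rows_p += [p] * 11
            rows_y += [1.0] * k + [0.0] * (11 - k)
        return np.array(rows_p), np.array(rows_y)

    def test_zero_statistic_under_exact_calibration(self):
        p, y = self._calibrated()
        out = hosmer_lemeshow(p, y, g=10)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert out["df"] == 8

    def test_matches_hand_computed_formula(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 20)
        y = (rng.random(20) < p).astype(float)
        w = rng.uniform(0.5, 2.0, 20)
        g = 4
        out = hosmer_lemeshow(p, y, w, g=g)
        # independent recomputation from the definition (weights normalized
        # to the sample size so the statistic is scale-free)
        w = w * len(w) / w.sum()
        order = np.argsort(p, kind="stable")
        cw = np.cumsum(w[order])
        grp = np.empty(20, dtype=int)
        grp[order] = np.searchsorted(cw[-1] * np.arange(1, g) / g, cw, side="left")
        expected = 0.0
        for gi in range(g):
            m = grp == gi
            n_g, o_g, e_g = w[m].sum(), (w[m] * y[m]).sum(), (w[m] * p[m]).sum()
            pbar = e_g / n_g
            expected += (o_g - e_g) ** 2 / (n_g * pbar * (1 - pbar))
        assert out["statistic"] == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_uniform_weight_rescaling(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, 50)
        y = (rng.random(50) < p).astype(float)
        w = rng.uniform(1, 3, 50)
        a = hosmer_lemeshow(p, y, w)["statistic"]
        b = hosmer_lemeshow(p, y, 10 * w)["statistic"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.full(30, 0.4), np.zeros(30))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_tied_predictions(self):
        assert auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.8], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        p = rng.random(n).round(2)  # rounding forces ties
        y = rng.integers(0, 2, n).astype(float)
        w = rng.uniform(0.5, 3.0, n)
        # O(n^2) concordance count
        num = den = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                ww = w[i] * w[j]
                num += ww * (1.0 if p[i] > p[j] else 0.5 if p[i] == p[j] else 0.0)
                den += ww
        assert auc(p, y, w) == pytest.approx(num / den, abs=1e-12)


class TestClassificationMetrics:
    def test_all_correct(self):
        out = classification_metrics([0.9, 0.2], [1, 0])
        assert out == {"sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0}

    def test_all_wrong(self):
        out = classification_metrics([0.4, 0.6], [1, 0])
        assert out == {"sensitivity": 0.0, "specificity": 0.0, "accuracy": 0.0}

    def test_weighted_confusion_tally(self):
        p = np.array([0.9, 0.8, 0.3, 0.6, 0.2, 0.1, 0.55, 0.45, 0.7, 0.05])
        y = np.array([1, 1, 1, 0, 0, 0, 1, 1, 0, 0.0])
        w = np.array([1.0, 2, 1, 1, 3, 1, 2, 1, 1, 2])
        out = classification_metrics(p, y, w)
        # hand tally: predicted positive iff p > 0.5
        sens = (1 + 2 + 2) / (1 + 2 + 1 + 2 + 1)
        spec = (3 + 1 + 2) / (1 + 3 + 1 + 1 + 2)
        acc = (1 + 2 + 2 + 3 + 1 + 2) / w.sum()
        assert out["sensitivity"] == pytest.approx(sens)
        assert out["specificity"] == pytest.approx(spec)
        assert out["accuracy"] == pytest.approx(acc)


class TestCrossval:
    def test_leave_one_out_equals_manual_loop(self):
        X, y = _fixture(n=12, seed=5)
        while len(np.unique(y)) < 2:  # pragma: no cover - seed guard
            X, y = _fixture(n=12, seed=6)
        cv = crossval(X, y, k=12, seed=0)
        manual = np.empty(12)
        folds = cv.folds
        for f in range(12):
            fit = fit_weighted_logistic(X.loc[folds != f], y[folds != f], cov_type="model")
            manual[folds == f] = fit.predict_proba(X.loc[folds == f])
        np.testing.assert_allclose(cv.predictions, manual, atol=1e-10)

    def test_folds_partition_sample(self):
        _, y = _fixture(n=50, seed=2)
        folds = stratified_folds(y, 5, seed=1)
        assert set(folds) == set(range(5))
        sizes = np.bincount(folds)
        assert sizes.sum() == 50 and sizes.max() - sizes.min() <= 2

    def test_same_seed_reproduces_folds_and_metrics(self):
        X, y = _fixture(n=60, seed=7)
        a = crossval(X, y, k=5, seed=11)
        b = crossval(X, y, k=5, seed=11)
        np.testing.assert_array_equal(a.folds, b.folds)
        assert a.metrics == b.metrics

    def test_rare_class_rejected_with_hint(self):
        X, y = _fixture(n=30, seed=1)
        y = np.zeros(30)
        y[0] = 1.0
        with pytest.raises(ValueError, match="smaller k"):
            crossval(X, y, k=10, seed=0)


class TestMetricDraws:
    def test_zero_covariance_gives_degenerate_interval(self):
        X, y = _fixture(n=60, seed=4)
        fit = fit_weighted_logistic(X, y, cov_type="model")
        fit.cov.iloc[:, :] = 0.0
        md = metric_uncertainty(fit, X, y, n_draws=50, seed=0)
        for lo, hi in md.interval.values():
            assert lo == hi

    def test_interval_is_25th_and_975th_order_statistic(self):
        values = np.random.default_rng(0).permutation(np.arange(1, 1001))
        lo, hi = order_statistic_interval(values)
        assert (lo, hi) == (25.0, 975.0)

    def test_too_few_draws_rejected(self):
        X, y = _fixture(n=30)
        fit = fit_weighted_logistic(X, y, cov_type="model")
        with pytest.raises(ValueError):
            metric_uncertainty(fit, X, y, n_draws=10)

    def test_interval_covers_point_estimate(self):
        # the draw distribution is centered at the fitted coefficients, so
        # the interval should nearly always cover the point metric
        hits = {"auc": 0, "accuracy": 0}
        reps = 50
        for rep in range(reps):
            X, y = _fixture(n=150, seed=100 + rep, k=2)
            if len(np.unique(y)) < 2:
                continue
            fit = fit_weighted_logistic(X, y, cov_type="model")
            md = metric_uncertainty(fit, X, y, n_draws=100, seed=rep)
            for m in hits:
                lo, hi = md.interval[m]
                if lo <= md.point[m] <= hi:
                    hits[m] += 1
        for m, h in hits.items():
            assert h >= 0.9 * reps


class TestOddsRatios:
    def test_null_coefficient(self):
        from demprev.classifier import ClassifierFit

        idx = ["intercept", "x"]
        fit = ClassifierFit(
            coef=pd.Series([0.0, 0.0], index=idx),
            cov=pd.DataFrame(0.04 * np.eye(2), index=idx, columns=idx),
            loglik=0.0,
            n=10,
        )
        t = or_table(fit).set_index("term")
        assert t.loc["x", "odds_ratio"] == pytest.approx(1.0)
        assert t.loc["x", "percent_change"] == pytest.approx(0.0)

    def test_percent_change_transform(self):
        assert percent_change_from_or(0.03) == pytest.approx(-97.0)
        assert percent_change_from_or(1.17) == pytest.approx(17.0)
        assert percent_change_from_or(0.43) == pytest.approx(-57.0)


class TestDesignProperties:
    def test_age_effect_attenuates_when_mediated_by_latents(self):
        """Diagnosis depends on age only through the latent declines, so the
        age coefficient collapses once the latent traits enter the model."""
        sc = ScenarioConfig(n_population=4000)  # defaults: b_age = 0
        pop = sd.generate_population(sc, 21)
        pop = pop.assign(age_c=pop["age"] - 70)
        base = fit_weighted_logistic(
            pop[["age_c", "sex"]], pop["dementia"], cov_type="model", label="base"
        )
        full = fit_weighted_logistic(
            pop[["age_c", "sex", "theta_cog", "theta_fun"]],
            pop["dementia"],
            cov_type="model",
            label="full",
        )
        assert base.coef["age_c"] > 0.05  # age predicts strongly on its own
        assert abs(full.coef["age_c"]) < 0.5 * base.coef["age_c"]

    def test_design_coverage_of_generating_coefficients(self):
        """Survey-weighted fits on the oversampled validation design cover
        the generating log-odds in ~95% of scaled replicates."""
        sc = ScenarioConfig(
            n_population=4000, n_sample_a=1500, target_n_b=750,
            b_sex=0.0, b0=-5.0,
        )
        truth = np.array([sc.b_cog, sc.b_fun])
        covered = np.zeros(2)
        reps = 50
        for rep in range(reps):
            pop = sd.generate_population(sc, 500 + rep)
            _, b = sd.draw_survey_samples(pop, sc, 900 + rep)
            fit = fit_weighted_logistic(
                b[["theta_cog", "theta_fun"]], b["dementia"], weights=b["weight"],
                psu=b["psu"], strata=b["stratum"], label="factor",
            )
            se = np.sqrt(np.diag(fit.cov.to_numpy()))[1:]
            est = fit.coef.to_numpy()[1:]
            covered += (est - 1.96 * se <= truth) & (truth <= est + 1.96 * se)
        for frac in covered / reps:
            assert 0.88 <= frac <= 1.0
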