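"""Index-development pipeline: screening, VIF, stepwise AIC, CV, utilities."""

import numpy as np
import pandas as pd
import pytest

import uef
from uef.index_dev import stratified_folds


def _cohort_frame(values_by_group, column="speed", n_per_group=(40, 40, 40), seed=0):
    """Build a minimal cohort table with one parameter column per group draw."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, (mu, sd), n in zip(uef.FRIED_CATEGORIES, values_by_group, n_per_group):
        for _ in range(n):
            rows.append({"fried_group": g, column: mu + sd * rng.standard_normal()})
    df = pd.DataFrame(rows)
    df["fried_group"] = pd.Categorical(
        df["fried_group"], categories=list(uef.FRIED_CATEGORIES), ordered=True
    )
    return df


class TestNormalityScreen:
    def test_normal_sample_untransformed(self):
        rng = np.random.default_rng(1)
        df = _cohort_frame([(0, 1)] * 3, n_per_group=(170, 170, 160), seed=1)
        df["speed"] = rng.standard_normal(len(df)) + 10
        rep = uef.normality_screen(df, parameters=("speed",))
        s = rep.screens["speed"]
        assert s.shapiro_p >= 0.05 and s.transform_applied == "none"

    def test_lognormal_sample_log_transformed(self):
        rng = np.random.default_rng(2)
        df = _cohort_frame([(0, 1)] * 3, n_per_group=(170, 170, 160), seed=2)
        df["speed"] = np.exp(rng.standard_normal(len(df)))
        rep = uef.normality_screen(df, parameters=("speed",))
        s = rep.screens["speed"]
        assert s.shapiro_p < 0.05 and s.transform_applied == "log"

    def test_constant_column_degenerate(self):
        df = _cohort_frame([(0, 1)] * 3, seed=3)
        df["speed"] = 5.0
        rep = uef.normality_screen(df, parameters=("speed",))
        assert rep.screens["speed"].degenerate
        assert rep.screens["speed"].transform_applied == "none"

    def test_negative_values_block_log(self):
        rng = np.random.default_rng(4)
        df = _cohort_frame([(0, 1)] * 3, n_per_group=(100, 100, 100), seed=4)
        df["speed"] = -np.exp(rng.standard_normal(len(df)))  # left-skewed, negative
        rep = uef.normality_screen(df, parameters=("speed",))
        s = rep.screens["speed"]
        assert not s.log_feasible and s.transform_applied == "none"

    def test_outliers_reported_not_removed(self):
        df = _cohort_frame([(0, 1)] * 3, seed=5)
        df.loc[0, "speed"] = 50.0  # gross outlier in the non-frail group
        rep = uef.normality_screen(df, parameters=("speed",))
        assert 0 in rep.screens["speed"].outliers["non-frail"]
        assert len(df) == 120  # untouched


class TestUnivariateScreen:
    def test_noise_not_selected(self):
        rng = np.random.default_rng(6)
        df = _cohort_frame([(0, 1)] * 3, n_per_group=(334, 333, 333), seed=6)
        df["speed"] = rng.standard_normal(len(df))
        res = uef.univariate_screen(df, parameters=("speed",))
        assert not res.loc["speed", "selected"]

    def test_monotone_predictor_selected(self):
        df = _cohort_frame(
            [(0, 1), (1, 1), (2, 1)], n_per_group=(334, 333, 333), seed=7
        )
        res = uef.univariate_screen(df, parameters=("speed",))
        assert res.loc["speed", "selected"]
        assert res.loc["speed", "p_value"] < 1e-6

    def test_all_eight_selected_on_default_cohort(self, default_cohort_352):
        """The frailty-graded generator reproduces the qualitative finding that
        every UEF parameter associates with Fried stage."""
        res = uef.univariate_screen(default_cohort_352)
        assert res["selected"].all()
        assert (res["p_value"] < 0.001).all()


class TestVIF:
    def test_orthogonal_columns_unity(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0],
                          "c": [1, -1, -1, 1.0]})
        v = uef.vif(X.iloc[:, :2].pipe(lambda d: pd.concat([d] * 3, ignore_index=True)))
        assert np.allclose(v, 1.0)

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(50)
        v = uef.vif(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_near_linear_combination_flagged(self):
        """x3 = x1 + x2 + small noise inflates VIF(x3) past the cutoff of 10,
        mirroring the speed/power collinearity finding."""
        rng = np.random.default_rng(9)
        x1, x2 = rng.standard_normal((2, 500))
        x3 = x1 + x2 + 0.01 * rng.standard_normal(500)
        v = uef.vif(pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}))
        assert v["x3"] > 10

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 columns"):
            uef.vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="rows"):
            uef.vif(pd.DataFrame(np.eye(3), columns=list("abc")))


class TestStepwise:
    def test_empty_candidates_intercept_only(self):
        y = np.repeat([0, 1, 2], 30)
        res = uef.stepwise_aic(pd.DataFrame(index=range(90)), y, candidates=[])
        assert res.selected == []
        assert len(res.path) == 1

    def test_informative_beats_noise(self):
        """The informative predictor always enters first; a pure-noise
        predictor is excluded in most replicates (AIC admits noise with
        probability ~16 %, so this is checked across seeds)."""
        noise_entries = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1, 2], [267, 267, 266])
            X = pd.DataFrame(
                {
                    "signal": np.repeat([0.0, 1.0, 2.0], [267, 267, 266])
                    + rng.standard_normal(800),
                    "noise": rng.standard_normal(800),
                }
            )
            res = uef.stepwise_aic(X, y)
            assert res.selected[0] == "signal"
            noise_entries += "noise" in res.selected
        assert noise_entries <= 2

    def test_near_duplicate_pair_one_enters(self):
        """Of two near-duplicate predictors (speed vs engineered power) only
        one survives forward selection."""
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1, 2], [300, 300, 300])
        speed = np.repeat([2.0, 1.0, 0.0], 300) + rng.standard_normal(900)
        power = 1000.0 * speed + 5.0 * rng.standard_normal(900)
        X = pd.DataFrame({"speed": speed, "power": power})
        res = uef.stepwise_aic(X, y)
        assert len(set(res.selected) & {"speed", "power"}) == 1

    def test_final_aic_beats_intercept_only(self, small_cohort_80):
        from uef.published import design_from_cohort

        X = design_from_cohort(small_cohort_80, ("speed", "flexibility", "bmi"))
        y = small_cohort_80["fried_group"]
        res = uef.stepwise_aic(X, y)
        base = uef.fit_proportional_odds(None, y)
        assert res.fit.aic <= base.aic


class TestCrossval:
    def test_fold_partition_contract(self):
        codes = np.repeat([0, 1, 2], [132, 175, 45])
        folds = stratified_folds(codes, 10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 352
        assert sizes.max() - sizes.min() <= 1
        # stratification: every fold contains each category
        for f in range(10):
            assert set(codes[folds == f]) == {0, 1, 2}

    def test_determinism(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1, 2], 40)
        X = pd.DataFrame({"x": np.repeat([0, 1, 2.0], 40) + rng.standard_normal(120)})
        a = uef.crossval(X, y, k=5, seed=3)
        b = uef.crossval(X, y, k=5, seed=3)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        assert np.allclose(a.auc_frailty, b.auc_frailty)

    def test_strongly_separated_cohort_auc_near_one(self):
        """Wide group separation drives both cross-validated AUCs toward 1
        (exact separation is rejected by the fitter, so overlap is small but
        non-zero)."""
        rng = np.random.default_rng(13)
        y = np.repeat([0, 1, 2], 100)
        X = pd.DataFrame({"x": np.repeat([0.0, 6.0, 12.0], 100)
                          + 2.0 * rng.standard_normal(300)})
        cv = uef.crossval(X, y, k=5, seed=1)
        assert cv.auc_prefrailty.mean() > 0.97
        assert cv.auc_frailty.mean() > 0.97
        assert cv.accuracy.mean() > 0.85

    def test_small_category_rejected(self):
        y = np.repeat([0, 1, 2], [30, 30, 5])
        X = pd.DataFrame({"x": np.arange(65.0)})
        with pytest.raises(ValueError, match="smaller k"):
            uef.crossval(X, y, k=10)


class TestRocAuc:
    def test_worked_example(self):
        assert uef.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_and_tied(self):
        assert uef.roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert uef.roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            uef.roc_auc([1, 2], [1, 1])

    def test_matches_pairwise_oracle(self):
        """Mann-Whitney formula equals exhaustive pairwise concordance."""
        rng = np.random.default_rng(14)
        for _ in range(50):
            n = rng.integers(4, 30)
            s = np.round(rng.random(n), 2)  # rounding forces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert uef.roc_auc(s, y) == pytest.approx(conc / (len(pos) * len(neg)))


class TestCorrelationsAndGamma:
    def test_linear_relation(self):
        x = np.linspace(0, 1, 50)
        r = uef.correlations(x, 2 * x + 1)
        assert r["pearson_r"] == pytest.approx(1.0)
        assert r["spearman_rho"] == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(-2, 2, 100)
        r = uef.correlations(x, x**3)
        assert r["spearman_rho"] == pytest.approx(1.0)
        assert r["pearson_r"] < 1.0

    def test_independent_near_zero(self):
        rng = np.random.default_rng(15)
        r = uef.correlations(rng.standard_normal(1000), rng.standard_normal(1000))
        assert abs(r["pearson_r"]) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            uef.correlations(np.ones(10), np.arange(10.0))

    def test_gamma_shape_recovery(self):
        rng = np.random.default_rng(16)
        x = rng.gamma(2.0, 0.1, size=2000)
        fit = uef.gamma_fit(x)
        assert fit["shape"] == pytest.approx(2.0, rel=0.10)

    def test_exponential_is_gamma_one(self):
        rng = np.random.default_rng(17)
        fit = uef.gamma_fit(rng.exponential(0.3, size=2000))
        assert fit["shape"] == pytest.approx(1.0, rel=0.15)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            uef.gamma_fit(np.full(100, 0.5))
        with pytest.raises(ValueError, match="10 observations"):
            uef.gamma_fit(np.arange(5.0))

    def test_zero_scores_offset(self):
        x = np.concatenate([np.zeros(20), np.linspace(0.1, 1, 180)])
        fit = uef.gamma_fit(x)  # must not raise on the zeros
        assert np.isfinite(fit["shape"])


class TestDescriptiveTable:
    def test_shape_and_counts(self, small_cohort_80):
        table = uef.descriptive_table(small_cohort_80)
        assert list(table.columns) == ["non-frail", "pre-frail", "frail", "p_value"]
        n = small_cohort_80["fried_group"].value_counts()
        first = table.loc["n (% of total)"]
        assert first["non-frail"].startswith(str(n["non-frail"]))
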