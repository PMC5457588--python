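"""Framingham-style points score: categories, points arithmetic, scorecards."""

import itertools

import numpy as np
import pandas as pd
import pytest

import uef
from uef.points import VariableCard, round_half_away_from_zero


def toy_fit(coef: dict) -> uef.OrdinalModelFit:
    names = ["alpha_nonfrail", "alpha_prefrail", *coef]
    return uef.OrdinalModelFit(
        category_order=uef.CATEGORY_ORDER,
        intercepts=np.array([-0.5, 1.9]),
        coef=pd.Series(coef, dtype=float),
        cov=pd.DataFrame(np.eye(len(names)), index=names, columns=names),
        log_likelihood=-100.0,
        aic=200.0 + 2 * len(names),
        n_obs=352,
    )


class TestDeriveCategories:
    def test_decreasing_means(self):
        cutoffs, W, ref = uef.derive_categories([100, 80, 60])
        assert cutoffs == (90, 70)
        assert W == (100, 80, 60)
        assert ref == 0

    def test_increasing_means(self):
        cutoffs, W, ref = uef.derive_categories([20, 25, 30])
        assert cutoffs == (22.5, 27.5)
        assert W[ref] == 20

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            uef.derive_categories([10, 30, 20], name="speed")

    def test_degenerate_equal_means(self):
        cutoffs, W, ref = uef.derive_categories([5, 5, 5])
        assert W == (5, 5, 5)


class TestBaseConstant:
    def test_published_age_coefficient(self):
        assert uef.base_constant(-0.0206, 4) == pytest.approx(0.0824)

    def test_simple(self):
        assert uef.base_constant(-0.05, 4) == pytest.approx(0.2)

    def test_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            uef.base_constant(0.0)


class TestComputePoints:
    @pytest.mark.parametrize(
        "beta,dW,B,expected",
        [
            (0.30, 2.0, 0.20, 3),
            (0.25, 1.0, 0.20, 1),  # 1.25 rounds down to 1
            (0.30, 0.0, 0.20, 0),  # reference category
            (0.25, 1.5, 0.25, 2),  # exact 1.5 tie rounds half away from zero
        ],
    )
    def test_arithmetic(self, beta, dW, B, expected):
        assert uef.compute_points(beta, dW, 0.0, B) == expected

    def test_rounding_rule(self):
        assert round_half_away_from_zero(1.5) == 2
        assert round_half_away_from_zero(-1.5) == -2
        assert round_half_away_from_zero(0.49) == 0


def _two_variable_card():
    """Toy card: variable u with points (0, 1, 2), v with points (0, 2, 4)."""
    u = VariableCard("u", W=(0, 10, 20), cutoffs=(5, 15), points=(0, 1, 2),
                     beta_risk=1.0, direction=1)
    v = VariableCard("v", W=(30, 20, 10), cutoffs=(25, 15), points=(0, 2, 4),
                     beta_risk=-1.0, direction=-1)
    return uef.ScoreCard(variables={"u": u, "v": v}, base_constant=0.1,
                         age_increment_years=4, max_total_points=6)


class TestApplyScorecard:
    def test_reference_floor_and_worst_ceiling(self):
        card = _two_variable_card()
        assert uef.apply_scorecard(card, {"u": 0, "v": 30}) == 0.0
        assert uef.apply_scorecard(card, {"u": 20, "v": 10}) == 1.0

    def test_middle_categories(self):
        card = _two_variable_card()
        assert uef.apply_scorecard(card, {"u": 10, "v": 20}) == pytest.approx(3 / 6)

    def test_boundary_goes_to_higher_risk(self):
        card = _two_variable_card()
        # u: cutoff 5 with risk increasing; v: cutoff 25 with risk decreasing
        assert uef.apply_scorecard(card, {"u": 5, "v": 30}) == pytest.approx(1 / 6)
        assert uef.apply_scorecard(card, {"u": 0, "v": 25}) == pytest.approx(2 / 6)

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            uef.apply_scorecard(_two_variable_card(), {"u": 0})
        with pytest.raises(ValueError, match="non-finite"):
            uef.apply_scorecard(_two_variable_card(), {"u": np.nan, "v": 30})

    def test_monotone_in_single_variable_moves(self):
        """Moving any one variable to a frailer category never lowers the
        score: exhaustive over all category combinations of the toy card."""
        card = _two_variable_card()
        u_vals = [0, 10, 20]  # categories 0, 1, 2
        v_vals = [30, 20, 10]
        score = lambda i, j: uef.apply_scorecard(card, {"u": u_vals[i], "v": v_vals[j]})
        for i, j in itertools.product(range(3), range(3)):
            if i < 2:
                assert score(i + 1, j) >= score(i, j)
            if j < 2:
                assert score(i, j + 1) >= score(i, j)


class TestBuildScorecard:
    def test_points_scale_with_beta(self):
        fit = toy_fit({"a": -0.2, "b": -0.4, "age": -0.05})
        means = pd.DataFrame(
            {"non-frail": [10.0, 10.0], "pre-frail": [12.0, 12.0], "frail": [14.0, 14.0]},
            index=["a", "b"],
        )
        card = uef.build_scorecard(fit, means)
        # B = 0.2; a: 0.2*2/0.2 = 2, 4; b: 0.4*2/0.2 = 4, 8
        assert card.variables["a"].points == (0, 2, 4)
        assert card.variables["b"].points == (0, 4, 8)
        assert card.max_total_points == 12

    def test_degenerate_variable_excluded_from_total(self):
        fit = toy_fit({"a": -0.2, "flat": -0.9, "age": -0.05})
        means = pd.DataFrame(
            {"non-frail": [10.0, 7.0], "pre-frail": [12.0, 7.0], "frail": [14.0, 7.0]},
            index=["a", "flat"],
        )
        card = uef.build_scorecard(fit, means)
        assert card.variables["flat"].points == (0, 0, 0)
        assert card.max_total_points == 4

    def test_sign_conflict_warns_but_builds(self):
        """A conditional coefficient opposing the marginal trend keeps its
        magnitude with the trend's risk direction."""
        fit = toy_fit({"a": +0.2, "age": -0.05})  # positive beta, rising W
        means = pd.DataFrame(
            {"non-frail": [10.0], "pre-frail": [12.0], "frail": [14.0]}, index=["a"]
        )
        with pytest.warns(UserWarning, match="opposes"):
            card = uef.build_scorecard(fit, means)
        assert card.variables["a"].points == (0, 2, 4)

    def test_missing_age_rejected(self):
        fit = toy_fit({"a": -0.2})
        means = pd.DataFrame(
            {"non-frail": [10.0], "pre-frail": [12.0], "frail": [14.0]}, index=["a"]
        )
        with pytest.raises(ValueError, match="age"):
            uef.build_scorecard(fit, means)

    def test_halving_base_constant_never_lowers_points(self):
        """Points are non-increasing in B over a grid (doubling B halves the
        pre-rounding values)."""
        fit_coef = {"a": -0.3, "age": -0.05}
        means = pd.DataFrame(
            {"non-frail": [0.0], "pre-frail": [1.0], "frail": [2.5]}, index=["a"]
        )
        prev = None
        for incr in (1, 2, 4, 8, 16):
            card = uef.build_scorecard(toy_fit(fit_coef), means, increment_years=incr)
            pts = card.variables["a"].points
            pre = [0.3 * w / (0.05 * incr) for w in (0.0, 1.0, 2.5)]
            assert pts == tuple(round_half_away_from_zero(p) for p in pre)
            if prev is not None:
                assert all(a <= b for a, b in zip(pts, prev))
            prev = pts


class TestYamlRoundTrip:
    def test_scorecard_serialisation(self):
        card = _two_variable_card()
        again = uef.ScoreCard.from_yaml(card.to_yaml())
        assert again.max_total_points == card.max_total_points
        assert again.variables["v"].points == card.variables["v"].points
        assert again.variables["v"].cutoffs == card.variables["v"].cutoffs


class TestSyntheticCohortScore:
    def test_mean_score_increases_with_frailty(self, default_cohort_352):
        """A scorecard built from the synthetic cohort's own fit yields mean
        scores strictly increasing across Fried groups, and a right-skewed
        distribution."""
        from scipy import stats

        from uef.published import design_from_cohort

        scored = ["speed", "flexibility", "log_moment", "speed_variability",
                  "speed_reduction", "flexion_number", "bmi"]
        X = design_from_cohort(default_cohort_352, scored + ["age", "sex_female"])
        fit = uef.fit_proportional_odds(X, default_cohort_352["fried_group"])
        means = (
            X[scored]
            .groupby(default_cohort_352["fried_group"].to_numpy())
            .mean()
            .T[list(uef.FRIED_CATEGORIES)]
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            card = uef.build_scorecard(fit, means, variables=scored)
        scores = uef.apply_scorecard(card, X[scored])
        by_group = scores.groupby(default_cohort_352["fried_group"].to_numpy()).mean()
        assert by_group["non-frail"] < by_group["pre-frail"] < by_group["frail"]
        assert scores.between(0, 1).all()
        assert stats.skew(scores) > 0
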