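"""Framingham-style points construction of the continuous UEF score.

Each scored variable (the UEF parameters retained by the categorical index,
plus BMI) is split into three categories at the midpoints of its three
frailty-group means W = (W_nonfrail, W_prefrail, W_frail).  The non-frail
group mean is the reference W_ref; a category's point value is

    points = round( beta_risk * (W - W_ref) / B )

with half-away-from-zero rounding, beta_risk the fitted coefficient re-signed
so that larger values always mean greater frailty risk, and the base constant
B = |beta_age| * increment_years (default 4 years — the typical age gap
between adjacent frailty groups), i.e. one point equals the risk carried by a
4-year age increase.  The total is normalised by the maximum attainable
points, giving a score on [0, 1] with 0 extreme resilience and 1 extreme
frailty.  Age and sex contribute to the base constant but are not themselves
scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ordinal import OrdinalModelFit

DEFAULT_AGE_INCREMENT_YEARS = 4.0

#: Variables never scored even when present in the fitted index.
NON_SCORED_PREDICTORS = ("age", "sex_female")


def round_half_away_from_zero(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class VariableCard:
    """Scoring rule for one variable.

    ``W`` are the frailty-group means in group order (non-frail, pre-frail,
    frail); ``cutoffs`` the midpoints of adjacent means; ``points`` the
    integer points per category (reference category 0).  ``direction`` is
    +1 when W increases with frailty (risk at high values) and -1 when it
    decreases; ``degenerate`` marks a variable whose three W are equal (all
    points 0, excluded from the normalisation).
    """

    name: str
    W: tuple[float, float, float]
    cutoffs: tuple[float, float]
    points: tuple[int, int, int]
    beta_risk: float
    direction: int
    degenerate: bool = False

    def category_of(self, value: float) -> int:
        """Category index 0..2; values exactly on a cutoff go to the
        higher-risk side."""
        if not np.isfinite(value):
            raise ValueError(f"non-finite value for scored variable {self.name!r}")
        if self.degenerate:
            return 0
        c1, c2 = self.cutoffs
        if self.direction > 0:  # risk increases with the value
            return 2 if value >= c2 else (1 if value >= c1 else 0)
        return 2 if value <= c2 else (1 if value <= c1 else 0)

    @property
    def max_points(self) -> int:
        return max(self.points)


@dataclass
class ScoreCard:
    """Complete points schedule for the continuous UEF score."""

    variables: dict[str, VariableCard]
    base_constant: float
    age_increment_years: float
    max_total_points: int

    def to_yaml(self) -> str:
        payload = {
            "version": 1,
            "base_constant": float(self.base_constant),
            "age_increment_years": float(self.age_increment_years),
            "max_total_points": int(self.max_total_points),
            "variables": {
                name: {
                    "W": [float(w) for w in v.W],
                    "cutoffs": [float(c) for c in v.cutoffs],
                    "points": [int(p) for p in v.points],
                    "beta_risk": float(v.beta_risk),
                    "direction": int(v.direction),
                    "degenerate": bool(v.degenerate),
                }
                for name, v in self.variables.items()
            },
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScoreCard":
        d = yaml.safe_load(text)
        variables = {
            name: VariableCard(
                name=name,
                W=tuple(v["W"]),
                cutoffs=tuple(v["cutoffs"]),
                points=tuple(v["points"]),
                beta_risk=v["beta_risk"],
                direction=v["direction"],
                degenerate=v.get("degenerate", False),
            )
            for name, v in d["variables"].items()
        }
        return cls(
            variables=variables,
            base_constant=d["base_constant"],
            age_increment_years=d["age_increment_years"],
            max_total_points=d["max_total_points"],
        )


def derive_categories(group_means, name: str = "variable"):
    """Cutoffs, reference values and reference index from group means.

    ``group_means`` are the variable's means in the three frailty groups in
    order (non-frail, pre-frail, frail).  Cutoffs are the midpoints of
    adjacent means; the reference is the non-frail (lowest-risk) end.  Means
    must be strictly monotone across groups (in either direction) for the
    midpoint construction to be well defined; three equal means are accepted
    as a degenerate (zero-point) variable.
    """
    W = tuple(float(w) for w in group_means)
    if len(W) != 3 or not all(np.isfinite(W)):
        raise ValueError(f"{name}: need three finite group means")
    if W[0] == W[1] == W[2]:
        return (W[0], W[0]), W, 0  # degenerate
    increasing = W[0] < W[1] < W[2]
    decreasing = W[0] > W[1] > W[2]
    if not (increasing or decreasing):
        raise ValueError(
            f"{name}: group means {W} are not monotone across frailty groups; "
            "midpoint cutoffs are ill-defined"
        )
    cutoffs = ((W[0] + W[1]) / 2.0, (W[1] + W[2]) / 2.0)
    return cutoffs, W, 0


def base_constant(
    age_beta: float, increment_years: float = DEFAULT_AGE_INCREMENT_YEARS
) -> float:
    """Base constant B = |beta_age| * increment: regression units per point."""
    if age_beta == 0:
        raise ValueError("age coefficient is zero; base constant undefined")
    if not np.isfinite(age_beta) or increment_years <= 0:
        raise ValueError("age_beta must be finite and increment_years positive")
    return abs(age_beta) * increment_years


def compute_points(beta_risk: float, W: float, W_ref: float, B: float) -> int:
    """Integer points for one category: round(beta_risk * (W - W_ref) / B)."""
    if B <= 0:
        raise ValueError("base constant must be positive")
    for v in (beta_risk, W, W_ref):
        if not np.isfinite(v):
            raise ValueError("non-finite input to compute_points")
    return round_half_away_from_zero(beta_risk * (W - W_ref) / B)


def build_scorecard(
    fit: OrdinalModelFit,
    group_means: pd.DataFrame,
    increment_years: float = DEFAULT_AGE_INCREMENT_YEARS,
    variables=None,
) -> ScoreCard:
    """Assemble a ScoreCard from a fitted index and per-group variable means.

    ``group_means`` is indexed by variable name with one column per frailty
    group in order (non-frail, pre-frail, frail) — in predictor space, i.e.
    the moment variable is ``log_moment``.  ``variables`` defaults to every
    fitted predictor except age and sex.  The fit must contain an age
    coefficient, which sets the base constant.

    The risk coefficient is the fitted coefficient re-signed so that moving
    towards the frail end of the variable's group-mean gradient always adds
    points: beta_risk = |beta| * sign(W_frail - W_nonfrail).  When the
    conditional (multivariable) coefficient sign contradicts the marginal
    trend — which collinearity among the fatigue measures can produce — the
    magnitude is kept and a warning is emitted.
    """
    if "age" not in fit.coef.index:
        raise ValueError("fit lacks an age coefficient; cannot set the base constant")
    B = base_constant(float(fit.coef["age"]), increment_years)
    if variables is None:
        variables = [v for v in fit.coef.index if v not in NON_SCORED_PREDICTORS]
    cards: dict[str, VariableCard] = {}
    max_total = 0
    for name in variables:
        if name not in fit.coef.index:
            raise ValueError(f"scored variable {name!r} missing from the fit")
        if name not in group_means.index:
            raise ValueError(f"group means missing for scored variable {name!r}")
        W_row = group_means.loc[name].to_numpy(dtype=float)
        cutoffs, W, ref = derive_categories(W_row, name=name)
        degenerate = W[0] == W[1] == W[2]
        beta = float(fit.coef[name])
        if degenerate:
            beta_risk = abs(beta)
            pts = (0, 0, 0)
            direction = 1
        else:
            direction = 1 if W[2] > W[0] else -1
            beta_risk = abs(beta) * direction
            # under the model orientation (positive = protective), a coherent
            # coefficient satisfies sign(beta) == -direction
            if beta != 0 and np.sign(beta) == direction:
                warnings.warn(
                    f"{name}: conditional coefficient sign ({beta:+.4g}) opposes "
                    f"the marginal group-mean trend {W}; using |beta| with the "
                    "trend's risk direction"
                )
            pts = tuple(compute_points(beta_risk, w, W[ref], B) for w in W)
            max_total += max(pts)
        cards[name] = VariableCard(
            name=name, W=W, cutoffs=cutoffs, points=pts,
            beta_risk=beta_risk, direction=direction, degenerate=degenerate,
        )
    if max_total <= 0:
        raise ValueError("all scored variables are degenerate; max points is 0")
    return ScoreCard(
        variables=cards,
        base_constant=B,
        age_increment_years=increment_years,
        max_total_points=max_total,
    )


def apply_scorecard(card: ScoreCard, values) -> float | pd.Series:
    """Continuous UEF score on [0, 1] for one subject or a cohort.

    ``values`` is a mapping of scored-variable values (returns a float) or a
    DataFrame with one column per scored variable (returns a Series).  Each
    variable is binned by the card's cutoffs (boundary values to the
    higher-risk category), integer points are summed, and the total is
    divided by the maximum attainable points.
    """
    if isinstance(values, pd.DataFrame):
        return values.apply(lambda row: apply_scorecard(card, row), axis=1)
    total = 0
    for name, v in card.variables.items():
        if name not in values:
            raise ValueError(f"missing scored variable {name!r}")
        total += v.points[v.category_of(float(values[name]))]
    return total / card.max_total_points
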