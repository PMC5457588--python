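"""Published UEF categorical-index coefficients, shipped as a versioned asset.

The multivariable proportional-odds estimates from the original development
cohort (n = 352) let the index be applied to new subjects without refitting.
`score_cohort` appends predicted probabilities and the arg-max category to a
cohort table that already carries extracted UEF parameters.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .ordinal import classify, predict_probabilities


def load_published_model() -> dict:
    """Load the published coefficient asset (dict with intercepts,
    coefficients, standard_errors, n_obs, version)."""
    text = resources.files("uef.data").joinpath("published_model.yaml").read_text()
    return yaml.safe_load(text)


def published_coefficients() -> tuple[pd.Series, tuple[float, float]]:
    """Return (coef Series, (alpha_nonfrail, alpha_prefrail))."""
    asset = load_published_model()
    coef = pd.Series(asset["coefficients"], dtype=float)
    icpt = asset["intercepts"]
    return coef, (float(icpt["alpha_nonfrail"]), float(icpt["alpha_prefrail"]))


def design_from_cohort(cohort: pd.DataFrame, predictors) -> pd.DataFrame:
    """Model matrix for the requested canonical predictors from a cohort table.

    Maps cohort columns to predictor names: ``log_moment`` = ln(moment),
    ``sex_female`` = 1 for female, ``age``/``bmi`` from the demographic
    columns, everything else straight from the extracted UEF parameters.
    """
    out = pd.DataFrame(index=cohort.index)
    for name in predictors:
        if name == "log_moment":
            m = cohort["moment"].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[name] = np.where(m > 0, np.log(np.where(m > 0, m, np.nan)), np.nan)
        elif name == "sex_female":
            out[name] = (cohort["sex"].astype(str).str.strip().str.lower() == "female").astype(
                float
            )
        elif name == "age":
            out[name] = cohort["age_years"].astype(float)
        elif name == "bmi":
            out[name] = cohort["bmi_kgm2"].astype(float)
        elif name in cohort.columns:
            out[name] = cohort[name].astype(float)
        else:
            raise ValueError(f"cohort table lacks a column for predictor {name!r}")
    return out


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the published index to a cohort table with extracted parameters.

    Returns a copy with p_nonfrail / p_prefrail / p_frail and the predicted
    ``uef_category`` appended.
    """
    coef, intercepts = published_coefficients()
    X = design_from_cohort(cohort, coef.index)
    probs = predict_probabilities(coef, X, intercepts=intercepts)
    out = cohort.copy()
    out[["p_nonfrail", "p_prefrail", "p_frail"]] = probs
    out["uef_category"] = classify(probs)
    return out
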