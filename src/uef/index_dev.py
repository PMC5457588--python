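"""Index-development pipeline: screening, collinearity, selection, validation.

The UEF categorical index was built in five steps, reproduced here as
composable operations on a cohort table with extracted UEF parameters:

1. descriptive screening — box-plot outliers within each frailty group and
   Shapiro-Wilk normality per parameter, with a log transform recorded when
   it rescues normality (:func:`normality_screen`);
2. univariate proportional-odds screening of each UEF parameter against the
   Fried stage (:func:`univariate_screen`);
3. collinearity by variance inflation factors, cutoff 10 (:func:`vif`);
4. forward stepwise AIC selection over UEF and demographic predictors
   (:func:`stepwise_aic`);
5. stratified 10-fold cross-validation reporting ROC AUC for pre-frailty and
   frailty, training AIC and classification accuracy (:func:`crossval`).

Score-distribution (gamma fit) and correlation utilities used for the
continuous score round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ordinal import (
    CATEGORY_ORDER,
    OrdinalModelFit,
    _encode_outcome,
    classify,
    fit_proportional_odds,
    predict_probabilities,
    wald_tests,
)

UEF_PARAMETER_COLUMNS = (
    "speed",
    "flexibility",
    "power",
    "rise_time",
    "moment",
    "speed_variability",
    "speed_reduction",
    "flexion_number",
)

VIF_CUTOFF = 10.0
UNIVARIATE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# step 1: descriptive / normality screening


@dataclass
class ParameterScreen:
    parameter: str
    shapiro_w: float
    shapiro_p: float
    transform_applied: str  # none | log
    log_feasible: bool
    shapiro_w_log: float
    shapiro_p_log: float
    outliers: dict[str, list]  # frailty group -> row labels beyond 1.5 IQR
    degenerate: bool = False


@dataclass
class ScreeningReport:
    screens: dict[str, ParameterScreen]

    def transforms(self) -> dict[str, str]:
        return {k: s.transform_applied for k, s in self.screens.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = {
            k: dict(
                shapiro_w=s.shapiro_w,
                shapiro_p=s.shapiro_p,
                transform=s.transform_applied,
                n_outliers=sum(len(v) for v in s.outliers.values()),
                degenerate=s.degenerate,
            )
            for k, s in self.screens.items()
        }
        return pd.DataFrame(rows).T


def _box_outliers(values: pd.Series) -> list:
    """Row labels beyond the 1.5*IQR box-plot whiskers."""
    q1, q3 = np.nanpercentile(values.to_numpy(dtype=float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (values < lo) | (values > hi)
    return list(values.index[mask.fillna(False)])


def normality_screen(
    cohort: pd.DataFrame, parameters=UEF_PARAMETER_COLUMNS, alpha: float = 0.05
) -> ScreeningReport:
    """Shapiro-Wilk normality per UEF parameter with per-group outlier flags.

    A log transform is recorded only when the raw test rejects normality
    (p < alpha), all values are positive, and the transformed test does not
    reject.  Outliers (points beyond the 1.5*IQR whiskers within each frailty
    group) are reported, never removed.  Constant columns are flagged
    degenerate and left untransformed.
    """
    groups = cohort.groupby("fried_group", observed=True)
    if any(len(g) < 3 for _, g in groups):
        raise ValueError("need >= 3 observations per frailty group")
    screens: dict[str, ParameterScreen] = {}
    for name in parameters:
        x = cohort[name].astype(float).dropna()
        outliers = {
            str(g): _box_outliers(sub[name].astype(float).dropna()) for g, sub in groups
        }
        if x.nunique() <= 1:
            screens[name] = ParameterScreen(
                name, float("nan"), float("nan"), "none", False,
                float("nan"), float("nan"), outliers, degenerate=True,
            )
            continue
        w, p = stats.shapiro(x.to_numpy())
        feasible = bool((x > 0).all())
        w_log = p_log = float("nan")
        transform = "none"
        if p < alpha and feasible:
            w_log, p_log = stats.shapiro(np.log(x.to_numpy()))
            if p_log >= alpha:
                transform = "log"
        screens[name] = ParameterScreen(
            name, float(w), float(p), transform, feasible, float(w_log), float(p_log), outliers
        )
    return ScreeningReport(screens)


# ---------------------------------------------------------------------------
# step 2: univariate association


def univariate_screen(
    cohort: pd.DataFrame,
    parameters=UEF_PARAMETER_COLUMNS,
    transforms: dict[str, str] | None = None,
    alpha: float = UNIVARIATE_ALPHA,
) -> pd.DataFrame:
    """Single-predictor proportional-odds fit per UEF parameter.

    Returns a DataFrame indexed by parameter with the slope estimate, Wald
    p-value and a ``selected`` flag (p < alpha).  A parameter whose fit fails
    is reported with NaN and ``selected=False`` instead of aborting the batch.
    """
    transforms = transforms or {}
    y = cohort["fried_group"]
    rows = {}
    for name in parameters:
        x = cohort[name].astype(float)
        label = name
        if transforms.get(name) == "log":
            x = np.log(x)
            label = f"log_{name}"
        try:
            fit = fit_proportional_odds(pd.DataFrame({label: x}), y)
            wt = wald_tests(fit).loc[label]
            rows[name] = dict(
                predictor=label,
                beta=float(fit.coef[label]),
                se=float(wt["se"]),
                chi2=float(wt["chi2"]),
                p_value=float(wt["p_value"]),
                selected=bool(wt["p_value"] < alpha),
            )
        except Exception as exc:  # noqa: BLE001 - per-parameter isolation
            warnings.warn(f"univariate fit failed for {name}: {exc}")
            rows[name] = dict(
                predictor=label, beta=float("nan"), se=float("nan"),
                chi2=float("nan"), p_value=float("nan"), selected=False,
            )
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# step 3: collinearity


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2) of column j
    regressed (with intercept) on all other columns.  Exact collinearity
    yields ``inf``.  Values above 10 indicate collinearity.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    A = X.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(X.columns):
        yj = A[:, j]
        others = np.column_stack([np.ones(A.shape[0]), np.delete(A, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# step 4: forward stepwise AIC


@dataclass
class StepwiseResult:
    selected: list[str]
    fit: OrdinalModelFit
    path: list[tuple[str | None, float]] = field(default_factory=list)  # (added, aic)


def stepwise_aic(
    X: pd.DataFrame, y, candidates=None, forced_out=()
) -> StepwiseResult:
    """Forward stepwise selection by AIC over proportional-odds models.

    Starting from the intercept-only model, at each step the candidate whose
    addition lowers the AIC the most enters; selection stops when no addition
    lowers the AIC.  Ties break by candidate declaration order.  Candidates
    whose fit fails are skipped with a warning.
    """
    candidates = list(X.columns if candidates is None else candidates)
    candidates = [c for c in candidates if c not in set(forced_out)]
    base = fit_proportional_odds(None, y)
    path: list[tuple[str | None, float]] = [(None, base.aic)]
    selected: list[str] = []
    current = base
    while candidates:
        best_name, best_fit = None, None
        for name in candidates:
            try:
                trial = fit_proportional_odds(X[selected + [name]], y)
            except Exception as exc:  # noqa: BLE001 - candidate isolation
                warnings.warn(f"stepwise candidate {name!r} skipped: {exc}")
                continue
            if best_fit is None or trial.aic < best_fit.aic - 1e-12:
                best_name, best_fit = name, trial
        if best_fit is None or best_fit.aic >= current.aic - 1e-12:
            break
        selected.append(best_name)
        candidates.remove(best_name)
        current = best_fit
        path.append((best_name, current.aic))
    return StepwiseResult(selected=selected, fit=current, path=path)


# ---------------------------------------------------------------------------
# step 5: cross-validation


@dataclass
class CVResult:
    """Per-fold and summary cross-validation metrics.

    ``auc_prefrailty`` scores (pre-frail or frail) vs non-frail with
    p_prefrail + p_frail; ``auc_frailty`` scores frail vs the rest with
    p_frail; ``aic`` is the training-fit AIC; ``accuracy`` the 3-class
    arg-max accuracy on the held-out fold.
    """

    k: int
    seed: int
    fold_assignments: np.ndarray
    auc_prefrailty: np.ndarray
    auc_frailty: np.ndarray
    aic: np.ndarray
    accuracy: np.ndarray

    def summary(self) -> pd.DataFrame:
        data = {
            "auc_prefrailty": self.auc_prefrailty,
            "auc_frailty": self.auc_frailty,
            "aic": self.aic,
            "accuracy": self.accuracy,
        }
        return pd.DataFrame(
            {k: {"mean": np.mean(v), "sd": np.std(v, ddof=1)} for k, v in data.items()}
        ).T


def stratified_folds(codes: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Random folds stratified by category.

    Subjects are permuted within category and dealt round-robin with a fold
    counter that continues across categories, so fold sizes differ by at most
    one both overall and within each category.
    """
    rng = np.random.default_rng(seed)
    folds = np.empty(codes.size, dtype=int)
    counter = 0
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        rng.shuffle(idx)
        for i in idx:
            folds[i] = counter % k
            counter += 1
    return folds


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the Mann-Whitney statistic.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg), identical
    to trapezoidal integration of the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def crossval(
    cohort_X: pd.DataFrame,
    y,
    k: int = 10,
    seed: int = 0,
    accuracy_mode: str = "three-class",
) -> CVResult:
    """Stratified k-fold cross-validation of the proportional-odds index.

    Per fold: fit on the k-1 training partitions, predict the held-out fold,
    and record AUC for pre-frailty (non-frail vs the rest, scored by
    p_prefrail + p_frail), AUC for frailty (frail vs the rest, scored by
    p_frail), the training AIC, and accuracy.  ``accuracy_mode`` is
    ``"three-class"`` (arg-max, default) or ``"dichotomous"`` (mean of the
    two one-vs-rest accuracies at the arg-max dichotomisations).
    """
    codes = _encode_outcome(y)
    counts = np.bincount(codes, minlength=3)
    if np.any(counts < k):
        lacking = [CATEGORY_ORDER[i] for i in np.flatnonzero(counts < k)]
        raise ValueError(
            f"category {lacking} has fewer than k={k} members; use a smaller k"
        )
    X = cohort_X.reset_index(drop=True)
    folds = stratified_folds(codes, k, seed)
    auc_pre, auc_fr, aics, accs = [], [], [], []
    for fold in range(k):
        test = folds == fold
        train = ~test
        fit = fit_proportional_odds(X.loc[train], codes[train])
        probs = predict_probabilities(fit, X.loc[test])
        score_pre = (probs["p_prefrail"] + probs["p_frail"]).to_numpy()
        score_fr = probs["p_frail"].to_numpy()
        yt = codes[test]
        auc_pre.append(roc_auc(score_pre, yt >= 1))
        auc_fr.append(roc_auc(score_fr, yt == 2))
        aics.append(fit.aic)
        pred = classify(probs)
        pred_codes = np.array([CATEGORY_ORDER.index(c) for c in pred])
        if accuracy_mode == "three-class":
            accs.append(float(np.mean(pred_codes == yt)))
        elif accuracy_mode == "dichotomous":
            a1 = float(np.mean((pred_codes >= 1) == (yt >= 1)))
            a2 = float(np.mean((pred_codes == 2) == (yt == 2)))
            accs.append(0.5 * (a1 + a2))
        else:
            raise ValueError(f"unknown accuracy_mode {accuracy_mode!r}")
    return CVResult(
        k=k,
        seed=seed,
        fold_assignments=folds,
        auc_prefrailty=np.array(auc_pre),
        auc_frailty=np.array(auc_fr),
        aic=np.array(aics),
        accuracy=np.array(accs),
    )


# ---------------------------------------------------------------------------
# score-distribution and correlation utilities


def correlations(x, y) -> dict[str, float]:
    """Pearson and Spearman rank correlations with p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlations need two equal-length vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }


def gamma_fit(scores) -> dict[str, float]:
    """Maximum-likelihood gamma fit of a score distribution with a KS check.

    Non-positive scores (a subject in all reference categories scores exactly
    0) are offset by half the smallest positive increment between distinct
    score values before fitting, since the gamma support is (0, inf).
    Returns shape, scale and the one-sample Kolmogorov-Smirnov statistic and
    p-value against the fitted gamma.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 10:
        raise ValueError("gamma_fit needs at least 10 observations")
    if np.unique(x).size == 1:
        raise ValueError("degenerate (constant) score sample")
    if np.any(x < 0):
        raise ValueError("scores must be >= 0")
    if np.any(x <= 0):
        diffs = np.diff(np.unique(x))
        eps = 0.5 * float(diffs[diffs > 0].min())
        x = np.where(x <= 0, eps, x)
    shape, _, scale = stats.gamma.fit(x, floc=0.0)
    ks = stats.kstest(x, stats.gamma(shape, loc=0.0, scale=scale).cdf)
    return {
        "shape": float(shape),
        "scale": float(scale),
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


# ---------------------------------------------------------------------------
# descriptive report (cohort characteristics table)


def descriptive_table(cohort: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Cohort characteristics by frailty group: counts, mean (SD), p-values.

    Continuous variables are compared by one-way ANOVA; the sex composition by
    a chi-square test on the 2x3 contingency table.  Mirrors the standard
    sociodemographic table of a cohort paper.
    """
    variables = list(
        variables
        if variables is not None
        else [c for c in ("age_years", "height_cm", "weight_kg", "bmi_kgm2", "mmse")
              if c in cohort.columns]
    )
    groups = [g for g in CATEGORY_ORDER if (cohort["fried_group"] == g).any()]
    n_total = len(cohort)
    rows = {}
    counts = {g: int((cohort["fried_group"] == g).sum()) for g in groups}
    rows["n (% of total)"] = {
        g: f"{counts[g]} ({100.0 * counts[g] / n_total:.0f}%)" for g in groups
    } | {"p_value": ""}
    if "sex" in cohort.columns:
        male = {
            g: int(
                (
                    cohort.loc[cohort["fried_group"] == g, "sex"].str.lower() == "male"
                ).sum()
            )
            for g in groups
        }
        table = np.array([[male[g], counts[g] - male[g]] for g in groups]).T
        chi2_p = stats.chi2_contingency(table).pvalue if table.min() >= 0 else np.nan
        rows["male, n (% of group)"] = {
            g: f"{male[g]} ({100.0 * male[g] / counts[g]:.0f}%)" for g in groups
        } | {"p_value": f"{chi2_p:.2f}"}
    for var in variables:
        samples = [
            cohort.loc[cohort["fried_group"] == g, var].dropna().to_numpy(dtype=float)
            for g in groups
        ]
        p = stats.f_oneway(*samples).pvalue if all(s.size > 1 for s in samples) else np.nan
        rows[var] = {
            g: f"{s.mean():.2f} ({s.std(ddof=1):.2f})" for g, s in zip(groups, samples)
        } | {"p_value": f"{p:.3g}"}
    return pd.DataFrame(rows).T[groups + ["p_value"]]
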