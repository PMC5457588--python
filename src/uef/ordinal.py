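"""Proportional-odds (cumulative-logit) ordinal logistic regression.

The UEF categorical index models the Fried frailty stage Y in
{non-frail < pre-frail < frail} as

    P(Y <= k | x) = logistic(alpha_k + x' beta),   k in {non-frail, pre-frail},

with a common coefficient vector beta across both cumulative thresholds.
Under this orientation a positive coefficient is protective: larger predictor
values push probability mass toward the less frail categories (e.g. faster
elbow flexion), and a negative coefficient (e.g. BMI) marks a risk factor.

Fitting is damped Newton maximisation of the exact likelihood with analytic
gradient and Hessian, on internally standardised predictors for numerical
stability; estimates, covariance (inverse observed information) and the AIC
are mapped back to the original predictor scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit
from scipy import stats

CATEGORY_ORDER = ("non-frail", "pre-frail", "frail")

#: Canonical predictor names used across the package.  The elbow moment always
#: enters the model as its natural logarithm (``log_moment``).
MODEL_PREDICTORS = (
    "speed",
    "flexibility",
    "log_moment",
    "speed_variability",
    "speed_reduction",
    "flexion_number",
    "sex_female",
    "age",
    "bmi",
)


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations fail to converge (e.g. complete separation)."""


class SingularDesignError(ValueError):
    """Raised when the predictor matrix is rank-deficient."""


@dataclass
class OrdinalModelFit:
    """Fitted proportional-odds model.

    ``intercepts`` holds (alpha_nonfrail, alpha_prefrail) on the logit scale
    with alpha_nonfrail < alpha_prefrail; ``coef`` is a named Series over the
    predictors; ``cov`` covers all parameters in the order (alpha_nonfrail,
    alpha_prefrail, *predictors).
    """

    category_order: tuple[str, ...]
    intercepts: np.ndarray
    coef: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    aic: float
    n_obs: int
    n_iter: int = 0
    converged: bool = True

    @property
    def n_params(self) -> int:
        return 2 + len(self.coef)

    @property
    def param_names(self) -> list[str]:
        return ["alpha_nonfrail", "alpha_prefrail", *self.coef.index]


@dataclass
class FrailtyProbabilities:
    """Predicted category probabilities for one subject; sums to 1."""

    p_nonfrail: float
    p_prefrail: float
    p_frail: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_nonfrail, self.p_prefrail, self.p_frail])


def _encode_outcome(y) -> np.ndarray:
    """Map a frailty outcome vector to integer codes 0/1/2 in category order."""
    if isinstance(y, pd.Series) and isinstance(y.dtype, pd.CategoricalDtype):
        cats = list(y.cat.categories)
        if cats != list(CATEGORY_ORDER):
            raise ValueError(f"outcome categories {cats} != {list(CATEGORY_ORDER)}")
        codes = y.cat.codes.to_numpy()
    else:
        arr = np.asarray(y)
        if arr.dtype.kind in "iu":
            codes = arr.astype(int)
        else:
            lut = {c: i for i, c in enumerate(CATEGORY_ORDER)}
            try:
                codes = np.array([lut[str(v).strip().lower()] for v in arr])
            except KeyError as exc:
                raise ValueError(f"unknown outcome category {exc.args[0]!r}") from exc
    if codes.min() < 0 or codes.max() > 2:
        raise ValueError("outcome codes must lie in {0, 1, 2}")
    return codes


def _loglik_parts(theta: np.ndarray, X: np.ndarray, codes: np.ndarray):
    """Log-likelihood, gradient and Hessian at theta = (a1, a2, beta)."""
    a1, a2 = theta[0], theta[1]
    beta = theta[2:]
    eta = X @ beta if beta.size else np.zeros(X.shape[0])
    u = a1 + eta
    v = a2 + eta
    c1 = expit(u)
    c2 = expit(v)

    m0 = codes == 0
    m1 = codes == 1
    m2 = codes == 2

    p_mid = c2[m1] - c1[m1]
    if np.any(p_mid <= 0):
        return -np.inf, None, None
    ll = float(log_expit(u[m0]).sum() + np.log(p_mid).sum() + log_expit(-v[m2]).sum())

    n = X.shape[0]
    gu = np.zeros(n)
    gv = np.zeros(n)
    huu = np.zeros(n)
    hvv = np.zeros(n)
    huv = np.zeros(n)

    # y = non-frail: log c1
    gu[m0] = 1.0 - c1[m0]
    huu[m0] = -c1[m0] * (1.0 - c1[m0])
    # y = frail: log(1 - c2)
    gv[m2] = -c2[m2]
    hvv[m2] = -c2[m2] * (1.0 - c2[m2])
    # y = pre-frail: log(c2 - c1)
    d1 = c1[m1] * (1.0 - c1[m1])
    d2 = c2[m1] * (1.0 - c2[m1])
    dd1 = d1 * (1.0 - 2.0 * c1[m1])
    dd2 = d2 * (1.0 - 2.0 * c2[m1])
    gu[m1] = -d1 / p_mid
    gv[m1] = d2 / p_mid
    huu[m1] = (-dd1 * p_mid - d1**2) / p_mid**2
    hvv[m1] = (dd2 * p_mid - d2**2) / p_mid**2
    huv[m1] = d1 * d2 / p_mid**2

    p = beta.size
    grad = np.empty(2 + p)
    grad[0] = gu.sum()
    grad[1] = gv.sum()
    if p:
        grad[2:] = X.T @ (gu + gv)

    H = np.empty((2 + p, 2 + p))
    H[0, 0] = huu.sum()
    H[1, 1] = hvv.sum()
    H[0, 1] = H[1, 0] = huv.sum()
    if p:
        h1 = X.T @ (huu + huv)
        h2 = X.T @ (huv + hvv)
        H[0, 2:] = H[2:, 0] = h1
        H[1, 2:] = H[2:, 1] = h2
        H[2:, 2:] = (X * (huu + 2 * huv + hvv)[:, None]).T @ X
    return ll, grad, H


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    Xc = X - X.mean(axis=0)
    scale = Xc.std(axis=0)
    const = [names[j] for j in np.flatnonzero(scale == 0)]
    if const:
        raise SingularDesignError(f"constant predictor column(s): {const}")
    r = np.linalg.matrix_rank(Xc)
    if r < X.shape[1]:
        # identify an offending subset via QR pivoting on the correlation matrix
        _, R = np.linalg.qr(Xc / scale)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise SingularDesignError(f"collinear predictor column(s): {bad or names}")


def fit_proportional_odds(
    X=None,
    y=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> OrdinalModelFit:
    """Maximum-likelihood fit of the proportional-odds model.

    Parameters
    ----------
    X : DataFrame or 2-D array or None
        Predictor matrix (None or zero columns for an intercept-only fit).
    y : sequence
        Frailty outcome: category strings, ordered categorical, or codes 0/1/2.
    tol : float
        Convergence threshold on the max-norm of the score vector.
    max_iter : int
        Maximum damped Newton iterations.

    Raises
    ------
    ConvergenceError
        On non-convergence, e.g. complete separation (the message names the
        predictor with the most extreme standardised coefficient).
    SingularDesignError
        If predictor columns are constant or collinear.
    """
    codes = _encode_outcome(y)
    counts = np.bincount(codes, minlength=3)
    if np.any(counts == 0):
        missing = [CATEGORY_ORDER[k] for k in np.flatnonzero(counts == 0)]
        raise ValueError(f"each category needs >= 1 observation; empty: {missing}")

    if X is None:
        Xdf = pd.DataFrame(index=range(codes.size))
    elif isinstance(X, pd.DataFrame):
        Xdf = X.reset_index(drop=True)
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[0] != codes.size:
            arr = arr.T
        Xdf = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    if Xdf.isna().any().any():
        bad = list(Xdf.columns[Xdf.isna().any()])
        raise ValueError(f"missing predictor values in column(s): {bad}")
    names = list(Xdf.columns)
    Xraw = Xdf.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xraw)):
        raise ValueError("non-finite predictor values")
    if Xraw.shape[0] != codes.size:
        raise ValueError("X and y length mismatch")
    _check_design(Xraw, names)

    # standardise for Newton stability; parameters mapped back afterwards
    p = Xraw.shape[1]
    if p:
        mu = Xraw.mean(axis=0)
        sd = Xraw.std(axis=0)
        Xs = (Xraw - mu) / sd
    else:
        mu = sd = np.empty(0)
        Xs = Xraw

    # start at the closed-form intercept-only solution
    cum = np.cumsum(counts)[:2] / codes.size
    theta = np.concatenate([np.log(cum / (1 - cum)), np.zeros(p)])

    ll, grad, H = _loglik_parts(theta, Xs, codes)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(H) @ grad
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            ll_new, g_new, H_new = _loglik_parts(cand, Xs, codes)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            break
        theta, ll, grad, H = cand, ll_new, g_new, H_new
        if p and np.max(np.abs(theta[2:])) > 30:
            worst = names[int(np.argmax(np.abs(theta[2:])))]
            raise ConvergenceError(
                f"diverging coefficient for predictor {worst!r}: "
                "possible complete separation"
            )
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged and np.max(np.abs(grad)) >= tol:
        worst = names[int(np.argmax(np.abs(theta[2:])))] if p else "intercepts"
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (gradient norm "
            f"{np.max(np.abs(grad)):.2e}); check predictor {worst!r} for separation"
        )

    cov_s = np.linalg.inv(-H)

    # back-transform: alpha = alpha_s - sum beta_s * mu / sd, beta = beta_s / sd
    if p:
        T = np.zeros((2 + p, 2 + p))
        T[0, 0] = T[1, 1] = 1.0
        T[0, 2:] = T[1, 2:] = -mu / sd
        T[2:, 2:] = np.diag(1.0 / sd)
        theta_o = T @ theta
        cov_o = T @ cov_s @ T.T
    else:
        theta_o = theta
        cov_o = cov_s

    param_names = ["alpha_nonfrail", "alpha_prefrail", *names]
    k = 2 + p
    return OrdinalModelFit(
        category_order=CATEGORY_ORDER,
        intercepts=theta_o[:2].copy(),
        coef=pd.Series(theta_o[2:], index=names, dtype=float),
        cov=pd.DataFrame(cov_o, index=param_names, columns=param_names),
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n_obs=int(codes.size),
        n_iter=n_iter,
        converged=converged,
    )


def linear_predictor(coef: pd.Series, x) -> float | np.ndarray:
    """x' beta for a mapping / Series (scalar) or DataFrame (vector)."""
    if isinstance(x, pd.DataFrame):
        missing = [c for c in coef.index if c not in x.columns]
        if missing:
            raise ValueError(f"missing predictor(s): {missing}")
        vals = x[list(coef.index)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite predictor values")
        return vals @ coef.to_numpy()
    eta = 0.0
    for name, b in coef.items():
        if name not in x:
            raise ValueError(f"missing predictor {name!r}")
        v = float(x[name])
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for predictor {name!r}")
        eta += b * v
    return eta


def predict_probabilities(fit_or_coef, x, intercepts=None):
    """Category probabilities under the proportional-odds model.

    ``fit_or_coef`` is an :class:`OrdinalModelFit`, or a named coefficient
    Series/mapping with ``intercepts`` = (alpha_nonfrail, alpha_prefrail)
    given separately (e.g. the published index coefficients).  ``x`` is a
    mapping of predictor values (returns :class:`FrailtyProbabilities`) or a
    DataFrame (returns a DataFrame with columns p_nonfrail/p_prefrail/p_frail).
    """
    if isinstance(fit_or_coef, OrdinalModelFit):
        coef = fit_or_coef.coef
        a1, a2 = fit_or_coef.intercepts
    else:
        coef = pd.Series(dict(fit_or_coef), dtype=float)
        if intercepts is None:
            raise ValueError("intercepts required when passing bare coefficients")
        a1, a2 = intercepts
    eta = linear_predictor(coef, x)
    c1 = expit(a1 + eta)
    c2 = expit(a2 + eta)
    if np.ndim(eta) == 0:
        return FrailtyProbabilities(
            p_nonfrail=float(c1), p_prefrail=float(c2 - c1), p_frail=float(1.0 - c2)
        )
    return pd.DataFrame(
        {"p_nonfrail": c1, "p_prefrail": c2 - c1, "p_frail": 1.0 - c2},
        index=x.index,
    )


def classify(p) -> str | np.ndarray:
    """Arg-max category; exact ties break toward the more frail category."""
    if isinstance(p, FrailtyProbabilities):
        arr = p.as_array()[None, :]
        scalar = True
    elif isinstance(p, pd.DataFrame):
        arr = p[["p_nonfrail", "p_prefrail", "p_frail"]].to_numpy()
        scalar = False
    else:
        arr = np.atleast_2d(np.asarray(p, dtype=float))
        scalar = arr.shape[0] == 1 and np.ndim(p) == 1
    # argmax on the reversed axis picks the frailest category among ties
    idx = 2 - np.argmax(arr[:, ::-1], axis=1)
    labels = np.array(CATEGORY_ORDER, dtype=object)[idx]
    return str(labels[0]) if scalar else labels


def wald_tests(fit: OrdinalModelFit, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter Wald chi-square tests and confidence intervals.

    chi2 = (beta / se)^2 against chi-square with 1 df; CI = beta +/- z * se.
    Parameters with non-positive estimated variance are flagged (NaN output).
    """
    names = fit.param_names
    est = np.concatenate([fit.intercepts, fit.coef.to_numpy()])
    var = np.diag(fit.cov.to_numpy()).copy()
    bad = var <= 0
    se = np.where(bad, np.nan, np.sqrt(np.where(bad, np.nan, var)))
    chi2 = (est / se) ** 2
    pval = stats.chi2.sf(chi2, df=1)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "chi2": chi2,
            "p_value": pval,
            "ci_lower": est - z * se,
            "ci_upper": est + z * se,
            "degenerate": bad,
        },
        index=names,
    )
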