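"""Count-regression analysis of simulation experiments.

Lethal-acute-toxicosis counts from replicated runs are overdispersed, so
the primary model is a negative-binomial GLM with a log link,
``log E[deaths] = b0 + b1*HCF + b2*SD (+ b3*HCF*SD)``, compared against a
Poisson GLM via corrected AIC.  Candidate mechanism variables (intake
statistics) are screened with single-factor NB models ranked by AICc, and
the link between the factors and each mechanism is quantified with
ordinary least squares.

Conventions (documented so cross-software comparisons are diagnosable):

* AIC counts the NB dispersion parameter as estimated (as R's ``MASS``
  does), and the Gaussian error variance likewise.
* Standardized betas z-score predictors with the population SD; for
  Gaussian models the response is z-scored too, for count models the
  coefficients are returned per predictor-SD on the log scale.  Influence
  ratios |beta_a / beta_b| are invariant to either convention.
* Quantiles use linear interpolation (numpy default, R type 7).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, GraztoxError

__all__ = [
    "GLMFit",
    "FitError",
    "fit_count_glm",
    "aicc",
    "percent_change",
    "standardized_betas",
    "StandardizedBetas",
    "fit_mechanism_ols",
    "single_factor_scan",
]

FAMILIES = ("negative_binomial", "poisson", "gaussian")


class FitError(GraztoxError, RuntimeError):
    """Raised when a model fit fails to converge or is ill-posed."""


@dataclass(frozen=True)
class GLMFit:
    """Record of one fitted model."""

    family: str
    link: str
    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    llf: float
    aic: float
    deviance: float
    df_resid: int
    n: int
    k: int  # estimated parameters, incl. dispersion / error variance
    theta: float | None = None  # NB size parameter (1/alpha)
    adj_r2: float | None = None
    std_betas: dict[str, float] | None = None

    @property
    def aicc(self) -> float:
        return aicc(self)


def _design(
    table: pd.DataFrame, terms: list[str], interaction: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    for t in terms:
        cols.append(table[t].to_numpy(dtype=float))
        names.append(t)
    if interaction:
        for a, b in itertools.combinations(terms, 2):
            cols.append(
                table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float)
            )
            names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    bad = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j])
    raise FitError(f"rank-deficient design; collinear terms: {bad}")


def fit_count_glm(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    family: str = "negative_binomial",
    interaction: bool = False,
) -> GLMFit:
    """Maximum-likelihood count GLM with a log link.

    ``negative_binomial`` estimates the dispersion by ML (NB2) and counts
    it in ``k``; ``poisson`` is the equidispersed comparison model.
    """
    if family not in ("negative_binomial", "poisson"):
        raise ConfigurationError(f"family must be one of {FAMILIES[:2]}")
    y = table[response].to_numpy(dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ConfigurationError(f"response {response!r} must be nonnegative integers")
    X, names = _design(table, terms, interaction)
    _check_rank(X, names)
    n = len(y)
    if family == "negative_binomial":
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=500, disp=0)
            if not res.mle_retvals.get("converged", False):
                res = model.fit(method="nm", maxiter=5000, disp=0)
        if not res.mle_retvals.get("converged", False):
            raise FitError(
                f"negative binomial fit did not converge: {res.mle_retvals}"
            )
        alpha = float(res.params[-1])
        theta = 1.0 / alpha if alpha > 1e-12 else float("inf")
        coefs = res.params[:-1]
        bse = res.bse[:-1]
        pvals = res.pvalues[:-1]
        llf = float(res.llf)
        k = len(names) + 1
        # deviance from the GLM parameterization at the ML dispersion
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-10))
            ).fit(start_params=coefs, maxiter=100)
        deviance = float(glm.deviance)
    else:
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        theta = None
        coefs = glm.params
        bse = glm.bse
        pvals = glm.pvalues
        llf = float(glm.llf)
        k = len(names)
        deviance = float(glm.deviance)
    return GLMFit(
        family=family,
        link="log",
        terms=tuple(names[1:]),
        params=dict(zip(names, map(float, coefs))),
        bse=dict(zip(names, map(float, bse))),
        pvalues=dict(zip(names, map(float, pvals))),
        llf=llf,
        aic=2 * k - 2 * llf,
        deviance=deviance,
        df_resid=n - len(names),
        n=n,
        k=k,
        theta=theta,
    )


def aicc(fit: GLMFit | float, k: int | None = None, n: int | None = None) -> float:
    """Corrected AIC: ``AIC + 2k(k+1)/(n-k-1)``.

    Accepts either a :class:`GLMFit` or a plain AIC value with explicit
    ``k`` (estimated parameters, including dispersion) and ``n``.
    """
    if isinstance(fit, GLMFit):
        aic_val, k, n = fit.aic, fit.k, fit.n
    else:
        aic_val = float(fit)
        if k is None or n is None:
            raise ConfigurationError("plain-AIC form requires k and n")
    if n <= k + 1:
        raise ConfigurationError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic_val + 2.0 * k * (k + 1) / (n - k - 1)


def percent_change(coef: float) -> float:
    """Percent change in expected count per unit predictor, from a log-link
    coefficient.

    Returns ``100 * (1 - exp(coef))``: positive values are percent
    *decreases* (the reporting convention for risk reductions), negative
    values percent increases.
    """
    if not np.isfinite(coef):
        raise ConfigurationError("coefficient must be finite")
    return 100.0 * (1.0 - np.exp(coef))


@dataclass(frozen=True)
class StandardizedBetas:
    """Standardized main-effects coefficients and their influence ratios."""

    betas: dict[str, float]
    family: str

    def ratio(self, a: str, b: str) -> float:
        """Relative influence |beta_a / beta_b|."""
        return abs(self.betas[a] / self.betas[b])


def standardized_betas(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    family: str = "negative_binomial",
) -> StandardizedBetas:
    """Standardized coefficients from the main-effects-only model.

    Predictors are z-scored (population SD); for Gaussian fits the
    response is z-scored as well.  Interaction terms are deliberately
    excluded: betas compare the main-effect influence of the factors.
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"family must be one of {FAMILIES}")
    work = table.copy()
    for t in terms:
        x = work[t].to_numpy(dtype=float)
        sdx = x.std(ddof=0)
        if sdx == 0 or len(np.unique(x)) < 2:
            raise ConfigurationError(f"term {t!r} is constant")
        work[t] = (x - x.mean()) / sdx
    if family == "gaussian":
        yv = work[response].to_numpy(dtype=float)
        sdy = yv.std(ddof=0)
        if sdy == 0:
            raise ConfigurationError(f"response {response!r} is constant")
        yz = (yv - yv.mean()) / sdy
        X, names = _design(work, terms, interaction=False)
        _check_rank(X, names)
        params = dict(zip(names, map(float, sm.OLS(yz, X).fit().params)))
    else:
        fit = fit_count_glm(work, response, terms, family=family, interaction=False)
        params = fit.params
    return StandardizedBetas(
        betas={t: params[t] for t in terms}, family=family
    )


def fit_mechanism_ols(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    interaction: bool = False,
) -> GLMFit:
    """Ordinary least squares for factor -> mechanism relationships.

    Reports adjusted R^2, and standardized betas taken from the same
    model refit without the interaction.
    """
    y = table[response].to_numpy(dtype=float)
    X, names = _design(table, terms, interaction)
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    n = len(y)
    k = len(names) + 1  # + error variance
    betas = None
    if len(terms) >= 1:
        try:
            betas = standardized_betas(table, response, terms, family="gaussian").betas
        except ConfigurationError:
            betas = None
    return GLMFit(
        family="gaussian",
        link="identity",
        terms=tuple(names[1:]),
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        llf=float(res.llf),
        aic=2 * k - 2 * float(res.llf),
        deviance=float(res.ssr),
        df_resid=int(res.df_resid),
        n=n,
        k=k,
        adj_r2=float(res.rsquared_adj),
        std_betas=betas,
    )


def single_factor_scan(
    table: pd.DataFrame,
    response: str,
    mechanism_columns: list[str],
    family: str = "negative_binomial",
) -> pd.DataFrame:
    """Screen candidate mechanisms with single-factor count models.

    For each mechanism column: fit ``response ~ mechanism`` (NB, log
    link), report AICc and the slope, the sample quartiles Q1/Q3
    (linear-interpolation quantiles), and the observed percent change in
    mean response between the lower-quartile runs (mechanism <= Q1) and
    the upper-quartile-group runs (median < mechanism <= Q3).  Rows are
    sorted by ascending AICc, so the best-supported mechanism comes
    first.  Constant mechanism columns are skipped with a warning.
    """
    if len(table) < 8:
        raise ConfigurationError("single_factor_scan needs at least 8 rows")
    rows = []
    for col in mechanism_columns:
        x = table[col].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            warnings.warn(f"mechanism {col!r} is constant; skipped", stacklevel=2)
            continue
        fit = fit_count_glm(table, response, [col], family=family)
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        y = table[response].to_numpy(dtype=float)
        g1 = y[x <= q1]
        g3 = y[(x > med) & (x <= q3)]
        m1 = g1.mean() if len(g1) else np.nan
        m3 = g3.mean() if len(g3) else np.nan
        pct = 100.0 * (m3 - m1) / m1 if m1 not in (0.0,) and np.isfinite(m1) else np.nan
        rows.append(
            {
                "mechanism": col,
                "aicc": fit.aicc,
                "coefficient": fit.params[col],
                "q1": q1,
                "q3": q3,
                "pct_delta_response": pct,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("aicc", ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["mechanism", "aicc", "coefficient", "q1", "q3",
                     "pct_delta_response"]
        )
    )
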