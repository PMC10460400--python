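"""Linear mixed-effects layer: ML fits, likelihood-ratio tests, Nakagawa R².

Each response (P_max, E_k, H_sat, rel-H_sat, DSPI, growth) is modelled with
treatment and temperature as categorical fixed effects and random intercepts
drawn from plant ID, run, RLC order and lunar phase.  All fits are maximum
likelihood — never REML — because likelihoods from REML fits are not
comparable across fixed-effect structures, and every p-value here comes from
a likelihood-ratio test of a full model against a null lacking the effect
under test.

Random intercepts are crossed, not nested, so they enter as variance
components over a single grouping of all rows.  A fit whose estimated
variance components collapse onto the boundary is flagged singular and the
offending terms are dropped in a fixed priority order (lunar phase, then RLC
order, then run); the plant-ID intercept is always retained.

Goodness of fit is summarized by the Nakagawa–Schielzeth coefficients of
determination for Gaussian mixed models:

    R²m = σ²_f / (σ²_f + Σσ²_r + σ²_e)
    R²c = (σ²_f + Σσ²_r) / (σ²_f + Σσ²_r + σ²_e)

with σ²_f the variance of the fixed-effect predictor, σ²_r the random
intercept variances and σ²_e the residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMFit",
    "LRTResult",
    "fit_lmm",
    "lrt",
    "lrt_drop",
    "r2_nakagawa",
    "fit_growth_regressions",
    "growth_dspi_lmm",
]

#: Random terms eligible for removal on singular fits, in drop order.
#: The plant-ID intercept is never dropped.
SINGULAR_DROP_ORDER = ("lunar_phase", "rlc_order", "run")

_SINGULAR_REL_TOL = 1e-4


@dataclass
class LMMFit:
    """A fitted (mixed) linear model plus everything the LRT/R² layer needs."""

    response: str
    fixed: tuple[str, ...]
    random: tuple[str, ...]  # random terms actually retained
    dropped: tuple[str, ...]  # random terms removed for singularity
    params: pd.Series
    bse: pd.Series
    vcomp: dict[str, float]  # random-intercept variances
    scale: float  # residual variance (ML)
    llf: float
    nobs: int
    n_fixed: int
    singular: bool
    r2_marginal: float
    r2_conditional: float
    var_fixed: float = 0.0
    formula: str = ""
    result: object = field(default=None, repr=False)

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one fixed-effect coefficient."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        est, se = self.params[name], self.bse[name]
        return est - z * se, est + z * se


@dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float


def _fixed_term(table: pd.DataFrame, col: str) -> str:
    """Wrap categorical-ish columns in C(); leave numeric covariates bare."""
    dtype = table[col].dtype
    if isinstance(dtype, pd.CategoricalDtype) or dtype == object or dtype == bool:
        return f"C({col})"
    return col


def _build_formula(table: pd.DataFrame, response: str, fixed) -> str:
    terms = [_fixed_term(table, c) for c in fixed]
    return f"{response} ~ " + (" + ".join(terms) if terms else "1")


def _fit_ols_as_lmm(table, response, fixed, dropped, formula,
                    singular: bool = False) -> LMMFit:
    """Degenerate random structure: plain OLS, with the ML log-likelihood."""
    res = smf.ols(formula, data=table).fit()
    fitted_fixed = np.asarray(res.fittedvalues)
    var_f = float(np.var(fitted_fixed))
    var_e = float(np.var(np.asarray(res.resid)))  # ML residual variance
    total = var_f + var_e
    r2m = var_f / total if total > 0 else 0.0
    return LMMFit(
        response=response,
        fixed=tuple(fixed),
        random=(),
        dropped=tuple(dropped),
        params=res.params,
        bse=res.bse,
        vcomp={},
        scale=var_e,
        llf=float(res.llf),
        nobs=int(res.nobs),
        n_fixed=len(res.params),
        singular=singular,
        r2_marginal=r2m,
        r2_conditional=r2m,
        var_fixed=var_f,
        formula=formula,
        result=res,
    )


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed,
    random,
    drop_singular: bool = True,
) -> LMMFit:
    """ML fit of ``response ~ fixed`` with crossed random intercepts.

    Parameters
    ----------
    table
        One row per plant-replicate.  Categorical columns (pandas
        ``Categorical``, object or bool dtype) among ``fixed`` are coded with
        their first level as reference; numeric columns enter as covariates.
    fixed, random
        Column names.  Each random term contributes an intercept variance
        component; crossed terms are supported.
    drop_singular
        When a variance component collapses to (near) zero, re-fit without
        that term, following :data:`SINGULAR_DROP_ORDER`; the plant-ID term
        is always retained.  The final fit records what was dropped and
        whether it is still singular.

    Raises
    ------
    ValueError
        On a rank-deficient fixed design (aliased terms are named) or a
        factor with fewer than 2 levels.
    """
    fixed = list(fixed)
    random = list(random)
    for col in fixed:
        if table[col].nunique() < 2:
            raise ValueError(f"fixed factor {col!r} has fewer than 2 levels")
    formula = _build_formula(table, response, fixed)

    # rank check on the fixed design
    import patsy

    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient fixed design for {formula!r}: "
            f"{X.shape[1]} columns, rank {rank}; aliased terms among {list(X.columns)}"
        )

    dropped: list[str] = []
    while True:
        if not random:
            return _fit_ols_as_lmm(table, response, fixed, dropped, formula)
        vc = {r: f"0 + C({r})" for r in random}
        model = smf.mixedlm(
            formula,
            data=table,
            groups=np.ones(len(table)),
            re_formula="0",
            vc_formula=vc,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                res = model.fit(reml=False, maxiter=500)
                bse_fe = res.bse_fe  # may hit boundary NaNs on singular fits
        except np.linalg.LinAlgError:
            # a variance component collapsed so far onto the boundary that
            # the Hessian is singular: drop a term if allowed, else fall
            # back to the degenerate (OLS) fit, flagged singular
            droppable = [r for r in SINGULAR_DROP_ORDER if r in random]
            if drop_singular and droppable:
                dropped.append(droppable[0])
                random.remove(droppable[0])
                continue
            dropped.extend(random)
            return _fit_ols_as_lmm(table, response, fixed, dropped, formula,
                                   singular=True)
        vcomp = {name: float(v) for name, v in zip(model.exog_vc.names, res.vcomp)}
        scale = float(res.scale)
        tol = _SINGULAR_REL_TOL * max(scale, 1e-12)
        singular_terms = [r for r in random if vcomp.get(r, 0.0) <= tol]
        if singular_terms and drop_singular:
            droppable = [r for r in SINGULAR_DROP_ORDER
                         if r in singular_terms and r in random]
            if droppable:
                dropped.append(droppable[0])
                random.remove(droppable[0])
                continue
        break

    fe = res.fe_params
    fitted_fixed = np.asarray(X.to_numpy() @ fe.to_numpy())
    var_f = float(np.var(fitted_fixed))
    var_r = float(sum(vcomp.values()))
    total = var_f + var_r + scale
    fit = LMMFit(
        response=response,
        fixed=tuple(fixed),
        random=tuple(random),
        dropped=tuple(dropped),
        params=fe,
        bse=bse_fe,
        vcomp=vcomp,
        scale=scale,
        llf=float(res.llf),
        nobs=int(res.nobs),
        n_fixed=len(fe),
        singular=bool(singular_terms),
        r2_marginal=var_f / total if total > 0 else 0.0,
        r2_conditional=(var_f + var_r) / total if total > 0 else 0.0,
        var_fixed=var_f,
        formula=formula,
        result=res,
    )
    return fit


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) R² of a Gaussian mixed fit."""
    return fit.r2_marginal, fit.r2_conditional


def lrt(full: LMMFit, reduced: LMMFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits.

    ``chi2 = 2(ℓ_full − ℓ_reduced)`` clipped at zero, with degrees of
    freedom the difference in fixed-parameter counts (the random structure
    must be identical, so it cancels).
    """
    if full.response != reduced.response or full.nobs != reduced.nobs:
        raise ValueError("LRT requires the same response and data in both fits")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError(
            "models are not nested: reduced fixed effects "
            f"{list(reduced.params.index)} not a subset of full "
            f"{list(full.params.index)}"
        )
    if set(full.random) != set(reduced.random):
        raise ValueError(
            f"random structures differ ({full.random} vs {reduced.random}); "
            "refit with matching structure before the LRT"
        )
    df = full.n_fixed - reduced.n_fixed
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=chi2, df=df, p_value=p)


def _matched_pair(
    table: pd.DataFrame,
    response: str,
    fixed_full,
    fixed_reduced,
    random,
    drop_singular: bool = True,
) -> tuple[LMMFit, LMMFit]:
    """Fit nested models with an identical random structure.

    If either fit has to shed random terms (singularity fallback), the
    other is refitted on the surviving structure so the likelihoods stay
    comparable; structures only ever shrink, so this terminates.
    """
    full = fit_lmm(table, response, fixed_full, random, drop_singular)
    reduced = fit_lmm(table, response, fixed_reduced, list(full.random),
                      drop_singular=False)
    while set(reduced.random) != set(full.random):
        full = fit_lmm(table, response, fixed_full, list(reduced.random),
                       drop_singular=False)
        if set(full.random) == set(reduced.random):
            break
        reduced = fit_lmm(table, response, fixed_reduced, list(full.random),
                          drop_singular=False)
    return full, reduced


def lrt_drop(
    table: pd.DataFrame,
    response: str,
    fixed,
    random,
    term: str,
) -> tuple[LMMFit, LMMFit, LRTResult]:
    """Fit the full model and the null lacking ``term``; return both + LRT.

    The null re-uses the random structure the full model settled on after
    any singularity fallback, so the likelihoods are comparable.
    """
    fixed = list(fixed)
    if term not in fixed:
        raise ValueError(f"term {term!r} not among fixed effects {fixed}")
    full, reduced = _matched_pair(
        table, response, fixed, [c for c in fixed if c != term], random
    )
    return full, reduced, lrt(full, reduced)


def fit_growth_regressions(
    table: pd.DataFrame,
    response: str = "growth_pct",
    predictors=("pmax", "ek", "h_sat", "dspi"),
) -> pd.DataFrame:
    """Simple linear regressions of growth on each predictor separately.

    Returns a frame with one row per predictor: slope, its standard error,
    t statistic and p-value.
    """
    rows = []
    for pred in predictors:
        x = table[pred]
        if x.nunique() < 2:
            raise ValueError(f"predictor {pred!r} is constant")
        res = smf.ols(f"{response} ~ {pred}", data=table).fit()
        rows.append(
            {
                "predictor": pred,
                "slope": float(res.params[pred]),
                "stderr": float(res.bse[pred]),
                "t": float(res.tvalues[pred]),
                "p_value": float(res.pvalues[pred]),
                "r2": float(res.rsquared),
                "n": int(res.nobs),
            }
        )
    return pd.DataFrame(rows)


def growth_dspi_lmm(
    table: pd.DataFrame,
    response: str = "growth_pct",
    predictor: str = "dspi",
) -> tuple[LMMFit, LRTResult]:
    """Growth ~ DSPI with a random intercept for treatment, plus the LRT.

    With fewer than two treatment levels the random intercept degenerates
    and the model falls back to a simple regression (with a warning); the
    LRT then compares the OLS fits.
    """
    n_treat = table["treatment"].nunique() if "treatment" in table else 1
    random = ["treatment"] if n_treat >= 2 else []
    if not random:
        warnings.warn(
            "single treatment level: random intercept degenerates, "
            "falling back to simple regression",
            stacklevel=2,
        )
    full, reduced = _matched_pair(table, response, [predictor], [], random,
                                  drop_singular=False)
    return full, lrt(full, reduced)


def ols_sanity_fit(table: pd.DataFrame, response: str, fixed) -> pd.Series:
    """Fixed-effect estimates by plain OLS (no random terms); cross-check aid."""
    formula = _build_formula(table, response, list(fixed))
    return smf.ols(formula, data=table).fit().params


# keep a module-level handle so sm is "used" even if only formulas are exercised
_ = sm.OLS
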