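"""Genotypic and phenotypic trait correlations plus yield regression.

The genotypic / phenotypic correlation duality comes from the analysis of
covariance: for each trait pair the RCBD cross-product decomposition yields
genotype and error mean cross-products (MCPG, MCPE) exactly parallel to the
mean squares, from which

    cov_g = (MCPG - MCPE) / r,   cov_e = MCPE,   cov_p = cov_g + cov_e

and the correlations r_g = cov_g / sqrt(s2g_x * s2g_y), r_p = cov_p /
sqrt(s2p_x * s2p_y). r_g is undefined when either trait's genotypic
variance is truncated to zero, and moment estimates can stray outside
[-1, 1]; both situations are flagged rather than hidden.

Multiple and stepwise ordinary-least-squares regression of grain yield on
the remaining traits runs on the genotype means within one location (one
observation per genotype), with a bidirectional p-value stepwise search and
squared semi-partial correlations as per-trait "contribution" statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .rcbd_anova import SignificanceMark, significance_mark
from .trial_data import TrialDataset
from .genetic_variability import variance_components
from .rcbd_anova import anova_rcbd, _balanced_matrix

__all__ = [
    "CovarianceComponents",
    "CorrelationMatrixPair",
    "RegressionFit",
    "cross_product_components",
    "correlation_matrices",
    "correlation_significance",
    "fit_multiple_regression",
    "stepwise_select",
]


@dataclass(frozen=True)
class CovarianceComponents:
    """Genotypic / error / phenotypic covariance components of a trait pair."""

    trait_x: str
    trait_y: str
    cov_g: float
    cov_e: float
    cov_p: float
    r: int


def cross_product_components(
    ds: TrialDataset, x: str, y: str, location: str
) -> CovarianceComponents:
    """ANCOVA cross-product components for a trait pair at one location.

    The genotype and error sums of cross-products mirror the RCBD sums of
    squares with products replacing squares:

        SCP_gen = r * sum_i (x_i. - x..)(y_i. - y..)
        SCP_err = sum_ij (x_ij - x_i. - x_.j + x..)(y_ij - y_i. - y_.j + y..)

    divided by the genotype and error degrees of freedom to give MCPG and
    MCPE; cov_g = (MCPG - MCPE) / r, cov_e = MCPE.
    """
    ds.require_trait(x)
    ds.require_trait(y)
    sub = ds.subset_location(location)
    xm = _balanced_matrix(sub, x, location)
    ym = _balanced_matrix(sub, y, location)
    g, r = xm.shape
    if r < 2:
        raise ValueError("at least 2 replicates required")

    def _resid(m):
        return m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()

    scp_gen = float(r * ((xm.mean(axis=1) - xm.mean()) * (ym.mean(axis=1) - ym.mean())).sum())
    scp_err = float((_resid(xm) * _resid(ym)).sum())
    mcpg = scp_gen / (g - 1)
    mcpe = scp_err / ((g - 1) * (r - 1))
    cov_g = (mcpg - mcpe) / r
    return CovarianceComponents(
        trait_x=x, trait_y=y, cov_g=cov_g, cov_e=mcpe, cov_p=cov_g + mcpe, r=r
    )


def correlation_significance(r: float, n_genotypes: int, alpha_pairs=(0.05, 0.01)) -> SignificanceMark:
    """Two-sided test of a correlation via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n_genotypes < 3:
        raise ValueError("need at least 3 genotypes")
    if not np.isfinite(r):
        return SignificanceMark(p=np.nan, mark="ns")
    r = float(np.clip(r, -1.0, 1.0))
    df = n_genotypes - 2
    if abs(r) >= 1.0:
        return SignificanceMark(p=0.0, mark="**")
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return significance_mark(p)


@dataclass
class CorrelationMatrixPair:
    """Genotypic (rg) and phenotypic (rp) correlation matrices.

    Cells of rg are NaN where either trait's genotypic variance is zero
    (``undefined`` marks them True); moment estimates outside [-1, 1] are
    clamped and recorded in ``clamped``. ``rg_marks`` / ``rp_marks`` hold
    the significance stars (rg uses the same critical-r convention as rp,
    an approximation since genotypic correlations have no exact small-
    sample test in this framework).
    """

    traits: list[str]
    rg: pd.DataFrame
    rp: pd.DataFrame
    rg_marks: pd.DataFrame
    rp_marks: pd.DataFrame
    undefined: pd.DataFrame
    clamped: pd.DataFrame


def correlation_matrices(
    ds: TrialDataset, location: str, traits: list[str] | None = None
) -> CorrelationMatrixPair:
    """rg / rp matrices over all trait pairs at one location."""
    traits = traits or ds.trait_names
    n_gen = len(ds.subset_location(location)["genotype"].unique())
    if n_gen < 3:
        raise ValueError("need at least 3 genotypes")

    comps: dict[tuple[str, str], CovarianceComponents] = {}
    var_g, var_p = {}, {}
    for t in traits:
        vc = variance_components(anova_rcbd(ds, t, location))
        var_g[t], var_p[t] = vc.sigma2_g, vc.sigma2_p
    for i, x in enumerate(traits):
        for y in traits[i + 1:]:
            comps[(x, y)] = cross_product_components(ds, x, y, location)

    k = len(traits)
    rg = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    rp = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    undefined = pd.DataFrame(False, index=traits, columns=traits)
    clamped = pd.DataFrame(False, index=traits, columns=traits)
    for t in traits:
        if var_g[t] <= 0:
            undefined.loc[t, t] = True
            rg.loc[t, t] = np.nan

    for (x, y), c in comps.items():
        if var_g[x] > 0 and var_g[y] > 0:
            val = c.cov_g / np.sqrt(var_g[x] * var_g[y])
            if abs(val) > 1:
                val = float(np.clip(val, -1, 1))
                clamped.loc[x, y] = clamped.loc[y, x] = True
            rg.loc[x, y] = rg.loc[y, x] = val
        else:
            rg.loc[x, y] = rg.loc[y, x] = np.nan
            undefined.loc[x, y] = undefined.loc[y, x] = True
        if var_p[x] > 0 and var_p[y] > 0:
            valp = c.cov_p / np.sqrt(var_p[x] * var_p[y])
            if abs(valp) > 1:
                valp = float(np.clip(valp, -1, 1))
                clamped.loc[x, y] = clamped.loc[y, x] = True
            rp.loc[x, y] = rp.loc[y, x] = valp
        else:
            rp.loc[x, y] = rp.loc[y, x] = np.nan
            undefined.loc[x, y] = undefined.loc[y, x] = True

    def marks(mat):
        out = pd.DataFrame("", index=traits, columns=traits)
        for i, x in enumerate(traits):
            for y in traits[i + 1:]:
                v = mat.loc[x, y]
                m = "-" if not np.isfinite(v) else correlation_significance(v, n_gen).mark
                out.loc[x, y] = out.loc[y, x] = m
        return out

    return CorrelationMatrixPair(
        traits=list(traits), rg=rg, rp=rp,
        rg_marks=marks(rg), rp_marks=marks(rp),
        undefined=undefined, clamped=clamped,
    )


@dataclass
class RegressionFit:
    """OLS fit of a response trait on predictor traits (genotype means)."""

    response: str
    predictors: list[str]
    coefficients: pd.Series      # includes "Intercept"
    r2: float
    adj_r2: float
    p_values: pd.Series
    selected: dict[str, bool] = field(default_factory=dict)
    contributions: pd.Series | None = None   # squared semi-partial correlations


def _genotype_mean_table(ds: TrialDataset, location: str, traits: list[str]) -> pd.DataFrame:
    sub = ds.subset_location(location)
    tab = sub.groupby("genotype", sort=False)[traits].mean()
    return tab


def fit_multiple_regression(
    means: pd.DataFrame, response: str, predictors: list[str]
) -> RegressionFit:
    """Ordinary least squares of ``response`` on ``predictors``.

    ``means`` holds one row per genotype (location-wise genotype means).
    Raises on rank deficiency (collinear predictor sets).
    """
    if len(means) < len(predictors) + 2:
        raise ValueError("need at least p + 2 genotypes")
    X = sm.add_constant(means[predictors].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    y = means[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    names = ["Intercept", *predictors]
    return RegressionFit(
        response=response,
        predictors=list(predictors),
        coefficients=pd.Series(fit.params, index=names),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        p_values=pd.Series(fit.pvalues, index=names),
        selected={p: True for p in predictors},
    )


def stepwise_select(
    means: pd.DataFrame,
    response: str,
    predictors: list[str],
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    criterion: str = "pvalue",
) -> RegressionFit:
    """Bidirectional stepwise OLS from the empty model.

    At each step the candidate with the smallest entry p-value below
    ``alpha_enter`` joins the model (ties broken by the given predictor
    order); any included predictor whose p-value rises above
    ``alpha_remove`` is dropped before the next entry scan. With
    ``criterion="aic"`` the step decisions minimise AIC instead. The final
    fit carries per-predictor contributions — squared semi-partial
    correlations with respect to the final model — as the conventional
    trait-contribution statistic.
    """
    if criterion not in ("pvalue", "aic"):
        raise ValueError("criterion must be 'pvalue' or 'aic'")
    y = means[response].to_numpy(dtype=float)

    def ols(sel):
        X = sm.add_constant(means[sel].to_numpy(dtype=float) if sel
                            else np.empty((len(means), 0)), has_constant="add")
        return sm.OLS(y, X).fit()

    selected: list[str] = []
    seen: set[frozenset] = set()
    while True:
        state = frozenset(selected)
        if state in seen:  # cycle guard (degenerate fits can oscillate)
            break
        seen.add(state)
        changed = False
        # forward step
        remaining = [p for p in predictors if p not in selected]
        best_p, best_cand, best_aic = np.inf, None, np.inf
        for cand in remaining:
            trial = selected + [cand]
            X = sm.add_constant(means[trial].to_numpy(dtype=float), has_constant="add")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            fit = sm.OLS(y, X).fit()
            pv = fit.pvalues[-1]
            if criterion == "pvalue":
                if pv < best_p - 1e-12:
                    best_p, best_cand = pv, cand
            else:
                if fit.aic < best_aic - 1e-9:
                    best_aic, best_cand, best_p = fit.aic, cand, pv
        if best_cand is not None:
            current = ols(selected)
            accept = (best_p <= alpha_enter) if criterion == "pvalue" else (
                best_aic < current.aic - 1e-9
            )
            if accept:
                selected.append(best_cand)
                changed = True
        # backward step
        if selected:
            fit = ols(selected)
            pvals = pd.Series(fit.pvalues[1:], index=selected)
            if criterion == "pvalue":
                worst = pvals.idxmax()
                if pvals[worst] > alpha_remove:
                    selected.remove(worst)
                    changed = True
            else:
                base_aic = fit.aic
                for cand in list(selected):
                    trial = [p for p in selected if p != cand]
                    if ols(trial).aic < base_aic - 1e-9:
                        selected.remove(cand)
                        changed = True
                        break
        if not changed:
            break

    fit = ols(selected)
    names = ["Intercept", *selected]
    full_r2 = float(fit.rsquared)
    contrib = {}
    for p in selected:
        reduced = [q for q in selected if q != p]
        contrib[p] = full_r2 - float(ols(reduced).rsquared)
    contrib_s = pd.Series(contrib).sort_values(ascending=False) if contrib else pd.Series(dtype=float)
    return RegressionFit(
        response=response,
        predictors=list(predictors),
        coefficients=pd.Series(fit.params, index=names),
        r2=full_r2,
        adj_r2=float(fit.rsquared_adj),
        p_values=pd.Series(fit.pvalues, index=names),
        selected={p: (p in selected) for p in predictors},
        contributions=contrib_s,
    )


def regression_report(
    ds: TrialDataset,
    location: str,
    response: str = "GY",
    predictors: list[str] | None = None,
    stepwise: bool = False,
    **kwargs,
) -> RegressionFit:
    """Regression of a response trait on the others, on genotype means."""
    predictors = predictors or [t for t in ds.trait_names if t != response]
    means = _genotype_mean_table(ds, location, [response, *predictors])
    if stepwise:
        return stepwise_select(means, response, predictors, **kwargs)
    return fit_multiple_regression(means, response, predictors)
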