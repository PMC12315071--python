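"""Mixed-effects linear models for tile-level responses.

Implements the study's modelling template: a tile-level response regressed
on z-scored heterogeneity, z-scored emersion ratio and their interaction,
with random intercepts for transect and for station nested within transect.
Fixed-effect p values use Satterthwaite denominator degrees of freedom;
marginal and conditional R-squared follow Nakagawa & Schielzeth's variance
partition.

The formula interface is deliberately small: terms are column names,
``C(col)`` for categoricals (treatment-coded against the first sorted
level) and ``a:b`` for products.  Numeric predictors are z-transformed
before interactions are formed, so interaction columns are products of
z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import MixedFit, fit_mixed

logger = logging.getLogger(__name__)

TRANSFORMS = {
    "identity": lambda v: v,
    "log": lambda v: np.log(v),
    "log1p": lambda v: np.log1p(v),
    "sqrt": lambda v: np.sqrt(v),
}


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sample (n-1) SD 1. Rejects constant input."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("zscore expects a 1-d array")
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (v - v.mean()) / sd


def transform_response(values, policy: str = "identity"):
    """Apply a named response transform; returns (values, label).

    ``log`` requires strictly positive input; use ``log1p`` for covers that
    include zeros (the +1 offset is recorded in the returned label).
    """
    if policy not in TRANSFORMS:
        raise ValueError(f"unknown transform policy {policy!r}")
    v = np.asarray(values, dtype=float)
    if policy == "log" and np.any(v <= 0):
        raise ValueError("log transform requires strictly positive values; use log1p")
    if policy == "sqrt" and np.any(v < 0):
        raise ValueError("sqrt transform requires nonnegative values")
    return TRANSFORMS[policy](v), policy


def build_design(
    data: pd.DataFrame,
    terms: list[str],
    zscore_numeric: bool = True,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build an intercept-plus-terms design matrix.

    Returns (X, column names, term -> column indices map).
    """

    def base_columns(token: str) -> dict[str, np.ndarray]:
        if token.startswith("C(") and token.endswith(")"):
            col = token[2:-1]
            if col not in data:
                raise KeyError(f"unknown column {col!r}")
            levels = sorted(pd.unique(data[col].astype(str)))
            return {
                f"{token}[{lev}]": (data[col].astype(str) == lev).to_numpy(float)
                for lev in levels[1:]
            }
        if token not in data:
            raise KeyError(f"unknown column {token!r}")
        v = data[token].to_numpy(float)
        if zscore_numeric and len(np.unique(v)) > 1:
            v = zscore(v)
        return {token: v}

    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["Intercept"]
    term_map: dict[str, list[int]] = {}
    for term in terms:
        parts = term.split(":")
        factors = [base_columns(p) for p in parts]
        combos = [("", np.ones(len(data)))]
        for fac in factors:
            combos = [
                (f"{nm}:{sub}" if nm else sub, v * w)
                for nm, v in combos
                for sub, w in fac.items()
            ]
        idx = []
        for nm, v in combos:
            idx.append(len(names))
            names.append(nm)
            cols.append(v)
        term_map[term] = idx
    return np.column_stack(cols), names, term_map


@dataclass
class LmmFit:
    """Tidy summary of one mixed-model fit plus its variance partition."""

    response: str
    transform: str
    fit: MixedFit
    terms: dict[str, list[int]]
    r2m: float
    r2c: float

    @property
    def table(self) -> pd.DataFrame:
        f = self.fit
        return pd.DataFrame(
            {
                "response": self.response,
                "term": f.names,
                "estimate": f.beta,
                "se": f.se,
                "t": f.tvalues,
                "df": f.df,
                "p": f.pvalues,
                "r2m": self.r2m,
                "r2c": self.r2c,
                "transform": self.transform,
                "singular": f.singular,
                "converged": f.converged,
                "df_method": f.df_method,
            }
        )


def nakagawa_r2(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional R-squared from the fitted variance partition."""
    var_fixed = float(np.var(fit.fittedvalues))
    var_rand = fit.vc_transect + fit.vc_station
    total = var_fixed + var_rand + fit.sigma2
    if total <= 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_rand) / total


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: list[str] | None = None,
    nesting: tuple[str, str] | None = ("transect_id", "station_id"),
    transform: str = "identity",
    df_method: str = "satterthwaite",
    zscore_predictors: bool = True,
) -> LmmFit:
    """Fit ``response ~ fixed`` with the study's nested random intercepts.

    ``fixed`` defaults to heterogeneity, emersion and their interaction.
    With ``nesting=None`` the model is ordinary least squares.
    """
    if fixed is None:
        fixed = ["heterogeneity", "emersion_ratio", "heterogeneity:emersion_ratio"]
    if response not in data:
        raise KeyError(f"unknown response {response!r}")
    y, label = transform_response(data[response].to_numpy(float), transform)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite values in response {response!r} after transform")
    X, names, term_map = build_design(data, fixed, zscore_numeric=zscore_predictors)
    if nesting is None:
        fit = fit_mixed(y, X, None, None, names)
    else:
        tcol, scol = nesting
        if data[tcol].nunique() < 2:
            raise ValueError("need at least two transects for the nested model")
        fit = fit_mixed(y, X, data[tcol], data[scol], names, df_method=df_method)
    r2m, r2c = nakagawa_r2(fit)
    return LmmFit(response=response, transform=label, fit=fit, terms=term_map, r2m=r2m, r2c=r2c)


def residual_diagnostics(fit: MixedFit) -> dict[str, float]:
    """Cheap numeric stand-ins for visual residual checks.

    Returns a QQ correlation (normality; ~1 is good) and the slope of
    sqrt(|resid|) on fitted values (scale-location; ~0 is good).
    """
    r = np.sort(fit.resid)
    n = len(r)
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_corr = float(np.corrcoef(r, q)[0, 1])
    f = fit.fittedvalues
    s = np.sqrt(np.abs(fit.resid))
    slope = float(np.polyfit(f, s, 1)[0]) if np.ptp(f) > 0 else 0.0
    return {"qq_corr": qq_corr, "scale_location_slope": slope}


def fit_response_suite(
    data: pd.DataFrame,
    responses: list[str],
    transforms: dict[str, str] | None = None,
    nesting: tuple[str, str] | None = ("transect_id", "station_id"),
) -> pd.DataFrame:
    """Fit the heterogeneity x emersion model to each response; tidy table."""
    transforms = transforms or {}
    rows = []
    for resp in responses:
        sub = data.dropna(subset=[resp])
        n_drop = len(data) - len(sub)
        if n_drop:
            logger.info("%s: dropped %d tiles with missing values", resp, n_drop)
        lf = fit_lmm(sub, resp, transform=transforms.get(resp, "identity"), nesting=nesting)
        tab = lf.table
        tab["n_obs"] = lf.fit.n_obs
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)
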