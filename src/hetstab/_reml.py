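"""Restricted maximum likelihood engine for the tile-design mixed model.

The whole analysis pipeline uses one model family: a Gaussian linear model
with random intercepts for transect and for station nested within transect,

    y = X beta + a[transect] + b[station] + e,
    a ~ N(0, v_T),  b ~ N(0, v_S),  e ~ N(0, s2),

fitted by REML with the two variance ratios profiled out.  Fixed-effect
inference uses t statistics with Satterthwaite-approximated denominator
degrees of freedom (the lmerTest convention); the approximation is computed
from numerical derivatives of the REML criterion and of Var(beta_j) with
respect to the variance parameters.  If it fails, residual degrees of
freedom are used and the fit is flagged.

When no grouping factors are supplied the engine reduces to ordinary least
squares with residual-df t tests, which is what the piecewise-SEM
"simplified" component models use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

_LOG_RATIO_BOUNDS = (-30.0, 10.0)
_SINGULAR_TOL = 1e-6  # variance ratio below this counts as a boundary fit


@dataclass
class MixedFit:
    """Result of one mixed-model (or OLS) fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray
    cov_beta: np.ndarray
    vc_transect: float
    vc_station: float
    sigma2: float
    loglik: float
    n_obs: int
    rank: int
    singular: bool
    converged: bool
    df_method: str
    mixed: bool
    # internals kept for Wald tests / downstream variance work
    _X: np.ndarray | None = field(default=None, repr=False)
    _resid: np.ndarray | None = field(default=None, repr=False)
    _fitted: np.ndarray | None = field(default=None, repr=False)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    @property
    def resid(self) -> np.ndarray:
        return self._resid

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._fitted

    def wald_f(self, indices: list[int]) -> tuple[float, float, float, float]:
        """Joint Wald F test that the given coefficients are all zero.

        Returns (F, df_num, df_den, p).  Denominator df is residual df,
        which is adequate for the balanced tile designs this engine serves.
        """
        idx = np.asarray(indices, dtype=int)
        b = self.beta[idx]
        C = self.cov_beta[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(C, b)) / q
        df_den = max(self.n_obs - self.rank, 1)
        p = float(stats.f.sf(F, q, df_den))
        return F, q, float(df_den), p


def _codes(labels) -> np.ndarray:
    _, inv = np.unique(np.asarray(labels), return_inverse=True)
    return inv


def fit_ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> MixedFit:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient fixed design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfr = n - p
    if dfr <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(resid @ resid) / dfr
    if s2 <= 1e-12 * max(1.0, float(y @ y) / n):
        raise ValueError("zero residual variance (constant or perfectly fitted response)")
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    df = np.full(p, float(dfr))
    pv = 2.0 * stats.t.sf(np.abs(t), dfr)
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + resid @ resid / s2)
    return MixedFit(
        names=list(names), beta=beta, se=se, tvalues=t, df=df, pvalues=pv,
        cov_beta=cov, vc_transect=0.0, vc_station=0.0, sigma2=s2,
        loglik=float(ll), n_obs=n, rank=p, singular=False, converged=True,
        df_method="residual", mixed=False, _X=X, _resid=resid, _fitted=X @ beta,
    )


class _RemlProblem:
    """REML criterion and derived quantities for one (y, X, grouping) triple.

    When stations all have equal size the two grouping Gram matrices
    commute (station blocks are nested in transect blocks), so both are
    diagonalised once by a shared orthogonal basis and every criterion
    evaluation is O(n p) instead of a fresh n x n Cholesky.  Designs with
    broken pairs fall back to the dense path transparently: the rotation
    is simply the identity and the "eigenvalues" are the full matrices.
    """

    def __init__(self, y, X, transect, station):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        tc = _codes(transect)
        sc = _codes(station)
        GT = (tc[:, None] == tc[None, :]).astype(float)
        GS = (sc[:, None] == sc[None, :]).astype(float)
        self._fast = bool(np.allclose(GT @ GS, GS @ GT))
        if self._fast:
            _, U = np.linalg.eigh(GT + np.pi * GS)
            self.lamT = np.maximum(np.einsum("ij,ik,kj->j", U, GT, U), 0.0)
            self.lamS = np.maximum(np.einsum("ij,ik,kj->j", U, GS, U), 0.0)
            self.Xr = U.T @ X
            self.yr = U.T @ y
        else:  # dense fallback
            self.GT, self.GS = GT, GS
            self.Xr, self.yr = X, y
        self.X, self.y = X, y

    def _weights(self, gT, gS):
        if self._fast:
            return 1.0 + gT * self.lamT + gS * self.lamS
        return np.eye(self.n) + gT * self.GT + gS * self.GS

    def _core(self, w):
        """(logdet, XtWiX, XtWiy, quad_fn) for weight vector or matrix w."""
        if self._fast:
            logdet = float(np.log(w).sum())
            Xw = self.Xr / w[:, None]
            XtWiX = self.Xr.T @ Xw
            XtWiy = Xw.T @ self.yr

            def quad(beta):
                r = self.yr - self.Xr @ beta
                return float((r * r / w).sum())

            return logdet, XtWiX, XtWiy, quad
        c = linalg.cho_factor(w, lower=True, check_finite=False)
        logdet = 2.0 * float(np.log(np.diag(c[0])).sum())
        WiX = linalg.cho_solve(c, self.Xr, check_finite=False)
        XtWiX = self.Xr.T @ WiX
        XtWiy = WiX.T @ self.yr

        def quad(beta):
            r = self.yr - self.Xr @ beta
            return float(r @ linalg.cho_solve(c, r, check_finite=False))

        return logdet, XtWiX, XtWiy, quad

    def profiled_deviance(self, logg):
        gT, gS = np.exp(np.clip(logg, *_LOG_RATIO_BOUNDS))
        try:
            logdetW, XtWiX, XtWiy, quad = self._core(self._weights(gT, gS))
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        q = quad(beta)
        sign, logdetX = np.linalg.slogdet(XtWiX)
        if sign <= 0 or q <= 0:
            return np.inf, None, None
        dev = (self.n - self.p) * np.log(q) + logdetW + logdetX
        return dev, beta, q

    def reml_loglik(self, theta):
        """REML log-likelihood (up to an additive constant) on the variance
        scale theta = (v_transect, v_station, sigma2)."""
        vT, vS, s2 = theta
        if s2 <= 0 or vT < 0 or vS < 0:
            return -np.inf
        if self._fast:
            v = s2 + vT * self.lamT + vS * self.lamS
            if np.any(v <= 0):
                return -np.inf
        else:
            v = s2 * np.eye(self.n) + vT * self.GT + vS * self.GS
        try:
            logdetV, XtViX, XtViy, quad = self._core(v)
            beta = np.linalg.solve(XtViX, XtViy)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return -np.inf
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logdetV + logdetX + quad(beta))

    def cov_beta(self, theta):
        vT, vS, s2 = theta
        if self._fast:
            v = s2 + vT * self.lamT + vS * self.lamS
            XtViX = self.Xr.T @ (self.Xr / v[:, None])
        else:
            V = s2 * np.eye(self.n) + vT * self.GT + vS * self.GS
            c = linalg.cho_factor(V, lower=True, check_finite=False)
            XtViX = self.Xr.T @ linalg.cho_solve(c, self.Xr, check_finite=False)
        return np.linalg.inv(XtViX)

    def cov_beta_adjusted(self, theta, A):
        """Kackar-Harville / Kenward-Roger small-sample covariance of the
        fixed effects: Phi + 2 Phi Lambda Phi, where Lambda accumulates the
        extra variability from estimating the variance parameters (A is
        their asymptotic covariance).  The variance-derivative matrices are
        diagonal in the fast basis, so this costs a handful of p x p
        products."""
        vT, vS, s2 = theta
        if self._fast:
            v = s2 + vT * self.lamT + vS * self.lamS
            lams = [self.lamT, self.lamS, np.ones(self.n)]
            XtViX = self.Xr.T @ (self.Xr / v[:, None])
            Phi = np.linalg.inv(XtViX)
            P = [-self.Xr.T @ (self.Xr * (lam / v**2)[:, None]) for lam in lams]
            Q = [
                [self.Xr.T @ (self.Xr * (li * lj / v**3)[:, None]) for lj in lams]
                for li in lams
            ]
        else:
            V = s2 * np.eye(self.n) + vT * self.GT + vS * self.GS
            c = linalg.cho_factor(V, lower=True, check_finite=False)
            ViX = linalg.cho_solve(c, self.Xr, check_finite=False)
            Phi = np.linalg.inv(self.Xr.T @ ViX)
            derivs = [self.GT, self.GS, np.eye(self.n)]
            ViD = [linalg.cho_solve(c, D, check_finite=False) for D in derivs]
            P = [-ViX.T @ D @ ViX for D in derivs]
            Q = [[ViX.T @ Di @ ViDj @ ViX for ViDj in ViD] for Di in derivs]
        Lam = np.zeros_like(Phi)
        for i in range(3):
            for j in range(3):
                Lam += A[i, j] * (Q[i][j] - P[i] @ Phi @ P[j])
        return Phi + 2.0 * Phi @ Lam @ Phi


def _num_hess(f, x, rel=1e-3, absmin=1e-9):
    """Numerical Hessian honouring the nonnegativity boundary of x.

    Steps are relative with a floor tied to the overall variance scale so
    that boundary components (variance estimates at 0) do not produce
    noise-dominated second differences."""
    k = len(x)
    H = np.zeros((k, k))
    scale = max(np.max(np.abs(x)), 1e-12)
    h = np.maximum(np.abs(x) * rel, rel * 1e-2 * scale)
    h = np.maximum(h, absmin)
    f0 = f(x)

    def at(deltas):
        xx = x.copy()
        for i, d in deltas:
            xx[i] += d
        return f(xx)

    for i in range(k):
        if x[i] - h[i] >= 0:
            H[i, i] = (at([(i, h[i])]) - 2 * f0 + at([(i, -h[i])])) / h[i] ** 2
        else:  # one-sided at the boundary
            H[i, i] = (at([(i, 2 * h[i])]) - 2 * at([(i, h[i])]) + f0) / h[i] ** 2
        for j in range(i + 1, k):
            if x[i] - h[i] >= 0 and x[j] - h[j] >= 0:
                H[i, j] = (
                    at([(i, h[i]), (j, h[j])]) - at([(i, h[i]), (j, -h[j])])
                    - at([(i, -h[i]), (j, h[j])]) + at([(i, -h[i]), (j, -h[j])])
                ) / (4 * h[i] * h[j])
            else:
                H[i, j] = (
                    at([(i, h[i]), (j, h[j])]) - at([(i, h[i])])
                    - at([(j, h[j])]) + f0
                ) / (h[i] * h[j])
            H[j, i] = H[i, j]
    return H


def _theta_cov(prob: _RemlProblem, theta: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the REML variance estimates (inverse
    observed information, numerically differentiated)."""
    nllf = lambda th: -prob.reml_loglik(th)
    H = _num_hess(nllf, theta)
    return np.linalg.pinv(H)


def _satterthwaite_df(prob: _RemlProblem, theta: np.ndarray, cov: np.ndarray, A: np.ndarray):
    """Satterthwaite denominator df for every fixed coefficient.

    df_j = 2 Var(b_j)^2 / (g_j' A g_j) where g_j is the gradient of
    Var(b_j) in the variance parameters and A the asymptotic covariance of
    the REML variance estimates (inverse observed information).
    """
    scale = max(np.max(np.abs(theta)), 1e-12)
    h = np.maximum(np.abs(theta) * 1e-3, 1e-5 * scale)
    grads = np.zeros((prob.p, 3))
    for k in range(3):
        tp = theta.copy()
        tp[k] += h[k]
        vp = np.diag(prob.cov_beta(tp))
        tm = theta.copy()
        tm[k] -= h[k]
        if tm[k] >= 0:
            vm = np.diag(prob.cov_beta(tm))
            grads[:, k] = (vp - vm) / (2 * h[k])
        else:
            grads[:, k] = (vp - np.diag(cov)) / h[k]
    var_b = np.diag(cov)
    denom = np.einsum("jk,kl,jl->j", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * var_b**2 / denom
    df = np.where(np.isfinite(df) & (denom > 0), df, np.nan)
    # residual df is the exact answer when both variance components vanish,
    # so it caps the approximation; numerical noise at boundary fits can
    # otherwise push df (and hence the t reference) spuriously high
    return np.clip(df, 1.0, float(prob.n - prob.p))


def fit_mixed(
    y,
    X,
    transect,
    station,
    names: list[str],
    df_method: str = "satterthwaite",
) -> MixedFit:
    """REML fit of the nested random-intercept model.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix.
    transect, station : grouping labels (any hashable dtype), one per row.
        Pass ``None`` for both to fall back to OLS.
    names : column names of X, used for coefficient lookup.
    df_method : "satterthwaite" (default) or "residual".
    """
    if transect is None and station is None:
        return fit_ols(y, X, names)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed design")
    prob = _RemlProblem(y, X, transect, station)

    best = None
    with np.errstate(invalid="ignore", over="ignore"):
        for start in ([np.log(0.1), np.log(0.1)], [np.log(1.0), np.log(1.0)]):
            res = optimize.minimize(
                lambda lg: prob.profiled_deviance(lg)[0],
                start,
                method="Nelder-Mead",
                options=dict(xatol=1e-06, fatol=1e-10, maxiter=600),
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if best.fun < np.inf:
                break
    converged = bool(best.success and np.isfinite(best.fun))
    dev, beta, q = prob.profiled_deviance(best.x)
    if beta is None:
        raise ValueError("mixed-model fit failed (non-finite REML criterion)")
    gT, gS = np.exp(np.clip(best.x, *_LOG_RATIO_BOUNDS))
    s2 = q / (n - p)
    theta = np.array([gT * s2, gS * s2, s2])
    singular = bool(min(gT, gS) < _SINGULAR_TOL)
    cov = prob.cov_beta(theta)
    se = np.sqrt(np.diag(cov))
    t = beta / se

    df = np.full(p, float(n - p))
    used_method = "residual"
    if df_method in ("satterthwaite", "kenward-roger"):
        try:
            A = _theta_cov(prob, theta)
            if df_method == "kenward-roger":
                adj = prob.cov_beta_adjusted(theta, A)
                # guard against a non-PSD adjustment at extreme boundaries
                if np.all(np.diag(adj) > 0):
                    cov = adj
                    se = np.sqrt(np.diag(cov))
                    t = beta / se
            df_s = _satterthwaite_df(prob, theta, cov, A)
            bad = ~np.isfinite(df_s)
            if bad.any():
                # boundary fits can defeat the approximation for individual
                # coefficients; those keep residual df
                df_s = np.where(bad, float(n - p), df_s)
                logger.info("Satterthwaite df fell back to residual df for %d coefficients", int(bad.sum()))
            df = df_s
            used_method = df_method
        except Exception:  # pragma: no cover - defensive
            logger.warning("small-sample df adjustment failed; using residual df")
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    fitted = X @ beta
    return MixedFit(
        names=list(names), beta=beta, se=se, tvalues=t, df=df, pvalues=pv,
        cov_beta=cov, vc_transect=float(theta[0]), vc_station=float(theta[1]),
        sigma2=float(s2), loglik=float(prob.reml_loglik(theta)), n_obs=n,
        rank=p, singular=singular, converged=converged, df_method=used_method,
        mixed=True, _X=X, _resid=y - fitted, _fitted=fitted,
    )
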