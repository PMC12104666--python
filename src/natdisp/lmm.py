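"""Gaussian linear mixed models with crossed random intercepts.

Fits y = X beta + sum_k Z_k u_k + e by restricted maximum likelihood,
with u_k ~ N(0, sigma_k^2 I) for each (possibly crossed) grouping factor
and e ~ N(0, sigma^2 I). Designed for the modest problem sizes of
territory-level dispersal data (n up to a few thousand rows, a few
hundred grouping levels): the covariance algebra runs through the
Woodbury identity on the q x q level space, never forming an n x n
matrix.

Fixed-effect degrees of freedom and p-values use the Satterthwaite
approximation: for a coefficient c'beta with variance f(theta) =
c' (X' V(theta)^-1 X)^-1 c, df = 2 f^2 / (g' A g) where g is the
gradient of f at the REML estimate and A the asymptotic covariance of
the variance parameters (twice the inverse Hessian of the REML
deviance). Both derivatives are obtained by central finite differences,
which is accurate to well below the reporting precision of the fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_SINGULAR_TOL = 1e-6  # variance ratio below which a component is reported singular


@dataclass
class LMMFit:
    """REML fit of a Gaussian LMM with independent random intercepts."""

    params: pd.Series
    bse: pd.Series
    df: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float  # residual variance
    re_var: Dict[str, float]  # random-intercept variances by factor name
    reml_criterion: float  # -2 * restricted log-likelihood (up to a constant)
    n: int
    converged: bool
    singular: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "SE": self.bse, "df": self.df,
            "t": self.tvalues, "p": self.pvalues,
        })


class _Workspace:
    """Sufficient statistics for the profiled REML deviance."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_labels: Sequence[np.ndarray]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.comp_slices = []
        blocks = []
        for labels in Z_labels:
            codes, levels = pd.factorize(labels)
            Z = np.zeros((self.n, len(levels)))
            Z[np.arange(self.n), codes] = 1.0
            self.comp_slices.append(Z.shape[1])
            blocks.append(Z)
        self.K = len(blocks)
        self.Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        self.q = self.Z.shape[1]
        self.W = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ X
        self.Zty = self.Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        return np.repeat(np.asarray(gamma, dtype=float), self.comp_slices)

    def core(self, gamma: np.ndarray):
        """Return (logdet V0, X'V0^-1 X, X'V0^-1 y, y'V0^-1 y)."""
        if self.q == 0 or self.K == 0:
            return 0.0, self.XtX, self.Xty, self.yty
        d = self._expand(np.maximum(gamma, 0.0))
        sq = np.sqrt(d)
        M = np.eye(self.q) + (sq[:, None] * self.W) * sq[None, :]
        cf = linalg.cho_factor(M, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        B = np.column_stack([self.ZtX, self.Zty]) * sq[:, None]
        S = linalg.cho_solve(cf, B)  # M^-1 [D^.5 Z'X, D^.5 Z'y]
        corr = B.T @ S
        XtViX = self.XtX - corr[: self.p, : self.p]
        XtViy = self.Xty - corr[: self.p, -1]
        ytViy = self.yty - corr[-1, -1]
        return logdet, XtViX, XtViy, ytViy

    def profiled_deviance(self, gamma: np.ndarray) -> float:
        """-2 restricted log-likelihood with sigma^2 profiled out."""
        if not np.all(np.isfinite(gamma)) or np.any(gamma > 1e10):
            return np.inf
        try:
            logdet, XtViX, XtViy, ytViy = self.core(gamma)
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return np.inf
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - float(beta @ XtViy)
        if rss <= 0:
            return np.inf
        dfres = self.n - self.p
        return logdet + logdet_X + dfres * np.log(rss / dfres)

    def deviance(self, theta: np.ndarray) -> float:
        """-2 restricted log-likelihood at theta = (sigma2, sigma_1^2, ...)."""
        sigma2 = theta[0]
        if sigma2 <= 0 or not np.all(np.isfinite(theta)):
            return np.inf
        gamma = np.maximum(theta[1:], 0.0) / sigma2
        try:
            logdet, XtViX, XtViy, ytViy = self.core(gamma)
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return np.inf
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - float(beta @ XtViy)
        return ((self.n - self.p) * np.log(sigma2) + logdet + logdet_X
                + rss / sigma2)

    def coef_variance(self, theta: np.ndarray) -> np.ndarray:
        """Diagonal of cov(beta-hat) at variance parameters theta."""
        sigma2 = theta[0]
        gamma = np.maximum(theta[1:], 0.0) / sigma2
        _, XtViX, _, _ = self.core(gamma)
        return sigma2 * np.diag(np.linalg.inv(XtViX))


def fit_lmm(y, X: pd.DataFrame, random: Optional[Dict[str, Sequence]] = None,
            ) -> LMMFit:
    """Fit a Gaussian LMM by REML with crossed random intercepts.

    Parameters
    ----------
    y
        Response vector.
    X
        Fixed-effect design matrix (include an intercept column).
    random
        Mapping factor name -> label vector (one entry per row of X);
        each factor contributes one independent random intercept. May be
        empty/None, in which case the fit is ordinary least squares.
    """
    yv = np.asarray(y, dtype=float)
    Xm = X.to_numpy(dtype=float)
    names = list(X.columns)
    random = random or {}
    ws = _Workspace(yv, Xm, [np.asarray(v) for v in random.values()])

    # degenerate case: the fixed effects fit exactly (e.g. a constant
    # response); the REML criterion is undefined, return the OLS solution
    beta0, *_ = np.linalg.lstsq(Xm, yv, rcond=None)
    rss0 = float(np.sum((yv - Xm @ beta0) ** 2))
    if rss0 <= 1e-12 * max(float(yv @ yv), 1.0):
        idx = pd.Index(names)
        zeros = np.zeros(ws.p)
        return LMMFit(params=pd.Series(beta0, idx), bse=pd.Series(zeros, idx),
                      df=pd.Series(np.full(ws.p, float(ws.n - ws.p)), idx),
                      tvalues=pd.Series(np.full(ws.p, np.nan), idx),
                      pvalues=pd.Series(np.full(ws.p, np.nan), idx),
                      sigma2=rss0 / max(ws.n - ws.p, 1),
                      re_var={k: 0.0 for k in random}, reml_criterion=-np.inf,
                      n=ws.n, converged=True, singular=True)

    if ws.K:
        best = None
        for start in ([0.1] * ws.K, [1.0] * ws.K):
            res = optimize.minimize(
                ws.profiled_deviance, np.array(start, dtype=float),
                method="L-BFGS-B", bounds=[(0.0, None)] * ws.K,
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        gamma = np.maximum(best.x, 0.0)
        converged = bool(best.success or np.isfinite(best.fun))
        crit = float(best.fun)
    else:
        gamma = np.zeros(0)
        converged = True
        crit = float(ws.profiled_deviance(gamma))
    if not np.isfinite(crit):
        raise RuntimeError("mixed-model fit did not converge (non-finite REML criterion)")

    _, XtViX, XtViy, ytViy = ws.core(gamma)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - float(beta @ XtViy)
    sigma2 = rss / (ws.n - ws.p)
    theta = np.concatenate([[sigma2], gamma * sigma2])
    covb = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(covb))

    dfs = _satterthwaite_df(ws, theta)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)

    singular = bool(ws.K and np.any(gamma < _SINGULAR_TOL))
    re_var = {name: float(g * sigma2) for name, g in zip(random.keys(), gamma)}
    idx = pd.Index(names)
    return LMMFit(
        params=pd.Series(beta, idx), bse=pd.Series(se, idx),
        df=pd.Series(dfs, idx), tvalues=pd.Series(tvals, idx),
        pvalues=pd.Series(pvals, idx), sigma2=float(sigma2), re_var=re_var,
        reml_criterion=crit, n=ws.n, converged=converged, singular=singular)


def _satterthwaite_df(ws: _Workspace, theta: np.ndarray) -> np.ndarray:
    """Satterthwaite df per coefficient via finite-difference derivatives."""
    n_theta = len(theta)
    dfres = float(ws.n - ws.p)
    steps = np.maximum(np.abs(theta), theta[0]) * 1e-4 + 1e-12

    # gradient of each coefficient variance wrt theta
    grads = np.zeros((ws.p, n_theta))
    for k in range(n_theta):
        hi, lo = theta.copy(), theta.copy()
        hi[k] += steps[k]
        lo[k] = max(lo[k] - steps[k], 0.0 if k > 0 else steps[k] * 1e-3)
        denom = hi[k] - lo[k]
        grads[:, k] = (ws.coef_variance(hi) - ws.coef_variance(lo)) / denom

    # covariance of theta-hat: 2 * inverse Hessian of the REML deviance
    H = np.zeros((n_theta, n_theta))
    for k in range(n_theta):
        for l in range(k, n_theta):
            H[k, l] = H[l, k] = _mixed_fd(ws.deviance, theta, k, l, steps)
    try:
        A = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(ws.p, dfres)

    f = ws.coef_variance(theta)
    dfs = np.empty(ws.p)
    for j in range(ws.p):
        denom = float(grads[j] @ A @ grads[j])
        if denom <= 0 or not np.isfinite(denom):
            dfs[j] = dfres
        else:
            dfs[j] = min(2.0 * f[j] ** 2 / denom, dfres)
        if dfs[j] < 1.0:
            dfs[j] = 1.0
    return dfs


def _fd_points(theta_k: float, h: float, lower: float):
    """Two evaluation abscissae straddling (or starting at) theta_k.

    Shifts to a one-sided scheme when the central point would cross the
    ``lower`` bound (variance parameters live on [0, inf))."""
    if theta_k - h > lower:
        return theta_k - h, theta_k + h
    return theta_k, theta_k + h


def _mixed_fd(fun, theta, k, l, steps):
    """Finite-difference second derivative d^2 fun / dtheta_k dtheta_l.

    Central where possible; one-sided at the boundary of the variance
    parameter space."""
    lower_k = 1e-12 if k == 0 else 0.0
    if k == l:
        t0 = theta[k]
        h = steps[k]
        if t0 - h > lower_k:
            pts = (t0 - h, t0, t0 + h)
        else:
            pts = (t0, t0 + h, t0 + 2 * h)
        vals = []
        for p in pts:
            t = theta.copy()
            t[k] = p
            vals.append(fun(t))
        return (vals[0] - 2.0 * vals[1] + vals[2]) / (h * h)
    lower_l = 1e-12 if l == 0 else 0.0
    ak, bk = _fd_points(theta[k], steps[k], lower_k)
    al, bl = _fd_points(theta[l], steps[l], lower_l)
    out = 0.0
    for pk, sk in ((bk, 1.0), (ak, -1.0)):
        for pl, sl in ((bl, 1.0), (al, -1.0)):
            t = theta.copy()
            t[k] = pk
            t[l] = pl
            out += sk * sl * fun(t)
    return out / ((bk - ak) * (bl - al))
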