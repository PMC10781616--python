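"""REML linear mixed models for the selection-regime analysis.

The regime comparison fits phenotype ~ regime * sex + generation +
group-activity with random intercepts for selection line, breeding
family and stimulus-group use count. Variance components are estimated
by restricted maximum likelihood; because all random terms are plain
intercepts with modest numbers of levels, V^-1 and determinants go
through the Woodbury identity, keeping every evaluation O(n q^2).
Coefficient t-tests use Satterthwaite degrees of freedom via the delta
method on the REML information matrix (the df-approximating convention
for mixed-model tests). Per-sex regime contrasts come with a
studentized-range (Tukey) adjustment over the contrast family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import studentized_range, t as t_dist


@dataclass
class MixedModelResult:
    coefficients: pd.DataFrame  # estimate, se, t, df, p
    varcomp: dict  # name -> variance (includes "residual")
    loglik: float
    converged: bool
    singular: bool
    design_columns: list
    _cov_beta: np.ndarray = field(repr=False, default=None)
    _theta_cov: Optional[np.ndarray] = field(repr=False, default=None)
    _cov_beta_fn: Optional[object] = field(repr=False, default=None)
    _theta: Optional[np.ndarray] = field(repr=False, default=None)


def _encode_terms(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list]:
    """Design matrix with intercept; 'a:b' denotes an interaction."""
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]

    def encode(term):
        s = df[term]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            return [
                ((s == lv).to_numpy(float), f"{term}[{lv}]") for lv in levels[1:]
            ]
        return [(s.to_numpy(float), term)]

    for term in terms:
        if ":" in term:
            parts = term.split(":")
            pieces = [encode(p) for p in parts]
            combo = pieces[0]
            for nxt in pieces[1:]:
                combo = [(a * b, f"{an}:{bn}") for a, an in combo for b, bn in nxt]
            for v, nm in combo:
                cols.append(v)
                names.append(nm)
        else:
            for v, nm in encode(term):
                cols.append(v)
                names.append(nm)
    return np.column_stack(cols), names


def _z_matrices(df: pd.DataFrame, random: Sequence[str]) -> dict:
    out = {}
    for term in random:
        codes, levels = pd.factorize(df[term])
        z = np.zeros((len(df), len(levels)))
        z[np.arange(len(df)), codes] = 1.0
        out[term] = z
    return out


def _solve_sym(a, b):
    """Solve a x = b for symmetric a, falling back to pseudo-inverse for
    rank-deficient (singular-design) cases."""
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(a) @ b


class _RemlProblem:
    def __init__(self, y, x, z_dict):
        self.y = y
        self.x = x
        self.names = list(z_dict)
        self.z = np.concatenate([z_dict[k] for k in self.names], axis=1) if z_dict else None
        self.sizes = [z_dict[k].shape[1] for k in self.names]
        self.n, self.p = x.shape

    def _v0_solve(self, gammas):
        """Return solve(V0, .), logdet(V0) with V0 = I + sum g_k Z_k Z_k'."""
        if self.z is None:
            return (lambda m: m), 0.0
        g = np.concatenate([np.full(s, gm) for s, gm in zip(self.sizes, gammas)])
        zs = self.z * np.sqrt(g)[None, :]
        q = zs.shape[1]
        inner = np.eye(q) + zs.T @ zs
        sign, logdet = np.linalg.slogdet(inner)
        inner_inv = np.linalg.inv(inner)

        def solve(m):
            return m - zs @ (inner_inv @ (zs.T @ m))

        return solve, logdet

    def profile(self, log_gammas):
        gammas = np.exp(log_gammas)
        solve, logdet_v0 = self._v0_solve(gammas)
        viy = solve(self.y)
        vix = solve(self.x)
        xtvx = self.x.T @ vix
        beta = _solve_sym(xtvx, self.x.T @ viy)
        r = self.y - self.x @ beta
        quad = float(r @ solve(r))
        df_resid = self.n - self.p
        sigma2 = quad / df_resid
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        reml = -0.5 * (
            df_resid * np.log(2 * np.pi * sigma2)
            + logdet_v0
            + logdet_xtvx
            + df_resid
        )
        return reml, beta, sigma2, xtvx

    def reml_loglik_theta(self, theta):
        """REML log-likelihood as a function of raw variances
        theta = (sigma2_e, sigma2_1, ...), without profiling."""
        sigma2 = theta[0]
        gammas = np.array(theta[1:]) / sigma2
        solve, logdet_v0 = self._v0_solve(gammas)
        viy = solve(self.y)
        vix = solve(self.x)
        xtvx = self.x.T @ vix
        beta = _solve_sym(xtvx, self.x.T @ viy)
        r = self.y - self.x @ beta
        quad = float(r @ solve(r)) / sigma2
        _, logdet_xtvx = np.linalg.slogdet(xtvx / sigma2)
        return -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi * sigma2)
            + logdet_v0
            + logdet_xtvx
            + quad
        )

    def cov_beta(self, theta):
        sigma2 = theta[0]
        gammas = np.array(theta[1:]) / sigma2
        solve, _ = self._v0_solve(gammas)
        xtvx = self.x.T @ solve(self.x)
        try:
            return sigma2 * np.linalg.inv(xtvx)
        except np.linalg.LinAlgError:
            return sigma2 * np.linalg.pinv(xtvx)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    random: Sequence[str],
    fix_variances: Optional[dict] = None,
) -> MixedModelResult:
    """Fit a random-intercept LMM by REML.

    ``fixed`` lists columns (categorical auto-encoded; 'a:b' for
    interactions); ``random`` lists grouping columns, one random
    intercept each. ``fix_variances`` (name -> variance, must include
    'residual') skips estimation and does a pure GLS solve — useful for
    oracle checks. Satterthwaite df per coefficient.
    """
    df = data.dropna(subset=[response]).reset_index(drop=True)
    y = df[response].to_numpy(float)
    x, names = _encode_terms(df, fixed)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("singular fixed-effect design", stacklevel=2)
    z_dict = _z_matrices(df, random)
    prob = _RemlProblem(y, x, z_dict)

    if fix_variances is not None:
        sigma2 = fix_variances["residual"]
        theta = np.array([sigma2] + [fix_variances[k] for k in prob.names])
        converged = True
    else:
        k = len(prob.names)
        x0 = np.full(k, np.log(0.1))

        def objective(lg):
            return -prob.profile(lg)[0]

        res = minimize(objective, x0, method="Nelder-Mead", options=dict(xatol=1e-6, fatol=1e-9, maxiter=3000))
        converged = bool(res.success)
        reml, beta, sigma2, _ = prob.profile(res.x)
        theta = np.concatenate([[sigma2], np.exp(res.x) * sigma2])

    loglik = prob.reml_loglik_theta(theta)
    cov_b = prob.cov_beta(theta)
    solve, _ = prob._v0_solve(np.array(theta[1:]) / theta[0])
    xtvx = x.T @ solve(x)
    beta = _solve_sym(xtvx, x.T @ solve(y))
    se = np.sqrt(np.diag(cov_b))
    singular = bool((theta[1:] < 1e-8 * theta[0]).any()) if len(theta) > 1 else False
    if singular:
        warnings.warn("singular fit: a variance component is (near) zero", stacklevel=2)

    # Satterthwaite: df_j = 2 (c'Cc)^2 / Var(c'C(theta)c), Var via the
    # inverse REML information (numeric Hessian in theta space)
    theta_cov = _theta_covariance(prob, theta)
    dfs = np.empty(len(beta))
    for j in range(len(beta)):
        c = np.zeros(len(beta))
        c[j] = 1.0
        dfs[j] = _satterthwaite_df(prob, theta, theta_cov, c)
    tvals = beta / se
    pvals = 2 * t_dist.sf(np.abs(tvals), dfs)
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tvals, "df": dfs, "p": pvals}, index=names
    )
    varcomp = {"residual": float(theta[0])}
    varcomp.update({nm: float(v) for nm, v in zip(prob.names, theta[1:])})
    return MixedModelResult(
        coefficients=coef,
        varcomp=varcomp,
        loglik=float(loglik),
        converged=converged,
        singular=singular,
        design_columns=names,
        _cov_beta=cov_b,
        _theta_cov=theta_cov,
        _cov_beta_fn=prob,
        _theta=theta,
    )


def _theta_covariance(prob: _RemlProblem, theta: np.ndarray) -> np.ndarray:
    k = len(theta)
    h = np.zeros((k, k))
    steps = np.maximum(1e-4, 1e-3 * np.abs(theta))

    def f(th):
        th = np.maximum(th, 1e-10)
        return prob.reml_loglik_theta(th)

    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * steps[i] * steps[j])
    info = -h
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def _satterthwaite_df(prob, theta, theta_cov, c) -> float:
    def g(th):
        cov = prob.cov_beta(np.maximum(th, 1e-10))
        return float(c @ cov @ c)

    k = len(theta)
    grad = np.empty(k)
    steps = np.maximum(1e-5, 1e-3 * np.abs(theta))
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        grad[i] = (g(theta + e) - g(theta - e)) / (2 * steps[i])
    var_g = float(grad @ theta_cov @ grad)
    g0 = g(theta)
    if not np.isfinite(var_g) or var_g <= 0 or not np.isfinite(g0):
        return float(prob.n - prob.p)
    return max(1.0, 2.0 * g0**2 / var_g)


def contrast(
    result: MixedModelResult, c: np.ndarray, adjust_k: int = 1
) -> dict:
    """Test a linear contrast of the fixed effects.

    ``adjust_k`` > 1 applies a Tukey (studentized-range) adjustment for
    a family of k means' pairwise comparisons.
    """
    c = np.asarray(c, float)
    est = float(c @ result.coefficients["estimate"].to_numpy())
    se = float(np.sqrt(c @ result._cov_beta @ c))
    df = _satterthwaite_df(result._cov_beta_fn, result._theta, result._theta_cov, c)
    tval = est / se
    if adjust_k > 1:
        p = float(studentized_range.sf(abs(tval) * np.sqrt(2.0), adjust_k, df))
    else:
        p = float(2 * t_dist.sf(abs(tval), df))
    return {"estimate": est, "se": se, "t": tval, "df": df, "p": p}


def regime_contrasts_by_sex(result: MixedModelResult) -> pd.DataFrame:
    """Polarization-vs-control contrast within each sex, Tukey-adjusted.

    Assumes the design contains regime[...] and a regime x sex
    interaction column (as produced by fixed=['regime', 'sex',
    'regime:sex', ...]).
    """
    names = result.design_columns
    reg = [i for i, nm in enumerate(names) if nm.startswith("regime[") and ":" not in nm]
    inter = [i for i, nm in enumerate(names) if ":" in nm and "regime[" in nm and "sex[" in nm]
    if len(reg) != 1 or len(inter) != 1:
        raise ValueError("design lacks regime and regime:sex columns")
    rows = {}
    c = np.zeros(len(names))
    c[reg[0]] = 1.0
    rows["F"] = contrast(result, c, adjust_k=2)
    c2 = c.copy()
    c2[inter[0]] = 1.0
    rows["M"] = contrast(result, c2, adjust_k=2)
    return pd.DataFrame(rows).T
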