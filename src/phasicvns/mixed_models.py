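"""Mixed-effects models for trial-level behavior and per-point series.

Gaussian linear mixed models are fitted with statsmodels ``MixedLM``
(REML by default, ML refits for likelihood-ratio tests).  Binomial
(logistic) mixed models use an in-house Laplace approximation to the
marginal likelihood with subject-level random effects, optimized by
L-BFGS; the per-subject modes are found by vectorized Newton iterations,
which keeps thousands of fits affordable.  Predictors are assessed by
likelihood-ratio chi-square tests of nested ML fits; interactions are
resolved by nested-coding models estimating the inner effect at each level
of the outer factor.

Wald inference for fixed effects conditions on the estimated random-effect
(co)variances, as is conventional for these models; nested-model t tests
use a normal approximation to the reference distribution (no Satterthwaite
degrees of freedom are computed) and are flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

import statsmodels.formula.api as smf

__all__ = ["FitResult", "fit_mixed", "lrt", "anova_lr", "odds_ratio",
           "resolve_interaction", "SeparationError"]


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate (e.g. outcome is constant)."""


@dataclass
class FitResult:
    params: pd.Series
    se: pd.Series                    # Wald SE (binomial: full-Hessian)
    loglik: float
    family: str
    method: str                      # "reml" | "ml" | "laplace"
    converged: bool
    singular: bool = False
    n_obs: int = 0
    n_groups: int = 0
    re_structure: str = ""
    notes: list = field(default_factory=list)

    def tvalues(self) -> pd.Series:
        return self.params / self.se

    def summary_frame(self) -> pd.DataFrame:
        t = self.tvalues()
        return pd.DataFrame({"beta": self.params, "se": self.se, "t": t,
                             "p_normal": 2 * stats.norm.sf(np.abs(t))})


def odds_ratio(beta: float) -> float:
    """Log-odds coefficient to odds ratio: OR = exp(beta)."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(beta))


# ---------------------------------------------------------------------------
# gaussian: statsmodels MixedLM with a convergence fallback ladder


def _fit_gaussian(data, formula, groups, re_formula, reml):
    ladder = [re_formula, "1"] if re_formula not in (None, "1") else ["1"]
    notes = []
    for re_f in ladder:
        md = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = md.fit(reml=reml)
            except (np.linalg.LinAlgError, ValueError) as exc:
                notes.append(f"re structure {re_f!r} failed: {exc}")
                continue
        params = res.fe_params
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(res.bse_fe)):
            notes.append(f"re structure {re_f!r} produced non-finite estimates")
            continue
        # the optimizer's strict gradient flag is informational only: a
        # finite fit at a (possibly boundary) optimum is usable
        if not res.converged:
            notes.append(f"re structure {re_f!r}: optimizer flag not set "
                         "(boundary or loose-gradient fit)")
        ev = np.linalg.eigvalsh(np.atleast_2d(res.cov_re))
        singular = bool(ev.min() < 1e-8 * max(ev.max(), 1e-12))
        return FitResult(
            params=pd.Series(params, index=params.index),
            se=res.bse_fe,
            loglik=float(res.llf),
            family="gaussian",
            method="reml" if reml else "ml",
            converged=True,
            singular=singular,
            n_obs=int(res.nobs),
            n_groups=len(md.group_labels),
            re_structure=re_f or "1",
            notes=notes,
        )
    raise RuntimeError("all random-effect structures failed: " + "; ".join(notes))


# ---------------------------------------------------------------------------
# binomial: Laplace-approximated logistic mixed model


def _chol_from_theta(theta, q):
    L = np.zeros((q, q))
    il = np.tril_indices(q)
    L[il] = theta
    L[np.diag_indices(q)] = np.exp(np.diag(L))
    return L


def _pirls_deviance(L, y, X, Z, groups, n_groups, state, tol=1e-10,
                    maxiter=80):
    """Profiled Laplace deviance at fixed variance parameters.

    Works in the spherical parameterization u = L v with v ~ N(0, I), so
    the per-group Newton blocks are I + L'Z'WZL — well conditioned even
    when a variance component collapses to the boundary.  The fixed
    effects and all per-group v are jointly maximized by Newton with
    block elimination (batched per-group solves, fixed effects through
    the Schur complement); the objective is strictly concave, so with
    step halving the iteration is globally convergent and, at the given
    tolerance, a deterministic map of the variance parameters regardless
    of the warm start.

    Returns ``(nll, beta, V, cov_beta)``; ``cov_beta`` is the inverse
    Schur complement, the conventional fixed-effect covariance
    conditional on the variance parameters.
    """
    p = X.shape[1]
    q = Z.shape[1]
    ZL = Z @ L
    beta = state[0].copy()
    V = state[1].copy()

    def blocks(w):
        A = np.empty((n_groups, q, q))
        for j in range(q):
            for k in range(j, q):
                h = np.bincount(groups, weights=ZL[:, j] * ZL[:, k] * w,
                                minlength=n_groups)
                A[:, j, k] = h
                A[:, k, j] = h
        C = np.empty((n_groups, p, q))
        for i in range(p):
            for j in range(q):
                C[:, i, j] = np.bincount(groups, weights=X[:, i] * ZL[:, j] * w,
                                         minlength=n_groups)
        return A, C

    def penalized(beta_, V_):
        eta = X @ beta_ + np.einsum("ij,ij->i", ZL, V_[groups])
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(V_ * V_)

    S = None
    eye = np.eye(q)
    for _ in range(maxiter):
        eta = X @ beta + np.einsum("ij,ij->i", ZL, V[groups])
        mu = special.expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        r = y - mu
        A, C = blocks(w)
        A += eye[None]
        gb = X.T @ r
        gv = np.column_stack([np.bincount(groups, weights=ZL[:, j] * r,
                                          minlength=n_groups)
                              for j in range(q)]) - V
        Ainv_gv = np.linalg.solve(A, gv[:, :, None])[:, :, 0]
        Ainv_Ct = np.linalg.solve(A, C.transpose(0, 2, 1))
        XWX = X.T @ (w[:, None] * X)
        S = XWX - np.einsum("gpq,gqr->pr", C, Ainv_Ct)
        rhs = gb - np.einsum("gpq,gq->p", C, Ainv_gv)
        dbeta = np.linalg.solve(S, rhs)
        dV = Ainv_gv - np.einsum("gqp,p->gq", Ainv_Ct, dbeta)
        step = 1.0
        base = penalized(beta, V)
        for _halve in range(12):
            nb, nV = beta + step * dbeta, V + step * dV
            if penalized(nb, nV) >= base - 1e-12:
                break
            step *= 0.5
        beta, V = nb, nV
        if max(np.max(np.abs(step * dbeta)), np.max(np.abs(step * dV))) < tol:
            break
    eta = X @ beta + np.einsum("ij,ij->i", ZL, V[groups])
    mu = special.expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    ll_cond = np.sum(y * eta - np.logaddexp(0.0, eta))
    quad = 0.5 * np.sum(V * V)
    A, _ = blocks(w)
    _, logdet = np.linalg.slogdet(eye[None] + A)
    nll = -(ll_cond - quad - 0.5 * logdet.sum())
    try:
        cov_beta = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        cov_beta = np.full((p, p), np.nan)
    return nll, beta, V, cov_beta


def _laplace_nll(beta, L, y, X, Z, groups, n_groups, tol=1e-9, maxiter=100,
                 V0=None):
    """Full Laplace negative marginal log-likelihood at (beta, theta).

    Unlike the profiled deviance, beta is held where given and only the
    per-group modes are optimized, in the spherical parameterization
    u = L v (Newton on a strictly concave, well-conditioned objective).
    Started from zero (or a fixed ``V0``), so the value is a
    deterministic map of the parameters.
    """
    q = Z.shape[1]
    V = np.zeros((n_groups, q)) if V0 is None else V0.copy()
    ZL = Z @ L
    xb = X @ beta
    eye = np.eye(q)

    def group_h(w):
        H = np.empty((n_groups, q, q))
        for j in range(q):
            for k in range(j, q):
                h = np.bincount(groups, weights=ZL[:, j] * ZL[:, k] * w,
                                minlength=n_groups)
                H[:, j, k] = h
                H[:, k, j] = h
        return H

    def penalized(V_):
        eta = xb + np.einsum("ij,ij->i", ZL, V_[groups])
        return (np.sum(y * eta - np.logaddexp(0.0, eta))
                - 0.5 * np.sum(V_ * V_))

    for _ in range(maxiter):
        eta = xb + np.einsum("ij,ij->i", ZL, V[groups])
        mu = special.expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        g = np.column_stack([np.bincount(groups, weights=ZL[:, j] * (y - mu),
                                         minlength=n_groups) for j in range(q)])
        g -= V
        dV = np.linalg.solve(group_h(w) + eye[None], g[:, :, None])[:, :, 0]
        stepsize = 1.0
        base = penalized(V)
        for _halve in range(12):
            nV = V + stepsize * dV
            if penalized(nV) >= base - 1e-12:
                break
            stepsize *= 0.5
        V = nV
        if np.max(np.abs(stepsize * dV)) < tol:
            break
    eta = xb + np.einsum("ij,ij->i", ZL, V[groups])
    mu = special.expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    ll_cond = np.sum(y * eta - np.logaddexp(0.0, eta))
    quad = 0.5 * np.sum(V * V)
    _, logdet = np.linalg.slogdet(eye[None] + group_h(w))
    out = -(ll_cond - quad - 0.5 * logdet.sum())
    if V0 is not None:
        V0[:] = V
    return out


def _fit_binomial_laplace(y, X, Z, groups, xnames, maxiter=200):
    n_groups = int(groups.max()) + 1
    p, q = X.shape[1], Z.shape[1]
    if y.min() == y.max():
        raise SeparationError("outcome is constant; logistic fit is separated")
    # starting values: a few IRLS steps of the plain GLM
    beta = np.zeros(p)
    for _ in range(8):
        mu = special.expit(X @ beta)
        w = mu * (1 - mu) + 1e-6
        beta = beta + np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (y - mu))
    n_theta = q * (q + 1) // 2
    theta0 = np.zeros(n_theta)
    il = np.tril_indices(q)
    theta0[np.flatnonzero(il[0] == il[1])] = np.log(0.5)
    state = [beta, np.zeros((n_groups, q))]

    def nll(theta):
        L = _chol_from_theta(theta, q)
        val, b, U, _ = _pirls_deviance(L, y, X, Z, groups, n_groups, state)
        state[0], state[1] = b, U            # warm start; result is theta-
        return val                           # deterministic at tolerance

    opt = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 3e-9,
                                     "eps": 1e-5})
    L0 = _chol_from_theta(opt.x, q)
    _, b0, _, _ = _pirls_deviance(L0, y, X, Z, groups, n_groups, state)

    # refine beta against the full Laplace objective: the profiled scheme
    # ignores the dependence of the curvature term on beta, which
    # attenuates estimates for strongly binary data
    V_warm = np.zeros((n_groups, q))
    _laplace_nll(b0, L0, y, X, Z, groups, n_groups, V0=V_warm)

    def full_nll_beta(b):
        return _laplace_nll(b, L0, y, X, Z, groups, n_groups,
                            tol=1e-8, V0=V_warm.copy())

    opt2 = optimize.minimize(full_nll_beta, b0, method="L-BFGS-B",
                             options={"maxiter": 10, "ftol": 1e-10,
                                      "eps": 1e-5})
    bhat = opt2.x
    Lhat = L0
    theta_hat = opt.x
    if np.any(np.abs(bhat) > 15):
        raise SeparationError("divergent coefficient; data are separated")
    Vhat = np.zeros((n_groups, q))
    final = _laplace_nll(bhat, Lhat, y, X, Z, groups, n_groups, V0=Vhat)
    # observed information over the full (beta, theta) vector: the inverse
    # beta block then carries the variance-parameter uncertainty, matching
    # the convention of mixed-model software.  Numeric differences use a
    # fixed warm start so every evaluation is deterministic.
    n_theta = theta_hat.size
    params_hat = np.concatenate([bhat, theta_hat])

    def nll_at(vec):
        return _laplace_nll(vec[:p], _chol_from_theta(vec[p:], q),
                            y, X, Z, groups, n_groups, V0=Vhat.copy())

    npar = p + n_theta
    h = 3e-4 * np.maximum(np.abs(params_hat), 1.0)
    # forward stencil: f(x+ei+ej) - f(x+ei) - f(x+ej) + f(x); O(h) accurate,
    # which is ample for standard errors, at a third of the evaluations
    f0 = nll_at(params_hat)
    fi = np.empty(npar)
    for i in range(npar):
        v = params_hat.copy()
        v[i] += h[i]
        fi[i] = nll_at(v)
    Hfull = np.empty((npar, npar))
    for i in range(npar):
        for j in range(i, npar):
            v = params_hat.copy()
            v[i] += h[i]
            v[j] += h[j]
            fij = nll_at(v)
            Hfull[i, j] = Hfull[j, i] = (fij - fi[i] - fi[j] + f0) / (h[i] * h[j])
    try:
        cov_beta = np.linalg.inv(Hfull)[:p, :p]
    except np.linalg.LinAlgError:
        cov_beta = np.full((p, p), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    sds = np.sqrt(np.diag(Lhat @ Lhat.T))
    singular = bool(np.any(sds < 1e-4))
    return FitResult(params=pd.Series(bhat, index=xnames),
                     se=pd.Series(se, index=xnames),
                     loglik=float(-final), family="binomial", method="laplace",
                     converged=bool(opt.success or opt2.success), singular=singular,
                     n_obs=y.size, n_groups=n_groups,
                     re_structure=f"q={q}", notes=[f"re_sd={np.round(sds, 3)}"],
                     )


def fit_mixed(data: pd.DataFrame, formula: str, groups: str,
              re_formula: Optional[str] = None, family: str = "gaussian",
              reml: bool = True) -> FitResult:
    """Fit a linear or logistic mixed model.

    ``formula`` is an R-style fixed-effects formula; ``re_formula``
    describes the random-effect design within ``groups`` (default random
    intercepts).  Gaussian models use REML unless ``reml=False`` (use ML
    fits for likelihood-ratio tests); binomial models maximize the Laplace-
    approximated marginal likelihood.  Non-convergence triggers a
    documented fallback to a random-intercept-only structure; a still-
    failing fit is returned flagged, not raised.
    """
    if data[groups].nunique() < 2:
        raise ValueError("need at least 2 grouping levels")
    if family == "gaussian":
        return _fit_gaussian(data, formula, groups, re_formula, reml)
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    ymat, X = patsy.dmatrices(formula, data, return_type="dataframe")
    y = ymat.to_numpy().ravel()
    Z = patsy.dmatrix(re_formula or "1", data, return_type="dataframe").to_numpy()
    codes, _ = pd.factorize(data[groups])
    return _fit_binomial_laplace(y, X.to_numpy(), Z, codes, list(X.columns))


def lrt(full: FitResult, reduced: FitResult):
    """Likelihood-ratio chi-square for nested ML (or Laplace) fits.

    Returns ``(chisq, df, p)``.  The statistic is floored at zero; the
    degrees of freedom are the fixed-effect parameter difference.
    """
    if full.method == "reml" or reduced.method == "reml":
        raise ValueError("LRT requires ML (or Laplace) fits, not REML")
    df = len(full.params) - len(reduced.params)
    if df < 0:
        raise ValueError("models are not nested (reduced has more parameters)")
    chisq = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    return chisq, df, p


def _drop_term(formula: str, term: str) -> str:
    lhs, rhs = formula.split("~")
    terms = [t.strip() for t in rhs.split("+")]
    kept = [t for t in terms if t != term]
    if len(kept) == len(terms):
        raise ValueError(f"term {term!r} not in formula")
    return f"{lhs.strip()} ~ {' + '.join(kept) if kept else '1'}"


def anova_lr(data: pd.DataFrame, formula: str, groups: str,
             re_formula: Optional[str] = None, family: str = "gaussian",
             terms: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-predictor likelihood-ratio chi-square tests (ML fits).

    Each term is dropped in turn from the full fixed-effects formula
    (``a*b`` expands to ``a + b + a:b`` first).  Returns a DataFrame with
    ``chisq, df, p`` per term.
    """
    lhs, rhs = formula.split("~")
    expanded = []
    for t in (s.strip() for s in rhs.split("+")):
        if "*" in t:
            a, b = (u.strip() for u in t.split("*"))
            expanded += [a, b, f"{a}:{b}"]
        else:
            expanded.append(t)
    full_formula = f"{lhs.strip()} ~ {' + '.join(expanded)}"
    full = fit_mixed(data, full_formula, groups, re_formula, family, reml=False)
    rows = {}
    for term in (terms or expanded):
        reduced = fit_mixed(data, _drop_term(full_formula, term), groups,
                            re_formula, family, reml=False)
        chisq, df, p = lrt(full, reduced)
        rows[term] = {"chisq": chisq, "df": df, "p": p}
    return pd.DataFrame(rows).T


def resolve_interaction(data: pd.DataFrame, outcome: str, outer: str,
                        inner: str, covariates: Sequence[str] = (),
                        groups: str = "subject") -> pd.DataFrame:
    """Nested-coding models: the inner effect at each level of the outer.

    Fits ``outcome ~ covariates + C(outer) + C(outer):inner`` with random
    intercepts and reports, per outer level, the inner effect's beta, SE,
    t, and a normal-approximation p value (no finite-df correction).
    """
    levels = sorted(data[outer].unique())
    if len(levels) != 2:
        raise ValueError("outer factor must have two levels")
    for lev in levels:
        sub = data[data[outer] == lev]
        if sub[groups].nunique() < 2:
            raise ValueError(f"level {lev!r} has <2 subjects")
    cov = " + ".join(covariates)
    formula = f"{outcome} ~ {cov + ' + ' if cov else ''}C({outer}) + C({outer}):{inner}"
    fit = _fit_gaussian(data, formula, groups, "1", reml=True)
    rows = []
    for lev in levels:
        name = [ix for ix in fit.params.index
                if f"[{lev}]" in ix or f"[T.{lev}]" in ix]
        name = [ix for ix in name if inner in ix]
        if len(name) != 1:
            raise RuntimeError(f"could not locate nested term for level {lev}")
        b = float(fit.params[name[0]])
        se = float(fit.se[name[0]])
        t = b / se
        rows.append({"level": lev, "beta": b, "se": se, "t": t,
                     "df": np.inf, "p": 2 * stats.norm.sf(abs(t)),
                     "df_method": "normal-approximation"})
    return pd.DataFrame(rows)
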