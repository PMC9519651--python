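"""Random-intercept mixed logistic regression.

``MixedLogit`` maximises the marginal likelihood of a logistic model with a
single Gaussian random intercept per group (animal).  The per-group integral
over the random effect is approximated by adaptive Gauss-Hermite quadrature:
the integrand is re-centred at its conditional mode and rescaled by the
conditional curvature before applying the Hermite rule, so that a modest
number of nodes (default 15, never below 9) is accurate even for large
groups.

The surface follows statsmodels: build the model from data, ``fit()``
returns a ``MixedLogitResults`` carrying estimates, Wald standard errors and
p-values, the random-intercept SD, log-likelihood, AIC and a ``summary()``
table.

Also here: collinearity screening (Pearson correlations and generalised
variance inflation factors), AIC model selection with a decisiveness rule
(delta-AIC >= 10), and Nakagawa's marginal/conditional R^2 for logistic
mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .design import INTERCEPT, ModelSpec, build_design, scenario_frame

logger = logging.getLogger(__name__)

SEPARATION_THRESHOLD = 15.0  # |beta| beyond this on the link scale


def _logistic_loglik_obs(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable in both tails
    return y * eta - np.logaddexp(0.0, eta)


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                  max_iter: int = 100):
    """Plain logistic regression by iteratively reweighted least squares.

    Returns (beta, cov, loglik, converged).  Used for starting values and as
    the exact fit when the random-intercept variance is fixed at zero.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        xtwx = X.T @ WX
        try:
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
        except np.linalg.LinAlgError:
            # separation drives weights to zero; a whisper of ridge keeps
            # the step defined (the separation warning still fires later)
            ridge = 1e-8 * np.trace(xtwx) / k * np.eye(k)
            beta_new = np.linalg.solve(xtwx + ridge, WX.T @ z)
        beta = beta_new
        ll = float(_logistic_loglik_obs(X @ beta, y).sum())
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov, float(_logistic_loglik_obs(eta, y).sum()), converged


class ConvergenceError(RuntimeError):
    pass


class MixedLogit:
    """Logistic regression with one Gaussian random intercept per group.

    Parameters
    ----------
    endog : array-like of 0/1
    exog : pandas.DataFrame
        Fixed-effect design matrix (include an intercept column).
    groups : array-like
        Group labels, one per observation; needs >= 2 distinct groups.
    """

    def __init__(self, endog, exog: pd.DataFrame, groups):
        y = np.asarray(endog, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("response is constant")
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{i}" for i in range(X.shape[1])]
        if not np.all(np.isfinite(X)):
            bad = [self.exog_names[j]
                   for j in np.unique(np.nonzero(~np.isfinite(X))[1])]
            raise ValueError(f"non-finite values in design column(s) {bad}")
        codes, uniques = pd.factorize(np.asarray(groups), sort=True)
        if len(uniques) < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        order = np.argsort(codes, kind="stable")
        self._y = np.ascontiguousarray(y[order])
        self._X = np.ascontiguousarray(X[order])
        self._gidx = np.ascontiguousarray(codes[order])
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        self.nobs = len(y)
        self.k_fe = X.shape[1]
        self._u_cache = np.zeros(self.n_groups)
        self.exog = exog if isinstance(exog, pd.DataFrame) else pd.DataFrame(X, columns=self.exog_names)

    # -- likelihood ------------------------------------------------------
    def _group_modes(self, eta: np.ndarray, sigma: float, tol: float = 1e-11,
                     max_iter: int = 50):
        """Conditional modes and curvatures of the random-effect integrands."""
        u = self._u_cache.copy()
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(max_iter):
            mu = special.expit(eta + u[self._gidx])
            grad = np.bincount(self._gidx, weights=self._y - mu,
                               minlength=self.n_groups) - u * inv_s2
            curv = np.bincount(self._gidx, weights=mu * (1.0 - mu),
                               minlength=self.n_groups) + inv_s2
            step = grad / curv
            # cap steps: the objective is strictly concave, large steps only
            # arise from bad starts
            np.clip(step, -5.0, 5.0, out=step)
            u += step
            if np.max(np.abs(step)) < tol:
                break
        mu = special.expit(eta + u[self._gidx])
        curv = np.bincount(self._gidx, weights=mu * (1.0 - mu),
                           minlength=self.n_groups) + inv_s2
        return u, curv

    def loglike(self, params: np.ndarray, quad_points: int = 15) -> float:
        """Marginal log-likelihood at params = (beta..., sigma)."""
        return self._eval(params, quad_points, need_grad=False)[0]

    def score(self, params: np.ndarray, quad_points: int = 15) -> np.ndarray:
        """Gradient of the marginal log-likelihood (fixed-node form)."""
        return self._eval(params, quad_points, need_grad=True)[1]

    def _eval(self, params: np.ndarray, quad_points: int, need_grad: bool):
        """Log-likelihood and (optionally) its gradient.

        The gradient uses the standard fixed-node form: with the quadrature
        accurate, the dependence of the adapted node locations on the
        parameters contributes negligibly, and the score is the posterior-
        weighted conditional score over the nodes.
        """
        beta, sigma = params[:-1], params[-1]
        eta = self._X @ beta
        if sigma < 1e-8:
            ll = float(_logistic_loglik_obs(eta, self._y).sum())
            if not need_grad:
                return ll, None
            resid = self._y - special.expit(eta)
            return ll, np.concatenate([self._X.T @ resid, [0.0]])
        u_hat, curv = self._group_modes(eta, sigma)
        self._u_cache = u_hat
        tau = 1.0 / np.sqrt(curv)
        z, w = hermgauss(quad_points)
        const = np.log(w) + z * z
        log_terms = np.empty((quad_points, self.n_groups))
        mus = np.empty((quad_points, len(self._y))) if need_grad else None
        u_nodes = np.empty((quad_points, self.n_groups))
        for k in range(quad_points):
            uk = u_hat + np.sqrt(2.0) * tau * z[k]
            u_nodes[k] = uk
            eta_k = eta + uk[self._gidx]
            ll_obs = _logistic_loglik_obs(eta_k, self._y)
            cond = np.bincount(self._gidx, weights=ll_obs, minlength=self.n_groups)
            prior = -0.5 * (uk / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            log_terms[k] = const[k] + cond + prior
            if need_grad:
                mus[k] = special.expit(eta_k)
        group_ll = np.log(np.sqrt(2.0) * tau) + special.logsumexp(log_terms, axis=0)
        ll = float(group_ll.sum())
        if not need_grad:
            return ll, None
        # posterior node weights per group
        log_p = log_terms - special.logsumexp(log_terms, axis=0, keepdims=True)
        p = np.exp(log_p)  # (K, G)
        mu_bar = (p[:, self._gidx] * mus).sum(axis=0)
        grad_beta = self._X.T @ (self._y - mu_bar)
        dsig = (u_nodes ** 2 / sigma ** 3) - 1.0 / sigma  # (K, G)
        grad_sigma = float((p * dsig).sum())
        return ll, np.concatenate([grad_beta, [grad_sigma]])

    # -- fitting ---------------------------------------------------------
    def fit(self, re_sd=None, quad_points: int = 15, start_params=None,
            maxiter: int = 300) -> "MixedLogitResults":
        """Maximise the marginal likelihood.

        Parameters
        ----------
        re_sd : float, optional
            Fix the random-intercept SD (0 gives plain logistic regression,
            solved exactly by IRLS).  Default: estimate it.
        quad_points : int
            Gauss-Hermite nodes (>= 9).
        """
        if quad_points < 9:
            raise ValueError("use at least 9 quadrature nodes")
        beta0, cov0, ll0, _ = irls_logistic(self._X, self._y)

        if re_sd is not None and re_sd < 1e-8:
            return self._results(beta0, 0.0, cov0, None, ll0, True, 0.0,
                                 sigma_fixed=True, quad_points=quad_points)

        if start_params is None:
            start = np.concatenate([beta0, [0.5 if re_sd is None else re_sd]])
        else:
            start = np.asarray(start_params, dtype=float)

        if re_sd is not None:
            def negll(b):
                ll, g = self._eval(np.concatenate([b, [re_sd]]), quad_points,
                                   need_grad=True)
                return -ll, -g[:-1]
            res = optimize.minimize(negll, start[:-1], method="L-BFGS-B",
                                    jac=True,
                                    options={"maxiter": maxiter, "ftol": 1e-12,
                                             "gtol": 1e-6})
            params = np.concatenate([res.x, [re_sd]])
        else:
            bounds = [(None, None)] * self.k_fe + [(1e-6, None)]

            def negll(p):
                ll, g = self._eval(p, quad_points, need_grad=True)
                return -ll, -g
            res = optimize.minimize(negll, start, method="L-BFGS-B",
                                    jac=True, bounds=bounds,
                                    options={"maxiter": maxiter, "ftol": 1e-12,
                                             "gtol": 1e-6})
            params = res.x
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        if not res.success:
            logger.warning("mixed logit optimizer: %s", res.message)
        beta, sigma = params[:-1], params[-1]
        llf = -float(res.fun)

        # observed information via central differences of the score
        free = params if re_sd is None else params[:-1]

        def neg_score(p):
            full = p if re_sd is None else np.concatenate([p, [re_sd]])
            g = self.score(full, quad_points)
            return -(g if re_sd is None else g[:-1])

        hess = _hessian_from_grad(neg_score, free)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        if not np.all(np.diag(cov) > 0):
            cov = np.linalg.pinv(hess)
        return self._results(beta, sigma, cov[: self.k_fe, : self.k_fe],
                             cov, llf, bool(res.success), grad_norm,
                             sigma_fixed=re_sd is not None,
                             quad_points=quad_points)

    def _results(self, beta, sigma, cov_beta, cov_full, llf, converged,
                 grad_norm, sigma_fixed, quad_points):
        warns = []
        if np.any(np.abs(beta) > SEPARATION_THRESHOLD):
            bad = [self.exog_names[i] for i in np.flatnonzero(
                np.abs(beta) > SEPARATION_THRESHOLD)]
            warns.append(f"possible quasi-separation: |estimate| > "
                         f"{SEPARATION_THRESHOLD} for {bad}")
            logger.warning(warns[-1])
        if not converged:
            warns.append("optimizer did not report convergence")
        sigma_se = np.nan
        if cov_full is not None and not sigma_fixed and cov_full.shape[0] == self.k_fe + 1:
            v = cov_full[-1, -1]
            sigma_se = float(np.sqrt(v)) if v > 0 else np.nan
        return MixedLogitResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names,
                                    columns=self.exog_names),
            re_sd=float(sigma), re_sd_se=sigma_se, llf=float(llf),
            converged=converged, grad_norm=grad_norm,
            sigma_fixed=sigma_fixed, quad_points=quad_points,
            warnings=warns,
        )


def _hessian_from_grad(grad_fn, x, eps: float = 1e-5) -> np.ndarray:
    """Symmetrised central-difference Jacobian of a gradient function."""
    k = len(x)
    h = eps * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i] = (grad_fn(x + ei) - grad_fn(x - ei)) / (2.0 * h[i])
    return 0.5 * (hess + hess.T)


@dataclass
class MixedLogitResults:
    """Estimates and diagnostics from a MixedLogit fit."""

    model: MixedLogit
    params: pd.Series
    cov_params: pd.DataFrame
    re_sd: float
    re_sd_se: float
    llf: float
    converged: bool
    grad_norm: float
    sigma_fixed: bool
    quad_points: int
    warnings: list = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.tvalues)),
                         index=self.params.index)

    @property
    def re_var(self) -> float:
        return self.re_sd ** 2

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_groups(self) -> int:
        return self.model.n_groups

    @property
    def df_model(self) -> int:
        # fixed effects plus the random-intercept variance (when estimated)
        return len(self.params) + (0 if self.sigma_fixed else 1)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    def fixed_linear_predictor(self) -> np.ndarray:
        return self.model.exog.to_numpy(dtype=float) @ self.params.to_numpy()

    def predict_response(self, scenario: dict, spec: ModelSpec) -> float:
        """Population-level probability (random intercept at 0) for a scenario."""
        row = scenario_frame(scenario)
        X, _, _ = build_design(row, spec, columns=self.params.index)
        eta = (X.to_numpy() @ self.params.to_numpy()).item()
        return float(special.expit(eta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "z": self.tvalues, "p": self.pvalues,
        })

    def summary(self) -> str:
        lines = [
            "Mixed logistic regression (random intercept)",
            f"  observations: {self.nobs}   groups: {self.n_groups}",
            f"  logLik: {self.llf:.4f}   AIC: {self.aic:.4f}",
            f"  random-intercept SD: {self.re_sd:.4f}"
            + ("" if self.sigma_fixed else f" (SE {self.re_sd_se:.4f})"),
            f"  converged: {self.converged} (max |grad| {self.grad_norm:.2e})",
            "",
            f"  {'term':<55s}{'estimate':>11s}{'se':>10s}{'z':>8s}{'p':>10s}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<55s}{self.params[name]:>11.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>10.4g}"
            )
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# diagnostics and selection


def check_collinearity(X: pd.DataFrame, term_map: dict | None = None):
    """Pearson correlations and generalised VIFs for a design matrix.

    Parameters
    ----------
    X : DataFrame
        Design matrix (the intercept column is ignored).
    term_map : dict, optional
        term -> list of column names (as produced by ``build_design``);
        defaults to one term per column.

    Returns
    -------
    corr : DataFrame of pairwise Pearson correlations.
    gvif : DataFrame with columns df, GVIF, GVIF^(1/(2*df)) per term.
    """
    cols = [c for c in X.columns if c != INTERCEPT]
    Xc = X[cols].to_numpy(dtype=float)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        dead = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant design column(s): {dead}")
    R = np.corrcoef(Xc, rowvar=False)
    if np.linalg.matrix_rank(R, tol=1e-10) < len(cols):
        raise ValueError("rank-deficient design matrix")
    corr = pd.DataFrame(R, index=cols, columns=cols)
    if term_map is None:
        term_map = {c: [c] for c in cols}
    det_R = np.linalg.det(R)
    rows = {}
    for term, names in term_map.items():
        idx = [cols.index(n) for n in names if n in cols]
        if not idx:
            continue
        other = [i for i in range(len(cols)) if i not in idx]
        det1 = np.linalg.det(R[np.ix_(idx, idx)])
        det2 = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        gvif = det1 * det2 / det_R
        dfree = len(idx)
        rows[term] = {"df": dfree, "GVIF": gvif,
                      "GVIF^(1/2df)": gvif ** (1.0 / (2.0 * dfree))}
    return corr, pd.DataFrame(rows).T


def aic_select(candidates: list, names=None, threshold: float = 10.0):
    """Pick the lowest-AIC fit; decisive iff runner-up is >= ``threshold`` worse.

    All candidates must be fitted on the same number of observations.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate fits")
    nobs = {c.nobs for c in candidates}
    if len(nobs) != 1:
        raise ValueError("candidates fitted on differing observation counts")
    if names is None:
        names = [f"model_{i}" for i in range(len(candidates))]
    aics = np.array([c.aic for c in candidates])
    order = np.argsort(aics, kind="stable")
    winner = candidates[order[0]]
    delta = aics - aics[order[0]]
    table = pd.DataFrame({"model": names, "AIC": aics, "dAIC": delta}
                         ).sort_values("AIC", kind="stable").reset_index(drop=True)
    gap = aics[order[1]] - aics[order[0]]
    if gap == 0:
        logger.info("AIC tie between top candidates")
    return winner, table, bool(gap >= threshold)


LOGISTIC_RESID_VAR = np.pi ** 2 / 3.0


def nakagawa_r2_from_variances(var_fixed: float, var_re: float):
    """Closed-form Nakagawa marginal/conditional R^2 for a logistic GLMM."""
    denom = var_fixed + var_re + LOGISTIC_RESID_VAR
    return var_fixed / denom, (var_fixed + var_re) / denom


def r2_nakagawa(result: MixedLogitResults):
    """Marginal and conditional R^2 of a fitted mixed logit.

    The fixed-effect variance is the sample variance of the fixed-effect
    linear predictor over the modelled observations; the residual variance
    of the logit link is pi^2/3.
    """
    var_f = float(np.var(result.fixed_linear_predictor(), ddof=1))
    return nakagawa_r2_from_variances(var_f, result.re_var)
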