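"""Mixed-effects logistic regression via Laplace-approximated ML.

The model for a binary outcome y_ij of group (subject) i in trial j is

    logit P(y_ij = 1) = x_ij' beta + z_ij' u_i,       u_i ~ N(0, Sigma),

with one fixed predictor plus intercept, and random structure either a
subject intercept (q = 1) or intercept + slope on the predictor (q = 2,
correlation estimated).  The marginal likelihood integrates the random
effects out with a Laplace approximation around each group's posterior
mode; the mode is found by Newton iterations (the penalized logistic
log-likelihood is strictly concave).  Fixed-effect standard errors come
from the numerically differentiated Hessian of the Laplace log-likelihood
and give Wald z-tests.

Marginal and conditional coefficients of determination follow the
latent-scale variance decomposition for logistic models:

    R2m = s2_f / (s2_f + s2_r + pi^2/3)
    R2c = (s2_f + s2_r) / (s2_f + s2_r + pi^2/3)

where s2_f is the variance of the fixed-effect linear predictor over the
data and s2_r the random-effect variance on the link scale (for slope
models, the per-observation z' Sigma z averaged over the design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

DISTRIBUTION_VARIANCE = np.pi**2 / 3.0  # logistic link


def nakagawa_r2(sigma2_fixed: float, sigma2_random: float,
                sigma2_dist: float = DISTRIBUTION_VARIANCE) -> tuple[float, float]:
    """Latent-scale (marginal, conditional) R^2 from variance components."""
    if min(sigma2_fixed, sigma2_random, sigma2_dist) < 0:
        raise ValueError("variance components must be nonnegative")
    denom = sigma2_fixed + sigma2_random + sigma2_dist
    return sigma2_fixed / denom, (sigma2_fixed + sigma2_random) / denom


class ConvergenceWarning(UserWarning):
    pass


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x):
    """log(1 + exp(x)), overflow-safe."""
    out = np.empty_like(x, dtype=float)
    small = x < 33
    out[small] = np.log1p(np.exp(x[small]))
    out[~small] = x[~small]
    return out


def _pooled_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Plain Newton logistic regression (starting values + GLM reduction)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        # lstsq tolerates degenerate designs (e.g. a constant predictor)
        step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


@dataclass
class MixedLogit:
    """Mixed-effects logistic model with one fixed predictor.

    Parameters
    ----------
    endog : (n,) 0/1 outcomes.
    exog : (n,) predictor values (z-scored upstream).
    groups : (n,) group labels (subjects).
    random_slope : include a random slope on the predictor (with correlated
        random intercept) in addition to the random intercept.
    """

    endog: np.ndarray
    exog: np.ndarray
    groups: np.ndarray
    random_slope: bool = False

    def __post_init__(self) -> None:
        self.endog = np.asarray(self.endog, dtype=float).ravel()
        self.exog = np.asarray(self.exog, dtype=float).ravel()
        if self.endog.shape != self.exog.shape:
            raise ValueError("endog and exog must have equal length")
        classes = np.unique(self.endog)
        if not np.isin(classes, [0.0, 1.0]).all():
            raise ValueError("endog must be coded 0/1")
        if classes.size < 2:
            raise ValueError("both outcome classes must be present")
        labels, idx = np.unique(np.asarray(self.groups), return_inverse=True)
        if labels.size < 2:
            raise ValueError("need at least 2 groups")
        self.group_labels = labels
        self._gidx = [np.flatnonzero(idx == g) for g in range(labels.size)]
        self.n_obs = self.endog.size
        self.n_groups = labels.size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictor: str,
                       group: str, random_slope: bool = False) -> "MixedLogit":
        sub = data[[response, predictor, group]].dropna()
        return cls(sub[response].to_numpy(), sub[predictor].to_numpy(),
                   sub[group].to_numpy(), random_slope=random_slope)

    # -- parameterization: theta = (b0, b1, log s0[, log s1, atanh rho]) --

    def _nq(self) -> int:
        return 2 if self.random_slope else 1

    def _chol(self, theta: np.ndarray) -> np.ndarray:
        """Lower Cholesky factor of Sigma from the unconstrained tail."""
        s0 = np.exp(theta[2])
        if not self.random_slope:
            return np.array([[s0]])
        s1 = np.exp(theta[3])
        rho = np.tanh(theta[4])
        return np.array([[s0, 0.0],
                         [rho * s1, np.sqrt(max(1 - rho**2, 1e-12)) * s1]])

    def _group_mode(self, yg, Xg, Zg, beta, L):
        """Newton mode of the penalized log-likelihood in b = L v (v-space)."""
        q = L.shape[0]
        v = np.zeros(q)
        off = Xg @ beta
        ZL = Zg @ L
        for _ in range(50):
            eta = off + ZL @ v
            mu = _sigmoid(eta)
            grad = ZL.T @ (yg - mu) - v
            w = np.clip(mu * (1 - mu), 1e-12, None)
            hess = (ZL * w[:, None]).T @ ZL + np.eye(q)
            step = np.linalg.solve(hess, grad)
            v = v + step
            if np.abs(step).max() < 1e-10:
                break
        eta = off + ZL @ v
        ll = float(np.sum(yg * eta - _log1pexp(eta))) - 0.5 * float(v @ v)
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        hess = (ZL * w[:, None]).T @ ZL + np.eye(q)
        sign, logdet = np.linalg.slogdet(hess)
        return v, ll - 0.5 * logdet

    def loglike(self, theta: np.ndarray) -> float:
        """Laplace-approximated marginal log-likelihood."""
        beta = theta[:2]
        L = self._chol(theta)
        total = 0.0
        for gi in self._gidx:
            yg = self.endog[gi]
            Xg = np.column_stack([np.ones(gi.size), self.exog[gi]])
            Zg = Xg[:, : self._nq()]
            _, ll = self._group_mode(yg, Xg, Zg, beta, L)
            total += ll
        return total

    def fit(self, start=None, gtol: float = 1e-8, maxiter: int = 200,
            allow_fallback: bool = True) -> "MixedLogitResults":
        """Maximize the Laplace marginal likelihood (BFGS, pooled-GLM start)."""
        X = np.column_stack([np.ones(self.n_obs), self.exog])
        beta0 = _pooled_logit(X, self.endog)
        separation = bool(np.abs(beta0).max() > 15)
        if separation:
            warnings.warn("possible complete separation; coefficients unstable",
                          ConvergenceWarning, stacklevel=2)
        if start is None:
            start = np.concatenate([
                beta0, [np.log(0.5)] + ([np.log(0.25), 0.0] if self.random_slope else []),
            ])
        res = optimize.minimize(
            lambda th: -self.loglike(th), np.asarray(start, dtype=float),
            method="BFGS", options={"gtol": gtol, "maxiter": maxiter},
        )
        theta = res.x
        # BFGS with finite-difference gradients often reports precision loss
        # at the optimum; accept when the gradient is effectively zero
        grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * max(
            1.0, abs(res.fun)
        )
        converged = bool(res.success or grad_ok)
        singular = bool(np.any(theta[2:4 if self.random_slope else 3] < np.log(1e-4)))
        if self.random_slope and allow_fallback and (not converged or singular):
            warnings.warn(
                "random-slope fit singular or non-converged; "
                "falling back to random intercept only",
                ConvergenceWarning, stacklevel=2,
            )
            fallback = MixedLogit(self.endog, self.exog, self.groups,
                                  random_slope=False)
            out = fallback.fit(gtol=gtol, maxiter=maxiter)
            out.fell_back = True
            return out
        return MixedLogitResults(self, theta, -res.fun, converged,
                                 separation=separation)


@dataclass
class MixedLogitResults:
    """Estimates, uncertainties and fit diagnostics of a MixedLogit fit."""

    model: MixedLogit
    theta: np.ndarray
    llf: float
    converged: bool
    separation: bool = False
    fell_back: bool = False
    _bse: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def params(self) -> np.ndarray:
        """Fixed effects (intercept, slope) on the log-odds scale."""
        return self.theta[:2]

    @property
    def cov_re(self) -> np.ndarray:
        L = self.model._chol(self.theta)
        return L @ L.T

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_groups(self) -> int:
        return self.model.n_groups

    def _hessian(self, eps: float = 1e-4) -> np.ndarray:
        """Numeric Hessian of the marginal log-likelihood at the optimum."""
        th = self.theta
        k = th.size
        H = np.zeros((k, k))
        f = self.model.loglike
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = eps
                ej = np.zeros(k); ej[j] = eps
                fpp = f(th + ei + ej)
                fpm = f(th + ei - ej)
                fmp = f(th - ei + ej)
                fmm = f(th - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
        return H

    @property
    def bse(self) -> np.ndarray:
        if self._bse is None:
            H = self._hessian()
            try:
                cov = np.linalg.inv(-H)
                var = np.clip(np.diag(cov)[:2], 0.0, None)
            except np.linalg.LinAlgError:
                var = np.full(2, np.nan)
            self._bse = np.sqrt(var)
        return self._bse

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald z-test p-values for the fixed effects."""
        return 2.0 * norm.sf(np.abs(self.tvalues))

    def fittedvalues(self) -> np.ndarray:
        """Population-level fitted probabilities (random effects at 0)."""
        eta = self.params[0] + self.params[1] * self.model.exog
        return _sigmoid(eta)

    # -- variance decomposition --

    def variance_components(self) -> dict:
        eta_fixed = self.params[0] + self.params[1] * self.model.exog
        s2f = float(np.var(eta_fixed))
        S = self.cov_re
        if self.model.random_slope:
            Z = np.column_stack([np.ones(self.n_obs), self.model.exog])
            s2r = float(np.mean(np.einsum("ij,jk,ik->i", Z, S, Z)))
        else:
            s2r = float(S[0, 0])
        return {"sigma2_fixed": s2f, "sigma2_random": s2r,
                "sigma2_dist": DISTRIBUTION_VARIANCE}

    def r2_nakagawa(self) -> tuple[float, float]:
        """(marginal, conditional) R^2 on the latent logit scale."""
        if not self.converged:
            raise RuntimeError("R2 undefined for a non-converged fit")
        v = self.variance_components()
        r2m, r2c = nakagawa_r2(v["sigma2_fixed"], v["sigma2_random"],
                               v["sigma2_dist"])
        return float(r2m), float(r2c)

    def summary(self) -> str:
        v = self.variance_components()
        r2m, r2c = self.r2_nakagawa() if self.converged else (np.nan, np.nan)
        lines = [
            "Mixed-effects logistic regression (Laplace ML)",
            "=" * 54,
            f"Observations: {self.n_obs:>6}    Groups: {self.n_groups:>4}    "
            f"Converged: {self.converged}",
            f"Random structure: "
            f"{'intercept + slope' if self.model.random_slope else 'intercept'}"
            + ("  [fell back from slope]" if self.fell_back else ""),
            f"Log-likelihood (marginal): {self.llf:.3f}",
            "-" * 54,
            f"{'':12}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>10}",
        ]
        names = ["Intercept", "x"]
        for name, b, se, z, p in zip(names, self.params, self.bse,
                                     self.tvalues, self.pvalues):
            lines.append(f"{name:<12}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>10.3g}")
        lines.append("-" * 54)
        S = self.cov_re
        lines.append(f"Var(intercept): {S[0, 0]:.4f}")
        if self.model.random_slope:
            rho = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]) if S[0, 0] * S[1, 1] > 0 else np.nan
            lines.append(f"Var(slope):     {S[1, 1]:.4f}   Corr: {rho:.3f}")
        lines.append(
            f"sigma2_f={v['sigma2_fixed']:.4f}  sigma2_r={v['sigma2_random']:.4f}  "
            f"R2m={r2m:.4f}  R2c={r2c:.4f}"
        )
        return "\n".join(lines)
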