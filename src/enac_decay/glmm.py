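"""Random-intercept gamma GLMM fitted by Gauss-Hermite maximum likelihood.

The model for a positive response :math:`y_{ij}` (observation *j* of
group *i*, here: aridity index of one occurrence of one species) is

.. math::

    y_{ij} \\mid b_i \\sim \\mathrm{Gamma}(\\nu,\\ \\mu_{ij}/\\nu), \\qquad
    \\log \\mu_{ij} = x_{ij}^T \\beta + b_i, \\qquad
    b_i \\sim N(0, \\sigma^2),

with shape :math:`\\nu` shared across observations.  The marginal
likelihood integrates the random intercept out per group with
Gauss-Hermite quadrature (exact enough for one-dimensional integrals at
~30 nodes) and all parameters — fixed effects, ``log sigma`` and ``log
shape`` — are maximized jointly by ML, so likelihood-ratio tests between
nested fixed-effect structures are valid.

An optional second nesting level (groups within superclusters, e.g.
species within clade) adds an outer quadrature; a fit whose outer
variance collapses to zero is flagged singular so callers can fall back
to the single-level model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .errors import DomainError

_SINGULAR_SD = 1e-3


@dataclass
class GammaGlmmFit:
    beta: np.ndarray
    sigma: float                 # random-intercept SD (log scale)
    shape: float                 # gamma shape
    sigma_outer: Optional[float] # second-level SD, None if single-level
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool

    @property
    def random_effect_variance(self) -> float:
        var = self.sigma ** 2
        if self.sigma_outer is not None:
            var += self.sigma_outer ** 2
        return var


def _prepare(y, X, groups):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(y <= 0):
        raise DomainError("gamma responses must be strictly positive")
    codes, idx = np.unique(np.asarray(groups), return_inverse=True)
    order = np.argsort(idx, kind="stable")
    y, X, idx = y[order], X[order], idx[order]
    starts = np.searchsorted(idx, np.arange(len(codes)))
    return y, X, idx, starts, len(codes), order


def _suffstats(y, X, beta, idx, n_groups):
    """Per-group sufficient statistics of the gamma log-likelihood.

    Because the random intercept shifts every observation of a group by
    the same amount, the group's conditional log-likelihood depends on
    the data only through ``n_i``, ``sum(log y)``, ``sum(eta)`` and
    ``S_i = sum(y * exp(-eta))``.
    """
    eta = X @ beta
    n_i = np.bincount(idx, minlength=n_groups).astype(float)
    l_i = np.bincount(idx, weights=np.log(y), minlength=n_groups)
    e_i = np.bincount(idx, weights=eta, minlength=n_groups)
    s_i = np.bincount(idx, weights=y * np.exp(-eta), minlength=n_groups)
    return n_i, l_i, e_i, s_i


def _agq_group_loglik(n_i, l_i, e_i, s_i, shape, sigma, gh_t, gh_logw):
    """Adaptive Gauss-Hermite marginal log-likelihood per group.

    The integrand ``exp(h_i(b))`` — conditional likelihood times the
    N(0, sigma^2) density — is sharply peaked once a group has more than
    a handful of observations, so plain quadrature centered at zero is
    badly inaccurate.  Each group's integral is therefore centered at its
    posterior mode (Newton on the concave ``h_i``) and scaled by the
    curvature there, the standard adaptive scheme.
    """
    k = shape
    var = sigma ** 2
    const_i = (
        n_i * (k * np.log(k) - special.gammaln(k))
        + (k - 1.0) * l_i
        - k * e_i
        - np.log(sigma)
        - 0.5 * np.log(2.0 * np.pi)
    )

    def h(b):
        return const_i - k * n_i * b - k * np.exp(-b) * s_i - b * b / (2 * var)

    # Newton for the mode: h' = -k n + k e^{-b} S - b/var, h'' < 0 everywhere
    b = np.zeros_like(n_i)
    for _ in range(50):
        eb = np.exp(-b)
        g1 = -k * n_i + k * eb * s_i - b / var
        g2 = -k * eb * s_i - 1.0 / var
        step = g1 / g2
        b = b - np.clip(step, -5.0, 5.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    tau = 1.0 / np.sqrt(k * np.exp(-b) * s_i + 1.0 / var)
    nodes = b[None, :] + np.sqrt(2.0) * tau[None, :] * gh_t[:, None]
    # log integral = log(sqrt(2) tau) + LSE_q[log w_q + t_q^2 + h(node_q)]
    stack = (gh_logw + gh_t ** 2)[:, None] + h(nodes)
    return (
        0.5 * np.log(2.0) + np.log(tau)
        + special.logsumexp(stack, axis=0)
    )


_LOG_SIGMA_BOUNDS = (-10.0, 5.0)
_LOG_SHAPE_BOUNDS = (-10.0, 15.0)  # upper bound caps degenerate zero-variance data


def _marginal_loglik(params, y, X, idx, n_groups, gh_t, gh_logw):
    p = X.shape[1]
    beta = params[:p]
    sigma = np.exp(np.clip(params[p], *_LOG_SIGMA_BOUNDS))
    shape = np.exp(np.clip(params[p + 1], *_LOG_SHAPE_BOUNDS))
    n_i, l_i, e_i, s_i = _suffstats(y, X, beta, idx, n_groups)
    return float(np.sum(
        _agq_group_loglik(n_i, l_i, e_i, s_i, shape, sigma, gh_t, gh_logw)
    ))


def _marginal_loglik_nested(params, y, X, idx, n_groups, outer_of_group,
                            n_outer, gh_t, gh_logw):
    """Two-level model: outer intercepts integrated by plain quadrature
    (few superclusters, smooth integrand), inner ones adaptively."""
    p = X.shape[1]
    beta = params[:p]
    sigma = np.exp(np.clip(params[p], *_LOG_SIGMA_BOUNDS))
    shape = np.exp(np.clip(params[p + 1], *_LOG_SHAPE_BOUNDS))
    sigma_outer = np.exp(np.clip(params[p + 2], *_LOG_SIGMA_BOUNDS))
    n_i, l_i, e_i, s_i = _suffstats(y, X, beta, idx, n_groups)
    rows = []
    outer_logw = gh_logw - 0.5 * np.log(np.pi)
    for u, lw_u in zip(np.sqrt(2.0) * sigma_outer * gh_t, outer_logw):
        # offset u shifts each group's eta: sum(eta) += n u, S *= e^{-u}
        inner = _agq_group_loglik(
            n_i, l_i, e_i + n_i * u, s_i * np.exp(-u),
            shape, sigma, gh_t, gh_logw,
        )
        per_outer = np.bincount(outer_of_group, weights=inner,
                                minlength=n_outer)
        rows.append(lw_u + per_outer)
    return float(np.sum(special.logsumexp(np.vstack(rows), axis=0)))


def fit_gamma_glmm(
    y: Sequence[float],
    X: Sequence[Sequence[float]],
    groups: Sequence,
    *,
    outer: Optional[Sequence] = None,
    nodes: int = 30,
    start: Optional[Sequence[float]] = None,
) -> GammaGlmmFit:
    """ML fit of the gamma random-intercept GLMM (log link).

    ``X`` must include the intercept column.  With ``outer`` given
    (a supercluster label per observation, constant within group), a
    nested two-level random-intercept model is fitted; a collapsed outer
    variance marks the fit ``singular``.  ``start`` optionally warm-starts
    the optimizer with ``(beta..., log sigma, log shape[, log sigma_outer])``.
    """
    y, X, idx, starts, n_groups, order = _prepare(y, X, groups)
    gh_t, gh_w = np.polynomial.hermite.hermgauss(nodes)
    gh_logw = np.log(gh_w)  # plain log-weights; adaptive scheme needs no 1/sqrt(pi)

    # moment-based starting values
    logy = np.log(y)
    group_means = np.bincount(idx, weights=logy) / np.bincount(idx)
    beta0 = np.zeros(X.shape[1])
    beta0[np.argmax(np.all(X == 1.0, axis=0))] = float(np.mean(logy))
    sigma0 = max(float(np.std(group_means)), 0.05)
    resid_var = max(float(np.mean((logy - group_means[idx]) ** 2)), 1e-3)
    shape0 = max(1.0 / resid_var, 0.1)

    if outer is None:
        if start is not None:
            x0 = np.asarray(start, dtype=float)
        else:
            x0 = np.concatenate([beta0, [np.log(sigma0), np.log(shape0)]])

        def nll(p):
            return -_marginal_loglik(p, y, X, idx, n_groups, gh_t, gh_logw)

        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        # quasi-Newton with numerical gradients can stall on this surface;
        # a simplex polish from its solution is cheap and reliable
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-7,
                                          "fatol": 1e-9})
        res = res2 if res2.fun <= res.fun else res
        p = X.shape[1]
        sigma = float(np.exp(np.clip(res.x[p], *_LOG_SIGMA_BOUNDS)))
        return GammaGlmmFit(
            beta=res.x[:p].copy(),
            sigma=sigma,
            shape=float(np.exp(np.clip(res.x[p + 1], *_LOG_SHAPE_BOUNDS))),
            sigma_outer=None,
            loglik=float(-res.fun),
            n_obs=len(y),
            n_groups=n_groups,
            converged=bool(res.success or res.fun < np.inf),
            singular=sigma < _SINGULAR_SD,
        )

    outer_arr = np.asarray(outer)[order]
    outer_of_group_labels = [outer_arr[s] for s in starts]
    ocodes, outer_of_group = np.unique(outer_of_group_labels,
                                       return_inverse=True)
    if start is not None:
        x0 = np.asarray(start, dtype=float)
    else:
        x0 = np.concatenate(
            [beta0,
             [np.log(sigma0), np.log(shape0), np.log(max(sigma0 / 2, 0.02))]]
        )

    def nll(p):
        return -_marginal_loglik_nested(
            p, y, X, idx, n_groups, outer_of_group, len(ocodes), gh_t, gh_logw
        )

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 6000, "xatol": 1e-6,
                                     "fatol": 1e-8})
    p = X.shape[1]
    sigma = float(np.exp(np.clip(res.x[p], *_LOG_SIGMA_BOUNDS)))
    sigma_outer = float(np.exp(np.clip(res.x[p + 2], *_LOG_SIGMA_BOUNDS)))
    return GammaGlmmFit(
        beta=res.x[:p].copy(),
        sigma=sigma,
        shape=float(np.exp(np.clip(res.x[p + 1], *_LOG_SHAPE_BOUNDS))),
        sigma_outer=sigma_outer,
        loglik=float(-res.fun),
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        singular=sigma_outer < _SINGULAR_SD or sigma < _SINGULAR_SD,
    )


def nakagawa_r2(fit: GammaGlmmFit, X: np.ndarray) -> tuple[float, float]:
    """Marginal and conditional r² by latent-scale variance decomposition.

    The fixed-effect variance is the variance of the linear predictor,
    the random-effect variance the summed intercept variances, and the
    observation-level variance of a log-link gamma model is
    ``trigamma(shape)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    var_f = float(np.var(X @ fit.beta))
    var_r = fit.random_effect_variance
    var_e = float(special.polygamma(1, fit.shape))
    total = var_f + var_r + var_e
    return var_f / total, (var_f + var_r) / total


def lrt(fit_null: GammaGlmmFit, fit_full: GammaGlmmFit, df: int = 1):
    """Likelihood-ratio chi-square and p-value between nested ML fits."""
    from scipy.stats import chi2

    stat = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    return stat, float(chi2.sf(stat, df))
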