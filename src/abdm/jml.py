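"""Joint maximum likelihood (JML) for the ABDM at fixed c.

All item and person effects are point-estimated simultaneously by maximising
the joint log-likelihood.  Setting the three partial derivatives (with
respect to beta_i, theta_p, alpha~_i) to zero yields closed-form fixed-point
estimators, iterated block-wise until the log-likelihood stabilises.  The
likelihood depends on the effects only through (beta_i + theta_p) * alpha~_i,
leaving a location shift between beta and theta and a common rescaling of
(beta, theta) against alpha~ unidentified; after every sweep the person
effects are projected back to mean 0 / variance 1 by the exactly
likelihood-preserving transformation
(beta, theta, alpha~) -> ((beta + mean)/sd, (theta - mean)/sd, alpha~ * sd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import log_density_abdm
from .simulate import EffectSet, ResponseMatrix

__all__ = [
    "JmlConfig",
    "JmlResult",
    "score",
    "fit_jml",
    "count_parameters",
    "JointMLABDM",
]


@dataclass(frozen=True)
class JmlConfig:
    """JML settings: fixed c, sweep cap and relative log-likelihood tolerance."""

    c: float = 0.35
    max_sweeps: int = 500
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("c must be > 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class JmlResult:
    effects: EffectSet
    log_likelihood: float
    n_sweeps: int
    converged: bool
    trace: list


def score(data: ResponseMatrix, effects: EffectSet, c: float):
    """Gradient of the joint log-likelihood w.r.t. (beta, theta, alpha~).

    d/dbeta_i  = sum_p (x_ip - 1/2) alpha~_i / c - t_ip (beta_i+theta_p) alpha~_i^2
    d/dtheta_p = sum_i (x_ip - 1/2) alpha~_i / c - t_ip (beta_i+theta_p) alpha~_i^2
    d/dalpha~_i = sum_p (x_ip - 1/2)(beta_i+theta_p)/c - t_ip (beta_i+theta_p)^2 alpha~_i
    """
    xm = data.x - 0.5
    a = effects.alpha_tilde
    v = effects.drift()
    core = xm * a[:, None] / c - data.t * v * (a ** 2)[:, None]
    g_beta = core.sum(axis=1)
    g_theta = core.sum(axis=0)
    g_alpha = (xm * v / c - data.t * v ** 2 * a[:, None]).sum(axis=1)
    return g_beta, g_theta, g_alpha


def _loglik(data: ResponseMatrix, effects: EffectSet, c: float) -> float:
    return float(np.sum(log_density_abdm(
        data.t, data.x, effects.drift(), effects.diffusion(), c)))


def fit_jml(data: ResponseMatrix, config: JmlConfig | None = None) -> JmlResult:
    """Block-coordinate ascent on the fixed-point estimators.

    Each block update (beta | theta, alpha~), (theta | beta, alpha~),
    (alpha~ | beta, theta) is the exact maximiser of the concave per-block
    likelihood, so the log-likelihood is non-decreasing across sweeps up to
    the positivity clamp on alpha~.
    """
    config = config if config is not None else JmlConfig()
    c = config.c
    xm = data.x - 0.5
    t = data.t
    n_i, n_p = data.n_items, data.n_persons

    # start theta at standardised person accuracy, a crude but scale-correct guess
    acc = data.x.mean(axis=0)
    sd = acc.std()
    if sd < 1e-12:
        theta = np.zeros(n_p)
    else:
        theta = (acc - acc.mean()) / sd
    beta = np.zeros(n_i)
    alpha = np.ones(n_i)

    ll_prev = -np.inf
    trace = []
    n_decreases = 0
    converged = False
    sweeps = 0
    for sweep in range(1, config.max_sweeps + 1):
        sweeps = sweep
        # beta_i = [sum_p (x-1/2)/(c alpha~_i) - sum_p t theta] / sum_p t
        t_row = t.sum(axis=1)
        beta = (xm.sum(axis=1) / (c * alpha) - t @ theta) / t_row
        # theta_p = [sum_i (x-1/2) alpha~/c - sum_i t alpha~^2 beta] / sum_i t alpha~^2
        a2 = alpha ** 2
        denom = t.T @ a2
        theta = (xm.T @ alpha / c - t.T @ (a2 * beta)) / denom
        # alpha~_i = [sum_p (x-1/2)(beta+theta)/c] / sum_p t (beta+theta)^2
        v = beta[:, None] + theta[None, :]
        num = (xm * v).sum(axis=1) / c
        den = (t * v ** 2).sum(axis=1)
        alpha = num / den
        bad = alpha <= 0
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} item(s) have non-positive reciprocal-volatility "
                "estimates (at-or-below-chance items); clamped to 1e-6",
                RuntimeWarning,
            )
            alpha = np.where(bad, 1e-6, alpha)

        # likelihood-preserving projection onto mean(theta)=0, var(theta)=1
        shift = theta.mean()
        beta = beta + shift
        theta = theta - shift
        scale = theta.std()
        if scale < 1e-10:
            warnings.warn(
                "person effects have collapsed to a point; the var(theta)=1 "
                "identification cannot be imposed meaningfully",
                RuntimeWarning,
            )
            break
        beta = beta / scale
        theta = theta / scale
        alpha = alpha * scale

        eff = EffectSet(beta=beta, theta=theta, alpha_tilde=alpha)
        ll = _loglik(data, eff, c)
        trace.append(ll)
        if ll < ll_prev - 1e-9 * abs(ll_prev):
            n_decreases += 1
            if n_decreases > 3:
                raise RuntimeError(
                    f"JML diverged: log-likelihood decreased for {n_decreases} "
                    f"consecutive sweeps (trace tail: {trace[-5:]})")
        else:
            n_decreases = 0
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= config.tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll

    eff = EffectSet(beta=beta, theta=theta, alpha_tilde=alpha)
    return JmlResult(effects=eff, log_likelihood=trace[-1], n_sweeps=sweeps,
                     converged=converged, trace=trace)


def count_parameters(n_items: int, n_persons: int, mode: str) -> int:
    """Free-parameter counts used in information criteria.

    ``bayesian-random-effects``: 2 N_I item effects + N_P person effects + 4
    free population parameters (mu_I, sigma2_I, mu_A, gamma2_A; the person
    population mean/variance are fixed for identification) + 1 for c.
    ``jml-fixed-c``: 2 N_I + N_P effects - 2 identification constraints on
    theta + 1 for c.
    """
    if n_items < 1 or n_persons < 1:
        raise ValueError("counts must be >= 1")
    if mode == "bayesian-random-effects":
        return 2 * n_items + n_persons + 4 + 1
    if mode == "jml-fixed-c":
        return 2 * n_items + n_persons - 2 + 1
    raise ValueError(f"unknown mode {mode!r}")


class JointMLABDM(BaseEstimator):
    """Joint maximum-likelihood ABDM fit at fixed c (scikit-learn style).

    Attributes after :meth:`fit`: ``beta_``, ``theta_``, ``alpha_tilde_``,
    ``log_likelihood_``, ``n_sweeps_``, ``converged_``.
    """

    def __init__(self, c: float = 0.35, max_sweeps: int = 500, tol: float = 1e-9):
        self.c = c
        self.max_sweeps = max_sweeps
        self.tol = tol

    def fit(self, rt, accuracy):
        data = ResponseMatrix(t=np.asarray(rt, float), x=np.asarray(accuracy))
        res = fit_jml(data, JmlConfig(c=self.c, max_sweeps=self.max_sweeps,
                                      tol=self.tol))
        self.beta_ = res.effects.beta
        self.theta_ = res.effects.theta
        self.alpha_tilde_ = res.effects.alpha_tilde
        self.log_likelihood_ = res.log_likelihood
        self.n_sweeps_ = res.n_sweeps
        self.converged_ = res.converged
        self.result_ = res
        return self
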