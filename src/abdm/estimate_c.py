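"""Profile-likelihood estimation of the volatility-to-caution ratio c.

``c`` is the only ABDM parameter entering the series factor of the density,
and it is shared by all persons and items, so its estimation is a
one-dimensional search: for each candidate ``c`` the item/person effects are
integrated out approximately by a short Gibbs run, and the full ABDM
log-likelihood evaluated at the posterior-mean effects serves as the profile
objective.  A golden-section search (default: interval [0.1, 1], at most 10
iterations, stop when the relative log-likelihood change drops below 1%,
inner chain of 2000 draws with 1000 burn-in) maximises the profile; a
moment estimator from pooled accuracy and mean RT provides a cheap starting
value for gradient- or grid-based alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import MomentSummary, log_density_abdm, moment_estimate_c
from .gibbs import GibbsState, PopulationConfig, _run_single_chain
from .simulate import ResponseMatrix

__all__ = [
    "SearchConfig",
    "objective",
    "golden_section",
    "grid_search",
    "initial_value_from_moments",
    "VolatilityCautionSearch",
]

_INV_PHI = (math.sqrt(5.0) - 1.0) / 2.0  # bracket shrink factor per iteration


@dataclass(frozen=True)
class SearchConfig:
    """Golden-section settings (defaults match the reference analysis)."""

    interval: tuple[float, float] = (0.1, 1.0)
    max_iter: int = 10
    rel_tol: float = 0.01
    inner_iter: int = 2_000
    inner_burn: int = 1_000

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (0 < lo < hi):
            raise ValueError("interval must satisfy 0 < lower < upper")
        if not self.rel_tol > 0:
            raise ValueError("rel_tol must be > 0")
        if not self.inner_burn < self.inner_iter:
            raise ValueError("inner_burn must be smaller than inner_iter")


def _candidate_rng(root_seed: int, c: float) -> np.random.Generator:
    """Deterministic stream per candidate c, so the profile is a fixed
    function of c given the root seed."""
    key = int(round(c * 1e9)) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), key]))


def objective(data: ResponseMatrix, c_candidate: float, config: SearchConfig,
              root_seed: int, prior: PopulationConfig | None = None,
              init: GibbsState | None = None):
    """Profile log-likelihood at one candidate c.

    Runs a single inner Gibbs chain at fixed ``c_candidate`` and returns
    (log-likelihood at the posterior-mean effects, posterior-mean state for
    warm starting the next candidate).
    """
    if not c_candidate > 0:
        raise ValueError("c_candidate must be > 0")
    prior = prior if prior is not None else PopulationConfig()
    rng = _candidate_rng(root_seed, c_candidate)
    chain = _run_single_chain(
        data, prior, c_candidate, config.inner_iter, config.inner_burn, rng,
        jitter=0.0 if init is not None else 0.5, init=init,
    )
    eff = chain.posterior_mean_effects()
    ll = profile_loglik(data, eff, c_candidate)
    warm = GibbsState(
        beta=eff.beta, theta=eff.theta, alpha_tilde=eff.alpha_tilde,
        mu_I=float(chain.mu_I.mean()), sigma2_I=float(chain.sigma2_I.mean()),
        mu_P=float(chain.mu_P.mean()), sigma2_P=float(chain.sigma2_P.mean()),
        mu_A=float(chain.mu_A.mean()), gamma2_A=float(chain.gamma2_A.mean()),
    )
    return ll, warm


def profile_loglik(data: ResponseMatrix, effects, c: float) -> float:
    """Sum of log ABDM densities over all cells at the given effects."""
    v = effects.drift()
    s = effects.diffusion()
    ll = float(np.sum(log_density_abdm(data.t, data.x, v, s, c)))
    if not np.isfinite(ll):
        raise RuntimeError(f"non-finite profile log-likelihood at c={c:g}")
    return ll


def initial_value_from_moments(data: ResponseMatrix) -> float:
    """Moment-estimator start value from pooled accuracy and pooled mean RT."""
    p = float(np.mean(data.x))
    if not (0 < p < 1):
        raise ValueError("pooled accuracy must lie strictly inside (0, 1)")
    return moment_estimate_c(MomentSummary(p=p, M=float(np.mean(data.t))))


def _golden_section_max(f, lo: float, hi: float, max_iter: int, rel_tol: float):
    """Generic golden-section maximisation of a scalar function.

    Evaluates two interior points, then one new point per iteration while the
    bracket shrinks by (sqrt(5)-1)/2; stops at ``max_iter`` extra evaluations
    or when successive objective values change by less than ``rel_tol`` in
    relative terms.  Returns (best x, trace of (x, f(x)) in evaluation order).
    """
    trace: list[tuple[float, float]] = []

    def g(x):
        val = f(x)
        if not math.isfinite(val):
            raise RuntimeError(
                f"non-finite objective {val!r} at x={x:g}; trace so far: {trace}")
        trace.append((x, val))
        return val

    x1 = hi - _INV_PHI * (hi - lo)
    x2 = lo + _INV_PHI * (hi - lo)
    f1, f2 = g(x1), g(x2)
    prev = f2
    for _ in range(max_iter):
        if f1 > f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _INV_PHI * (hi - lo)
            new = f1 = g(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _INV_PHI * (hi - lo)
            new = f2 = g(x2)
        if abs(new - prev) < rel_tol * abs(prev):
            break
        prev = new
    best_x, _ = max(trace, key=lambda pair: pair[1])
    return best_x, trace


def golden_section(data: ResponseMatrix, search: SearchConfig | None = None,
                   root_seed: int = 0, prior: PopulationConfig | None = None,
                   warm_start: bool = True):
    """Golden-section maximisation of the profile log-likelihood.

    Assumes a unimodal objective on the interval.  Each iteration evaluates
    one new interior point and shrinks the bracket by (sqrt(5)-1)/2; the
    search stops at ``max_iter`` evaluations past the initial pair, or when
    the relative change in the objective between successive evaluations falls
    below ``rel_tol``.  Returns ``(c_hat, trace)`` where ``c_hat`` is the best
    evaluated candidate and ``trace`` lists ``(c, log-likelihood)`` in
    evaluation order.
    """
    search = search if search is not None else SearchConfig()
    lo, hi = search.interval
    warm: GibbsState | None = None

    def f(c):
        nonlocal warm
        ll, w = objective(data, c, search, root_seed, prior=prior,
                          init=warm if warm_start else None)
        if warm_start:
            warm = w
        return ll

    return _golden_section_max(f, lo, hi, search.max_iter, search.rel_tol)


def grid_search(data: ResponseMatrix, search: SearchConfig | None = None,
                root_seed: int = 0, prior: PopulationConfig | None = None,
                n_points: int = 11):
    """Fallback equally-spaced grid scan of the profile (unimodality-free)."""
    search = search if search is not None else SearchConfig()
    lo, hi = search.interval
    trace = []
    warm = None
    for c in np.linspace(lo, hi, n_points):
        ll, warm = objective(data, float(c), search, root_seed, prior=prior, init=warm)
        trace.append((float(c), ll))
    c_hat, _ = max(trace, key=lambda pair: pair[1])
    return c_hat, trace


class VolatilityCautionSearch(BaseEstimator):
    """Estimator interface for the golden-section search over c.

    Attributes after :meth:`fit`: ``c_`` (the estimate), ``trace_`` (list of
    evaluated ``(c, log-likelihood)`` pairs), ``initial_moment_c_`` (the
    moment-estimator start value, informational).
    """

    def __init__(self, interval: tuple[float, float] = (0.1, 1.0),
                 max_iter: int = 10, rel_tol: float = 0.01,
                 inner_iter: int = 2_000, inner_burn: int = 1_000,
                 prior: PopulationConfig | None = None, use_grid: bool = False,
                 grid_points: int = 11, random_state: int = 0):
        self.interval = interval
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.inner_iter = inner_iter
        self.inner_burn = inner_burn
        self.prior = prior
        self.use_grid = use_grid
        self.grid_points = grid_points
        self.random_state = random_state

    def fit(self, rt, accuracy):
        data = ResponseMatrix(t=np.asarray(rt, float), x=np.asarray(accuracy))
        search = SearchConfig(
            interval=tuple(self.interval), max_iter=self.max_iter,
            rel_tol=self.rel_tol, inner_iter=self.inner_iter,
            inner_burn=self.inner_burn,
        )
        self.initial_moment_c_ = initial_value_from_moments(data)
        seed = int(self.random_state) if self.random_state is not None else 0
        if self.use_grid:
            self.c_, self.trace_ = grid_search(
                data, search, root_seed=seed, prior=self.prior,
                n_points=self.grid_points)
        else:
            self.c_, self.trace_ = golden_section(
                data, search, root_seed=seed, prior=self.prior)
        return self
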