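"""Synthetic ABDM study data.

Generates complete persons-by-items response-time/accuracy designs from the
hierarchical ABDM: item easiness ``beta_i ~ N(mu_I, sigma2_I)``, person
ability ``theta_p ~ N(mu_P, sigma2_P)``, item reciprocal volatility
``alpha~_i ~ N(mu_A, gamma2_A)`` truncated below, with per-cell drift
``v_ip = beta_i + theta_p``, diffusion coefficient ``s_ip = 1/alpha~_i`` and
a shared volatility-to-caution ratio ``c``.  The default configuration is the
reference simulation design used throughout this package: 120 persons, 70
items, mu_I = 1, sigma2_I = 1, mu_P = 0, sigma2_P = 1, mu_A = 1,
gamma2_A = 1/2 with alpha~ truncated at 1/2, and c = 0.35.

Response times are drawn by inverting the conditional first-passage-time CDF
on a log-spaced grid; given the choice, the decision-time law does not depend
on which boundary was hit, so the choice is Bernoulli with the closed-form
accuracy and the time is drawn from a density proportional to
``exp(-t v^2 / (2 s^2)) S(t, c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtri_exp

from .core import TrialParams, fpt_series

__all__ = [
    "GeneratingConfig",
    "EffectSet",
    "ResponseMatrix",
    "PAPER_CONFIG",
    "truncated_normal",
    "draw_effects",
    "sample_trial",
    "sample_matrix",
    "generate_study",
    "random_walk_oracle",
]


@dataclass(frozen=True)
class GeneratingConfig:
    """Population configuration for study generation (defaults: see module docstring)."""

    n_persons: int = 120
    n_items: int = 70
    mu_I: float = 1.0
    sigma2_I: float = 1.0
    mu_P: float = 0.0
    sigma2_P: float = 1.0
    mu_A: float = 1.0
    gamma2_A: float = 0.5
    alpha_truncation_lower: float = 0.5
    c: float = 0.35
    t0: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_items < 1:
            raise ValueError("n_persons and n_items must be >= 1")
        for name in ("sigma2_I", "sigma2_P", "gamma2_A"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_truncation_lower < 0:
            raise ValueError("alpha_truncation_lower must be >= 0")
        if not self.c > 0:
            raise ValueError("c must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")


#: the reference generating configuration (120 persons x 70 items)
PAPER_CONFIG = GeneratingConfig()


@dataclass
class EffectSet:
    """Item and person effects: easiness, ability, reciprocal volatility."""

    beta: np.ndarray
    theta: np.ndarray
    alpha_tilde: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.alpha_tilde = np.asarray(self.alpha_tilde, dtype=float)
        if np.any(self.alpha_tilde <= 0):
            raise ValueError("alpha_tilde must be strictly positive")

    @property
    def n_items(self) -> int:
        return self.beta.size

    @property
    def n_persons(self) -> int:
        return self.theta.size

    def drift(self) -> np.ndarray:
        """v_ip = beta_i + theta_p, shape (n_items, n_persons)."""
        return self.beta[:, None] + self.theta[None, :]

    def diffusion(self) -> np.ndarray:
        """s_ip = 1/alpha~_i broadcast to (n_items, n_persons)."""
        return np.broadcast_to((1.0 / self.alpha_tilde)[:, None],
                               (self.n_items, self.n_persons))


@dataclass
class ResponseMatrix:
    """Complete n_items x n_persons response times and accuracies."""

    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=int)
        if self.t.shape != self.x.shape or self.t.ndim != 2:
            raise ValueError("t and x must be 2-D arrays of identical shape")
        if np.any(self.t <= 0):
            raise ValueError("all response times must be strictly positive")
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("accuracies must be 0 or 1")

    @property
    def n_items(self) -> int:
        return self.t.shape[0]

    @property
    def n_persons(self) -> int:
        return self.t.shape[1]


def truncated_normal(rng: np.random.Generator, mean, sd, lower) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated to [lower, inf).

    Uses inverse-CDF sampling through the log survival function, which stays
    accurate when the mean lies many standard deviations below the bound
    (no rejection loop, no tail underflow).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    shape = np.broadcast_shapes(mean.shape, sd.shape)
    a = (lower - mean) / sd
    u = rng.random(shape)
    # X = mean + sd * Phi^{-1}(1 - (1-u) * Phi(-a)) computed in log space
    z = -ndtri_exp(np.log1p(-u) + log_ndtr(-a))
    return mean + sd * z


def draw_effects(config: GeneratingConfig, rng: np.random.Generator) -> EffectSet:
    """Draw item/person effects from the population model."""
    beta = rng.normal(config.mu_I, np.sqrt(config.sigma2_I), config.n_items)
    theta = rng.normal(config.mu_P, np.sqrt(config.sigma2_P), config.n_persons)
    alpha = truncated_normal(
        rng,
        np.full(config.n_items, config.mu_A),
        np.full(config.n_items, np.sqrt(config.gamma2_A)),
        config.alpha_truncation_lower,
    )
    return EffectSet(beta=beta, theta=theta, alpha_tilde=alpha)


# ---------------------------------------------------------------------------
# response sampling by CDF inversion
# ---------------------------------------------------------------------------

def _time_grid(c: float, n_grid: int) -> np.ndarray:
    """Log-spaced grid covering the first-passage-time support for ratio c.

    The lower end puts < e^-45 of first-passage mass below it; the upper end
    truncates the exponential tail (rate >= pi^2 c^2 / 2) below e^-80.
    """
    t_lo = 1.0 / (8.0 * c ** 2 * 45.0)
    t_hi = 160.0 / (np.pi ** 2 * c ** 2)
    return np.geomspace(t_lo, t_hi, n_grid)


def sample_matrix(effects: EffectSet, c: float, rng: np.random.Generator,
                  n_grid: int = 1024) -> ResponseMatrix:
    """Sample one complete response matrix for the given effects."""
    v = effects.drift()
    s = effects.diffusion()
    shape = v.shape
    grid = _time_grid(c, n_grid)
    series = np.clip(fpt_series(grid, c), 0.0, None)
    log_series = np.where(series > 0, np.log(np.where(series > 0, series, 1.0)), -np.inf)

    rate = (v / s).ravel() ** 2 / 2.0
    x = (rng.random(shape) < 1.0 / (1.0 + np.exp(-v / (c * s)))).astype(int)
    u = rng.random(rate.size)

    t = np.empty(rate.size)
    dt = np.diff(grid)
    chunk = max(1, int(8e6 / n_grid))
    for lo in range(0, rate.size, chunk):
        logw = -np.outer(rate[lo:lo + chunk], grid) + log_series[None, :]
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        cdf = np.concatenate(
            [np.zeros((w.shape[0], 1)),
             np.cumsum(0.5 * (w[:, 1:] + w[:, :-1]) * dt[None, :], axis=1)],
            axis=1,
        )
        norm = cdf[:, -1:]
        if np.any(norm <= 0):
            i = int(np.nonzero(norm.ravel() <= 0)[0][0]) + lo
            raise RuntimeError(
                f"CDF inversion failed for cell {i}: v={v.ravel()[i]:g}, "
                f"s={s.ravel()[i]:g}, c={c:g}"
            )
        cdf /= norm
        uu = u[lo:lo + chunk]
        idx = np.clip((cdf < uu[:, None]).sum(axis=1), 1, n_grid - 1)
        r = np.arange(w.shape[0])
        c0, c1 = cdf[r, idx - 1], cdf[r, idx]
        frac = (uu - c0) / np.where(c1 > c0, c1 - c0, 1.0)
        t[lo:lo + chunk] = grid[idx - 1] + frac * (grid[idx] - grid[idx - 1])
    return ResponseMatrix(t=t.reshape(shape), x=x)


def sample_trial(params: TrialParams, rng: np.random.Generator,
                 size: int | None = None, n_grid: int = 2048):
    """Draw (t, x) for a single parameter setting.

    Returns scalars when ``size`` is None, else arrays of length ``size``.
    """
    n = 1 if size is None else int(size)
    # replicate the single cell across pseudo-persons to vectorise
    eff = EffectSet(beta=np.array([params.v]), theta=np.zeros(n),
                    alpha_tilde=np.array([1.0 / params.s]))
    mat = sample_matrix(eff, params.c, rng, n_grid=n_grid)
    t, x = mat.t.ravel(), mat.x.ravel()
    if size is None:
        return float(t[0]), int(x[0])
    return t, x


def generate_study(config: GeneratingConfig,
                   rng: np.random.Generator | None = None):
    """Generate effects and a complete response matrix; adds t0 to all RTs.

    Deterministic given ``config.seed`` (or the supplied generator): identical
    seeds yield bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effects = draw_effects(config, rng)
    mat = sample_matrix(effects, config.c, rng)
    if config.t0 > 0:
        mat = ResponseMatrix(t=mat.t + config.t0, x=mat.x)
    return effects, mat


def random_walk_oracle(params: TrialParams, rng: np.random.Generator,
                       step: float = 1e-4, max_steps: int = 10_000_000):
    """Euler random-walk approximation of one trial; cross-check only.

    Accumulates ``dX = v dt + s sqrt(dt) eps`` from ``z = a/2`` until a
    boundary at 0 or ``a = s/c`` is crossed; bias is O(sqrt(step)).
    """
    a = params.s / params.c
    pos = a / 2.0
    sqdt = np.sqrt(step)
    block = 8192
    elapsed = 0
    while elapsed < max_steps:
        incr = params.v * step + params.s * sqdt * rng.standard_normal(block)
        path = pos + np.cumsum(incr)
        hit_hi = path >= a
        hit_lo = path <= 0.0
        hit = hit_hi | hit_lo
        if hit.any():
            j = int(np.argmax(hit))
            t = (elapsed + j + 1) * step
            return t, int(hit_hi[j])
        pos = path[-1]
        elapsed += block
    raise RuntimeError("random walk did not terminate within max_steps")
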