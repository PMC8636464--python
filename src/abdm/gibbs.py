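"""Conjugate Gibbs sampler for the hierarchical ABDM at fixed c.

Dropping series terms (which do not involve the effects), the per-cell
likelihood kernel is

    exp( (x_ip - 1/2) alpha~_i (beta_i + theta_p)/c
         - t_ip alpha~_i^2 (beta_i + theta_p)^2 / 2 ),

an exponential-family form that is quadratic in each of ``beta_i``,
``theta_p`` and ``alpha~_i`` separately.  With normal population priors on
``beta``/``theta``, a zero-truncated normal population prior on ``alpha~``,
and normal/inverse-gamma hyperpriors, every full conditional is a (possibly
truncated) normal or an inverse gamma, so a systematic-scan Gibbs sampler
applies.  The model is identified by fixing ``mu_P = 0`` and
``sigma2_P = 1``; with a latent regression for ``theta`` the analogous
constraints are ``lambda_0 = 0`` and ``sigma2_res = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from sklearn.base import BaseEstimator

from .simulate import ResponseMatrix, truncated_normal

__all__ = [
    "PopulationConfig",
    "RegressionSpec",
    "GibbsState",
    "PosteriorSamples",
    "GibbsABDM",
    "update_beta",
    "update_theta",
    "update_alpha_tilde",
    "update_population",
    "update_regression",
    "run_chains",
]


@dataclass
class PopulationConfig:
    """Population parameters, hyperprior constants and identification flags.

    The hyperprior constants are weakly informative by default (prior means
    at each parameter's natural scale, prior variances 100, inverse-gamma
    shape/scale 0.01) and are dominated by the data at realistic test sizes.
    """

    nu_P0: float = 0.0
    tau2_P0: float = 100.0
    a_P0: float = 0.01
    b_P0: float = 0.01
    nu_I0: float = 1.0
    tau2_I0: float = 100.0
    a_I0: float = 0.01
    b_I0: float = 0.01
    nu_A0: float = 1.0
    tau2_A0: float = 100.0
    a_A0: float = 0.01
    b_A0: float = 0.01
    fix_mu_P: bool = True
    fix_sigma2_P: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith(("tau2", "a_", "b_")):
                if not getattr(self, f.name) > 0:
                    raise ValueError(f"{f.name} must be > 0")


@dataclass
class RegressionSpec:
    """Latent regression of theta on a design matrix Y (first column ones).

    ``lambda_0`` (intercept) is fixed at 0 and ``sigma2_res`` at 1 by default
    to identify location and scale of the person effects.
    """

    Y: np.ndarray
    fix_lambda0: bool = True
    fix_sigma2_res: bool = True

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("design matrix Y must be 2-D")
        if not np.allclose(self.Y[:, 0], 1.0):
            raise ValueError("first column of the design matrix must be all ones")
        if np.linalg.matrix_rank(self.Y) < self.Y.shape[1]:
            raise ValueError("design matrix Y is rank deficient")

    @property
    def n_covariates(self) -> int:
        return self.Y.shape[1] - 1


@dataclass
class GibbsState:
    """Current values of all sampled quantities."""

    beta: np.ndarray
    theta: np.ndarray
    alpha_tilde: np.ndarray
    mu_I: float = 1.0
    sigma2_I: float = 1.0
    mu_P: float = 0.0
    sigma2_P: float = 1.0
    mu_A: float = 1.0
    gamma2_A: float = 1.0
    lam: np.ndarray | None = None
    sigma2_res: float = 1.0


@dataclass
class PosteriorSamples:
    """Post-burn-in draws of one chain (one row per stored iteration)."""

    beta: np.ndarray
    theta: np.ndarray
    alpha_tilde: np.ndarray
    mu_I: np.ndarray
    sigma2_I: np.ndarray
    mu_P: np.ndarray
    sigma2_P: np.ndarray
    mu_A: np.ndarray
    gamma2_A: np.ndarray
    chain_id: int = 0
    n_burn: int = 0
    lam: np.ndarray | None = None
    sigma2_res: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def posterior_mean_effects(self):
        from .simulate import EffectSet

        return EffectSet(
            beta=self.beta.mean(axis=0),
            theta=self.theta.mean(axis=0),
            alpha_tilde=self.alpha_tilde.mean(axis=0),
        )


# ---------------------------------------------------------------------------
# full-conditional updates (each returns the new draws; state is not mutated)
# ---------------------------------------------------------------------------

def beta_conditional(data: ResponseMatrix, state: GibbsState, c: float):
    """(mean, variance) of the normal full conditional for each beta_i.

    Written in alpha~ (alpha = 1/alpha~): the precision contribution of the
    data is alpha~_i^2 sum_p t_ip; with no data the conditional is the prior.
    """
    a2 = state.alpha_tilde ** 2
    prec = a2 * data.t.sum(axis=1) + 1.0 / state.sigma2_I
    var = 1.0 / prec
    num = (state.alpha_tilde * (data.x - 0.5).sum(axis=1) / c
           - a2 * (data.t @ state.theta)
           + state.mu_I / state.sigma2_I)
    return num * var, var


def theta_conditional(data: ResponseMatrix, state: GibbsState, c: float,
                      regression: RegressionSpec | None = None):
    """(mean, variance) of the normal full conditional for each theta_p.

    With an active latent regression the prior term mu_P/sigma2_P is replaced
    by (Y lambda)_p / sigma2_res.
    """
    a2 = state.alpha_tilde ** 2
    prior_var = state.sigma2_res if regression is not None else state.sigma2_P
    if regression is not None:
        prior_mean = regression.Y @ state.lam
    else:
        prior_mean = state.mu_P
    prec = data.t.T @ a2 + 1.0 / prior_var
    var = 1.0 / prec
    num = ((data.x - 0.5).T @ state.alpha_tilde / c
           - data.t.T @ (a2 * state.beta)
           + prior_mean / prior_var)
    return num * var, var


def alpha_conditional(data: ResponseMatrix, state: GibbsState, c: float):
    """(mean, variance) of the [0, inf)-truncated normal conditional for alpha~_i."""
    v = state.beta[:, None] + state.theta[None, :]
    prec = (data.t * v ** 2).sum(axis=1) + 1.0 / state.gamma2_A
    var = 1.0 / prec
    mean = (state.mu_A / state.gamma2_A
            + ((data.x - 0.5) * v).sum(axis=1) / c) * var
    return mean, var


def update_beta(data: ResponseMatrix, state: GibbsState, c: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw beta_i | rest ~ N(beta^_i, sigma^2_i) (sums over persons)."""
    mean, var = beta_conditional(data, state, c)
    return rng.normal(mean, np.sqrt(var))


def update_theta(data: ResponseMatrix, state: GibbsState, c: float,
                 rng: np.random.Generator,
                 regression: RegressionSpec | None = None) -> np.ndarray:
    """Draw theta_p | rest ~ N(theta^_p, sigma^2_p) (sums over items)."""
    mean, var = theta_conditional(data, state, c, regression=regression)
    return rng.normal(mean, np.sqrt(var))


def update_alpha_tilde(data: ResponseMatrix, state: GibbsState, c: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw alpha~_i | rest from its truncated normal full conditional."""
    mean, var = alpha_conditional(data, state, c)
    return truncated_normal(rng, mean, np.sqrt(var), 0.0)


def _invgamma(rng: np.random.Generator, a: float, b) -> float:
    return float(b / rng.gamma(a))


def update_location_gauge(state: GibbsState, regression: RegressionSpec,
                          rng: np.random.Generator) -> float:
    """Translation group move for the beta <-> theta location trade-off.

    The likelihood depends on the effects only through beta_i + theta_p, so
    shifting all theta up by d and all beta down by d is a flat direction
    that the one-at-a-time scan traverses in a slow random walk; in the
    latent-regression model only the reference-group prior anchors it.  A
    group move (translation group, Lebesgue Haar measure) samples d from its
    exact conditional under the priors,

        d ~ N( [sum_i (beta_i - mu_I)/sigma2_I - sum_p (theta_p - (Y lam)_p)
                / sigma2_res] / P,  1/P ),
        P = N_I/sigma2_I + N_P/sigma2_res,

    and applies beta -> beta - d, theta -> theta + d, leaving the posterior
    invariant while decorrelating the location.  Returns the sampled shift.
    """
    m = regression.Y @ state.lam
    prec = (state.beta.size / state.sigma2_I
            + state.theta.size / state.sigma2_res)
    mean = ((state.beta - state.mu_I).sum() / state.sigma2_I
            - (state.theta - m).sum() / state.sigma2_res) / prec
    d = float(rng.normal(mean, np.sqrt(1.0 / prec)))
    state.beta = state.beta - d
    state.theta = state.theta + d
    return d


def update_population(state: GibbsState, prior: PopulationConfig,
                      rng: np.random.Generator) -> dict:
    """Normal / inverse-gamma conditionals for the population parameters.

    ``mu_P`` and ``sigma2_P`` are skipped when fixed by the identification
    flags.  Each mean conditional uses the current variance draw.
    """
    out = {}
    n_i = state.beta.size
    n_p = state.theta.size

    def _mean(total, n, sigma2, nu0, tau20):
        var = tau20 * sigma2 / (tau20 * n + sigma2)
        mean = (tau20 * total + sigma2 * nu0) / (tau20 * n + sigma2)
        return float(rng.normal(mean, np.sqrt(var)))

    out["sigma2_I"] = _invgamma(
        rng, prior.a_I0 + n_i / 2.0,
        ((state.beta - state.mu_I) ** 2).sum() / 2.0 + prior.b_I0)
    out["mu_I"] = _mean(state.beta.sum(), n_i, out["sigma2_I"],
                        prior.nu_I0, prior.tau2_I0)
    if not prior.fix_sigma2_P:
        out["sigma2_P"] = _invgamma(
            rng, prior.a_P0 + n_p / 2.0,
            ((state.theta - state.mu_P) ** 2).sum() / 2.0 + prior.b_P0)
    if not prior.fix_mu_P:
        sig2p = out.get("sigma2_P", state.sigma2_P)
        out["mu_P"] = _mean(state.theta.sum(), n_p, sig2p,
                            prior.nu_P0, prior.tau2_P0)
    out["gamma2_A"] = _invgamma(
        rng, prior.a_A0 + n_i / 2.0,
        ((state.alpha_tilde - state.mu_A) ** 2).sum() / 2.0 + prior.b_A0)
    out["mu_A"] = _mean(state.alpha_tilde.sum(), n_i, out["gamma2_A"],
                        prior.nu_A0, prior.tau2_A0)
    return out


def update_regression(state: GibbsState, regression: RegressionSpec,
                      rng: np.random.Generator) -> dict:
    """Bayesian linear regression of theta on Y under [lambda, s2] ~ 1/s2.

    Components fixed by the identification flags (intercept, residual
    variance) are not drawn.
    """
    Y = regression.Y
    theta = state.theta
    n, kp1 = Y.shape
    free = np.arange(1 if regression.fix_lambda0 else 0, kp1)
    out = {}
    lam = np.zeros(kp1) if regression.fix_lambda0 else state.lam.copy()
    if free.size:
        Yf = Y[:, free]
        gram = Yf.T @ Yf
        lam_hat = np.linalg.solve(gram, Yf.T @ theta)
        cov = np.linalg.inv(gram) * state.sigma2_res
        lam[free] = rng.multivariate_normal(lam_hat, cov, method="cholesky")
    out["lam"] = lam
    if not regression.fix_sigma2_res:
        resid = theta - Y @ lam
        out["sigma2_res"] = _invgamma(rng, n / 2.0, (resid ** 2).sum() / 2.0)
    return out


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _run_single_chain(data: ResponseMatrix, prior: PopulationConfig, c: float,
                      n_iter: int, n_burn: int, rng: np.random.Generator,
                      chain_id: int = 0, jitter: float = 0.5,
                      regression: RegressionSpec | None = None,
                      init: GibbsState | None = None) -> PosteriorSamples:
    n_i, n_p = data.n_items, data.n_persons
    if init is None:
        state = GibbsState(
            beta=np.zeros(n_i), theta=np.zeros(n_p), alpha_tilde=np.ones(n_i),
            mu_I=prior.nu_I0, sigma2_I=1.0, mu_P=prior.nu_P0, sigma2_P=1.0,
            mu_A=prior.nu_A0, gamma2_A=1.0,
        )
        if jitter > 0:  # over-dispersed starting points for multi-chain runs
            state.beta = state.beta + rng.normal(0.0, jitter, n_i)
            state.theta = state.theta + rng.normal(0.0, jitter, n_p)
            state.alpha_tilde = np.abs(state.alpha_tilde + rng.normal(0.0, jitter, n_i)) + 1e-3
            state.mu_I += rng.normal(0.0, jitter)
            state.mu_A += rng.normal(0.0, jitter)
    else:
        state = GibbsState(
            beta=init.beta.copy(), theta=init.theta.copy(),
            alpha_tilde=init.alpha_tilde.copy(), mu_I=init.mu_I,
            sigma2_I=init.sigma2_I, mu_P=init.mu_P, sigma2_P=init.sigma2_P,
            mu_A=init.mu_A, gamma2_A=init.gamma2_A, lam=init.lam,
            sigma2_res=init.sigma2_res,
        )
    if regression is not None and state.lam is None:
        state.lam = np.zeros(regression.Y.shape[1])

    n_keep = n_iter - n_burn
    if n_keep < 0:
        raise ValueError("n_burn must not exceed n_iter")
    store = {
        "beta": np.empty((n_keep, n_i)),
        "theta": np.empty((n_keep, n_p)),
        "alpha_tilde": np.empty((n_keep, n_i)),
        "mu_I": np.empty(n_keep), "sigma2_I": np.empty(n_keep),
        "mu_P": np.empty(n_keep), "sigma2_P": np.empty(n_keep),
        "mu_A": np.empty(n_keep), "gamma2_A": np.empty(n_keep),
    }
    lam_store = (np.empty((n_keep, regression.Y.shape[1]))
                 if regression is not None else None)
    s2res_store = np.empty(n_keep) if regression is not None else None

    for it in range(n_iter):
        try:
            state.beta = update_beta(data, state, c, rng)
            state.theta = update_theta(data, state, c, rng, regression=regression)
            state.alpha_tilde = update_alpha_tilde(data, state, c, rng)
            # the latent regression replaces only the theta random-effects
            # law; item and volatility population parameters update as usual
            for k, val in update_population(state, prior, rng).items():
                if regression is not None and k in ("mu_P", "sigma2_P"):
                    continue
                setattr(state, k, val)
            if regression is not None:
                update_location_gauge(state, regression, rng)
                for k, val in update_regression(state, regression, rng).items():
                    setattr(state, k, val)
        except Exception as err:
            raise RuntimeError(f"Gibbs update failed at iteration {it}") from err
        j = it - n_burn
        if j >= 0:
            store["beta"][j] = state.beta
            store["theta"][j] = state.theta
            store["alpha_tilde"][j] = state.alpha_tilde
            for k in ("mu_I", "sigma2_I", "mu_P", "sigma2_P", "mu_A", "gamma2_A"):
                store[k][j] = getattr(state, k)
            if regression is not None:
                lam_store[j] = state.lam
                s2res_store[j] = state.sigma2_res
    return PosteriorSamples(chain_id=chain_id, n_burn=n_burn,
                            lam=lam_store, sigma2_res=s2res_store, **store)


def run_chains(data: ResponseMatrix, prior: PopulationConfig, c: float,
               n_chains: int = 3, n_iter: int = 12_000, n_burn: int = 2_000,
               rng: np.random.Generator | None = None, jitter: float = 0.5,
               regression: RegressionSpec | None = None,
               init: GibbsState | None = None) -> list[PosteriorSamples]:
    """Run independent Gibbs chains from over-dispersed starting points."""
    if rng is None:
        rng = np.random.default_rng()
    child = rng.spawn(n_chains)
    return [
        _run_single_chain(data, prior, c, n_iter, n_burn, child[i], chain_id=i,
                          jitter=jitter, regression=regression, init=init)
        for i in range(n_chains)
    ]


class GibbsABDM(BaseEstimator):
    """Hierarchical Bayesian ABDM fitted by conjugate Gibbs sampling.

    Parameters
    ----------
    c : float
        Volatility-to-caution ratio, held fixed during sampling.
    n_chains, n_iter, n_burn : int
        Number of chains, iterations per chain, and discarded burn-in draws.
    prior : PopulationConfig, optional
        Hyperprior constants and identification flags.
    jitter : float
        Scale of the over-dispersion applied to each chain's starting point.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    beta_, theta_, alpha_tilde_ : ndarray
        Posterior-mean effects, pooled over chains.
    mu_I_, sigma2_I_, mu_A_, gamma2_A_ : float
        Posterior means of the free population parameters.
    chains_ : list of PosteriorSamples
    lambda_ : ndarray, present when a latent regression is active.
    """

    def __init__(self, c: float = 0.35, n_chains: int = 3, n_iter: int = 12_000,
                 n_burn: int = 2_000, prior: PopulationConfig | None = None,
                 jitter: float = 0.5, random_state=None):
        self.c = c
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.prior = prior
        self.jitter = jitter
        self.random_state = random_state

    def fit(self, rt, accuracy, covariates=None, init: GibbsState | None = None):
        """Fit to an (n_items, n_persons) design.

        Parameters
        ----------
        rt, accuracy : array-like of shape (n_items, n_persons)
        covariates : array-like of shape (n_persons, K), optional
            Person covariates; activates the latent regression for theta
            (intercept added internally, fixed at 0).
        """
        data = ResponseMatrix(t=np.asarray(rt, float), x=np.asarray(accuracy))
        if not self.c > 0:
            raise ValueError("c must be > 0")
        prior = self.prior if self.prior is not None else PopulationConfig()
        regression = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            regression = RegressionSpec(Y=np.column_stack([np.ones(len(cov)), cov]))
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        self.chains_ = run_chains(
            data, prior, self.c, n_chains=self.n_chains, n_iter=self.n_iter,
            n_burn=self.n_burn, rng=rng, jitter=self.jitter,
            regression=regression, init=init,
        )
        beta = np.concatenate([ch.beta for ch in self.chains_])
        if beta.shape[0] > 0:
            theta = np.concatenate([ch.theta for ch in self.chains_])
            alpha = np.concatenate([ch.alpha_tilde for ch in self.chains_])
            self.beta_ = beta.mean(axis=0)
            self.theta_ = theta.mean(axis=0)
            self.alpha_tilde_ = alpha.mean(axis=0)
            for name in ("mu_I", "sigma2_I", "mu_P", "sigma2_P", "mu_A", "gamma2_A"):
                val = np.concatenate([getattr(ch, name) for ch in self.chains_]).mean()
                setattr(self, name + "_", float(val))
            if regression is not None:
                self.lambda_ = np.concatenate([ch.lam for ch in self.chains_]).mean(axis=0)
                self.sigma2_res_ = float(
                    np.concatenate([ch.sigma2_res for ch in self.chains_]).mean())
        self.n_items_ = data.n_items
        self.n_persons_ = data.n_persons
        return self

    def effects_(self):
        from .simulate import EffectSet

        return EffectSet(beta=self.beta_, theta=self.theta_,
                         alpha_tilde=self.alpha_tilde_)

    def predict(self, kind: str = "rt"):
        """Posterior-mean cell predictions: mean RT or accuracy."""
        from .core import TrialParams, mean_rt, p_correct

        eff = self.effects_()
        v = eff.drift()
        s = eff.diffusion()
        fn = mean_rt if kind == "rt" else p_correct
        if kind not in ("rt", "accuracy"):
            raise ValueError("kind must be 'rt' or 'accuracy'")
        out = np.empty_like(v)
        for idx in np.ndindex(v.shape):
            out[idx] = fn(TrialParams(v=v[idx], s=s[idx], c=self.c))
        return out
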