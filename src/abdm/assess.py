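"""Model-fit criteria, convergence diagnostics, posterior predictive checks
and the five-by-five person/item cross-validation protocol.

AIC, BIC and DIC are computed on the *conditional* likelihood: the full ABDM
density evaluated with the person/item effects plugged in (not integrated
out).  For BIC the observation count defaults to the number of
(response-time, accuracy) cells, N_I * N_P.  Both conventions are
config-exposed.  The convergence diagnostic is the classic (split-free)
Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TrialParams, log_density_abdm, log_fpt_series, mean_rt, p_correct
from .gibbs import PosteriorSamples
from .jml import JmlConfig, count_parameters, fit_jml
from .simulate import EffectSet, ResponseMatrix, sample_matrix

__all__ = [
    "FitCriteria",
    "FoldPlan",
    "compute_criteria",
    "r_hat",
    "r_hat_table",
    "posterior_predictive",
    "make_fold_plan",
    "crossvalidate",
]


@dataclass(frozen=True)
class FitCriteria:
    """Conditional-likelihood fit criteria."""

    log_likelihood: float
    aic: float
    bic: float
    dic: float
    p_d: float
    n_params: int
    n_obs: int


def _deviances(data: ResponseMatrix, samples: PosteriorSamples, c: float,
               max_draws: int | None) -> np.ndarray:
    """-2 log-likelihood per stored draw; the series factor is shared."""
    n = samples.n_draws if max_draws is None else min(max_draws, samples.n_draws)
    log_series = np.asarray(log_fpt_series(data.t, c))
    xm = data.x - 0.5
    const = data.t.size * (math.log(np.pi) + 2.0 * math.log(c)) + log_series.sum()
    dev = np.empty(n)
    for d in range(n):
        a = samples.alpha_tilde[d]
        v = samples.beta[d][:, None] + samples.theta[d][None, :]
        ll = const + float(np.sum(
            xm * v * a[:, None] / c - data.t * v ** 2 * (a ** 2)[:, None] / 2.0))
        dev[d] = -2.0 * ll
    return dev


def compute_criteria(data: ResponseMatrix, samples: PosteriorSamples, c: float,
                     max_draws: int | None = 1000,
                     mode: str = "bayesian-random-effects",
                     n_obs: int | None = None) -> FitCriteria:
    """AIC/BIC/DIC from one chain's stored draws.

    DIC = mean deviance + p_D with p_D = mean deviance - deviance at the
    posterior-mean effects; by default only the first 1000 post-burn-in draws
    enter, mirroring a single-chain evaluation.
    """
    if samples.n_draws == 0:
        raise ValueError("samples must contain at least one stored draw")
    dev = _deviances(data, samples, c, max_draws)
    n = dev.size
    sub = PosteriorSamples(
        beta=samples.beta[:n], theta=samples.theta[:n],
        alpha_tilde=samples.alpha_tilde[:n], mu_I=samples.mu_I[:n],
        sigma2_I=samples.sigma2_I[:n], mu_P=samples.mu_P[:n],
        sigma2_P=samples.sigma2_P[:n], mu_A=samples.mu_A[:n],
        gamma2_A=samples.gamma2_A[:n])
    eff = sub.posterior_mean_effects()
    ll_hat = float(np.sum(log_density_abdm(data.t, data.x, eff.drift(),
                                           eff.diffusion(), c)))
    d_bar = float(dev.mean())
    p_d = d_bar - (-2.0 * ll_hat)
    if p_d < 0:
        warnings.warn(
            f"negative effective number of parameters p_D={p_d:.3f}; this can "
            "occur with conditional-likelihood DIC", RuntimeWarning)
    n_obs = data.t.size if n_obs is None else n_obs
    k = count_parameters(data.n_items, data.n_persons, mode)
    return FitCriteria(
        log_likelihood=ll_hat,
        aic=-2.0 * ll_hat + 2.0 * k,
        bic=-2.0 * ll_hat + k * math.log(n_obs),
        dic=d_bar + p_d,
        p_d=p_d,
        n_params=k,
        n_obs=n_obs,
    )


def r_hat(chains) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains``: array-like of shape (n_chains, n_draws) with equal-length
    post-burn-in chains.  R-hat = sqrt(((n-1)/n W + B/n) / W) with W the mean
    within-chain variance and B the between-chain variance of the means.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = arr.shape
    if m < 2:
        raise ValueError("at least two chains are required for R-hat")
    if n < 2:
        raise ValueError("chains must contain at least two draws")
    w = arr.var(axis=1, ddof=1).mean()
    b = n * arr.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0  # identical constant chains
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def r_hat_table(chains: list[PosteriorSamples]) -> pd.DataFrame:
    """R-hat for every scalar parameter across chains (tidy, one row each)."""
    if len(chains) < 2:
        raise ValueError("at least two chains are required")
    rows = []
    for name in ("mu_I", "sigma2_I", "mu_P", "sigma2_P", "mu_A", "gamma2_A"):
        draws = np.stack([getattr(ch, name) for ch in chains])
        if np.allclose(draws.var(axis=1), 0):  # identification-fixed
            continue
        rows.append(("population", name, r_hat(draws)))
    for group, attr in (("beta", "beta"), ("theta", "theta"),
                        ("alpha_tilde", "alpha_tilde")):
        stacked = np.stack([getattr(ch, attr) for ch in chains])  # (m, n, dim)
        for j in range(stacked.shape[2]):
            rows.append((group, f"{group}[{j}]", r_hat(stacked[:, :, j])))
    return pd.DataFrame(rows, columns=["group", "parameter", "r_hat"])


def posterior_predictive(data: ResponseMatrix, samples: PosteriorSamples,
                         c: float, n_rep: int, rng: np.random.Generator):
    """Posterior predictive item/person mean RTs and accuracies.

    For ``n_rep`` draws (evenly thinned from the stored chain) a complete
    response matrix is simulated from the ABDM at that draw's effects; the
    0.025/0.975 quantiles of the replicate means form the predictive
    intervals.  Returns ``(items_df, persons_df)``.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    idx = np.linspace(0, samples.n_draws - 1, n_rep).round().astype(int)
    item_rt = np.empty((n_rep, data.n_items))
    item_acc = np.empty((n_rep, data.n_items))
    pers_rt = np.empty((n_rep, data.n_persons))
    pers_acc = np.empty((n_rep, data.n_persons))
    for r, d in enumerate(idx):
        eff = EffectSet(beta=samples.beta[d], theta=samples.theta[d],
                        alpha_tilde=samples.alpha_tilde[d])
        rep = sample_matrix(eff, c, rng, n_grid=512)
        item_rt[r] = rep.t.mean(axis=1)
        item_acc[r] = rep.x.mean(axis=1)
        pers_rt[r] = rep.t.mean(axis=0)
        pers_acc[r] = rep.x.mean(axis=0)

    def _frame(rt_rep, acc_rep, obs_rt, obs_acc, label):
        q = lambda a, p: np.quantile(a, p, axis=0)
        return pd.DataFrame({
            label: np.arange(rt_rep.shape[1]),
            "observed_mean_rt": obs_rt,
            "pred_mean_rt": rt_rep.mean(axis=0),
            "rt_lo": q(rt_rep, 0.025), "rt_hi": q(rt_rep, 0.975),
            "observed_accuracy": obs_acc,
            "pred_accuracy": acc_rep.mean(axis=0),
            "acc_lo": q(acc_rep, 0.025), "acc_hi": q(acc_rep, 0.975),
        })

    items = _frame(item_rt, item_acc, data.t.mean(axis=1), data.x.mean(axis=1),
                   "item")
    persons = _frame(pers_rt, pers_acc, data.t.mean(axis=0), data.x.mean(axis=0),
                     "person")
    return items, persons


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Partition of persons and items into folds (default five each)."""

    person_folds: tuple
    item_folds: tuple

    def __post_init__(self) -> None:
        for folds, label in ((self.person_folds, "person"),
                             (self.item_folds, "item")):
            seen = np.concatenate([np.asarray(f, int) for f in folds])
            if len(np.unique(seen)) != len(seen):
                raise ValueError(f"{label} folds overlap")


def make_fold_plan(n_persons: int, n_items: int, n_person_folds: int = 5,
                   n_item_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic, near-equal-size random partition into folds."""
    rng = np.random.default_rng(seed)
    p_perm = rng.permutation(n_persons)
    i_perm = rng.permutation(n_items)
    return FoldPlan(
        person_folds=tuple(np.sort(f) for f in np.array_split(p_perm, n_person_folds)),
        item_folds=tuple(np.sort(f) for f in np.array_split(i_perm, n_item_folds)),
    )


def crossvalidate(data: ResponseMatrix, plan: FoldPlan | None, c: float,
                  max_sweeps: int = 500) -> pd.DataFrame:
    """Out-of-sample prediction over all person-fold x item-fold combinations.

    Item parameters come from JML fits that exclude one person fold; person
    parameters come from fits that exclude one item fold.  For every held-out
    cell the closed-form mean RT and accuracy are predicted from the combined
    parameters.  With ``plan=None`` the in-sample fitted values for all cells
    are returned instead.  Per-fold fit failures are reported in the
    ``fit_error`` column and do not abort the remaining folds.
    """
    cfg = JmlConfig(c=c, max_sweeps=max_sweeps)
    if plan is None:
        res = fit_jml(data, cfg)
        return _predict_cells(data, res.effects, res.effects, c,
                              np.arange(data.n_items), np.arange(data.n_persons),
                              person_fold=-1, item_fold=-1)

    person_fits: dict[int, object] = {}
    item_fits: dict[int, object] = {}
    errors: dict[tuple[str, int], str] = {}
    for k, fold in enumerate(plan.person_folds):
        keep = np.setdiff1d(np.arange(data.n_persons), fold)
        try:
            person_fits[k] = fit_jml(
                ResponseMatrix(t=data.t[:, keep], x=data.x[:, keep]), cfg)
        except Exception as err:  # keep going; report per fold
            errors[("person", k)] = str(err)
    for j, fold in enumerate(plan.item_folds):
        keep = np.setdiff1d(np.arange(data.n_items), fold)
        try:
            item_fits[j] = (fit_jml(
                ResponseMatrix(t=data.t[keep], x=data.x[keep]), cfg), keep)
        except Exception as err:
            errors[("item", j)] = str(err)

    frames = []
    for j, item_fold in enumerate(plan.item_folds):
        for k, person_fold in enumerate(plan.person_folds):
            if ("person", k) in errors or ("item", j) in errors:
                frames.append(pd.DataFrame({
                    "item": np.repeat(item_fold, len(person_fold)),
                    "person": np.tile(person_fold, len(item_fold)),
                    "fit_error": errors.get(("person", k),
                                            errors.get(("item", j))),
                }))
                continue
            item_eff = person_fits[k].effects  # all items present
            pers_res, _keep = item_fits[j]
            frames.append(_predict_cells(
                data, item_eff, pers_res.effects, c, item_fold, person_fold,
                person_fold=k, item_fold=j))
    return pd.concat(frames, ignore_index=True)


def _predict_cells(data, item_effects, person_effects, c, items, persons,
                   person_fold, item_fold) -> pd.DataFrame:
    rows = []
    for i in np.asarray(items, int):
        b = item_effects.beta[i]
        a = item_effects.alpha_tilde[i]
        for p in np.asarray(persons, int):
            th = person_effects.theta[p]
            par = TrialParams(v=b + th, s=1.0 / a, c=c)
            rows.append((i, p, item_fold, person_fold, data.t[i, p],
                         mean_rt(par), int(data.x[i, p]), p_correct(par)))
    df = pd.DataFrame(rows, columns=["item", "person", "item_fold",
                                     "person_fold", "observed_rt", "pred_rt",
                                     "observed_accuracy", "pred_accuracy"])
    df["rt_error"] = df["observed_rt"] - df["pred_rt"]
    df["accuracy_error"] = df["observed_accuracy"] - df["pred_accuracy"]
    df["fit_error"] = None
    return df
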