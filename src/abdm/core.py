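"""Closed-form results for the attention-based diffusion model (ABDM).

The ABDM describes a two-choice decision as a Wiener process with drift ``v``
and diffusion coefficient ``s`` between absorbing boundaries at 0 and ``a``,
started midway (``z = a/2``, unbiased responding), with the boundary
separation tied to the volatility through a fixed ratio ``c = s/a``
(volatility-to-caution ratio).  Under these assumptions the joint density of
decision time ``t`` and choice ``x`` (1 = correct) collapses to

    f(t, x) = pi c^2 exp([x - 1/2] v/(c s) - t v^2 / (2 s^2))
              * sum_k k sin(pi k / 2) exp(-pi^2 c^2 k^2 t / 2),

where only odd ``k`` contribute, with alternating signs.  Choice accuracy is
two-parameter logistic in ``v/(c s)`` and the mean decision time has a closed
form, which together yield a moment estimator for ``c``.

All functions operate in the caller's time units; :func:`rescale_units` in
:mod:`abdm.io` documents the induced reparameterisation for unit changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialParams",
    "ClassicParams",
    "MomentSummary",
    "SeriesError",
    "fpt_series",
    "log_fpt_series",
    "density_classic",
    "density_abdm",
    "log_density_abdm",
    "mean_rt",
    "p_correct",
    "moment_estimate_c",
]

#: default hard cap on the number of series terms before declaring failure
MAX_TERMS = 100_000

#: below this time floor the large-time series converges slowly; the same
#: series is used with a raised term budget (see docs/methods.md)
SMALL_T_FLOOR = 1e-4


class SeriesError(RuntimeError):
    """The first-passage-time series did not converge within the term cap."""


@dataclass(frozen=True)
class TrialParams:
    """Per-trial ABDM parameters.

    Parameters
    ----------
    v : float
        Drift rate (evidence / s); any sign.
    s : float
        Diffusion coefficient (evidence / sqrt(s)); > 0.
    c : float
        Volatility-to-caution ratio ``s/a`` (1 / sqrt(s)); > 0.

    The boundary separation ``a = s/c`` and starting point ``z = a/2`` are
    derived, not stored.
    """

    v: float
    s: float
    c: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"diffusion coefficient s must be > 0, got {self.s}")
        if not self.c > 0:
            raise ValueError(f"volatility-to-caution ratio c must be > 0, got {self.c}")

    @property
    def a(self) -> float:
        """Boundary separation ``s / c``."""
        return self.s / self.c

    @property
    def z(self) -> float:
        """Starting point, fixed at ``a / 2`` (unbiased)."""
        return self.a / 2.0

    def to_classic(self) -> "ClassicParams":
        return ClassicParams(v=self.v, s=self.s, a=self.a, z=self.z)


@dataclass(frozen=True)
class ClassicParams:
    """Parameters of the general two-boundary Wiener diffusion (no ratio tie)."""

    v: float
    s: float
    a: float
    z: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"diffusion coefficient s must be > 0, got {self.s}")
        if not (0 < self.z < self.a):
            raise ValueError(f"starting point must satisfy 0 < z < a, got z={self.z}, a={self.a}")


@dataclass(frozen=True)
class MomentSummary:
    """Pooled accuracy ``p``, mean RT ``M`` and log-odds ``L = log(p/(1-p))``."""

    p: float
    M: float

    def __post_init__(self) -> None:
        if not (0 < self.p < 1):
            raise ValueError(f"accuracy p must lie in (0, 1), got {self.p}")
        if not self.M > 0:
            raise ValueError(f"mean RT M must be > 0, got {self.M}")

    @property
    def L(self) -> float:
        return math.log(self.p / (1.0 - self.p))


# ---------------------------------------------------------------------------
# series machinery
# ---------------------------------------------------------------------------

def _series_sum_scalar(b: float, tol: float, max_terms: int) -> float:
    """sum over odd k of (-1)^((k-1)/2) * k * exp(-b k^2).

    Terms alternate in sign and their magnitude is unimodal in k (peak near
    k* = 1/sqrt(2b)); convergence is only declared once past the peak.
    """
    total = 0.0
    k_peak = math.sqrt(1.0 / (2.0 * b)) if b > 0 else math.inf
    tiny = np.finfo(float).tiny
    for k in range(1, 2 * max_terms, 2):
        sign = 1.0 if (k % 4) == 1 else -1.0
        mag = k * math.exp(-b * k * k)
        total += sign * mag
        if k > k_peak and mag <= tol * max(abs(total), tiny):
            return total
    raise SeriesError(
        f"first-passage series did not converge within {max_terms} odd terms (b={b:g})"
    )


def _series_sum_mpmath(b: float) -> float:
    """High-precision evaluation for small b, where the alternating series
    cancels below the double-precision noise floor.

    The true sum behaves like exp(-pi^2/(16 b)) for small b; once that
    underflows a double (b < ~8.8e-4) the float answer is exactly 0.0 and no
    summation is needed (log-scale callers use the closed asymptotic).
    """
    import mpmath as mp

    if b < 8.8e-4:
        return 0.0
    with mp.workdps(min(400, int(0.3 / b) + 30)):
        bb = mp.mpf(b)
        total = mp.mpf(0)
        k = 1
        while True:
            term = k * mp.exp(-bb * k * k)
            total += term if (k % 4) == 1 else -term
            if k * k * b > 50 and term < mp.mpf(10) ** (-mp.mp.dps) * (abs(total) + 1):
                break
            k += 2
            if k > 2 * MAX_TERMS:
                raise SeriesError(f"high-precision series did not converge (b={b:g})")
        return float(total)


def fpt_series(t, c: float, tol: float = 1e-12, max_terms: int = MAX_TERMS):
    """Series factor S(t, c) = sum_k k sin(pi k/2) exp(-pi^2 c^2 k^2 t / 2).

    Vectorised over ``t``.  For arguments where double-precision cancellation
    would swamp the (exponentially small) true value, the sum is re-evaluated
    in high precision so the result is always a usable positive number.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise ValueError("time t must be > 0")
    shape = t_arr.shape
    b = ((np.pi ** 2) * (c ** 2) * t_arr / 2.0).ravel()

    out = np.empty_like(b)
    # vectorised evaluation with a shared odd-k grid
    b_min = float(b.min())
    k_star = 1.0 / math.sqrt(2.0 * max(b_min, 1e-300))
    # absolute tail below 1e-20 so truncation never masquerades as a tiny sum
    k_needed = math.sqrt(max(k_star ** 2, 1.0)
                         + max(-math.log(tol), 46.1) / max(b_min, 1e-300))
    if k_needed > 2 * max_terms:
        raise SeriesError(
            f"series requires ~{k_needed:.0f} terms, above the cap {2 * max_terms}"
        )
    k = np.arange(1, 2 * math.ceil(k_needed / 2) + 2, 2, dtype=float)
    sign = np.where((k.astype(int) % 4) == 1, 1.0, -1.0)
    # chunk over t to bound memory
    chunk = max(1, int(4e6 / k.size))
    for lo in range(0, b.size, chunk):
        bb = b[lo:lo + chunk, None]
        out[lo:lo + chunk] = np.einsum(
            "k,tk->t", sign * k, np.exp(-bb * k[None, :] ** 2)
        )

    # cancellation guard: rounding error scales with the sum of |terms|,
    # which is ~1/(4b) for small b and ~exp(-b) otherwise
    noise = 32 * np.finfo(float).eps * np.maximum(1.0, 0.25 / b)
    bad = out < noise
    if np.any(bad):
        for i in np.nonzero(bad)[0]:
            out[i] = _series_sum_mpmath(float(b[i]))
    out = out.reshape(shape)
    return out if np.ndim(t) else float(out[0])


def log_fpt_series(t, c: float, tol: float = 1e-12):
    """log S(t, c), vectorised over ``t``.

    Where the series value underflows double precision entirely (c^2 t below
    ~2e-4), the leading small-time first-passage asymptotic
    ``S ~ (1/pi) * (1/2) (2 pi tau^3)^{-1/2} exp(-1/(8 tau))`` with
    ``tau = c^2 t`` supplies the logarithm.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    s = np.asarray(fpt_series(t_arr, c, tol=tol))
    tau = (c ** 2) * t_arr
    asymp = (-math.log(np.pi) + math.log(0.5)
             - 0.5 * np.log(2.0 * np.pi * tau ** 3) - 1.0 / (8.0 * tau))
    with np.errstate(divide="ignore"):
        logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), asymp)
    return logs if np.ndim(t) else float(logs[0])


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def density_classic(t: float, x: int, params: ClassicParams,
                    tol: float = 1e-12, max_terms: int = MAX_TERMS) -> float:
    """Joint density f(t, x) of the general two-boundary Wiener diffusion.

    ``x = 1`` is absorption at the upper boundary ``a`` (the correct/option-A
    response), ``x = 0`` absorption at 0.
    """
    if t <= 0:
        raise ValueError("time t must be > 0")
    if x not in (0, 1):
        raise ValueError("choice x must be 0 or 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    v, s, a, z = params.v, params.s, params.a, params.z
    # reflect so the series is always written for absorption at the upper bound
    if x == 1:
        vv, zz = v, z
    else:
        vv, zz = -v, a - z
    pref = (np.pi * s ** 2 / a ** 2) * math.exp(
        (a - zz) * vv / s ** 2 - t * vv ** 2 / (2 * s ** 2)
    )
    b = (np.pi ** 2) * (s ** 2) * t / (2 * a ** 2)
    w = np.pi * zz / a
    total = 0.0
    # magnitudes k*exp(-b k^2) peak near k* = 1/sqrt(2b); the sin factor can
    # (near-)vanish at individual k, so two consecutive sub-tolerance terms
    # past the peak are required before declaring convergence
    k_peak = math.sqrt(1.0 / (2.0 * b)) if b > 0 else math.inf
    small_run = 0
    tiny = np.finfo(float).tiny
    terms_budget = max_terms if t >= SMALL_T_FLOOR else 10 * max_terms
    for k in range(1, terms_budget + 1):
        term = k * math.sin(k * w) * math.exp(-b * k * k)
        total += term
        if k > k_peak and abs(term) <= tol * max(abs(total), tiny):
            small_run += 1
            if small_run >= 2:
                return pref * max(total, 0.0)
        else:
            small_run = 0
    raise SeriesError(
        f"classic-density series did not converge within {terms_budget} terms "
        f"(t={t:g}, a={a:g}, s={s:g})"
    )


def density_abdm(t: float, x: int, params: TrialParams,
                 tol: float = 1e-12, max_terms: int = MAX_TERMS) -> float:
    """Joint density f(t, x) of the ABDM (``a = s/c``, ``z = a/2``)."""
    if t <= 0:
        raise ValueError("time t must be > 0")
    if x not in (0, 1):
        raise ValueError("choice x must be 0 or 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    v, s, c = params.v, params.s, params.c
    b = (np.pi ** 2) * (c ** 2) * t / 2.0
    budget = max_terms if t >= SMALL_T_FLOOR else 10 * max_terms
    series = _series_sum_scalar(b, tol, budget)
    noise = 32 * np.finfo(float).eps * max(1.0, 0.25 / b)
    if series < noise:  # below the double-precision cancellation floor
        series = max(_series_sum_mpmath(b), 0.0)
    pref = np.pi * c ** 2 * math.exp((x - 0.5) * v / (c * s) - t * v ** 2 / (2 * s ** 2))
    return pref * series


def log_density_abdm(t, x, v, s, c: float, tol: float = 1e-12):
    """Vectorised log f(t, x); the series factor depends on (t, c) only.

    All of ``t``, ``x``, ``v``, ``s`` broadcast against each other; ``c`` is
    scalar.  This is the workhorse for likelihood evaluation: the costly
    series is computed once per response time.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    log_series = log_fpt_series(t, c, tol=tol)
    return (
        math.log(np.pi) + 2.0 * math.log(c)
        + (x - 0.5) * v / (c * s)
        - t * v ** 2 / (2.0 * s ** 2)
        + log_series
    )


# ---------------------------------------------------------------------------
# moments and the moment estimator
# ---------------------------------------------------------------------------

def mean_rt(params: TrialParams) -> float:
    """Mean decision time E(T) = (a/2v) (1 - e^{-va/s^2})/(1 + e^{-va/s^2}).

    With ``a = s/c`` this is ``tanh(L/2) / (2 L c^2)`` for ``L = v/(cs)``;
    the ``v -> 0`` limit is ``1/(4 c^2)``.  Even in ``v``.
    """
    L = params.v / (params.c * params.s)
    if abs(L) < 1e-10:
        return 1.0 / (4.0 * params.c ** 2)
    return math.tanh(L / 2.0) / (2.0 * L * params.c ** 2)


def p_correct(params: TrialParams) -> float:
    """P(X = 1) = 1 / (1 + exp(-v/(c s))): a 2-PL model in ``v/(c s)``."""
    return float(1.0 / (1.0 + np.exp(-params.v / (params.c * params.s))))


def p_correct_classic(params: ClassicParams) -> float:
    """General absorption probability (exp(-2zv/s^2) - 1)/(exp(-2av/s^2) - 1)."""
    v, s, a, z = params.v, params.s, params.a, params.z
    if abs(v) < 1e-12:
        return z / a
    num = math.expm1(-2.0 * z * v / s ** 2)
    den = math.expm1(-2.0 * a * v / s ** 2)
    return num / den


def moment_estimate_c(m: MomentSummary) -> float:
    """Moment estimator of the volatility-to-caution ratio.

    Inverts the accuracy and mean-RT equations:
    ``c_hat = sqrt( (1/(2 L M)) * (1 - e^{-L}) / (1 + e^{-L}) )`` with
    ``L = log(p/(1-p))``; the ``p -> 1/2`` (``L -> 0``) continuity limit is
    ``sqrt(1/(4 M))``.
    """
    L = m.L
    if abs(L) < 1e-8:
        return math.sqrt(1.0 / (4.0 * m.M))
    return math.sqrt(math.tanh(L / 2.0) / (2.0 * L * m.M))
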