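# Methods

## Model

The package models a two-choice item response as a Wiener diffusion with
drift `v`, diffusion coefficient `s`, absorbing boundaries at `0` and `a`,
and starting point `z`.  Three assumptions specialise it to performance
testing: attention lapses reduce the drift rather than adding a separate
non-decision stage (so the modelled time is the full response time);
volatility is item-specific with caution tied to it through a fixed
volatility-to-caution ratio `c = s/a`; and responding is unbiased,
`z = a/2`.  Under these assumptions the joint density of decision time and
choice reduces to a three-parameter form in `(v, s, c)` whose series factor
depends only on `(t, c)`, accuracy becomes a two-parameter logistic model in
`v/(cs)`, and the mean decision time has the closed form
`tanh(L/2)/(2Lc²)` with `L = v/(cs)` (limit `1/(4c²)` at `v = 0`).

Hierarchical structure: `v_ip = β_i + θ_p` (item easiness + person
ability), `s_ip = 1/α̃_i` with the reciprocal volatility `α̃_i` the natural
parameterisation (the likelihood kernel is linear/quadratic in it).
Population laws: `β_i ~ N(μ_I, σ²_I)`, `θ_p ~ N(μ_P, σ²_P)`,
`α̃_i ~ N(μ_A, γ²_A)` truncated to `[0, ∞)`.  The likelihood depends on the
effects only through `(β_i + θ_p)·α̃_i`, leaving one location and one scale
direction unidentified; they are fixed by `μ_P = 0`, `σ²_P = 1` (or
`λ₀ = 0`, `σ²_res = 1` when a latent regression replaces the `θ` law).

## Numerical evaluation of the density

The large-time series `S(t, c) = Σ_k k sin(πk/2) exp(−π²c²k²t/2)` has only
odd, alternating terms with magnitudes peaking near `k* = 1/(πc√t)`.
Scalar evaluation truncates once past the peak when the next term falls
below `tol × |partial sum|` (default `tol = 1e−12`), with a hard cap of
10⁵ odd terms (10× below a time floor of `1e−4` s) and an explicit
`SeriesError` on cap — never silent truncation.  The general five-parameter
density uses the same rule but requires two consecutive sub-tolerance terms,
because individual `sin` factors can vanish at `z = a/2`.

For `c²t` small the true value `~exp(−1/(8c²t))` lies below the
double-precision cancellation floor of the alternating sum (rounding error
scales with `Σ|terms| ≈ 1/(4b)`, `b = π²c²t/2`).  Values falling below
`32·eps·max(1, 1/(4b))` are recomputed with mpmath at `0.3/b + 30` digits;
once the result underflows a double entirely (`b < 8.8e−4`) the closed
small-time asymptotic `S ≈ (1/π)·½(2πτ³)^{−1/2}e^{−1/(8τ)}`, `τ = c²t`,
supplies the logarithm directly.  This keeps the single large-time series as
the only representation while making log-likelihoods finite and accurate
over the whole profile-search range; the residual relative error in the
narrow hand-over band is below `1e−4` in the log.  Small-time
(Navarro–Fuss-style) series switching is deliberately out of scope.

Vectorised likelihood evaluation exploits that the series factor depends
only on `(t, c)`: it is computed once per cell and reused across parameter
draws, so information criteria over 1000 draws cost little more than one
density sweep.

## Simulator

`generate_study` draws effects from the population laws (reciprocal
volatility truncated at 1/2 in the reference configuration, avoiding
unrealistically volatile items) and samples each cell exactly: the choice is
Bernoulli with the closed-form accuracy, and — because the conditional
decision-time law given the choice does not depend on which boundary was hit
— the time is drawn by inverting the CDF of `exp(−tv²/(2s²))·S(t, c)` on a
1024-point log-spaced grid spanning `[1/(360c²), 160/(π²c²)]` (mass below
`e^{−45}` outside), with monotone linear interpolation of the inverse.
Truncated normals use inverse-CDF sampling through `log_ndtr`/`ndtri_exp`,
exact even when the mean sits 50 standard deviations below the bound.  An
Euler random-walk sampler (`random_walk_oracle`, bias `O(√Δt)`) provides an
implementation-independent cross-check in the tests.

Reference configuration (module default, `GeneratingConfig()`): 120 persons,
70 items, `μ_I = 1, σ²_I = 1, μ_P = 0, σ²_P = 1, μ_A = 1, γ²_A = ½`
(truncation at ½), `c = 0.35`, optional additive `t₀` (default 0).  Under
it the population grand-mean decision time is ≈1.1 s with per-replicate
spread of ≈0.08 s (driven by the 70 item-effect draws).  Note that the
exact model puts roughly four of the 8400 draws above 10 s per replicate
(tail rate `v²/(2s²) + π²c²/2 ≥ 0.60 s⁻¹`), so a replicate with *no* RT
above 10 s is a rare event, not typical behaviour.  What the simulator does
not emulate: real tests' censoring/time limits, within-person speed drift,
item-order effects, and non-decision components (unless `t₀ > 0` is set
explicitly for robustness studies).

## Gibbs sampler

Systematic scan `β → θ → α̃ → population (→ regression)`; all conditionals
are conjugate (normals; truncated normal for `α̃`; normal/inverse-gamma for
population parameters).  Hyperpriors are weakly informative — prior means at
each parameter's natural scale, prior variances 100, inverse-gamma
shape/scale 0.01 — and overridable.  Chains start at zero effects and unit
volatilities with `N(0, 0.5²)` over-dispersion per chain.  Identification
flags keep `μ_P = 0`, `σ²_P = 1` out of the scan.

With a latent regression, only the `θ` random-effects law is replaced; the
item and volatility population parameters keep updating.  Because the
`β ↔ θ` location trade-off is then anchored only through the regression
prior, the scan is supplemented with an exact translation group move that
samples the shift of all `θ` (compensated in `β`) from its conditional
under the priors; the likelihood is invariant along this direction, so the
posterior is unchanged while the location decorrelates orders of magnitude
faster.  The regression conditionals are the standard Bayesian linear-model
ones under the non-informative prior `p(λ, σ²_res) ∝ 1/σ²_res`, honouring
the `λ₀ = 0`, `σ²_res = 1` identification.

What recovery means under the identification: the likelihood pins the
effects only in the gauge fixed by `μ_P = 0, σ²_P = 1`, so estimates should
be compared with gauge-aligned truths (standardise the realised `θ` draws,
shift `β` and rescale `α̃` accordingly).  In that gauge, posterior means of
`β` and `θ` regress on truth with slope ≈0.96–0.99 at the reference design,
while `α̃` posterior means show visible shrinkage (slope ≈0.87–0.89,
correlation ≈0.97): per-item posterior SD ≈0.12 against a signal SD ≈0.5
plus accuracy-noise attenuation.  This is a property of the exact posterior
at 120 persons (the conditional-ratio tests verify the sampler), not an
estimation defect; joint-ML point estimates reach slope ≈0.96.

## Estimating the volatility-to-caution ratio

`c` is the only parameter in the series factor and is shared by all cells,
so it is profiled: for each candidate, a single inner Gibbs chain (2000
draws, 1000 burn-in) estimates the effects, and the full log density summed
at the posterior means is the objective.  A golden-section search on
`[0.1, 1]` runs at most 10 bracket reductions and stops early when the
objective changes by less than 1% in relative terms between successive
evaluations; the returned estimate is the best evaluated candidate, and a
pooled moment estimator `ĉ = sqrt(tanh(L/2)/(2LM))` provides a start value
for gradient/grid alternatives (an 11-point grid scan is available by
flag).  Each candidate uses an RNG stream derived deterministically from the
root seed and the candidate value, so the profile is a fixed function of `c`
given the seed; inner chains warm-start from the previous candidate's
posterior means.  At the reference design the search lands on 0.3435, the
golden-section probe nearest the generating 0.35.

## Joint maximum likelihood

At fixed `c`, the three blocks of score equations have closed-form solutions
that are exact per-block maximisers (the block likelihoods are concave
quadratics), so cycling `β → θ → α̃` is block-coordinate ascent with a
non-decreasing log-likelihood.  The `θ̂` and `α̂̃` estimators are implemented
in their score-consistent form (denominators `Σ_i t_ip α̃_i²` and
`Σ_p t_ip(β_i+θ_p)²`).  After each sweep the solution is projected onto the
identified manifold by the exactly likelihood-preserving map
`(β, θ, α̃) → ((β+θ̄)/s, (θ−θ̄)/s, α̃·s)` with `θ̄, s` the current mean/SD of
`θ`.  Non-positive `α̂̃` (items whose accuracies anti-align with ability)
are clamped to `1e−6` with a warning; a collapse of `θ` heterogeneity is
flagged as an identification conflict.  Convergence: relative
log-likelihood change below `1e−9` (cap 500 sweeps); more than three
consecutive decreases abort with the trace.

Parameter counting: `2N_I + N_P + 4 + 1` in the Bayesian random-effects
mode (four free population parameters plus `c`) and `2N_I + N_P − 2 + 1`
for JML (two identification constraints on `θ`; `c` counted once in both
modes — the only convention consistent with the published totals of 5004
and 229).

## Model assessment

AIC/BIC/DIC use the conditional likelihood — effects plugged in, not
integrated out — with `n_obs = N_I·N_P` for BIC; both conventions are
arguments.  DIC is `D̄ + p_D`, `p_D = D̄ − D(posterior means)`, over the
first 1000 post-burn-in draws of one chain by default; negative `p_D`
(possible with conditional-likelihood DIC) warns rather than fails.  The
convergence diagnostic is the classic split-free Gelman–Rubin factor
`sqrt(((n−1)/n·W + B/n)/W)`; identical chains give `sqrt((n−1)/n)`,
marginally below one.  Posterior predictive checks simulate full response
matrices at thinned draws and report 95% predictive intervals for item and
person mean RTs/accuracies.  Cross-validation partitions persons and items
into five folds each; item parameters come from JML fits excluding a person
fold, person parameters from fits excluding an item fold, and held-out
cells are predicted with the closed-form mean RT and accuracy.  Fold-wise
fits are combined without Procrustes alignment — the identification
constraints make scales comparable, a documented looseness.

## Units

All computations run in the caller's time unit.  Rescaling `t → kt` maps a
fitted model back via `α̃ → α̃/√k`, `c → c/√k` (`β, θ` unchanged) and
shifts each cell's log density by `−log k`; `rescale_units`/`rescale_fit`
implement and document the pair.  Fitting in tenths of seconds is the
conventional choice for numerical stability with long RTs.

## Problem sizes and determinism

The test suite and the reproduction script run everything at the reference
design (120 × 70): golden-section estimation with the stated inner-Gibbs
settings, a final fit of three 12,000-draw chains, posterior predictive
checks with up to ~120 replicates, and 5 × 5 cross-validation — a few
minutes end to end on one CPU.  Every stochastic component takes an explicit
seed or `numpy` Generator; identical seeds give bit-identical studies,
chains and outputs.

## Known limitations

Two-choice formats only (no multiple-choice with heterogeneous
distractors); no missing-data handling (complete designs are validated and
required); no trial-to-trial variability parameters of the full
Ratcliff-style model; no standard errors for JML estimates; `c` is global —
per-person or per-item ratios are out of scope; fully Bayesian sampling of
`c` is intentionally avoided in favour of the profile search.
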