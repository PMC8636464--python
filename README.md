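# abdm — attention-based diffusion modelling of response times and accuracies

`abdm` implements a psychometric diffusion model for two-choice performance
tests in which both the response time and the correctness of each answer
carry information about a test taker's ability.  It is aimed at
psychometricians and cognitive modellers who want a process-level account of
item responding that still scales to large persons-by-items designs.

## The model

A response arises from a Wiener evidence-accumulation process with drift
`v`, diffusion coefficient `s`, boundary separation `a` and starting point
`z`.  Three substantive assumptions adapt it to performance testing:

* **attention lapses slow the drift** rather than adding a separate
  non-decision time, so the observed RT is the decision time itself;
* **volatility is item-specific** (`s_ip = α_i`) and respondents tie their
  caution to it through a fixed volatility-to-caution ratio `c = s/a`;
* **responding is unbiased**, `z = a/2`.

With these assumptions the joint density of decision time `t` and choice
`x ∈ {0, 1}` collapses to

    f(t, x) = π c² exp([x − ½] v/(cs) − t v²/(2s²))
              · Σ_k k sin(πk/2) exp(−π² c² k² t / 2),

drift decomposes additively into item easiness and person ability,
`v_ip = β_i + θ_p`, and accuracy follows a two-parameter logistic model,
`P(X = 1) = 1/(1 + exp(−v/(cs)))`.  Because the effects enter the kernel
only linearly and quadratically, all full conditionals are (truncated)
normals or inverse gammas and the hierarchical model is fitted by plain
conjugate Gibbs sampling; `c`, the only parameter in the series factor, is
profiled out by a golden-section search.  A joint maximum-likelihood fitter,
a latent regression of ability on covariates, information criteria
(AIC/BIC/DIC on the conditional likelihood), Gelman–Rubin diagnostics,
posterior predictive checks and a 5 × 5 person/item cross-validation
protocol round out the toolkit.

## Worked example

```python
import numpy as np
from abdm import GeneratingConfig, generate_study, VolatilityCautionSearch, GibbsABDM
from abdm.assess import r_hat_table

# simulate the reference design: 120 persons x 70 items, c = 0.35
effects, data = generate_study(GeneratingConfig(seed=1))
print(f"grand mean RT {data.t.mean():.2f} s, accuracy {data.x.mean():.2f}")

est = VolatilityCautionSearch(random_state=1).fit(data.t, data.x)
print(f"c_hat = {est.c_:.4f} after {len(est.trace_)} profile evaluations")

model = GibbsABDM(c=est.c_, n_chains=3, n_iter=12_000, n_burn=2_000,
                  random_state=1).fit(data.t, data.x)
tab = r_hat_table(model.chains_)
print(f"max R-hat: population {tab[tab.group == 'population'].r_hat.max():.3f}, "
      f"effects {tab[tab.group != 'population'].r_hat.max():.3f}")
print(f"corr(beta_hat, beta_true) = "
      f"{np.corrcoef(model.beta_, effects.beta)[0, 1]:.3f}")
```

prints

```
grand mean RT 1.19 s, accuracy 0.73
c_hat = 0.3435 after 8 profile evaluations
max R-hat: population 1.004, effects 1.007
corr(beta_hat, beta_true) = 0.991
```

The grand-mean decision time of about a second and the ~73% overall accuracy
are typical of timed two-choice ability tests; the recovered ratio 0.3435
sits next to the generating 0.35 (the golden-section probe closest to it),
the convergence diagnostics are comfortably below the usual 1.02/1.03
ceilings, and the item-easiness posterior means correlate 0.99 with the
generating values.

A `click` CLI mirrors the library for shell use — `abdm simulate`,
`fit-gibbs`, `estimate-c`, `fit-jml`, `assess`, `ppc`, `crossval` — reading
and writing long-format CSV (`person_id,item_id,rt,accuracy`) plus a JSON
manifest per run.

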