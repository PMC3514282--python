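# ivf-jointfx

Joint Bayesian modelling of success (live birth) and treatment
discontinuation in IVF programs, for biostatisticians and reproductive
epidemiologists studying informative dropout in multi-attempt treatment
data.

Couples undergo up to four IVF attempts.  Whether a couple conceives and
whether it abandons treatment after a failure are driven in part by the
same unmeasured couple-specific factors (prognosis, psychological burden).
The package implements a shared random-effects joint model — two mixed
logistic regressions linked by a couple-level latent factor:

    logit(p_i)  = α^succ + β_age^succ + β_center^succ + f_i
    logit(π_i)  = α^disc + β_age^disc + β_center^disc + λ_center f_i + ε_i

with `f_i ~ N(0, σ_f²)`, `ε_i ~ N(0, σ_ε²)`.  `p_i` is the per-attempt
live-birth probability, `π_i` the probability of discontinuing after a
failed attempt, and the center-specific loading `λ` measures the link
between the two processes (λ < 0: factors that favor success protect
against dropout).  Fitting is by Pólya-Gamma-augmented Gibbs sampling with
multiple chains, burn-in and thinning; convergence is assessed with the
Brooks–Gelman corrected potential scale reduction factor.  The hypothesis
λ = 0 is tested with partial Bayes factors on learning/test splits of the
cohort, on the L = 2·log BF scale (L ≤ −2 significant, L ≤ −6 strong),
with a prior- and split-sensitivity analysis.

Because the underlying two-center cohort (3,002 couples) is not publicly
deposited, the package ships a calibrated synthetic-cohort generator that
reproduces the study's structure — center sizes, age margins, published
effect estimates, and first-attempt rates — and serves as the test bed for
the whole pipeline.  See `docs/methods.md` for model, priors, sampler and
calibration details.

## Worked example

```python
from ivf_jointfx import (GeneratorConfig, simulate_cohort, attempt_rates,
                         SharedRandomEffectsModel)

cohort = simulate_cohort(GeneratorConfig(n_couples=3002, seed=7))
print(attempt_rates(cohort).rounded()[["center", "attempt", "live_birth_pct", "disc_pct"]]
      .head(4).to_string(index=False))

model = SharedRandomEffectsModel(seed=1).fit(cohort)
print(model.summary_.loc[["lambda_paris", "lambda_midcity"]].round(2))
print("OR(discontinuation, MIDCITY vs PARIS) =",
      round(model.or_summary("beta_center_disc").median, 2))
```

prints (seed 7):

```
center  attempt  live_birth_pct  disc_pct
 PARIS        1            21.0      39.0
 PARIS        2            19.0      37.0
 PARIS        3            18.0      30.0
 PARIS        4            13.0       NaN
                mean    sd  q2.5  median  q97.5  rhat
lambda_paris    0.07  0.47 -0.65    0.04   1.06  1.07
lambda_midcity -0.29  0.36 -0.77   -0.33   0.36  1.10
OR(discontinuation, MIDCITY vs PARIS) = 0.47
```

The generator calibrates the first-attempt Parisian live-birth rate at 22%
with a 37% discontinuation rate among its failures (this cohort draw
prints 21/39); later-attempt declines arise from selective dropout of
low-`f` couples.  The fitted loadings recover the generating values (0 in
Paris, −0.21 in the medium-sized city center) within their posterior
uncertainty — the loading is weakly identified, so its posterior is wide —
and the discontinuation odds ratio between centers recovers the
generating 0.55 within the credible interval.

A command-line interface wraps the same functions:

```
ivf-jointfx simulate --n 3002 --seed 7 --out cohort.csv
ivf-jointfx describe --cohort cohort.csv
ivf-jointfx fit --cohort cohort.csv --seed 1 --out-dir results/
ivf-jointfx bftest --cohort cohort.csv --center MIDCITY \
    --n-learning 502 --n-test 2500
ivf-jointfx run --config analysis.yaml
```

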