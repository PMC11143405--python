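# ollged

Fitting and evaluation of the **odd log-logistic generalized exponential
(OLLGE) distribution**, a three-parameter lifetime model for survival and
waiting-time data whose hazard can be increasing, decreasing, unimodal or
reversed-J — shapes a plain exponential or generalized exponential cannot
all reach.

The model starts from the generalized exponential (GE) baseline

```
F(x) = (1 − e^{−λx})^α ,      x > 0,  λ, α > 0,
```

and tilts its odds by a third shape parameter γ > 0 (the odd log-logistic
transform):

```
G(x) = F(x)^γ / [ F(x)^γ + (1 − F(x))^γ ].
```

γ = 1 recovers GE(α, λ); γ = α = 1 recovers Exp(λ).  The package provides

* numerically stable `pdf / logpdf / cdf / sf / hazard / quantile / rvs`
  (everything is computed from `expm1`/`log1p`/logistic primitives, so the
  tails never cancel — `logpdf(500, (1,1,1))` is exactly −500);
* moments and shape measures: adaptive-quadrature raw moments (the
  authoritative route), the classical power-series expansion of the cdf with
  an explicit truncation-failure signal, the moment generating function,
  octile-based (Galton) skewness and (Moors) kurtosis, mean residual life and
  mean inactivity time, and order-statistic densities and moments;
* maximum-likelihood fitting in log-parameter space with a deterministic
  multi-start grid, seeded jitter and a derivative-free polish, standard
  errors from the numerically differentiated observed information, and a
  goodness-of-fit suite (−2ℓ̂, AIC, BIC, Kolmogorov–Smirnov with asymptotic
  p-value, modified Anderson–Darling A\* and Cramér–von Mises W\*);
* the nested/rival baselines used in model comparisons: generalized
  exponential, exponential (closed-form MLE) and log-logistic;
* a Monte-Carlo bias/MSE study of the ML estimator;
* two bundled lifetime datasets: 64 waiting times (seconds) between Kiama
  Blowhole eruptions, and 45 survival times (years) of chemotherapy
  patients.

The front end follows the statsmodels idiom: a model object built from data
whose `fit()` returns a results object.

## Worked example

```python
import ollged as og

sample = og.load_builtin("chemo45")          # 45 survival times, years
res = og.OddLogLogisticGE(sample.values).fit(seed=0)
print(res.summary())
```

```
OLLGED maximum-likelihood fit
  n = 45, log-likelihood = -56.0940, -2l = 112.1881
  AIC = 118.1881, BIC = 123.6081, converged = True (27 starts)
  parameter   estimate      std.err
  lambda         2.7681       1.1186
  alpha          7.2780       5.3350
  gamma          0.3192       0.1344
```

The scale estimate λ̂ ≈ 2.77 is in 1/years; γ̂ ≈ 0.32 < 1 says the data’s
odds grow more slowly than the GE baseline’s (a heavier right tail).  The
goodness-of-fit report and a four-model comparison:

```python
rep = res.gof()
print(f"KS D = {rep.ks_stat:.4f}, p = {rep.ks_pvalue:.4f}")
print(og.compare_models(sample, seed=0, label="chemo45"))
```

```
KS D = 0.0594, p = 0.9973
Model comparison on 'chemo45' (n = 45)
            -2l      AIC      BIC     W*     A*     KS  p-value
ollged 112.1881 118.1881 123.6081 0.0292 0.2455 0.0594   0.9973
ged    116.1897 120.1897 123.8030 0.0835 0.5492 0.1099   0.6488
ed     116.4372 118.4372 120.2439 0.0596 0.4533 0.0908   0.8517
lld    120.3713 124.3713 127.9846 0.0700 0.5118 0.0849   0.9019
```

The OLLGE model wins on every criterion except BIC, where the one-parameter
exponential's smaller penalty prevails.  (AIC and BIC are always recomputed
from −2ℓ̂, k and n, never echoed from a table.)

The same machinery is scriptable from the shell:

```bash
ollged fit --data builtin:kiama64 --model ollged --seed 1
ollged compare --data builtin:chemo45 --models ollged,ged,ed,lld --seed 1
ollged dpqr --lambda 1 --alpha 1 --gamma 1 --q 0.5        # -> ln 2
ollged simulate --lambda 1.5 --alpha 1.5 --gamma 0.2 --n 300 --reps 200 --seed 1
```

## Notes on fidelity

`docs/methods.md` documents the model, the numerical choices, and the
places where our converged results deviate from the tabulated reference
values (a very flat likelihood ridge for the waiting-time data, the
formal — and often divergent — character of the power-series moment route,
and a Monte-Carlo design point whose tabulated MSE lies below the
Cramér–Rao bound).
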