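# eq5dmap

Map non-validated stroke-registry outcome variables to EQ-5D-3L utility
weights.

National stroke quality registers record outcomes — assistance needed with
toileting and dressing, restricted mobility, perceived general health, low
mood — that are clinically meaningful but not part of any preference-based
instrument, so they cannot feed cost-utility analyses or QALY comparisons
across conditions. *Mapping* (also called crosswalking or transfer to
utility) fixes this by regressing observed EQ-5D utility weights on the
registry answers in a sample that has both, then applying the fitted
coefficients wherever only the registry answers exist — including decades
of historical registry data.

`eq5dmap` implements this pipeline for a 3-month post-stroke follow-up
questionnaire:

- **EQ-5D-3L scoring** under the UK social tariff (Dolan time-trade-off
  value set): `index = 1 − 0.081·1[any dysfunction] − Σ level decrements −
  0.269·1[any level 3]`, ranging over the 243 profiles from −0.594
  (state 33333) to 1.0 (11111).
- **Dummy coding** of the six registry variables (toilet assistance,
  dressing assistance, mobility, general health, mood, proxy response)
  into the shared intercept + 11-dummy design, reference = "no disability".
- **Three mapping regressions** handling the ceiling of the utility scale
  at 1 differently:
  - OLS with heteroscedasticity-consistent (HC1) standard errors —
    ignores the ceiling;
  - Tobit: maximum likelihood for a right-censored Gaussian outcome,
    `y = min(x'β + ε, 1)`, `ε ~ N(0, σ²)`;
  - CLAD (Powell's censored least absolute deviation):
    `min_β Σ|y_i − min(x_i'β, 1)|`, fitted by iterative deletion with
    percentile-bootstrap confidence intervals — consistent under
    non-normal, heteroscedastic errors with conditional median zero.
- **Published coefficient sets** for all three models, usable for
  prediction out of the box (Tobit/CLAD predictions censored at 1).
- **A validation battery**: MAE, MSE, fractions of absolute errors below
  0.05/0.10, mean error stratified by observed-utility band, a Welch test
  for error clustering below vs. above utility 0.5, VIF and
  coefficient-correlation diagnostics, and scatter/error plots.
- **A synthetic cohort generator** that emulates such a stroke cohort
  (latent-severity-correlated registry answers, ceiling atom at 1), so
  the full estimate → validate pipeline runs with no external data.

## Worked example

```python
from eq5dmap import (BootstrapConfig, GeneratorConfig, UtilityMapping,
                     generate_cohort, split_sample)

cohort = generate_cohort(GeneratorConfig(n=544, seed=7, mode="latent_censored"))
est, val = split_sample(cohort, seed=7)          # 272 / 272
res = UtilityMapping(est).fit("ols")
print(res.summary())
print(res.validate(val).render_table())
```

prints (abridged):

```
EQ-5D utility mapping — OLS (HC1 robust standard errors)
n = 272    R² = 0.699
                                Coef.   [95% CI       ]
Constant                        0.884     0.843   0.924
Toilet assistance              -0.095    -0.180  -0.009
Dressing assistance            -0.180    -0.237  -0.122
...
Maximum attainable prediction: 0.884

Validation (n = 272)
Model         Mean      SD     Min     Max     MAE     MSE  AE<0.05  AE<0.10
Observed     0.604   0.322  -0.584   1.000     n/a     n/a      n/a      n/a
OLS          0.593   0.268  -0.336   0.884   0.163   0.039     17%     32%

Mean error by observed-utility band:
  <0         -0.19  (n=15)
  0.00-0.24  -0.10  (n=19)
  ...
Error clustering below vs. above 0.5: P = 1.729e-11
```

Reading this: the fitted constant (0.884) is the predicted utility of a
patient with no recorded impairments — and, since every dummy lowers the
prediction, the model's maximum attainable weight. Each coefficient is the
utility decrement attached to that answer (needing dressing assistance
costs 0.180 utility). On the held-out half the model predicts with a mean
absolute error of 0.163, compresses the spread (SD 0.268 vs. 0.322
observed), and its errors cluster: utilities below 0.5 are overpredicted
(negative band means), a pattern typical of mapping models.

The published models work the same way without any fitting:

```python
from eq5dmap import CovariateVector, predict, published_model

predict(published_model("ols"), CovariateVector())    # 0.902
predict(published_model("tobit"), CovariateVector())  # 1.0 (1.068 censored)
```

The same pipeline is scriptable from the shell:

```sh
eq5dmap demo --seed 7 --out demo_out            # simulate → split → fit ×3 → validate
eq5dmap simulate --n 544 --seed 1 --out cohort.csv --split part
eq5dmap fit --data part_estimation.csv --out models/
eq5dmap validate --model models/model_ols.json --data part_validation.csv \
    --out report.json --plots figures/
```

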