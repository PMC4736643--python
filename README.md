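# retfit

Fitting parametric probability distributions to **interval-censored
propagule retention-time data**, and measuring what the choice of fitting
method costs you downstream in seed-dispersal estimates.

## The problem

Plants, invertebrates and microbes that disperse passively ride animal
vectors: propagules are ingested (endozoochory) or attached to fur and
feathers (epizoochory), carried while the vector moves, and released after
a retention time R.  The dispersal distance is D = V × R, so the
probability distribution of R — usually lognormal, gamma or Weibull,
right-skewed with a mode in the first hours — shapes the whole dispersal
kernel, including the ecologically critical long-distance tail.

Retention time is continuous, but feeding trials measure it discretely:
droppings are collected at scheduled times, so each propagule's R is only
known up to an interval (lower, upper] between collections — the data are
*interval-censored*.  Practitioners fit continuous distributions to such
data in several ways, most commonly by pretending the collection time (the
interval's upper bound) was the exact retention time.  `retfit` implements
the five methods in use and a simulation benchmark of their accuracy:

| method  | data seen                         | estimator |
|---------|-----------------------------------|-----------|
| `lower` / `mid` / `upper` | interval bound replicated per count | plain ML on the points |
| `cd_ml` | censored interval counts          | interval-censored ML: Σᵢ nᵢ log[F(uᵢ)−F(lᵢ)] + n_c log[1−F(h)] |
| `cd_nls`| empirical cumulative proportions  | least squares on Σ(pᵢ − F(uᵢ))² |

Fit quality is scored by the Kolmogorov–Smirnov statistic between the
fitted and the true distribution (sampled protocol: one-sample KS of 500
draws from the fit against the true CDF, noise floor ≈ 0.039; plus an
exact sup-norm oracle), and by signed parameter errors.

## Worked example

```sh
python examples/fit_single_trial.py
```

```
trial: N=500, 19 intervals, 0 not retrieved by 52 h
method     mu_hat  sigma_hat  exact KS
lower       1.644      0.612     0.102
mid         1.792      0.587     0.009
upper       1.917      0.574     0.081
cd_ml       1.785      0.575     0.017
cd_nls      1.783      0.570     0.020
```

Five hundred retention times from a lognormal (μ=1.8, σ=0.6; median ≈ 6 h)
were binned into hourly collections to 8 h then 4-hourly to 52 h.  The
censored-data fits (`cd_ml`, `cd_nls`) and the mid-interval fit recover the
truth to within ~0.02 in cumulative probability, while the lower/upper
bound shortcuts shift the location parameter by about half a bin width
(μ̂ = 1.64 / 1.92 vs 1.80) and deviate by 0.08–0.10 in cumulative
probability.  Propagated into dispersal distance at a 60 km/h vector speed
(`examples/dispersal_kernel.py`), the upper-bound shortcut inflates the
median dispersal distance by ~33% and the long-distance dispersal
frequency accordingly; a 1.3 h error in median retention alone moves the
median dispersal distance by 1.3 h × 60 km/h = 78 km.

Other examples: `method_benchmark.py` (five methods × three families over
a Latin-Hypercube design of distribution shapes), `sampling_design.py`
(sample-size and collection-schedule effects).  A thin CLI mirrors the
main workflows: `retfit fit data.csv --family lognormal --method cd_ml`,
`retfit kernel ...`, `retfit experiment --config cfg.yaml --out-dir out/`.

## Library layout

- `retfit.distributions` — lognormal/gamma/Weibull retention-time families,
  (μ, σ) parameterized (log-mean/log-sd, shape/rate, shape/scale).
- `retfit.sampling` — collection schemes, censored-trial simulation,
  Latin-Hypercube parameter designs, movement models, censored-CSV I/O.
- `retfit.fitting` — the five fitting methods.
- `retfit.evaluation` — sampled and exact KS, parameter differences,
  replicate aggregation.
- `retfit.kernel` — Monte-Carlo dispersal kernels (%LDD, mean, median,
  Q99) and percent-bias tables relative to `cd_ml`.
- `retfit.experiments` — the four simulation studies (method comparison,
  sample size, interval schemes, kernel bias), deterministic per master
  seed.

See `docs/methods.md` for the model, numerical choices and limitations.

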