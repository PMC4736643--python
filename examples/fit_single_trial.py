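"""Fit one simulated feeding trial with all five methods.

Simulates 500 propagule retention times from a lognormal (mu=1.8,
sigma=0.6; median ~6 h), bins them into the common hourly-to-8 h then
4 h-to-52 h collection schedule, and fits the lognormal back by each
method.  Bound methods see discretized times; CD methods see the censored
counts.  The KS column is the exact maximum cumulative-probability
deviation between the fitted and the true distribution (0 = perfect).
"""

from retfit import (METHODS, RetentionDistribution, default_scheme, fit,
                    ks_exact, simulate_censored)

original = RetentionDistribution("lognormal", 1.8, 0.6)
sample = simulate_censored(original, n=500, scheme=default_scheme(), seed=42)
print(f"trial: N={sample.n_total}, {len(sample.counts)} intervals, "
      f"{sample.right_censored} not retrieved by {sample.horizon:.0f} h")
print(f"{'method':8} {'mu_hat':>8} {'sigma_hat':>10} {'exact KS':>9}")
for method in METHODS:
    r = fit(sample, "lognormal", method)
    fitted = RetentionDistribution("lognormal", r.mu_hat, r.sigma_hat)
    ks = ks_exact(fitted, original).statistic
    print(f"{method:8} {r.mu_hat:8.3f} {r.sigma_hat:10.3f} {ks:9.3f}")
print("\ntruth: mu=1.800, sigma=0.600 — the CD and mid fits track it;"
      "\nlower/upper-bound fits shift mu by roughly half a bin width.")
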