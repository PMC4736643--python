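"""From retention-time fits to dispersal-kernel bias.

A propagule carried by a vector flying 60 km/h disperses D = 60 x R km.
We simulate a coarse feeding trial (4 h collections, N=500), fit the
retention distribution by interval-censored ML (cd_ml) and by the common
shortcut of fitting the collection times themselves (upper), then compare
the resulting dispersal kernels.  %LDD is the percentage of dispersal
events beyond 100 km; Q99 the 99th distance percentile.  The shortcut
inflates the estimate of long-distance dispersal.
"""

from retfit import (MovementModel, RetentionDistribution, bias_table,
                    estimate_kernel, fit, median_shift, regular_scheme,
                    simulate_censored)

original = RetentionDistribution("lognormal", 1.8, 0.6)
sample = simulate_censored(original, 500, regular_scheme(4.0), seed=11)
mallard = MovementModel.fixed_speed(60.0)

summaries = {}
for method in ("cd_ml", "upper", "mid"):
    r = fit(sample, "lognormal", method)
    fitted = RetentionDistribution("lognormal", r.mu_hat, r.sigma_hat)
    summaries[method] = estimate_kernel(fitted, mallard, n=100_000, seed=3)

print(f"{'method':7} {'%LDD':>6} {'mean km':>8} {'median km':>10} {'Q99 km':>8}")
for m, s in summaries.items():
    print(f"{m:7} {s.pldd:6.2f} {s.mean_km:8.1f} {s.median_km:10.1f} {s.q99_km:8.1f}")
print("\npercent bias relative to cd_ml:")
print(bias_table(summaries).round(1).to_string())

print("\nrule of thumb: a 1.3 h error in median retention at 60 km/h shifts")
print(f"the median dispersal distance by {median_shift(1.3, 60.0):.0f} km.")
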