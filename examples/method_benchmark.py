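"""Benchmark the five fitting methods over varied distribution shapes.

Runs a reduced method-comparison study: for each family, 4 Latin-Hypercube
parameter sets x 8 replicate trials (N=500, mixed 1 h/4 h schedule), all
five methods, scored by the sampled KS protocol.  Lower mean KS = more
accurate recovery of the original distribution; the cumulative-distribution
fits (cd_ml, cd_nls) should come out best, the lower/upper-bound fits worst.
"""

from retfit import ExperimentConfig, run_method_comparison

config = ExperimentConfig(study="method_comparison", lhs_k=4, n_replicates=8, seed=1)
tidy, summary = run_method_comparison(config)
cols = ["family", "method", "ks_mean", "ks_se", "mu_diff_mean", "sigma_diff_mean"]
print(summary[cols].round(4).to_string(index=False))
print("\nks_mean near 0.04 is indistinguishable from a perfect fit under"
      "\nthis protocol; the bound methods sit several times higher.")
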