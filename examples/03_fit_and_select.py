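"""Fit the hierarchical survival model and rank the insect variables.

Runs the desk-scale sampler (3 chains x 10,000 sweeps) on a synthetic
dataset of ~100 nests (a couple of paper-sized seasons pooled; a single
35-nest study carries only modest evidence) and prints the selection table: posterior inclusion
probability and Bayes factor per candidate variable, the top model, and
effect summaries conditional on it.  Takes a few minutes.
"""

import numpy as np

import nestsurv as ns
from nestsurv.mcmc import ModelConfig, gelman_rubin, run_mcmc
from nestsurv.selection import summarize_selection

fix = ns.make_default_fixture(seed=1, pairs_per_year=36)  # a 3-season-sized study
dataset = ns.fixture_dataset(fix)
print(f"{len(fix.histories)} nests, {len(dataset.series)} candidate insect variables")

config = ModelConfig(n_chains=3, n_iter=10_000, burn_in=2_000, seed=1)
samples = run_mcmc(dataset, config)

summary = summarize_selection(samples.stacked("w"), samples.stacked("beta"),
                              samples.metric_names)
print(summary.to_frame().to_string(index=False))
print("\ntop model:", "".join(map(str, summary.top_model)))
print(summary.conditional_beta.to_string(index=False))
print(f"\ngenerating truth: beta = -0.7 on simulium_annulus:log_count; "
      f"a Bayes factor above 3 signals support for that variable.")
for p in ("mu_pair", "sigma_pair", "beta_renest", "V"):
    print(f"R-hat[{p}] = {gelman_rubin(samples, p):.3f} (converged if < 1.05)")
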