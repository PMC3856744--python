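"""Posterior-predictive daily survival and success-vs-exposure curve.

Reuses a quick fit of the default dataset, then predicts daily nest
survival for an unexposed first nest and for one exposed at the mean
observed black-fly level, and tabulates the probability of producing a
hatchling against days of exposure during a 30-day incubation.
"""

import numpy as np

import nestsurv as ns
from nestsurv.mcmc import ModelConfig, run_mcmc
from nestsurv.predict import exposure_curve, predict_daily_survival

VAR = "simulium_annulus:log_count"

fix = ns.make_default_fixture(seed=1)
dataset = ns.fixture_dataset(fix)
samples = run_mcmc(dataset, ModelConfig(n_chains=2, n_iter=6_000, burn_in=1_500, seed=2))

z = dataset.series[0]
mean_level = float(np.mean(z.values[z.observed & (z.values > 0)]))
rng = np.random.default_rng(0)

# full scenarios: every covariate at 0 (no insects) vs black-fly ln-count
# raised to its mean observed positive level
unexposed = {name: 0.0 for name in samples.metric_names}
exposed = dict(unexposed, **{VAR: mean_level})
s0 = predict_daily_survival(samples, unexposed, rng=rng)
s1 = predict_daily_survival(samples, exposed, rng=rng)
print(f"daily survival, first nest, unexposed:      "
      f"{s0['mean']:.3f} (95% CI {s0['lower']:.3f}-{s0['upper']:.3f})")
print(f"daily survival at mean ln-count ({mean_level:.2f}): "
      f"{s1['mean']:.3f} (95% CI {s1['lower']:.3f}-{s1['upper']:.3f})")

curve = exposure_curve(samples, VAR, mean_level, baseline=unexposed, rng=rng)
print("\nsuccess probability vs days of black-fly exposure (30-day incubation):")
print(curve[curve.days_exposed.isin([0, 10, 20, 30])].to_string(index=False))
print("\nThe drop from d=0 to d=30 quantifies how much sustained insect "
      "harassment costs a pair in hatching probability.")
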