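# Methods

`nestsurv` fits a hierarchical Bayesian model of daily nest survival in
which incompletely observed, temporally varying covariates — spatially
interpolated biting-insect indices — are imputed inside the MCMC by
parallel Markovian submodels, and competing covariates are compared by
indicator-variable (Kuo–Mallick) Bayesian model selection.

## The model

**Observation layer.** Each nest *i* has an encounter history X_{i,t}:
1 (checked alive), 0 (checked failed), missing (not checked). Records
start at the detection day (always alive) and end at hatch or at the first
failed check. Nest fate is monotone, so every day up to the last
alive-check is certainly alive and contributes log S_{i,t} per transition;
a failure observed after an unchecked stretch of g days contributes
log(1 − Π_{k} S) over the stretch, the failure day marginalized
analytically (the sum over failure days telescopes to one minus the
probability of surviving the whole stretch). This marginalization is exact
for any gap length, so no latent alive-state sampling is used. Nests
incubated full term without hatching are *encoded by the data preparer* as
failed on incubation day 30; the reader performs no inference.

**Daily survival.**

    logit S_{i,t} = β0[pair_i] + β_renest · renest_i + Σ_m w_m β_m Z_{m,i,t+1}

with β0[pair] ~ Normal(μ_pair, σ²_pair) a nesting-pair random intercept, a
fixed renesting effect, and M candidate insect covariates Z_m gated by
binary inclusion indicators w_m. The covariate for the transition into day
t+1 is the day-(t+1) value (configurable to same-day for sensitivity
analysis). Covariates enter unstandardized.

**Covariate construction.** Trap counts are carried to nests by the
inverse-distance-squared interpolator (weighted mean over the traps active
that day; days without an active trap are missing). Three metrics per
taxon: ln(count+1); presence (interpolated count strictly > 0); and an
indicator for counts strictly exceeding the 90% quantile of all pooled
observed interpolated counts for the taxon (linear-interpolation "type 7"
quantile by default; both the quantile rule and within/across-year pooling
are configurable — the indicator is identical on raw or log scale by
monotonicity).

**Covariate process models.** ln(count+1) indices follow a year-specific
Gaussian AR(1): I_t | I_{t−1} ~ N(α_y + ρ_y (I_{t−1} − α_y), 1/τ_y), with
the stationary law N(α_y, 1/(τ_y(1 − ρ_y²))) on a series' first day.
Binary indices follow the process portion of a dynamic occupancy model:
persistence φ_y from an occupied day, colonization γ_y from an unoccupied
one, stationary occupancy ψ_y = γ_y/(γ_y + 1 − φ_y) on day one. The
first-day law is the stationary distribution by design (a diffuse
alternative was considered and rejected: it adds a free parameter with no
data support). The centered AR(1) mean parameterization is used; the
uncentered alternative is not exposed because it changes only the meaning
of α.

**Priors** (all fitted-model defaults): Normal(0, 1000) for unconstrained
locations (μ_pair, β_renest, α_y); Gamma(0.1, 0.1) for precisions
(pair-intercept precision, τ_y); Uniform(0, 1) for φ_y, γ_y;
Uniform(−1, 1) for ρ_y; Bernoulli(0.5) for every w_m; and Gamma(shape
3.29, rate 7.8) for the total covariate-block prior variance V, each
coefficient carrying prior Normal(0, V/K′) with K′ = max(Σ_m w_m, 1).
Scaling by K keeps total prior uncertainty constant across model
dimensions; K′ handles the empty model, where the scaling is otherwise
undefined, by treating the block as a single slot. A self-check
(`selection.marginal_survival_prior_quantiles`) simulates the survival
probability induced by the V prior and verifies its 5%/95% quantiles lie
inside (0.03, 0.97), i.e. the prior is roughly flat on the probability
scale — this also pins the (shape, rate) reading of Gamma(3.29, 7.8): the
(shape, scale) reading concentrates survival at 0 and 1 and fails the
check.

**Selection summaries.** The posterior mean of w_m is the variable's
inclusion probability p_m, and BF_m = [p_m/(1−p_m)]/[w/(1−w)] with prior
w = 0.5 is the posterior-to-prior odds of inclusion. When every retained
draw includes (or excludes) a variable, the BF is reported as a bound
computed by substituting one draw's worth of probability. Coefficient
summaries are reported conditional on the most-visited indicator pattern;
Jeffreys-style verbal labels (3–12 "some support", >12 "strong") are
attached as a heuristic only.

## The sampler

A hand-rolled Metropolis-within-Gibbs sweep, fixed order:

1. **Latent covariate imputation.** Each missing nest×day value is updated
   one at a time in a fixed order. AR(1) sites propose from the exact
   Gaussian chain conditional, so the Metropolis acceptance ratio reduces
   to the survival-likelihood ratio of the one transition the day feeds
   (sites feeding no observed transition are exact Gibbs draws). Binary
   sites are exact two-point Gibbs draws (chain terms × survival terms
   enumerated).
2. **Covariate-process parameters.** α_y and τ_y by conjugate
   Normal/Gamma draws (the stationary first-day terms included, which
   keeps conjugacy); ρ_y by reflecting random-walk Metropolis on (−1, 1);
   (φ_y, γ_y) by a joint logit-scale random-walk Metropolis against the
   transition-count likelihood (on a complete one-step grid this reduces
   to Beta conditionals with a first-day Metropolis correction, which is
   how the public `update_occupancy_params` is implemented).
3. **Survival parameters.** All pair intercepts in one Metropolis pass
   (independent accept/reject per pair; pairs contributing no transitions
   are exact prior draws); μ_pair and the pair precision conjugately;
   β_renest and each included β_m by random-walk Metropolis; excluded β_m
   refreshed from their Normal(0, V/K′) prior, which preserves mixing
   across models.
4. **Indicators and V.** Each w_m by its exact Bernoulli full conditional:
   the survival-likelihood ratio of including vs excluding at the current
   β_m, times the prior-density ratio of *all* coefficients under the two
   implied K values (flipping one indicator rescales every coefficient's
   prior variance), times the prior odds. V by random-walk Metropolis on
   log V.

Proposal scales adapt toward standard acceptance targets during burn-in
only and are frozen afterwards, preserving detailed balance of retained
draws. Chains are seeded independently from (seed, chain index); runs are
bit-reproducible.

### Computational representation

Internally each nest × metric series lives on a **reduced day grid**: the
days with actual trap data plus the days that nest's survival transitions
consume. Latent days outside both sets are marginalized out exactly by the
Markov property — consecutive grid points k days apart are tied by the
k-step AR(1) law (coefficient ρ^k, variance σ²_s(1−ρ^{2k})) or the k-step
two-state transition matrix (eigenvalue λ = φ−γ). This changes nothing in
the posterior over retained quantities and removes most of the latent
state. Full one-step-grid reference implementations of every covariate
operation are kept in `covariate_models` and the reduced-grid path is
tested against them. Parameter updates use per-step-length sufficient
statistics, making each full-conditional evaluation O(k_max). Hot loops
(survival likelihood, imputation sweeps, the pair-intercept pass) are
numba-compiled; likelihood changes from single-parameter proposals are
computed incrementally against a per-transition log-S cache, touching only
transitions whose covariate is nonzero.

**Numerical details.** log-logistic terms use the stable ±x branches;
log(1 − e^x) switches expansions at log 2; the reflecting ρ walk keeps the
chain in (−1, 1) with a symmetric proposal; occupancy probabilities are
clipped at 1e−12 before logs when evaluating extreme proposals. A
non-finite joint density at initialization raises immediately with a state
dump. Initialization: latent AR(1) values at their year mean of observed
values, binary values at the observed frequency, effects at zero, all
indicators on, variance parameters at prior means, intercepts at the crude
(Mayfield-style) daily-survival logit.

**Run profiles.** The desk default is 3 chains × 10,000 sweeps with 2,000
burn-in; `ModelConfig.paper_profile()` mirrors the full-length design
(three chains totalling 500,000 retained draws after 20,000 burn-in).
`covariate_update_period` refreshes the latent-covariate blocks (and their
process parameters) every k-th sweep — a fixed partial-sweep schedule,
still a valid Gibbs sampler; 2 is recommended at several hundred nests,
where those blocks dominate cost and their conditionals are tight.
Convergence is monitored by the classic potential scale reduction factor
(between/within chain variance), flagged at 1.05.

## Synthetic data

The generator inverts the model plus the field-realistic features the
fitted structure has to cope with:

* **Insects.** Per (taxon, year), trap log-intensity = baseline + a
  Gaussian-shaped seasonal emergence wave (black flies peaking in late
  April, horse flies and mosquitoes later) + a shared AR(1) deviation + an
  independent per-trap AR(1) deviation; counts are Poisson draws, zero
  outside the taxon's emergence window. Trapping happens on 50 of 72 days
  (year one, 7 traps) and 5 of 75 days (year two, 3 traps), with 3% random
  trap-day dropout. Wave amplitude is set so that a single ~34-nest season
  identifies the true effect with precision comparable to the fitted field
  analysis (posterior CI half-width ≈ 0.4).
* **Nests.** 12 pairs per year; first nests start on days 5–20; a failure
  by day 35 triggers one renesting attempt with probability 0.55 after a
  5–8 day delay if a 30-day incubation still fits the season. Daily
  survival follows the logit-linear truth (μ_pair = 3.3, σ_pair = 0.5,
  β_renest = 0.5, β = −0.7 on the black-fly ln-count index, all other
  variables null), using the *fully observed* interpolated covariates.
  Checks are daily with occasional 2–3-day gaps; failures are recorded at
  the first check after death; successful nests hatch on day 30.
* **Pipeline fidelity.** Fixtures go through the same zero-filling
  (emergence windows), interpolation and metric construction as real data,
  so the fitted covariates on unsampled days are genuinely latent.

What the generator does **not** emulate: spatially structured insect
fields beyond the shared wave, detection failure (all nests found),
age-varying hazards, covariate measurement error at observed days beyond
Poisson sampling, or inter-annual dynamics. Passing recovery tests
therefore demonstrates that the estimation machinery is calibrated for
data that match the model's assumptions at field-like sparsity — not that
the model is robust to failures of those assumptions.

## Validation design and problem sizes

* Bayes-factor arithmetic is checked exactly against self-consistent rows
  of the published selection table.
* The binary-covariate imputation is compared with brute-force enumeration
  of all completions of a 5-day latent stretch on one nest (joint
  total-variation distance < 0.02 at 1e5 sweeps; the noise floor of an
  empirical joint over 2^m cells limits m well below the 12 the state
  space would allow).
* A no-data run (two single-day detections, no trapped days) must
  reproduce every prior; with nothing in the likelihood all full
  conditionals collapse to exact prior draws, so this checks the sweep
  plumbing end to end.
* Parameter recovery: 20 independent datasets at tenfold nest count (240
  pairs), each fitted with a single 10,000-sweep chain (2,000 burn-in,
  covariate blocks refreshed every 2nd sweep; a single longer chain per
  replicate was preferred to three short ones since replication across
  datasets already measures run-to-run stability). The 95% credible
  interval for the true effect (conditional on its inclusion) must cover
  −0.7, and its inclusion probability must top all eleven null variables,
  in ≥ 18 of 20 replicates each.
* Survival-likelihood exactness (Bernoulli product; failure-day
  enumeration for gaps), the closed-form S^30 nest-success limit, and the
  R-hat diagnostic round out the suite.

## Known limitations

* Single-site imputation mixes slowly for very long unanchored latent
  stretches; the emergence-window zeros mitigate this for field-shaped
  data, but a season with almost no trapping and no windows would mix
  poorly.
* The V/K prior deliberately shrinks coefficients toward zero when many
  indicators are on; with weakly informative data, conditional effect
  estimates sit noticeably inside the generating value (the price of
  constant total prior uncertainty).
* Coefficient recovery is for the model-scale effect of the
  *interpolated* index. The interpolation itself is a fixed design choice
  (no kriging or model-based spatial smoothing — deliberately out of
  scope), and nests' indices share trap data while the process model
  treats them as independent series, a pseudo-replication the original
  analysis accepts too.
* The occupancy-parameter update on reduced grids is a joint logit
  Metropolis rather than the Beta-conjugate form; its acceptance is tuned
  during burn-in but can be low if φ and γ are extremely unequal.
* The three metrics of one taxon are monotone functions of the same
  exposure and hence strongly correlated candidates. Single-site indicator
  Gibbs mixes slowly between such collinear competitors, and in replicated
  synthetic studies a binary companion occasionally absorbs part of a
  ln-count effect. Rankings between correlated metrics of the same taxon
  should be read with this in mind (the cross-taxon rankings are far more
  stable).
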