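# Methods

## Model

`pitmark` fits a joint live-recapture / dead-recovery state-space model to
capture histories of individuals released in staggered cohorts and
re-sampled at K occasions with unequal intervals. Codes per cell:
pre-release (`.`), not detected (`0`), detected alive (`1`), recovered
dead (`2`), censored after a dead recovery (`x`). The release occasion is
the individual's 0th capture: it is deterministic and contributes no
survival or detection term.

For occasion k after release, with Δt_k the interval length in months and
j(k) a season label (summer/winter):

* alive state: L_k | L_{k−1} ~ Bernoulli(L_{k−1} · S_{j}^{Δt_k}), with the
  single season index of the interval — an interval spanning both seasons
  is not split by month; a single S_j is raised to the whole Δt;
* live observation: O_l,k ~ Bernoulli(L_k · Pc_{l,j});
* dead observation (dead-inclusive variants): O_d,k ~ Bernoulli(D_k ·
  Pc_{d,j}), where D_k indicates an available shell.

Assumptions inherited from the study design: no tag loss, no emigration,
constant sampling protocol and area, and no covariate effects (age enters
only through the interval lengths).

### Season assignment

Summer runs June–October and winter October–May, so October belongs to
both definitions. Convention adopted: occasions *dated* in October are
summer occasions; when classifying the months an interval spans, October
counts toward winter, so an interval starting in October is a winter
interval. Intervals are labelled by the majority of calendar months they
span (`majority` rule, the default), ties going to the season of the
terminal occasion; `start` and `terminal` rules are available as
alternatives. On the study calendar the rules agree on every interval.

### Shell persistence

What happens to a shell after death is not observable. Default
`until_recovered`: a dead individual's shell remains detectable at every
subsequent occasion until first recovered (code 2), after which the
individual is censored. The one recovered shell in the study was
excavated from 35 cm of substrate long after any plausible death date,
which motivates persistence. The alternative `single_occasion` mode makes
the shell detectable only at the first occasion after death; it pins the
death time of a recovered individual to its recovery occasion.

### Variants and priors

Eight presets: `model1` (S, Pc_l, Pc_d all seasonal), `model2` (seasonal
Pc_d only), `model3` (no seasonality), `model4` (no seasonality, no dead
submodel — dead recoveries then only constrain the death time and carry
no detection term), and hierarchical counterparts `model1-1` …
`model4-1`. Population probabilities and hypermeans carry Uniform(0,1)
priors. Hierarchical individual rates follow Normal(μ, σ) truncated to
[0,1]; the SDs are shared across seasons and carry Uniform(0,
`prior_sd_upper`) priors with default upper bound 0.5 — a weakly
informative choice for a standard deviation of a quantity bounded in
[0,1], in the spirit of uniform-on-SD recommendations for hierarchical
variance parameters.

## Dataset reconstruction (minimal-miss rule)

The motivating study published only per-occasion totals: releases
(23, 28, 38, 9, 1 at occasions 1–5), live recaptures (23, 50, 88, 97, 96,
95, 94 at occasions 2–8) and one dead recovery (occasion 5).
`reconstruct_dataset` builds the canonical individual-level completion:

1. a backward pass computes, per occasion, the smallest number of alive
   individuals consistent with all later counts; a live-detection deficit
   is a temporary miss (`0`, individual seen later) only when later
   counts force the individual to be alive, otherwise it is a permanent
   disappearance assigned to the earliest consistent interval;
2. a recovered-dead individual dies in the interval immediately before
   its recovery (the latest time consistent with the counts);
3. events are assigned to the lowest-index individuals of the earliest
   eligible cohort, one event per individual.

For the study totals this yields exactly two temporary misses (occasions
3 and 4) and five deaths: one recovered at occasion 5, two unrecovered in
the 5→6 interval and one in each of 6→7 and 7→8. Under the
non-hierarchical likelihoods individuals within a cohort are
exchangeable, so only these pattern counts matter; the fixed assignment
makes the output byte-reproducible. Whether the occasion 6–8 count
declines were really deaths or interleaved misses is unknowable from the
totals; the minimal-miss completion contains the fewest possible
non-detections, so posterior detection (and survival) estimates from it
are one-sided: they can only exceed estimates from the original data.

## Sampler

One sweep updates:

* **death occasions** — exact Gibbs. A row's alive path is monotone, so
  its free part is the death occasion τ ∈ {release+1, …, K} (K = alive
  throughout). The full conditional over τ is enumerated in closed form
  from cumulative transition and observation log-terms, vectorised over
  individuals, and sampled by Gumbel-max;
* **detection probabilities** (non-hierarchical) — conjugate
  Beta(1 + successes, 1 + failures) over the at-risk cells per season;
* **monthly survival** — logit-scale random-walk Metropolis against
  exposure · log S + Σ deaths · log(1 − S^Δt); non-integer Δt makes this
  non-conjugate;
* **hierarchical blocks** — per-individual logit random walks against
  (truncated-normal prior × row likelihood), applied to all individuals
  in parallel, plus random-walk updates of hypermeans and shared SDs.

Proposal scales adapt every 50 iterations of burn-in toward ~35%
acceptance and are then frozen, so the post-burn-in kernel satisfies
detailed balance. Chain c is seeded with `config.seed + c`; runs are
bit-reproducible. Defaults are desk-scale: 3 chains × 20,000 iterations
with 5,000 burn-in for non-hierarchical variants (the study's original
WinBUGS runs used 10⁵–10⁷ iterations; the shorter runs are
convergence-checked instead, with R̂ ≤ 1.05 required before summaries
are trusted). Hierarchical variants mix more slowly, particularly the
Pc_d hierarchy, and need several-fold longer runs.

Numerical choices: likelihood mismatches return −∞ rather than raising,
so samplers reject invalid proposals uniformly; parameters are kept
strictly inside (0,1) by the logit parameterisation; a degenerate
calendar (equal ages) or an inconsistent history is rejected at
construction time.

## DIC

Deviance focus is the observation layer conditional on latent states —
the convention of samplers that treat O_l and O_d as the observed
stochastic nodes — with `complete_data` available as a switch (the
choice shifts every model's DIC by a data-dependent amount, so one focus
must be used within a comparison). D̄ averages the recorded deviance
trace; D(θ̂) plugs in the posterior-mean parameters and the per-cell
posterior modal latent states (the alive frequencies are monotone along
each row, so the cell-wise mode is itself a valid monotone path — a
deterministic, reproducible plug-in). With this latent plug-in p_D can
go negative when never-recovered deaths leave the latent layer genuinely
uncertain (the modal path commits to deaths that many posterior draws
place later); this is a known DIC pathology for discrete latent
plug-ins, and it is why the comparison rules, not p_D itself, carry the
scientific weight. On data whose latent layer is fully observed, p_D
recovers the free-parameter count. Dead-inclusive and dead-exclusive
variants condition on different data and are ranked in separate blocks
(six dead-inclusive models; `model4` vs `model4-1`), with Δ ≤ 5 = well
supported, 5–10 = substantially less supported, > 10 = excluded.

## Simulator and what passing tests show

`simulate_histories` generates data under any variant on any design. The
default truth emulates the study conditions: five cohorts of 23/28/38/9/1
on the eight-occasion, 27.5-month calendar, S = 0.998 per month,
Pc_l = 0.98, Pc_d = 0.4, with hierarchical truths expanding individual
rates from the truncated normals. Replicate r uses seed `base + r`.

The recovery harness (20 replicates by default in the validation suite,
with 3 × 2,500-iteration fits; a 5,000-individual design for the
consistency check) shows that the sampler recovers the generating
parameters with near-nominal credible-interval coverage and vanishing
bias *under the model's own assumptions*. The simulator does not emulate
tag loss, emigration, spatial structure, or over-dispersed detection, so
passing these checks validates the inference machinery, not the
biological adequacy of the model for any particular river.

Problem sizes used in the validation suite (exact-oracle checks on ≤ 4
individuals × ≤ 5 occasions with 250² grid quadrature; 99-individual
study-scale fits; one 5,000-individual consistency fit) were chosen so
the whole suite runs on a laptop in a few minutes.

## Known limitations

* The reconstruction is one consistent completion of the published
  totals, not the original data; only one-sided statements about the
  study's estimates are warranted, and printed DIC values from the
  original data are not reproducible from totals alone.
* p_D under the observation-layer focus with modal-latent plug-in can be
  negative (above); the `complete_data` focus avoids this at the cost of
  a different deviance scale.
* Hierarchical variants with a single recovered shell leave the Pc_d
  hierarchy (μ_Pc_d, σ_Pc_d) close to prior-dominated; long runs and
  skeptical reading of those posteriors are advised.
* No covariates, time-varying (beyond two-season) rates, tag loss, or
  movement.
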