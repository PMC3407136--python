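# Methods

## The model

The package fits one hierarchical Bayesian mixing model to the isotope data
of an entire food web. The observed quantities are replicated isotope ratios
`X_ijr` (per mil) for every species *i* and element *j* (δ¹³C and δ¹⁵N by
default; any number of tracers is supported), plus a binary topological web:
which consumer eats which resource. Optional per-resource elemental
concentrations `c_kj` enable concentration-weighted mixing; they default to
1, which reduces the identity to pure isotopic mixing.

Latent quantities:

- `s_ij` — mean isotope ratio of species *i*, element *j* (per mil). Free
  parameters for basal species only. Every consumer mean is the
  deterministic concentration-weighted mixture of its resources' means plus
  link-specific trophic enrichment:
  `s_ij = Σ_m q_im c_k[m]j (s_k[m]j + Δ_k[m]→i,j) / Σ_m q_im c_k[m]j`.
  Means are evaluated in topological order. A cannibal self-link is legal:
  the defining equation is linear in the consumer's own mean and is solved
  exactly. Feeding loops of length ≥ 2 are rejected — the sequential
  structure cannot represent them.
- `q_i` — dietary proportion vector of consumer *i* on the simplex over its
  `M_i` resources; prior `Dirichlet(α = 1, …, 1)` (flat).
- `Δ_link,j` — trophic enrichment factor (TEF) of one link and element
  (per mil); prior `Normal(Λ_j, τ_j²)` with `Λ_C = 0.8`, `Λ_N = 3.4` (diet–
  tissue enrichment literature values) and `τ_j ~ half-Cauchy(scale 25)`,
  i.e. the between-link TEF spread is estimated from the web itself. A
  uniform-prior variant uses fixed bounds `[-2.2, 3.0]` (C) and `[1.4, 5.4]`
  (N), the literature mean ± 2 SD. A `fixed_sd` option pins the TEF prior SD
  instead of estimating it, which is how "known TEF" analyses are expressed.
- `σ²_ij` — residual variance per species × element (per mil²); prior
  `Gamma(0.001, 0.001)` on the precision (the standard vague convention).
- basal means — prior `Normal(0, 1000²)` (vague on the per-mil scale).

Likelihood: `X_ijr ~ Normal(s_ij, σ²_ij)`, independent across replicates.
Because consumer means are deterministic functions of basal means, diets and
TEFs, isotope information propagates through the whole web in both
directions; this is the point of fitting the web jointly rather than one
consumer at a time.

## Sampling

The posterior is sampled on an unconstrained parameterisation: additive
log-ratio (ALR) coordinates for each diet simplex, log variances, log TEF
spreads, and non-centred TEFs (`Δ = Λ + τ·η`, `η ~ N(0,1)`), with all
change-of-variable Jacobians included. The non-centred form avoids the
hierarchical funnel that makes centred per-link TEFs nearly unsamplable when
individual links carry little direct information.

The kernel (numba-compiled) performs, per iteration:

1. one componentwise **slice-sampling** sweep (stepping-out with at most 6
   expansions, then shrinkage). Slice sampling needs no acceptance-rate
   tuning; per-coordinate bracket widths are adapted to twice the average
   conditional move during burn-in (every 50 sweeps) and frozen afterwards;
2. one **swap move** per consumer: two randomly chosen resources exchange
   their diet shares together with their TEF coordinates, accepted by a
   Metropolis ratio. The map is an involution with unit Jacobian (the ALR
   Jacobian, Π q_m, is permutation-invariant). Diet posteriors are
   frequently multimodal when two resources are isotopically similar;
   axis-aligned updates essentially never cross between such modes, while
   the swap move does.

Initial states put basal means at sample means, variances at sample
variances (floored at 1e-3), diets at the barycentre, TEFs at their prior
means; chains beyond the first are jittered (SD 0.5 on the unconstrained
scale) and re-jittered until the density is finite. Defaults follow the
standard short-run recipe — 10000 iterations, 5000 burn-in, thinning 5,
3 chains — giving 1000 retained draws per chain. Convergence is summarised
by split-chain Gelman–Rubin R-hat per natural-scale parameter, with < 1.1 as
the operational threshold; effective sample sizes and Monte-Carlo standard
errors come from arviz. The compiled target density is verified against an
independent numpy implementation of the likelihood, priors and Jacobians to
1e-10 in the test suite, and against closed-form posteriors (two-source
mixing; the conjugate inverse-gamma variance posterior).

## Synthetic data (what the generator emulates)

The virtual-data generator reproduces the validation conditions used to
study the model:

- topologies from the **niche model** with species count S and target
  connectance C = L/S² (feeding ranges `r = n·x`, `x ~ Beta(1, (1−2C)/(2C))`,
  centre `~ U(r/2, n)`, smallest-niche species forced basal). Webs that are
  disconnected, cyclic after cannibal-link removal, or contain trophically
  identical species are redrawn (10000-attempt bound). Cannibal links are
  removed before data generation; study ranges are S 10–30, C 0.05–0.3,
  n 5–50 replicates, σ² 0.1–10;
- true diets drawn flat-Dirichlet over each consumer's resources;
- true TEFs drawn per link and element from `Normal(0.8, 1.3²)` (C) and
  `Normal(3.4, 1.0²)` (N). The means match the model's prior locations; the
  SDs are back-solved from the "mean ± 2 SD" uniform ranges above, the only
  anchor available — they are configurable;
- basal signatures uniform on [−30, 0] ‰ (C) and [0, 5] ‰ (N), independent
  per species and element; consumer means propagated sequentially through
  the true diets and TEFs; n Gaussian replicates per species × element.

What it deliberately does not emulate: tissue-specific fractionation,
isotopic routing, temporal variation, covarying basal signatures, or
concentration data (concentrations default to 1 in simulations). Passing
recovery tests therefore demonstrates statistical correctness of the
machinery under the stated generating process, not field realism.

### A note on attainable recovery

Per-link TEF noise with SD 1.3/1.0 ‰ is irreducible by replicates (no link
is observed directly), so the posterior medians of weakly constrained,
multi-resource consumers shrink toward the flat-prior mean 1/M. At desk
scale the regression of posterior-median on true proportions in the
S=20/C=0.1/n=10/σ²=0.1 regime yields slopes of roughly 0.75–0.96 depending
on the web realisation (shrinkage grows with a consumer's resource count);
exact recovery is confirmed whenever TEFs are fixed. Smaller generating TEF
spreads would raise the slope toward 1; the defaults were chosen from the
literature anchor above and kept.

## Topological perturbations

- **False links**: absent non-self pairs whose resource's sample-mean δ¹⁵N
  is below the consumer's; candidates (individually or jointly) closing a
  feeding loop are rejected, since the mixing structure is acyclic. Added
  links carry true proportion 0 for evaluation.
- **Omitted links**: uniform k-subsets, resampled until every consumer keeps
  ≥ 1 resource. Surviving links keep their original, un-renormalised true
  proportions (renormalising would hide the signature of missing flows).
- **Omitted species**: uniform k-subsets (k capped at 20% of S,
  round-half-up), resampled until no surviving consumer is resource-less.
- **Trophospecies aggregation**: additive-Jaccard trophic similarity
  (resource- and consumer-neighbourhood overlaps added, tagged by role),
  average-linkage (ASBC) agglomeration over original-species pairs, merging
  while the best pair's similarity ≥ the threshold; equal similarities merge
  the lexicographically smallest pair. Members' replicates are pooled, links
  unioned, and true diets remain defined only for un-aggregated consumers
  (an aggregated consumer's internal flows cannot be apportioned).
- Level caps use round-half-up of 20% of links/species — the convention
  consistent with suite sizes 880/970/2320 for webs of 29/203, 26/228 and
  50/556 species/links — with 10 replicate draws per level.

Accuracy is the OLS slope (with intercept) of estimated on true proportions
pooled over all links of a test set; precision is the R² of that regression.

## Bayes factors

Candidate topologies over the same species set are compared by the
product-space (Carlin–Chib) method: a binary indicator M is Gibbs-sampled
jointly with both models' parameter blocks, `BF = posterior odds / prior
odds` with 0.5/0.5 prior model probabilities and 3 chains by default.
Coordinates whose meaning is identical under both candidates — residual
variances, TEF spreads, basal means, and the diet/TEF coordinates of
consumers whose resource lists do not differ — are shared between the
blocks; only the difference (typically a handful of coordinates when
candidates differ by a few links) is refreshed from moment-matched
full-covariance normal pseudo-priors fitted to single-model pilot runs.
Sharing is what keeps the indicator mixing: with whole-vector pseudo-priors
the density ratio has enormous variance in ~10²-dimensional posteriors and
the indicator never switches. With identical candidates the construction
reduces exactly to a fair coin. Convergence is assessed by R-hat of the
indicator across chains; if the indicator never switches in some chain the
BF is withheld. Only pairwise comparisons are supported, matching the
intended use.

## Numerical choices and edge cases

- ALR reference category is each consumer's last-listed resource; the
  canonical resource order is the web's link order, so results are invariant
  to relabeling but reproducible for a fixed input file.
- Single-resource consumers have q ≡ 1 and contribute no free diet
  coordinates.
- Degenerate inputs fail loudly: duplicate links, unknown species, missing
  data cells, non-positive variances, cycles, infeasible perturbation
  levels.
- `σ²` is floored at 1e-3 only in the initial state, never in the target.
- When the TEF prior SD is pinned (`fixed_sd`) or the uniform family is
  used, the unused log-τ coordinate carries a standard-normal dummy density
  so the flat joint stays proper; it decouples from everything else.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` (package code) and a per-chain seed for the
  compiled kernel's RNG; fits are bit-reproducible for a fixed seed.

## Desk-scale profiles

Full-scale validation (1500 random parameter draws; 20%-cap perturbation
suites of hundreds of fits) is cluster-sized. The shipped tests and the
acceptance script run desk-scale analogues: the same generating conditions
with smaller webs, fewer replicates and shorter single chains for trend
suites (these problem sizes are stated in the tests themselves), and the
full default MCMC settings wherever a headline number is recomputed.

## Known limitations

- Feeding loops of length ≥ 2 (other than cannibalism) are outside the
  model class; aggregation or false-link proposals that would create them
  are rejected.
- The regression-slope accuracy index conflates shrinkage with bias; under
  heavy TEF noise the slope is attenuated even when the posterior is
  exactly calibrated (see the note above).
- Under link omission, un-renormalised truths inflate surviving estimates
  and push the regression slope up, while the mis-specification also
  inflates the shared TEF spread, whose extra shrinkage pulls it down. On
  dense webs the inflation dominates (slope rises, precision falls); on
  small sparse webs, where omission can strip consumers down to single
  resources, the shrinkage side dominates and the slope direction flips.
- Energy-flow (biomass flux) webs are not estimated; diet proportions are
  assimilation-based mixture weights only.
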