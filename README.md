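# isoweb

Bayesian stable-isotope mixing models for **whole food webs**: estimate the
dietary proportions of *every* consumer in a topological web simultaneously
from replicated δ¹³C / δ¹⁵N measurements (extensible to more tracers), with
trophic enrichment factors (TEFs) treated as link-specific random effects.

Classical mixing models (IsoError, MixSIR, SIAR) treat one consumer at a
time. Here the whole web is one hierarchical model, so isotope information
pools through the network: a predator's signature constrains its prey's
latent means and vice versa.

## The model

For species *i*, element *j* and replicate measurement `X_ijr`:

```
X_ijr ~ Normal(s_ij, sigma2_ij)

s_ij  =  sum_m q_i[m] * c_k[m],j * (s_k[m],j + Delta_k[m]->i,j)
         -----------------------------------------------------   (consumers)
         sum_m q_i[m] * c_k[m],j
```

where `k[m]` runs over consumer *i*'s resources, `q_i` is its dietary
proportion vector on the simplex, `c` are (optional) elemental
concentrations, and `Delta` is the TEF of one trophic link. Basal species'
means are free parameters; every consumer mean is the deterministic mixture
above, evaluated in topological order (cannibal self-links are resolved in
closed form; longer feeding loops are not representable).

Priors: `q_i ~ Dirichlet(1, …, 1)`; `Delta_link,j ~ Normal(Λ_j, τ_j²)` with
`Λ_C = 0.8 ‰`, `Λ_N = 3.4 ‰` and `τ_j ~ half-Cauchy(25)` (a uniform TEF
prior variant with bounds `[-2.2, 3.0]` and `[1.4, 5.4] ‰` is available);
`Normal(0, 1000²)` on basal means; `Gamma(0.001, 0.001)` on residual
precisions. The posterior is sampled by componentwise slice sampling over an
unconstrained parameterisation (additive log-ratio diets, log variances,
non-centred TEFs) with a mode-hopping swap move, compiled with numba.
Defaults: 10000 iterations, 5000 burn-in, thinning 5, 3 chains; convergence
is monitored with split-chain R-hat.

The package also ships the full validation machinery: a niche-model topology
generator, a virtual-data generator (uniform basal signatures, sequential
propagation, Gaussian replicates), topological perturbations (false links,
omitted links/species, trophospecies aggregation by additive-Jaccard/ASBC
clustering), slope/R² accuracy–precision scoring, and product-space
(Carlin–Chib) Bayes factors between candidate topologies.

## Worked example

```python
from isoweb import NicheModelConfig, make_test_set, accuracy_precision
from isoweb.model import IsoWebModel

# a virtual experiment: 20-species niche web, connectance 0.1,
# 10 replicates per species, residual variance 0.1
ts = make_test_set(NicheModelConfig(S=20, C=0.1, seed=3), n=10,
                   variances=0.1, seed=3)

res = IsoWebModel(ts.web, ts.data).fit(seed=3)       # default MCMC settings
ds = res.diet_summary()
multi = ds[ds.consumer.map(lambda c: len(ts.web.resources_of(c)) >= 3)]
print(multi.head(4).to_string(index=False))
print("max R-hat:", round(res.max_rhat, 3))

ev = accuracy_precision(res.diet_medians(), ts.diets)
print(f"slope={ev.slope:.3f}  R2={ev.r_squared:.3f}  n={ev.n_pairs}")
```

Output from this exact script:

```
consumer resource   median     lo95     hi95     rhat
    sp08     sp01 0.117477 0.005203 0.408184 1.029644
    sp08     sp02 0.392544 0.188713 0.558373 1.053742
    sp08     sp03 0.109346 0.004484 0.372788 1.018083
    sp08     sp04 0.126891 0.009939 0.353490 1.010141
max R-hat: 1.705
slope=0.907  R2=0.837  n=54
```

`slope` (accuracy) is the OLS coefficient of posterior-median versus true
dietary proportions over all 54 links — 1.0 means unbiased recovery — and
`R²` (precision) is its coefficient of determination. The wide 95% credible
intervals reflect between-link TEF variation, which the model propagates
rather than ignores; the max R-hat above 1.1 flags a handful of multimodal
diet components for which a longer run would be warranted.

From the shell, the same pipeline is:

```bash
isoweb simulate-web --species 20 --connectance 0.1 --seed 3 --out web.csv
isoweb simulate-data --web web.csv --n 10 --var-c 0.1 --var-n 0.1 --seed 3 --out-prefix sim
isoweb fit --web web.csv --data sim_isotopes.csv --seed 3 --out posterior.csv
isoweb evaluate --estimates posterior.csv --truth sim_true_diets.csv
```

`isoweb perturb`, `isoweb compare` and `isoweb sweep` drive the topological
sensitivity analysis and model comparison; see `--help` on each.

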