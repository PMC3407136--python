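"""The joint probability model: likelihood, mixture structure, and priors.

Observed isotope ratios X_ijr of species i, element j are Normal(s_ij,
sigma2_ij).  Basal-species means are free parameters; every consumer mean is
the deterministic concentration-weighted mixture of its resources' means
plus link-specific TEFs,

    s_ij = sum_m q_im c_kj (s_kj + Delta_kj) / sum_m q_im c_kj ,

so isotope information pools through the whole web.  Cannibal self-links are
resolved in closed form from the linear self-consistency equation; cycles of
length >= 2 are rejected.  Priors: Dirichlet(alpha) on each diet simplex,
hierarchical Normal(mean_j, tau_j^2) with half-Cauchy(tau_j) on TEFs (or a
uniform variant), Normal on basal means, Gamma on residual precisions.

`IsoWebModel` is the user-facing entry point: construct from a web and an
isotope dataset, call :meth:`IsoWebModel.fit` to sample the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import IsotopeDataset
from .foodweb import FoodWeb, topological_order, validate_web
from .priors import PriorConfig

__all__ = [
    "ParameterState",
    "IsoWebModel",
    "consumer_means",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]


@dataclass
class ParameterState:
    """One full set of latent quantities.

    basal_means: (species, element) -> mean isotope ratio (per mil), basal only
    sigma2:      (species, element) -> residual variance (per mil^2), all species
    diets:       (consumer, resource) -> dietary proportion
    tefs:        (consumer, resource, element) -> enrichment (per mil)
    tau:         element -> TEF prior SD (per mil)

    Consumer means are not free: they are recomputed from (basal_means,
    diets, tefs, concentrations) via the mixture identity.
    """

    basal_means: dict[tuple[str, str], float]
    sigma2: dict[tuple[str, str], float]
    diets: dict[tuple[str, str], float]
    tefs: dict[tuple[str, str, str], float]
    tau: dict[str, float]


def consumer_means(
    state: ParameterState,
    web: FoodWeb,
    concentrations: dict[tuple[str, str], float] | None = None,
) -> dict[tuple[str, str], float]:
    """Deterministic species means implied by a parameter state.

    Identical mixture identity as the synthetic-data propagation, evaluated
    on latent parameters.  A cannibal self-link with proportion q_self is
    resolved exactly:  s (sum q c - q_self c_self) =
    sum_{m != self} q c (s_res + D) + q_self c_self D_self.
    """
    elements = sorted({e for (_, e) in state.sigma2})
    conc = concentrations or {}
    means: dict[tuple[str, str], float] = dict(state.basal_means)
    for sp in topological_order(web):
        if web.is_basal(sp):
            for e in elements:
                if (sp, e) not in means:
                    raise ValueError(f"missing basal mean for ({sp!r}, {e!r})")
            continue
        for e in elements:
            num = 0.0
            den = 0.0
            for r in web.resources_of(sp):
                w = state.diets[(sp, r)] * conc.get((r, e), 1.0)
                d = state.tefs[(sp, r, e)]
                if r == sp:
                    num += w * d
                else:
                    num += w * (means[(r, e)] + d)
                    den += w
            if den <= 0.0:
                raise ValueError(
                    f"consumer {sp!r} has no effective non-self diet weight"
                )
            means[(sp, e)] = num / den
    return means


def log_likelihood(
    state: ParameterState,
    web: FoodWeb,
    data: IsotopeDataset,
    concentrations: dict[tuple[str, str], float] | None = None,
) -> float:
    """Sum of Normal log-densities of every replicate at its species mean."""
    means = consumer_means(state, web, concentrations)
    total = 0.0
    for sp in web.species:
        for e in data.elements:
            x = data.values(sp, e)
            if len(x) == 0:
                raise ValueError(f"no measurements for ({sp!r}, {e!r})")
            s2 = state.sigma2[(sp, e)]
            if s2 <= 0.0:
                return -np.inf
            m = means[(sp, e)]
            total += float(
                -0.5 * len(x) * (math.log(2.0 * math.pi) + math.log(s2))
                - np.sum((x - m) ** 2) / (2.0 * s2)
            )
    return total


def log_prior(state: ParameterState, web: FoodWeb, prior: PriorConfig) -> float:
    """Joint log prior density; -inf encodes support violations."""
    lp = 0.0
    elements = sorted(state.tau)
    # diet simplexes: Dirichlet(alpha) per consumer
    a = prior.dirichlet_alpha
    for c in web.consumers:
        resources = web.resources_of(c)
        q = np.array([state.diets[(c, r)] for r in resources])
        if np.any(q <= 0.0) or abs(q.sum() - 1.0) > 1e-6:
            return -np.inf
        M = len(q)
        if M > 1:
            lp += math.lgamma(M * a) - M * math.lgamma(a) + (a - 1.0) * np.log(q).sum()
    # TEF spread and per-link TEFs
    for e in elements:
        p = prior.tef_prior(e)
        tau = state.tau[e]
        if p.family == "normal" and p.fixed_sd is None:
            if tau <= 0.0:
                return -np.inf
            lp += math.log(2.0) - math.log(
                math.pi * p.sd_scale * (1.0 + (tau / p.sd_scale) ** 2)
            )
    for (c, r) in web.links:
        for e in elements:
            p = prior.tef_prior(e)
            d = state.tefs[(c, r, e)]
            if p.family == "uniform":
                lo, hi = p.bounds
                if not lo <= d <= hi:
                    return -np.inf
                lp += -math.log(hi - lo)
            else:
                sd = p.fixed_sd if p.fixed_sd is not None else state.tau[e]
                if sd <= 0.0:
                    return -np.inf
                lp += float(stats.norm.logpdf(d, p.mean, sd))
    # basal means
    for (sp, e), s in state.basal_means.items():
        lp += float(stats.norm.logpdf(s, prior.basal_mean_loc, prior.basal_mean_sd))
    # residual precisions
    sh, rt = prior.residual_precision_shape, prior.residual_precision_rate
    for (sp, e), s2 in state.sigma2.items():
        if s2 <= 0.0:
            return -np.inf
        lp += float(stats.gamma.logpdf(1.0 / s2, sh, scale=1.0 / rt))
    return float(lp)


def log_posterior(
    state: ParameterState,
    web: FoodWeb,
    data: IsotopeDataset,
    prior: PriorConfig,
    concentrations: dict[tuple[str, str], float] | None = None,
) -> float:
    lpr = log_prior(state, web, prior)
    if not np.isfinite(lpr):
        return -np.inf
    return lpr + log_likelihood(state, web, data, concentrations)


# ---------------------------------------------------------------------------
# Flat parameterisation shared with the compiled sampler
# ---------------------------------------------------------------------------


class ModelArrays:
    """Index arrays and the flat unconstrained parameter layout.

    theta = [basal means | log sigma2 | ALR diet coords | TEFs | log tau],
    species ordered topologically so means propagate in one pass.
    """

    def __init__(
        self,
        web: FoodWeb,
        data: IsotopeDataset,
        prior: PriorConfig,
        elements: tuple[str, ...] | None = None,
    ):
        self.web = web
        self.prior = prior
        self.elements = tuple(elements or data.elements)
        E = len(self.elements)
        self.species = topological_order(web)
        S = len(self.species)
        self.sp_index = {s: i for i, s in enumerate(self.species)}

        basal = set(web.basal)
        self.basal_species = [s for s in self.species if s in basal]
        self.basal_slot = np.full(S, -1, dtype=np.int64)
        for slot, s in enumerate(self.basal_species):
            self.basal_slot[self.sp_index[s]] = slot
        nb = len(self.basal_species)

        # CSR of resources per consumer; link order is canonical
        cons_ptr = np.zeros(S + 1, dtype=np.int64)
        res_idx: list[int] = []
        self.link_pairs: list[tuple[str, str]] = []
        zoff = np.full(S, -1, dtype=np.int64)
        nz = 0
        for i, sp in enumerate(self.species):
            resources = web.resources_of(sp)
            for r in resources:
                res_idx.append(self.sp_index[r])
                self.link_pairs.append((sp, r))
            cons_ptr[i + 1] = cons_ptr[i] + len(resources)
            if len(resources) >= 2:
                zoff[i] = nz
                nz += len(resources) - 1
        self.cons_ptr = cons_ptr
        self.res_idx = np.array(res_idx, dtype=np.int64)
        self.zoff = zoff
        self.nz = nz
        L = len(self.link_pairs)

        self.conc = np.ones((S, E))
        for i, sp in enumerate(self.species):
            for j, e in enumerate(self.elements):
                self.conc[i, j] = data.concentration(sp, e)

        self.nobs = np.zeros((S, E))
        self.sumx = np.zeros((S, E))
        self.sumx2 = np.zeros((S, E))
        for i, sp in enumerate(self.species):
            for j, e in enumerate(self.elements):
                x = data.values(sp, e)
                self.nobs[i, j] = len(x)
                self.sumx[i, j] = x.sum()
                self.sumx2[i, j] = (x**2).sum()

        self.tef_family = np.zeros(E, dtype=np.int64)
        self.tef_mean = np.zeros(E)
        self.tef_sd_fixed = np.full(E, np.nan)
        self.hc_scale = np.full(E, 25.0)
        self.tef_lo = np.zeros(E)
        self.tef_hi = np.ones(E)
        for j, e in enumerate(self.elements):
            p = prior.tef_prior(e)
            self.tef_family[j] = 0 if p.family == "normal" else 1
            self.tef_mean[j] = p.mean
            if p.fixed_sd is not None:
                self.tef_sd_fixed[j] = p.fixed_sd
            self.hc_scale[j] = p.sd_scale
            if p.bounds is not None:
                self.tef_lo[j], self.tef_hi[j] = p.bounds

        self.E, self.S, self.nb, self.L = E, S, nb, L
        self.off_u = nb * E
        self.off_z = self.off_u + S * E
        self.off_d = self.off_z + nz
        self.off_v = self.off_d + L * E
        self.n_params = self.off_v + E

    # -- kernel plumbing ----------------------------------------------------
    def kernel_args(self, use_likelihood: bool = True) -> tuple:
        return (
            self.E,
            self.S,
            self.L,
            self.basal_slot,
            self.cons_ptr,
            self.res_idx,
            self.zoff,
            self.conc,
            self.nobs,
            self.sumx,
            self.sumx2,
            1 if use_likelihood else 0,
            self.tef_family,
            self.tef_mean,
            self.tef_sd_fixed,
            self.hc_scale,
            self.tef_lo,
            self.tef_hi,
            float(self.prior.dirichlet_alpha),
            float(self.prior.basal_mean_loc),
            float(self.prior.basal_mean_sd),
            float(self.prior.residual_precision_shape),
            float(self.prior.residual_precision_rate),
            self.off_u,
            self.off_z,
            self.off_d,
            self.off_v,
        )

    # -- flat <-> structured -------------------------------------------------
    def flatten(self, state: ParameterState) -> np.ndarray:
        theta = np.zeros(self.n_params)
        for slot, sp in enumerate(self.basal_species):
            for j, e in enumerate(self.elements):
                theta[slot * self.E + j] = state.basal_means[(sp, e)]
        for i, sp in enumerate(self.species):
            for j, e in enumerate(self.elements):
                theta[self.off_u + i * self.E + j] = math.log(state.sigma2[(sp, e)])
        for i, sp in enumerate(self.species):
            a, b = self.cons_ptr[i], self.cons_ptr[i + 1]
            if b - a < 2:
                continue
            q = np.array(
                [state.diets[self.link_pairs[m]] for m in range(a, b)]
            )
            z = np.log(q[:-1]) - np.log(q[-1])
            theta[self.off_z + self.zoff[i] : self.off_z + self.zoff[i] + b - a - 1] = z
        for j, e in enumerate(self.elements):
            theta[self.off_v + j] = math.log(state.tau.get(e, 1.0))
        for m, (c, r) in enumerate(self.link_pairs):
            for j, e in enumerate(self.elements):
                d = state.tefs[(c, r, e)]
                if self.tef_family[j] == 0:
                    sd = self._tau_eff(theta, j)
                    theta[self.off_d + m * self.E + j] = (d - self.tef_mean[j]) / sd
                else:
                    theta[self.off_d + m * self.E + j] = d
        return theta

    def _tau_eff(self, theta: np.ndarray, j: int) -> float:
        """Effective TEF prior SD of element j (pinned or exp(log tau))."""
        if not np.isnan(self.tef_sd_fixed[j]):
            return float(self.tef_sd_fixed[j])
        return float(math.exp(theta[self.off_v + j]))

    def diets_from_theta(self, theta: np.ndarray) -> np.ndarray:
        """Per-link diet proportions (length L) for one theta vector."""
        q = np.empty(self.L)
        for i in range(self.S):
            a, b = self.cons_ptr[i], self.cons_ptr[i + 1]
            M = b - a
            if M == 0:
                continue
            if M == 1:
                q[a] = 1.0
                continue
            z = theta[self.off_z + self.zoff[i] : self.off_z + self.zoff[i] + M - 1]
            full = np.concatenate([z, [0.0]])
            full -= full.max()
            expz = np.exp(full)
            q[a:b] = expz / expz.sum()
        return q

    def unflatten(self, theta: np.ndarray) -> ParameterState:
        E = self.E
        basal_means = {
            (sp, e): float(theta[slot * E + j])
            for slot, sp in enumerate(self.basal_species)
            for j, e in enumerate(self.elements)
        }
        sigma2 = {
            (sp, e): float(math.exp(theta[self.off_u + i * E + j]))
            for i, sp in enumerate(self.species)
            for j, e in enumerate(self.elements)
        }
        qflat = self.diets_from_theta(theta)
        diets = {pair: float(qflat[m]) for m, pair in enumerate(self.link_pairs)}
        tefs = {}
        for m, (c, r) in enumerate(self.link_pairs):
            for j, e in enumerate(self.elements):
                x = float(theta[self.off_d + m * E + j])
                if self.tef_family[j] == 0:
                    x = float(self.tef_mean[j]) + self._tau_eff(theta, j) * x
                tefs[(c, r, e)] = x
        tau = {
            e: float(math.exp(theta[self.off_v + j]))
            for j, e in enumerate(self.elements)
        }
        return ParameterState(basal_means, sigma2, diets, tefs, tau)

    def log_jacobian(self, theta: np.ndarray) -> float:
        """log |d(natural)/d(unconstrained)| for the transformed coordinates."""
        lj = 0.0
        q = self.diets_from_theta(theta)
        for i in range(self.S):
            a, b = self.cons_ptr[i], self.cons_ptr[i + 1]
            if b - a >= 2:
                lj += float(np.log(q[a:b]).sum())
        # log sigma2: density over precision p = exp(-u); |dp/du| = p
        lj += float(-theta[self.off_u : self.off_z].sum())
        # log tau for hierarchical elements; when tau is pinned (fixed_sd or
        # uniform family) the unused coordinate carries a standard-normal
        # dummy density instead, keeping the flat joint proper
        for j in range(self.E):
            v = theta[self.off_v + j]
            if np.isnan(self.tef_sd_fixed[j]) and self.tef_family[j] == 0:
                lj += float(v)
            else:
                lj += -0.5 * math.log(2.0 * math.pi) - 0.5 * float(v) ** 2
            # non-centred TEFs: d(Delta)/d(eta) = tau_eff per link
            if self.tef_family[j] == 0:
                lj += self.L * math.log(self._tau_eff(theta, j))
        return lj

    def coordinate_names(self) -> list[str]:
        names = []
        for sp in self.basal_species:
            names += [f"s[{sp},{e}]" for e in self.elements]
        for sp in self.species:
            names += [f"log_sigma2[{sp},{e}]" for e in self.elements]
        for i, sp in enumerate(self.species):
            a, b = self.cons_ptr[i], self.cons_ptr[i + 1]
            if b - a >= 2:
                names += [
                    f"alr_q[{sp}|{self.link_pairs[m][1]}]" for m in range(a, b - 1)
                ]
        for (c, r) in self.link_pairs:
            for j, e in enumerate(self.elements):
                tag = "eta" if self.tef_family[j] == 0 else "delta"
                names.append(f"{tag}[{c}->{r},{e}]")
        names += [f"log_tau[{e}]" for e in self.elements]
        return names


class IsoWebModel:
    """Bayesian isotope mixing model over a whole food web.

    Parameters
    ----------
    web
        Topological web (cannibal self-links allowed, longer cycles not).
    data
        Replicated isotope measurements covering every species and element,
        optionally with per-resource elemental concentrations.
    prior
        Prior configuration; defaults to vague priors with the standard TEF
        means (0.8 for d13C, 3.4 for d15N).
    """

    def __init__(
        self,
        web: FoodWeb,
        data: IsotopeDataset,
        prior: PriorConfig | None = None,
    ):
        violations = validate_web(web, allow_cannibalism=True)
        if violations:
            raise ValueError("invalid web: " + "; ".join(violations))
        self.web = web
        self.data = data
        self.prior = prior if prior is not None else PriorConfig.default(data.elements)
        missing = [
            (sp, e)
            for sp in web.species
            for e in data.elements
            if data.n_replicates(sp, e) == 0
        ]
        if missing:
            raise ValueError(f"data missing for species/element cells: {missing}")
        self.arrays = ModelArrays(web, data, self.prior)
        self._conc_dict = {
            (sp, e): data.concentration(sp, e)
            for sp in web.species
            for e in data.elements
        }

    @classmethod
    def from_files(cls, web_path, data_path, conc_path=None, prior_path=None,
                   species_path=None) -> "IsoWebModel":
        from .foodweb import read_web

        web = read_web(web_path, species_path)
        data = IsotopeDataset.from_csv(data_path, conc_path)
        prior = None if prior_path is None else PriorConfig.from_yaml(prior_path)
        return cls(web, data, prior)

    # -- densities ----------------------------------------------------------
    def loglike(self, state: ParameterState) -> float:
        return log_likelihood(state, self.web, self.data, self._conc_dict)

    def logprior(self, state: ParameterState) -> float:
        return log_prior(state, self.web, self.prior)

    def logpost(self, state: ParameterState) -> float:
        return log_posterior(state, self.web, self.data, self.prior, self._conc_dict)

    def logpost_unconstrained(self, theta: np.ndarray, prior_only: bool = False) -> float:
        """Reference log density on the flat unconstrained scale (with Jacobians)."""
        state = self.arrays.unflatten(theta)
        lp = self.logprior(state)
        if not np.isfinite(lp):
            return -np.inf
        if not prior_only:
            lp += self.loglike(state)
        return lp + self.arrays.log_jacobian(theta)

    # -- initialisation -------------------------------------------------------
    def initial_theta(self, rng: np.random.Generator, jitter: float = 0.0) -> np.ndarray:
        """Data-informed start: basal means at sample means, sigma2 at sample
        variances (floored), diets at the barycentre, TEFs at their prior
        means; optionally jittered for overdispersed chains."""
        arr = self.arrays
        theta = np.zeros(arr.n_params)
        for slot, sp in enumerate(arr.basal_species):
            for j, e in enumerate(arr.elements):
                theta[slot * arr.E + j] = self.data.mean(sp, e)
        for i, sp in enumerate(arr.species):
            for j, e in enumerate(arr.elements):
                v = max(self.data.var(sp, e), 1e-3)
                theta[arr.off_u + i * arr.E + j] = math.log(v)
        # normal-family TEFs are non-centred (eta = 0 puts Delta at its mean);
        # uniform-family TEFs start at the prior mean directly
        tef_init = np.where(arr.tef_family == 0, 0.0, arr.tef_mean)
        theta[arr.off_d : arr.off_v] = np.tile(tef_init, arr.L)
        theta[arr.off_v :] = 0.0  # tau = 1
        if jitter > 0.0:
            theta = theta + rng.normal(0.0, jitter, size=theta.shape)
        # keep uniform-family TEFs inside their support
        for j in range(arr.E):
            if arr.tef_family[j] == 1:
                lo, hi = arr.tef_lo[j], arr.tef_hi[j]
                span = hi - lo
                idx = arr.off_d + j + arr.E * np.arange(arr.L)
                theta[idx] = np.clip(theta[idx], lo + 0.01 * span, hi - 0.01 * span)
        return theta

    def fit(
        self,
        iterations: int = 10_000,
        burn_in: int = 5_000,
        thin: int = 5,
        chains: int = 3,
        seed: int | None = None,
        prior_only: bool = False,
        adapt_interval: int = 50,
    ):
        """Sample the posterior by componentwise slice sampling.

        Returns an :class:`isoweb.results.IsoWebResults`.  Chains are
        deterministic given ``seed``; per-coordinate slice bracket widths
        adapt during burn-in and are frozen afterwards.
        """
        from .results import IsoWebResults, MCMCConfig, PosteriorSamples
        from ._kernel import run_chain

        config = MCMCConfig(iterations, burn_in, thin, chains, seed)
        arr = self.arrays
        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.generate_state(2 * chains, dtype=np.uint32)
        args = arr.kernel_args(use_likelihood=not prior_only)

        all_draws, all_lps, all_acc = [], [], []
        for c in range(chains):
            rng = np.random.default_rng(chain_seeds[2 * c])
            jitter = 0.0 if c == 0 else 0.5
            theta = self.initial_theta(rng, jitter)
            for _ in range(100):
                if np.isfinite(self.logpost_unconstrained(theta, prior_only)):
                    break
                theta = self.initial_theta(rng, jitter)
            else:
                raise RuntimeError("could not find a finite-density starting state")
            widths = np.full(arr.n_params, 0.5)
            draws, lps, _, acc = run_chain(
                theta,
                widths,
                iterations,
                burn_in,
                thin,
                adapt_interval,
                int(chain_seeds[2 * c + 1] & 0x7FFFFFFF),
                args,
            )
            all_draws.append(draws)
            all_lps.append(lps)
            all_acc.append(acc)

        samples = PosteriorSamples(
            theta=np.stack(all_draws),
            logpost=np.stack(all_lps),
            names=arr.coordinate_names(),
            arrays=arr,
            config=config,
            acceptance=np.stack(all_acc),
        )
        return IsoWebResults(self, samples)
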