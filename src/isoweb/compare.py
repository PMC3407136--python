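"""Bayes factors between candidate topologies via the product-space method.

Two candidate webs over the same species set are combined into one large
model with a discrete indicator M; the indicator's posterior frequency gives
posterior model probabilities, and BF = posterior odds / prior odds.

Parameters whose meaning is identical under both topologies (residual
variances, TEF spreads, basal means and diet/TEF coordinates of consumers
whose resource lists do not differ) are shared between the two parameter
blocks; only model-specific coordinates carry moment-matched normal
pseudo-priors fitted to single-model pilot runs (Carlin-Chib style).
Restricting the pseudo-priors to the low-dimensional difference between the
candidates is what keeps the indicator mixing; with identical candidates the
indicator reduces exactly to a fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import IsotopeDataset
from .foodweb import FoodWeb
from .priors import PriorConfig
from .results import ess, split_rhat
from ._kernel import logpost_flat, set_seed, slice_sweep

__all__ = ["ComparisonResult", "PseudoPrior", "bayes_factor"]


@dataclass(frozen=True)
class PseudoPrior:
    """Moment-matched multivariate normal fit to a pilot posterior.

    A full covariance (Cholesky-factored) is essential: with independent
    marginals the density ratio between the true posterior and the
    pseudo-prior has enormous variance in high dimension and the model
    indicator never mixes.
    """

    mean: np.ndarray
    chol: np.ndarray  # lower-triangular L with cov = L L'

    def logpdf(self, theta: np.ndarray) -> float:
        from scipy.linalg import solve_triangular

        z = solve_triangular(self.chol, theta - self.mean, lower=True)
        return float(
            -0.5 * len(theta) * np.log(2 * np.pi)
            - np.log(np.diag(self.chol)).sum()
            - 0.5 * (z**2).sum()
        )

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.chol @ rng.standard_normal(len(self.mean))

    @classmethod
    def from_samples(cls, theta: np.ndarray, inflate: float = 1.1) -> "PseudoPrior":
        flat = theta.reshape(-1, theta.shape[-1])
        cov = np.atleast_2d(np.cov(flat.T)) * inflate**2
        ridge = 1e-8 + 1e-4 * float(np.mean(np.diag(cov)))
        for _ in range(12):
            try:
                chol = np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
                return cls(flat.mean(axis=0), chol)
            except np.linalg.LinAlgError:
                ridge *= 10.0
        raise np.linalg.LinAlgError("pilot covariance could not be factored")


class _EmptyPseudo:
    """Pseudo-prior over an empty coordinate set (identical candidates)."""

    def logpdf(self, theta) -> float:
        return 0.0

    def draw(self, rng) -> np.ndarray:
        return np.empty(0)


def _shared_coordinates(model_a, model_b):
    """Indices of coordinates shared between the two layouts, plus the
    model-specific remainder of each.

    Coordinates match by name; diet (ALR) coordinates are shared only for
    consumers whose full resource tuple is identical in both webs, since the
    ALR reference category otherwise differs.
    """
    names_a = model_a.arrays.coordinate_names()
    names_b = model_b.arrays.coordinate_names()
    idx_b = {n: i for i, n in enumerate(names_b)}
    differing = {
        s
        for s in model_a.web.species
        if model_a.web.resources_of(s) != model_b.web.resources_of(s)
    }

    def eligible(name: str) -> bool:
        if name.startswith("alr_q["):
            consumer = name[len("alr_q[") : -1].split("|", 1)[0]
            return consumer not in differing
        return True

    shared_a, shared_b = [], []
    for i, n in enumerate(names_a):
        if n in idx_b and eligible(n):
            shared_a.append(i)
            shared_b.append(idx_b[n])
    shared_a_set = set(shared_a)
    shared_b_set = set(shared_b)
    spec_a = np.array(
        [i for i in range(len(names_a)) if i not in shared_a_set], dtype=int
    )
    spec_b = np.array(
        [i for i in range(len(names_b)) if i not in shared_b_set], dtype=int
    )
    return np.array(shared_a, dtype=int), np.array(shared_b, dtype=int), spec_a, spec_b


@dataclass
class ComparisonResult:
    """Product-space comparison of two topologies (A vs B).

    ``bayes_factor`` is BF_A:B (posterior odds / prior odds); values > 1
    favour A.  It is withheld (None) when the indicator fails to switch in
    some chain.
    """

    posterior_prob: dict[str, float]
    prior_prob: dict[str, float]
    bayes_factor: float | None
    indicator_traces: np.ndarray  # (chains, draws), 1 = model A active
    indicator_rhat: float
    converged: bool
    mcse_prob_a: float | None = None

    def summary(self) -> str:
        bf = "withheld (indicator did not mix)" if self.bayes_factor is None else (
            f"{self.bayes_factor:.3f}"
        )
        return (
            f"P(A|data) = {self.posterior_prob['A']:.3f}, "
            f"P(B|data) = {self.posterior_prob['B']:.3f}, BF_A:B = {bf}"
        )


def _pilot(model, iterations, burn_in, thin, chains, seed):
    res = model.fit(
        iterations=iterations, burn_in=burn_in, thin=thin, chains=chains, seed=seed
    )
    return res.samples.theta, res


def bayes_factor(
    data: IsotopeDataset,
    web_a: FoodWeb,
    web_b: FoodWeb,
    prior: PriorConfig | None = None,
    iterations: int = 10_000,
    burn_in: int = 5_000,
    thin: int = 5,
    chains: int = 3,
    seed: int | None = None,
    prior_probs: tuple[float, float] = (0.5, 0.5),
    pilot_iterations: int | None = None,
) -> ComparisonResult:
    """Bayes factor BF_A:B for two candidate topologies on shared data.

    Both webs must span the same species set.  Each sweep updates the active
    model's parameters by one Metropolis pass of its own posterior, refreshes
    the inactive model's parameters from its pseudo-prior, and Gibbs-samples
    the indicator.  Convergence is assessed by R-hat of the indicator across
    chains; a chain in which the indicator never switches flags
    non-convergence and the BF is withheld.
    """
    from .model import IsoWebModel

    if set(web_a.species) != set(web_b.species):
        raise ValueError("candidate webs must share the same species set")
    if not np.isclose(sum(prior_probs), 1.0) or min(prior_probs) <= 0:
        raise ValueError("prior probabilities must be positive and sum to 1")

    model_a = IsoWebModel(web_a, data, prior)
    model_b = IsoWebModel(web_b, data, prior)
    ss = np.random.SeedSequence(seed)
    s_pa, s_pb, s_ps, s_kernel = [
        int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) for s in ss.spawn(4)
    ]

    pil_iter = pilot_iterations or max(2000, iterations // 2)
    pil_burn = pil_iter // 2
    theta_a, res_a = _pilot(model_a, pil_iter, pil_burn, 1, 2, s_pa)
    theta_b, res_b = _pilot(model_b, pil_iter, pil_burn, 1, 2, s_pb)
    flat_a = theta_a.reshape(-1, theta_a.shape[-1])
    flat_b = theta_b.reshape(-1, theta_b.shape[-1])

    sh_a, sh_b, spec_a, spec_b = _shared_coordinates(model_a, model_b)
    pseudo_a = (
        PseudoPrior.from_samples(flat_a[:, spec_a]) if len(spec_a) else _EmptyPseudo()
    )
    pseudo_b = (
        PseudoPrior.from_samples(flat_b[:, spec_b]) if len(spec_b) else _EmptyPseudo()
    )

    args_a = model_a.arrays.kernel_args(True)
    args_b = model_b.arrays.kernel_args(True)
    # per-coordinate slice bracket widths: ~2x pilot posterior SDs
    scales_a = 2.0 * np.maximum(flat_a.std(axis=0), 1e-3)
    scales_b = 2.0 * np.maximum(flat_b.std(axis=0), 1e-3)

    log_prior_a = float(np.log(prior_probs[0]))
    log_prior_b = float(np.log(prior_probs[1]))
    rng = np.random.default_rng(s_ps)
    set_seed(s_kernel)

    n_keep = (iterations - burn_in) // thin
    traces = np.zeros((chains, n_keep))
    dummy_acc_a = np.zeros(len(scales_a))
    dummy_acc_b = np.zeros(len(scales_b))

    for c in range(chains):
        # start at a pilot draw of the chain's starting model
        ta = flat_a[rng.integers(len(flat_a))].copy()
        tb = flat_b[rng.integers(len(flat_b))].copy()
        m_is_a = bool(c % 2 == 0)
        if m_is_a:
            tb[sh_b] = ta[sh_a]
            tb[spec_b] = pseudo_b.draw(rng)
        else:
            ta[sh_a] = tb[sh_b]
            ta[spec_a] = pseudo_a.draw(rng)
        lp_a = logpost_flat(ta, args_a)
        lp_b = logpost_flat(tb, args_b)
        kept = 0
        for it in range(iterations):
            if m_is_a:
                lp_a = slice_sweep(ta, scales_a, lp_a, dummy_acc_a, args_a)
                tb[sh_b] = ta[sh_a]
                tb[spec_b] = pseudo_b.draw(rng)
                lp_b = logpost_flat(tb, args_b)
            else:
                lp_b = slice_sweep(tb, scales_b, lp_b, dummy_acc_b, args_b)
                ta[sh_a] = tb[sh_b]
                ta[spec_a] = pseudo_a.draw(rng)
                lp_a = logpost_flat(ta, args_a)
            w_a = log_prior_a + lp_a + pseudo_b.logpdf(tb[spec_b])
            w_b = log_prior_b + lp_b + pseudo_a.logpdf(ta[spec_a])
            p_a = 1.0 / (1.0 + np.exp(np.clip(w_b - w_a, -700, 700)))
            m_is_a = bool(rng.random() < p_a)
            if it >= burn_in and (it - burn_in) % thin == thin - 1 and kept < n_keep:
                traces[c, kept] = 1.0 if m_is_a else 0.0
                kept += 1

    switched = [bool(np.any(np.diff(t) != 0)) for t in traces]
    r = split_rhat(traces) if chains >= 2 else np.nan
    converged = all(switched) and (chains < 2 or (np.isfinite(r) and r < 1.1))

    p_a_hat = float(traces.mean())
    p_b_hat = 1.0 - p_a_hat
    post = {"A": p_a_hat, "B": p_b_hat}
    pri = {"A": prior_probs[0], "B": prior_probs[1]}
    if not all(switched) or p_a_hat in (0.0, 1.0):
        bf = None
        mcse = None
    else:
        bf = (p_a_hat / p_b_hat) / (prior_probs[0] / prior_probs[1])
        n_eff = ess(traces)
        mcse = float(np.sqrt(p_a_hat * p_b_hat / n_eff))
    return ComparisonResult(
        posterior_prob=post,
        prior_prob=pri,
        bayes_factor=bf,
        indicator_traces=traces,
        indicator_rhat=float(r) if np.isfinite(r) else np.nan,
        converged=converged,
        mcse_prob_a=mcse,
    )
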