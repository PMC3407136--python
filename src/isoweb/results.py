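"""Posterior containers, convergence diagnostics and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "IsoWebResults",
    "rhat",
    "split_rhat",
    "ess",
    "summarize",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings (defaults follow the standard short-run recipe:
    10000 iterations, 5000 burn-in, thinning 5, three chains)."""

    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    chains: int = 3
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


def split_rhat(x: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor with split chains.

    ``x`` has shape (chains, draws).  Identical chains give 1.0; diverging
    chain means give values well above 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (chains, draws)")
    m, n = x.shape
    if n < 4:
        return np.nan
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m2, n2 = halves.shape
    means = halves.mean(axis=1)
    vars_ = halves.var(axis=1, ddof=1)
    w = vars_.mean()
    b = n2 * means.var(ddof=1)
    if w <= 0.0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def rhat(samples: "PosteriorSamples", parameter: str) -> float:
    """R-hat of one natural-scale parameter (requires >= 2 chains)."""
    names = samples.natural_names()
    if parameter not in names:
        raise KeyError(parameter)
    x = samples.natural_matrix()[:, :, names.index(parameter)]
    if x.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    return split_rhat(x)


def ess(x: np.ndarray) -> float:
    """Effective sample size of (chains, draws) via arviz (bulk ESS)."""
    import arviz as az

    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if np.allclose(x, x.flat[0]):
        return float(x.size)
    val = float(az.ess(az.convert_to_dataset(x[:, :, None]))["x"].values[0])
    return max(val, 1.0)


def mcse_mean(x: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean via ESS."""
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(ess(x)))


@dataclass
class PosteriorSamples:
    """Retained MCMC draws on the flat unconstrained scale.

    ``theta``: (chains, draws, P); ``logpost``: (chains, draws);
    ``names``: flat coordinate names; ``arrays``: the model layout used to
    map draws back to natural parameters.
    """

    theta: np.ndarray
    logpost: np.ndarray
    names: list[str]
    arrays: object
    config: MCMCConfig
    acceptance: np.ndarray | None = None
    _natural: np.ndarray | None = field(default=None, repr=False)
    _natural_names: list[str] | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def natural_names(self) -> list[str]:
        if self._natural_names is None:
            self._build_natural()
        return self._natural_names

    def natural_matrix(self) -> np.ndarray:
        """(chains, draws, K) draws on the natural scale."""
        if self._natural is None:
            self._build_natural()
        return self._natural

    def _build_natural(self) -> None:
        arr = self.arrays
        E = arr.E
        names: list[str] = []
        cols: list[np.ndarray] = []
        th = self.theta  # (C, N, P)

        for slot, sp in enumerate(arr.basal_species):
            for j, e in enumerate(arr.elements):
                names.append(f"s[{sp},{e}]")
                cols.append(th[:, :, slot * E + j])
        for i, sp in enumerate(arr.species):
            for j, e in enumerate(arr.elements):
                names.append(f"sigma2[{sp},{e}]")
                cols.append(np.exp(np.minimum(th[:, :, arr.off_u + i * E + j], 700.0)))
        # diet proportions per link, via the ALR inverse per consumer
        qcols = {m: None for m in range(arr.L)}
        for i, sp in enumerate(arr.species):
            a, b = arr.cons_ptr[i], arr.cons_ptr[i + 1]
            M = b - a
            if M == 0:
                continue
            if M == 1:
                qcols[a] = np.ones(th.shape[:2])
                continue
            z = th[:, :, arr.off_z + arr.zoff[i] : arr.off_z + arr.zoff[i] + M - 1]
            full = np.concatenate([z, np.zeros(th.shape[:2] + (1,))], axis=2)
            full -= full.max(axis=2, keepdims=True)
            expz = np.exp(full)
            qs = expz / expz.sum(axis=2, keepdims=True)
            for m in range(M):
                qcols[a + m] = qs[:, :, m]
        for m, (c, r) in enumerate(arr.link_pairs):
            names.append(f"q[{c}->{r}]")
            cols.append(qcols[m])
        tau_eff = []
        for j in range(E):
            if not np.isnan(arr.tef_sd_fixed[j]):
                tau_eff.append(np.full(th.shape[:2], arr.tef_sd_fixed[j]))
            else:
                tau_eff.append(np.exp(th[:, :, arr.off_v + j]))
        for m, (c, r) in enumerate(arr.link_pairs):
            for j, e in enumerate(arr.elements):
                names.append(f"delta[{c}->{r},{e}]")
                x = th[:, :, arr.off_d + m * E + j]
                if arr.tef_family[j] == 0:
                    x = arr.tef_mean[j] + tau_eff[j] * x
                cols.append(x)
        for j, e in enumerate(arr.elements):
            names.append(f"tau[{e}]")
            cols.append(np.exp(th[:, :, arr.off_v + j]))

        self._natural_names = names
        self._natural = np.stack(cols, axis=2)

    def natural_draws(self) -> pd.DataFrame:
        """Pooled draws (all chains concatenated) as a DataFrame."""
        mat = self.natural_matrix()
        pooled = mat.reshape(-1, mat.shape[2])
        return pd.DataFrame(pooled, columns=self.natural_names())


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter median, 95% credible interval, R-hat and ESS.

    Quantiles pool the post-burn-in, post-thin draws across chains;
    R-hat uses the split-chain Gelman-Rubin statistic.
    """
    mat = samples.natural_matrix()
    names = samples.natural_names()
    pooled = mat.reshape(-1, mat.shape[2])
    med = np.median(pooled, axis=0)
    lo = np.quantile(pooled, 0.025, axis=0)
    hi = np.quantile(pooled, 0.975, axis=0)
    rhats = np.array(
        [
            split_rhat(mat[:, :, k]) if mat.shape[0] >= 2 else np.nan
            for k in range(mat.shape[2])
        ]
    )
    esss = np.array([ess(mat[:, :, k]) for k in range(mat.shape[2])])
    return pd.DataFrame(
        {
            "parameter": names,
            "median": med,
            "lo95": lo,
            "hi95": hi,
            "rhat": rhats,
            "ess": esss,
        }
    ).set_index("parameter")


class IsoWebResults:
    """Fit results: posterior draws plus convenience summaries.

    ``summary()`` returns the full per-parameter table; ``diet_summary()``
    restricts it to dietary proportions with consumer/resource columns.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self._summary: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = summarize(self.samples)
        return self._summary

    # -- diets ---------------------------------------------------------------
    def diet_summary(self) -> pd.DataFrame:
        arr = self.model.arrays
        s = self.summary()
        rows = []
        for c, r in arr.link_pairs:
            row = s.loc[f"q[{c}->{r}]"]
            rows.append(
                {
                    "consumer": c,
                    "resource": r,
                    "median": row["median"],
                    "lo95": row["lo95"],
                    "hi95": row["hi95"],
                    "rhat": row["rhat"],
                }
            )
        return pd.DataFrame(rows)

    def diet_medians(self) -> dict[tuple[str, str], float]:
        """Posterior-median dietary proportion per link (the point estimate)."""
        ds = self.diet_summary()
        return {
            (row.consumer, row.resource): float(row.median)
            for row in ds.itertuples()
        }

    def diet_draws(self, consumer: str, resource: str) -> np.ndarray:
        """(chains, draws) posterior samples of one dietary proportion."""
        k = self.samples.natural_names().index(f"q[{consumer}->{resource}]")
        return self.samples.natural_matrix()[:, :, k]

    def parameter_draws(self, name: str) -> np.ndarray:
        k = self.samples.natural_names().index(name)
        return self.samples.natural_matrix()[:, :, k]

    # -- diagnostics -----------------------------------------------------------
    @property
    def max_rhat(self) -> float:
        r = self.summary()["rhat"].to_numpy()
        if np.all(np.isnan(r)):  # single chain: R-hat undefined
            return float("nan")
        return float(np.nanmax(r))

    @property
    def converged(self) -> bool:
        """All reported parameters below the conventional 1.1 threshold."""
        return bool(self.max_rhat < 1.1)

    @property
    def acceptance_rates(self) -> np.ndarray | None:
        return self.samples.acceptance

    def to_csv(self, path) -> None:
        """Long-format summary `parameter,median,lo95,hi95,rhat`."""
        self.summary().reset_index()[
            ["parameter", "median", "lo95", "hi95", "rhat"]
        ].to_csv(path, index=False)

    # -- plotting ---------------------------------------------------------------
    def plot_diet_recovery(self, truth, path=None):
        """Scatter of posterior-median vs true dietary proportions."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        truth_map = truth.proportions if hasattr(truth, "proportions") else dict(truth)
        est = self.diet_medians()
        keys = [k for k in est if k in truth_map]
        x = [truth_map[k] for k in keys]
        y = [est[k] for k in keys]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(x, y, s=15, alpha=0.7)
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        ax.set_xlabel("true dietary proportion")
        ax.set_ylabel("estimated (posterior median)")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def fit(web, data, prior=None, mcmc: MCMCConfig | None = None) -> IsoWebResults:
    """Functional wrapper around :meth:`isoweb.model.IsoWebModel.fit`."""
    from .model import IsoWebModel

    mcmc = mcmc or MCMCConfig()
    return IsoWebModel(web, data, prior).fit(
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        chains=mcmc.chains,
        seed=mcmc.seed,
    )
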