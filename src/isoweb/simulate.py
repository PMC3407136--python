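"""Virtual test-data generation: true diets, TEFs, propagated means, replicates.

Basal species receive isotope means drawn uniformly over realistic ranges
(-30 to 0 per mil for d13C, 0 to 5 for d15N); consumer means are computed
sequentially up trophic levels as concentration-weighted mixtures of their
resources plus normally distributed link-specific trophic enrichment factors
(TEFs); replicated measurements add Gaussian residual noise.  Every
downstream stage (fitting, perturbation, evaluation) is testable against the
known truth this module produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import IsotopeDataset
from .foodweb import (
    FoodWeb,
    NicheModelConfig,
    generate_niche_web,
    remove_cannibal_links,
    topological_order,
)

__all__ = [
    "TrueDiets",
    "TrueTEFs",
    "SpeciesMeans",
    "TestSet",
    "DEFAULT_TEF_MEANS",
    "DEFAULT_TEF_SDS",
    "DEFAULT_BASAL_RANGES",
    "draw_true_diets",
    "draw_true_tefs",
    "draw_basal_means",
    "propagate_means",
    "sample_isotopes",
    "make_test_set",
]

DEFAULT_ELEMENTS = ("d13C", "d15N")
# TEF generation: means from the diet-tissue enrichment literature; SDs
# back-solved from the "mean +/- 2 SD" uniform ranges [-2.2, 3.0] (C) and
# [1.4, 5.4] (N).
DEFAULT_TEF_MEANS = {"d13C": 0.8, "d15N": 3.4}
DEFAULT_TEF_SDS = {"d13C": 1.3, "d15N": 1.0}
DEFAULT_BASAL_RANGES = {"d13C": (-30.0, 0.0), "d15N": (0.0, 5.0)}


@dataclass(frozen=True)
class TrueDiets:
    """Known dietary proportions, keyed by (consumer, resource) link."""

    proportions: dict[tuple[str, str], float]

    def diet_of(self, consumer: str) -> dict[str, float]:
        return {r: q for (c, r), q in self.proportions.items() if c == consumer}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"consumer": c, "resource": r, "proportion": q}
            for (c, r), q in self.proportions.items()
        ]
        return pd.DataFrame(rows, columns=["consumer", "resource", "proportion"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrueDiets":
        return cls(
            {
                (row.consumer, row.resource): float(row.proportion)
                for row in df.itertuples()
            }
        )


@dataclass(frozen=True)
class TrueTEFs:
    """Known per-link, per-element trophic enrichment factors (per mil)."""

    values: dict[tuple[str, str, str], float]
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TEF_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TEF_SDS))

    def get(self, consumer: str, resource: str, element: str) -> float:
        return self.values[(consumer, resource, element)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"consumer": c, "resource": r, "element": e, "tef": v}
            for (c, r, e), v in self.values.items()
        ]
        return pd.DataFrame(rows, columns=["consumer", "resource", "element", "tef"])


# latent per species x element mean isotope ratios
SpeciesMeans = dict


def draw_true_diets(web: FoodWeb, rng: np.random.Generator | int | None = None) -> TrueDiets:
    """Draw each consumer's diet from the flat Dirichlet over its resources."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    props: dict[tuple[str, str], float] = {}
    for consumer in web.species:
        resources = web.resources_of(consumer)
        if not resources:
            continue
        q = rng.dirichlet(np.ones(len(resources)))
        for r, qi in zip(resources, q):
            props[(consumer, r)] = float(qi)
    return TrueDiets(props)


def draw_true_tefs(
    web: FoodWeb,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrueTEFs:
    """Independent normal TEF per (link, element); sd=0 gives the mean exactly."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    means = dict(DEFAULT_TEF_MEANS) if means is None else dict(means)
    sds = dict(DEFAULT_TEF_SDS) if sds is None else dict(sds)
    for e in elements:
        if sds[e] < 0:
            raise ValueError(f"TEF sd for {e} must be >= 0")
    vals = {
        (c, r, e): float(rng.normal(means[e], sds[e]))
        for c, r in web.links
        for e in elements
    }
    return TrueTEFs(vals, means, sds)


def draw_basal_means(
    web: FoodWeb,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
    ranges: dict[str, tuple[float, float]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> SpeciesMeans:
    """Uniform basal isotope means, independent per species and element."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ranges = dict(DEFAULT_BASAL_RANGES) if ranges is None else dict(ranges)
    return {
        (s, e): float(rng.uniform(*ranges[e]))
        for s in web.basal
        for e in elements
    }


def propagate_means(
    web: FoodWeb,
    diets: TrueDiets,
    tefs: TrueTEFs,
    basal_means: SpeciesMeans,
    concentrations: dict[tuple[str, str], float] | None = None,
) -> SpeciesMeans:
    """Sequentially compute consumer means up the web.

    For consumer i and element j,

        s_ij = sum_m q_m c_kj (s_kj + D_kj) / sum_m q_m c_kj

    over its resources k, evaluated in topological order so every resource
    mean exists before it is consumed.  With all concentrations equal this is
    the plain diet-weighted mixture plus enrichment.
    """
    elements = sorted({e for (_, e) in basal_means})
    for s in web.basal:
        for e in elements:
            if (s, e) not in basal_means:
                raise ValueError(f"missing basal mean for ({s!r}, {e!r})")
    conc = concentrations or {}
    means: SpeciesMeans = dict(basal_means)
    for sp in topological_order(web):
        if web.is_basal(sp):
            continue
        resources = web.resources_of(sp)
        if sp in resources:
            raise ValueError(
                f"cannibal link on {sp!r}: remove self-links before generating "
                "virtual data (the fitted model handles them, the generator "
                "does not)"
            )
        for e in elements:
            num = 0.0
            den = 0.0
            for r in resources:
                w = diets.proportions[(sp, r)] * conc.get((r, e), 1.0)
                num += w * (means[(r, e)] + tefs.get(sp, r, e))
                den += w
            means[(sp, e)] = num / den
    return means


def sample_isotopes(
    means: SpeciesMeans,
    variances,
    n: int,
    rng: np.random.Generator | int | None = None,
    concentrations: pd.DataFrame | None = None,
) -> IsotopeDataset:
    """n independent Normal(mean, variance) replicates per species x element.

    ``variances`` may be a scalar, a per-element dict, or a per
    (species, element) dict; all entries must be positive.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n < 1:
        raise ValueError("n must be >= 1")

    def var_of(sp: str, e: str) -> float:
        if isinstance(variances, dict):
            v = variances.get((sp, e), variances.get(e))
            if v is None:
                raise ValueError(f"no variance for ({sp!r}, {e!r})")
        else:
            v = variances
        v = float(v)
        if v <= 0:
            raise ValueError("variances must be strictly positive")
        return v

    rows = []
    for (sp, e), m in means.items():
        draws = rng.normal(m, np.sqrt(var_of(sp, e)), size=n)
        rows.extend({"species": sp, "element": e, "value": float(x)} for x in draws)
    return IsotopeDataset(pd.DataFrame(rows), concentrations)


@dataclass(frozen=True)
class TestSet:
    """A complete virtual experiment: web, truth, and noisy observations."""

    web: FoodWeb
    diets: TrueDiets
    tefs: TrueTEFs
    means: SpeciesMeans
    data: IsotopeDataset
    seed: int | None = None


def make_test_set(
    niche_config: NicheModelConfig,
    n: int = 10,
    variances=1.0,
    tef_means: dict[str, float] | None = None,
    tef_sds: dict[str, float] | None = None,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
    basal_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> TestSet:
    """Compose the full pipeline: niche web (cannibal links removed), flat
    Dirichlet true diets, normal TEFs, propagated means, Gaussian replicates.
    Fully determined by ``seed``."""
    if seed is None:
        seed = niche_config.seed
    ss = np.random.SeedSequence(seed)
    r_web, r_diet, r_tef, r_basal, r_obs = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    web = remove_cannibal_links(generate_niche_web(niche_config, rng=r_web))
    diets = draw_true_diets(web, r_diet)
    tefs = draw_true_tefs(web, elements, tef_means, tef_sds, r_tef)
    basal = draw_basal_means(web, elements, basal_ranges, r_basal)
    means = propagate_means(web, diets, tefs, basal)
    data = sample_isotopes(means, variances, n, r_obs)
    return TestSet(web, diets, tefs, means, data, seed)
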