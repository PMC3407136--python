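"""Topological food webs: representation, validation, IO and the niche model.

A food web is a set of species and directed consumer->resource links.  Basal
species (primary producers and other nodes with no resources) anchor the
isotope propagation; every other species' isotope mean is a mixture over its
resources.  Webs used for simulation must be acyclic apart from cannibal
self-links; model fitting additionally tolerates self-links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FoodWeb",
    "NicheModelConfig",
    "WebParseError",
    "generate_niche_web",
    "remove_cannibal_links",
    "validate_web",
    "topological_order",
    "read_web",
    "write_web",
]


class WebParseError(ValueError):
    """Raised when an edge-list or species file cannot be interpreted."""


@dataclass(frozen=True)
class FoodWeb:
    """An immutable topological food web.

    Parameters
    ----------
    species
        Ordered unique labels (file/insertion order is canonical).
    links
        Ordered (consumer, resource) pairs; duplicates are rejected.
    declared_basal
        Optional explicit basal set from a companion species file; used only
        by :func:`validate_web` to cross-check against the link structure.
    """

    species: tuple[str, ...]
    links: tuple[tuple[str, str], ...]
    declared_basal: frozenset[str] | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        seen = set()
        sp = set(self.species)
        for c, r in self.links:
            if (c, r) in seen:
                raise ValueError(f"duplicate link {c!r} -> {r!r}")
            seen.add((c, r))
            if c not in sp or r not in sp:
                raise ValueError(f"link endpoint not in species list: {c!r} -> {r!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def connectance(self) -> float:
        """L / S^2 (the niche-model convention)."""
        return self.n_links / self.n_species**2

    def resources_of(self, consumer: str) -> tuple[str, ...]:
        return tuple(r for c, r in self.links if c == consumer)

    def consumers_of(self, resource: str) -> tuple[str, ...]:
        return tuple(c for c, r in self.links if r == resource)

    @property
    def basal(self) -> tuple[str, ...]:
        """Species with no outgoing resource links."""
        consumers = {c for c, _ in self.links}
        return tuple(s for s in self.species if s not in consumers)

    @property
    def consumers(self) -> tuple[str, ...]:
        has_res = {c for c, _ in self.links}
        return tuple(s for s in self.species if s in has_res)

    def is_basal(self, sp: str) -> bool:
        return sp not in {c for c, _ in self.links}

    @property
    def cannibal_links(self) -> tuple[tuple[str, str], ...]:
        return tuple((c, r) for c, r in self.links if c == r)

    def has_link(self, consumer: str, resource: str) -> bool:
        return (consumer, resource) in set(self.links)

    def to_digraph(self, drop_cannibal: bool = False) -> nx.DiGraph:
        """Directed graph with resource -> consumer orientation (flow of mass)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for c, r in self.links:
            if drop_cannibal and c == r:
                continue
            g.add_edge(r, c)
        return g

    def relabel(self, mapping: dict[str, str]) -> "FoodWeb":
        return FoodWeb(
            tuple(mapping.get(s, s) for s in self.species),
            tuple((mapping.get(c, c), mapping.get(r, r)) for c, r in self.links),
        )


def remove_cannibal_links(web: FoodWeb) -> FoodWeb:
    """Drop all self-links (consumer == resource); species set unchanged."""
    return FoodWeb(
        web.species,
        tuple((c, r) for c, r in web.links if c != r),
        web.declared_basal,
    )


def validate_web(web: FoodWeb, allow_cannibalism: bool = True) -> list[str]:
    """Return a list of invariant violations (empty when the web is valid).

    Never raises; each violation names the offending species or link.
    """
    violations: list[str] = []
    for c, r in web.cannibal_links:
        if not allow_cannibalism:
            violations.append(f"cannibal link not allowed: {c} -> {c}")
        elif web.resources_of(c) == (c,):
            violations.append(
                f"species {c!r} consumes only itself (no external resource)"
            )
    if web.declared_basal is not None:
        for s in web.declared_basal - set(web.species):
            violations.append(f"declared basal species {s!r} not in web")
        basal = set(web.basal)
        for s in sorted(web.declared_basal & set(web.species) - basal):
            violations.append(f"species {s!r} declared basal but has resource links")
        for s in sorted(basal - web.declared_basal):
            violations.append(
                f"species {s!r} declared consumer but has no resource links"
            )
    g = web.to_digraph(drop_cannibal=True)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        names = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
        violations.append(f"cycle of length >= 2: {names}")
    return violations


def topological_order(web: FoodWeb) -> list[str]:
    """Species ordered so every resource precedes all of its consumers.

    Cannibal self-links are ignored; basal species come first, and ties are
    broken by the web's canonical species order so the result is
    deterministic.  Raises ``ValueError`` on cycles of length >= 2.
    """
    g = web.to_digraph(drop_cannibal=True)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("web contains a cycle of length >= 2; no topological order")
    idx = {s: i for i, s in enumerate(web.species)}
    basal = set(web.basal)
    order = list(
        nx.lexicographical_topological_sort(g, key=lambda s: (s not in basal, idx[s]))
    )
    return order


# ---------------------------------------------------------------------------
# Niche model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NicheModelConfig:
    """Parameters of the niche-model topology generator.

    S species are placed on a one-dimensional niche axis; each consumes all
    species whose niche value falls in a Beta-distributed feeding range, so
    the expected connectance L/S^2 equals C.
    """

    S: int
    C: float
    seed: int | None = None

    def __post_init__(self):
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if not 0.0 < self.C < 0.5:
            raise ValueError("C must lie in (0, 0.5) for the Beta shape to be positive")


def _niche_web_once(S: int, C: float, rng: np.random.Generator) -> FoodWeb:
    n = np.sort(rng.uniform(0.0, 1.0, size=S))
    beta_shape = (1.0 - 2.0 * C) / (2.0 * C)
    x = rng.beta(1.0, beta_shape, size=S)
    r = n * x
    r[0] = 0.0  # smallest-niche species forced basal
    lo = r / 2.0
    hi = np.minimum(n, 1.0)  # centre drawn in [r/2, n]
    centre = rng.uniform(lo, hi)
    width = max(2, len(str(S)))
    labels = [f"sp{i + 1:0{width}d}" for i in range(S)]
    links = []
    for i in range(S):
        if r[i] <= 0.0:
            continue
        in_range = np.abs(n - centre[i]) <= r[i] / 2.0
        for j in np.nonzero(in_range)[0]:
            links.append((labels[i], labels[j]))
    return FoodWeb(tuple(labels), tuple(links))


def _niche_web_valid(web: FoodWeb) -> bool:
    bare = remove_cannibal_links(web)
    # species left with no role at all after cannibal-link removal
    g = bare.to_digraph()
    if not nx.is_weakly_connected(g):
        return False
    if not nx.is_directed_acyclic_graph(g):
        return False
    # trophically identical species (same resources and same consumers)
    signatures = set()
    for s in bare.species:
        sig = (frozenset(bare.resources_of(s)), frozenset(bare.consumers_of(s)))
        if sig in signatures:
            return False
        signatures.add(sig)
    # a species feeding only on itself has no solvable mixture equation
    for c, _ in web.cannibal_links:
        if not bare.resources_of(c):
            return False
    return True


def generate_niche_web(
    config: NicheModelConfig,
    rng: np.random.Generator | None = None,
    max_tries: int = 10_000,
) -> FoodWeb:
    """Generate one valid niche-model web.

    Invalid draws (disconnected, cyclic after cannibal-link removal, or with
    trophically duplicate species) are discarded and redrawn; after
    ``max_tries`` failures the (S, C) combination is deemed infeasible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(max_tries):
        web = _niche_web_once(config.S, config.C, rng)
        if _niche_web_valid(web):
            return web
    raise RuntimeError(
        f"no valid niche web for S={config.S}, C={config.C} after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_web(path, species_path=None) -> FoodWeb:
    """Read a web from a ``consumer,resource`` edge list.

    An optional companion species file (``species,is_basal``) declares the
    full species set -- required to represent species with no links -- and
    the intended basal roles.  Without it, species are taken in first-seen
    order from the edge list.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for col in ("consumer", "resource"):
        if col not in df.columns:
            raise WebParseError(f"edge list {path} lacks required column {col!r}")
    if df[["consumer", "resource"]].isna().any().any():
        raise WebParseError(f"edge list {path} has malformed rows with missing fields")
    links = list(df[["consumer", "resource"]].itertuples(index=False, name=None))
    dupes = df[df.duplicated(subset=["consumer", "resource"])]
    if len(dupes):
        c, r = dupes.iloc[0][["consumer", "resource"]]
        raise WebParseError(f"duplicate link {c!r} -> {r!r} in {path}")

    declared_basal = None
    if species_path is not None:
        sdf = pd.read_csv(species_path, dtype=str, skipinitialspace=True)
        if "species" not in sdf.columns:
            raise WebParseError(f"species file {species_path} lacks 'species' column")
        species = tuple(sdf["species"])
        if "is_basal" in sdf.columns:
            truthy = {"1", "true", "yes"}
            declared_basal = frozenset(
                sdf.loc[
                    sdf["is_basal"].str.strip().str.lower().isin(truthy), "species"
                ]
            )
        unknown = {s for link in links for s in link} - set(species)
        if unknown:
            raise WebParseError(
                f"link species not in species file: {sorted(unknown)!r}"
            )
    else:
        seen: dict[str, None] = {}
        for c, r in links:
            seen.setdefault(c)
            seen.setdefault(r)
        species = tuple(seen)
    return FoodWeb(species, tuple(links), declared_basal)


def write_web(web: FoodWeb, path, species_path=None) -> None:
    """Write the edge list (and optionally the species/basal companion file)."""
    pd.DataFrame(web.links, columns=["consumer", "resource"]).to_csv(path, index=False)
    if species_path is not None:
        basal = set(web.basal)
        pd.DataFrame(
            {"species": web.species, "is_basal": [s in basal for s in web.species]}
        ).to_csv(species_path, index=False)


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounding up (perturbation level caps)."""
    return int(math.floor(x + 0.5))
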