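"""Topologically perturbed test sets: false links, omissions, aggregation.

Four kinds of topological uncertainty are emulated on a web with known true
diets and isotope data:

- false links: absent consumer->resource pairs that look plausible by
  nitrogen (resource sample-mean d15N below the consumer's) are added; their
  true proportion is 0 for evaluation;
- omitted links: existing links removed (every consumer keeps >= 1 resource);
  surviving links keep their original, un-renormalised true proportions;
- omitted species: species and all incident links removed, their isotope
  data dropped;
- trophospecies aggregation: species merged by additive-Jaccard trophic
  similarity under average-linkage (ASBC) clustering; members' isotope
  replicates are pooled, and true diets remain comparable only for
  un-aggregated consumers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .datasets import IsotopeDataset
from .foodweb import FoodWeb, round_half_up, validate_web
from .simulate import TrueDiets

__all__ = [
    "PerturbedTestSet",
    "add_false_links",
    "false_link_candidates",
    "omit_links",
    "omit_species",
    "trophic_similarity",
    "aggregate",
    "aggregated_true_diets",
    "aggregation_sweep",
    "perturbation_suite",
]


@dataclass(frozen=True)
class PerturbedTestSet:
    """A perturbed web with comparable truth for evaluation."""

    web: FoodWeb
    data: IsotopeDataset
    mapping: dict[str, str]  # original species -> node in the perturbed web
    true_diets: TrueDiets  # restricted to evaluable links
    kind: str
    level: float
    replicate: int = 0
    seed: int | None = None


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# false links
# ---------------------------------------------------------------------------


def false_link_candidates(web: FoodWeb, data: IsotopeDataset,
                          element: str = "d15N") -> list[tuple[str, str]]:
    """Absent non-self links whose resource looks like plausible prey:
    resource sample-mean d15N below the consumer's.

    Candidates that would close a feeding loop of length >= 2 are excluded
    (the sequential mixing structure requires acyclic webs apart from
    self-links).
    """
    import networkx as nx

    mean15 = {s: data.mean(s, element) for s in web.species}
    existing = set(web.links)
    eats = nx.DiGraph()  # consumer -> resource orientation
    eats.add_nodes_from(web.species)
    eats.add_edges_from(l for l in web.links if l[0] != l[1])
    prey_closure = {s: nx.descendants(eats, s) for s in web.species}
    return [
        (c, r)
        for c in web.species
        for r in web.species
        if c != r
        and (c, r) not in existing
        and mean15[r] < mean15[c]
        and c not in prey_closure[r]
    ]


def add_false_links(web: FoodWeb, data: IsotopeDataset, k: int,
                    rng=None, max_tries: int = 10_000) -> FoodWeb:
    """Add k distinct uniformly chosen admissible false links.

    Individually admissible links can still close a feeding loop jointly, so
    draws whose combination leaves a cycle are rejected and resampled.
    """
    import networkx as nx

    if k == 0:
        return web
    cands = false_link_candidates(web, data)
    if k > len(cands):
        raise ValueError(f"k={k} exceeds the {len(cands)} admissible false links")
    rng = _rng(rng)
    for _ in range(max_tries):
        pick = rng.choice(len(cands), size=k, replace=False)
        new_web = FoodWeb(
            web.species, web.links + tuple(cands[i] for i in sorted(pick))
        )
        if nx.is_directed_acyclic_graph(new_web.to_digraph(drop_cannibal=True)):
            return new_web
    raise RuntimeError(f"no acyclic {k}-false-link addition found in {max_tries} tries")


# ---------------------------------------------------------------------------
# omissions
# ---------------------------------------------------------------------------


def omit_links(web: FoodWeb, k: int, rng=None, max_tries: int = 10_000) -> FoodWeb:
    """Remove a uniformly chosen k-subset of links, resampling until every
    remaining consumer keeps at least one resource."""
    if k == 0:
        return web
    if k >= web.n_links:
        raise ValueError("cannot omit all links")
    rng = _rng(rng)
    n_res = {c: len(web.resources_of(c)) for c in web.consumers}
    for _ in range(max_tries):
        drop = {web.links[i] for i in rng.choice(web.n_links, size=k, replace=False)}
        lost: dict[str, int] = {}
        for c, _r in drop:
            lost[c] = lost.get(c, 0) + 1
        if all(n_res[c] - lost.get(c, 0) >= 1 for c in lost):
            return FoodWeb(
                web.species, tuple(l for l in web.links if l not in drop)
            )
    raise RuntimeError(f"no valid {k}-link omission found in {max_tries} tries")


def omit_species(web: FoodWeb, data: IsotopeDataset, k: int, rng=None,
                 max_tries: int = 10_000) -> tuple[FoodWeb, IsotopeDataset]:
    """Remove k uniformly chosen species (plus incident links and data),
    resampling until no remaining consumer loses all of its resources."""
    if k == 0:
        return web, data
    cap = round_half_up(0.2 * web.n_species)
    if k > cap:
        raise ValueError(f"k={k} exceeds 20% species cap {cap}")
    rng = _rng(rng)
    for _ in range(max_tries):
        drop = set(
            web.species[i] for i in rng.choice(web.n_species, size=k, replace=False)
        )
        keep_links = [
            (c, r) for c, r in web.links if c not in drop and r not in drop
        ]
        survivors = [s for s in web.species if s not in drop]
        kept_consumers = {c for c, _ in keep_links}
        orig_consumers = {c for c, _ in web.links}
        if all(
            s in kept_consumers for s in survivors if s in orig_consumers
        ):
            new_web = FoodWeb(tuple(survivors), tuple(keep_links))
            return new_web, data.subset(survivors)
    raise RuntimeError(f"no valid {k}-species omission found in {max_tries} tries")


# ---------------------------------------------------------------------------
# trophospecies aggregation
# ---------------------------------------------------------------------------


def trophic_similarity(web: FoodWeb) -> tuple[list[str], np.ndarray]:
    """Additive-Jaccard trophic similarity between species.

    Resource and consumer neighbourhoods are tagged by role so shared-prey
    and shared-predator overlaps add:
        J(a,b) = (|Ra & Rb| + |Ca & Cb|) / (|Ra | Rb| + |Ca | Cb|).
    J(a,a) = 1; species with disjoint (or empty) neighbourhoods get 0.
    """
    sp = list(web.species)
    res = {s: set(web.resources_of(s)) for s in sp}
    cons = {s: set(web.consumers_of(s)) for s in sp}
    n = len(sp)
    J = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        a, b = sp[i], sp[j]
        inter = len(res[a] & res[b]) + len(cons[a] & cons[b])
        union = len(res[a] | res[b]) + len(cons[a] | cons[b])
        J[i, j] = J[j, i] = inter / union if union else 0.0
    return sp, J


def _asbc_merge_sequence(web: FoodWeb, min_similarity: float):
    """Average-linkage (ASBC) agglomeration trace.

    Cluster-pair similarity is the mean pairwise similarity over all
    original-species pairs.  Merging proceeds greedily while the best pair's
    similarity >= min_similarity; equal similarities are broken by the
    lexicographically smallest (sorted-member) pair.  Yields
    (similarity, clusters) after each merge.
    """
    sp, J = trophic_similarity(web)
    idx = {s: i for i, s in enumerate(sp)}
    clusters: list[tuple[str, ...]] = [(s,) for s in sp]

    def sim(ca, cb) -> float:
        vals = [J[idx[a], idx[b]] for a in ca for b in cb]
        return float(np.mean(vals))

    while len(clusters) > 1:
        best = None
        for ca, cb in itertools.combinations(sorted(clusters), 2):
            s = sim(ca, cb)
            if best is None or s > best[0] + 1e-12:
                best = (s, ca, cb)
        s, ca, cb = best
        if s < min_similarity:
            return
        clusters.remove(ca)
        clusters.remove(cb)
        clusters.append(tuple(sorted(ca + cb)))
        yield s, [tuple(c) for c in clusters]


def _cluster_label(members: tuple[str, ...]) -> str:
    return "+".join(members) if len(members) > 1 else members[0]


def aggregated_true_diets(original_diets: TrueDiets,
                          mapping: dict[str, str]) -> TrueDiets:
    """True diets of the aggregated web, for un-aggregated consumers only.

    A singleton consumer's proportion on a trophospecies is the sum of its
    original proportions over that cluster's members; aggregated consumers
    are excluded (their members' flows cannot be apportioned).
    """
    members: dict[str, list[str]] = {}
    for orig, node in mapping.items():
        members.setdefault(node, []).append(orig)
    out: dict[tuple[str, str], float] = {}
    for (c, r), q in original_diets.proportions.items():
        node_c = mapping.get(c, c)
        if len(members.get(node_c, [c])) != 1:
            continue
        node_r = mapping.get(r, r)
        out[(node_c, node_r)] = out.get((node_c, node_r), 0.0) + q
    return TrueDiets(out)


def _aggregate_web(web: FoodWeb, mapping: dict[str, str]) -> FoodWeb:
    nodes: dict[str, None] = {}
    for s in web.species:
        nodes.setdefault(mapping[s])
    links: dict[tuple[str, str], None] = {}
    for c, r in web.links:
        links.setdefault((mapping[c], mapping[r]))
    return FoodWeb(tuple(nodes), tuple(links))


def aggregate(web: FoodWeb, data: IsotopeDataset, threshold: float,
              diets: TrueDiets | None = None) -> PerturbedTestSet:
    """Aggregate trophospecies at a similarity threshold in [0.5, 1].

    threshold=1 reproduces the original web; lower thresholds merge all
    cluster pairs whose ASBC similarity stays >= threshold.  Members' isotope
    replicates are pooled and their links unioned.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1]")
    clusters = [(s,) for s in web.species]
    if threshold < 1.0:
        for _s, cl in _asbc_merge_sequence(web, threshold):
            clusters = cl
    mapping = {
        m: _cluster_label(tuple(c)) for c in clusters for m in c
    }
    new_web = _aggregate_web(web, mapping)
    new_data = data.pooled(mapping)
    truths = (
        aggregated_true_diets(diets, mapping) if diets is not None else TrueDiets({})
    )
    return PerturbedTestSet(
        web=new_web,
        data=new_data,
        mapping=mapping,
        true_diets=truths,
        kind="aggregate",
        level=threshold,
    )


def aggregation_sweep(web: FoodWeb, data: IsotopeDataset,
                      diets: TrueDiets | None = None,
                      min_threshold: float = 0.5) -> list[PerturbedTestSet]:
    """One test set per new aggregation as the threshold descends from 1."""
    out = []
    clusters_trace = list(_asbc_merge_sequence(web, min_threshold))
    for sim, clusters in clusters_trace:
        mapping = {m: _cluster_label(tuple(c)) for c in clusters for m in c}
        agg_web = _aggregate_web(web, mapping)
        if validate_web(agg_web):
            # merging can close a feeding loop between trophospecies; such
            # webs cannot be fitted, so the sweep stops at the last valid one
            break
        truths = (
            aggregated_true_diets(diets, mapping)
            if diets is not None
            else TrueDiets({})
        )
        out.append(
            PerturbedTestSet(
                web=agg_web,
                data=data.pooled(mapping),
                mapping=mapping,
                true_diets=truths,
                kind="aggregate",
                level=float(sim),
            )
        )
    return out


# ---------------------------------------------------------------------------
# full suite
# ---------------------------------------------------------------------------


def perturbation_suite(
    web: FoodWeb,
    data: IsotopeDataset,
    diets: TrueDiets,
    fraction: float = 0.2,
    replicates: int = 10,
    seed: int | None = None,
    include_aggregation: bool = True,
) -> list[PerturbedTestSet]:
    """All perturbed test sets for one web.

    Levels run 1..round_half_up(fraction * L) for false and omitted links and
    1..round_half_up(fraction * S) for omitted species, with ``replicates``
    independently seeded draws per level, plus the aggregation sweep.
    """
    if fraction == 0:
        return []
    rng = np.random.default_rng(seed)
    identity = {s: s for s in web.species}
    out: list[PerturbedTestSet] = []
    max_links = round_half_up(fraction * web.n_links)
    max_species = round_half_up(fraction * web.n_species)

    for k in range(1, max_links + 1):
        for rep in range(replicates):
            child = int(rng.integers(0, 2**31 - 1))
            new_web = add_false_links(web, data, k, np.random.default_rng(child))
            truths = dict(diets.proportions)
            for link in set(new_web.links) - set(web.links):
                truths[link] = 0.0
            out.append(
                PerturbedTestSet(new_web, data, identity, TrueDiets(truths),
                                 "false_links", k, rep, child)
            )
    for k in range(1, max_links + 1):
        for rep in range(replicates):
            child = int(rng.integers(0, 2**31 - 1))
            new_web = omit_links(web, k, np.random.default_rng(child))
            kept = set(new_web.links)
            truths = {l: q for l, q in diets.proportions.items() if l in kept}
            out.append(
                PerturbedTestSet(new_web, data, identity, TrueDiets(truths),
                                 "omit_links", k, rep, child)
            )
    for k in range(1, max_species + 1):
        for rep in range(replicates):
            child = int(rng.integers(0, 2**31 - 1))
            new_web, new_data = omit_species(
                web, data, k, np.random.default_rng(child)
            )
            kept = set(new_web.links)
            truths = {l: q for l, q in diets.proportions.items() if l in kept}
            mapping = {s: s for s in new_web.species}
            out.append(
                PerturbedTestSet(new_web, new_data, mapping, TrueDiets(truths),
                                 "omit_species", k, rep, child)
            )
    if include_aggregation:
        out.extend(aggregation_sweep(web, data, diets))
    for ts in out:
        assert not validate_web(ts.web), f"perturbed web invalid: {ts.kind} {ts.level}"
    return out
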