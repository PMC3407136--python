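import numpy as np
import pandas as pd
import pytest

from isoweb import FoodWeb, IsotopeDataset, TrueDiets, validate_web
from isoweb.foodweb import round_half_up
from isoweb.perturb import (
    add_false_links,
    aggregate,
    aggregated_true_diets,
    aggregation_sweep,
    false_link_candidates,
    omit_links,
    omit_species,
    perturbation_suite,
    trophic_similarity,
)


def dataset_with_means(web, means15, n=4, seed=0):
    """Tight data so sample-mean d15N ordering matches the latent means."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in web.species:
        for e in ("d13C", "d15N"):
            m = means15[sp] if e == "d15N" else -20.0
            for v in rng.normal(m, 0.01, n):
                rows.append({"species": sp, "element": e, "value": float(v)})
    return IsotopeDataset(pd.DataFrame(rows))


@pytest.fixture
def chain3():
    web = FoodWeb(("bottom", "mid", "top"), (("mid", "bottom"), ("top", "mid")))
    data = dataset_with_means(web, {"bottom": 0.0, "mid": 3.0, "top": 6.0})
    return web, data


class TestFalseLinks:
    def test_candidate_enumeration_on_chain(self, chain3):
        web, data = chain3
        assert false_link_candidates(web, data) == [("top", "bottom")]

    def test_k0_identity(self, chain3):
        web, data = chain3
        assert add_false_links(web, data, 0) is web

    def test_k_exceeds_candidates(self, chain3):
        web, data = chain3
        with pytest.raises(ValueError, match="exceeds"):
            add_false_links(web, data, 2, np.random.default_rng(0))

    def test_added_links_are_admissible_and_acyclic(self, small_testset):
        web, data = small_testset.web, small_testset.data
        cands = set(false_link_candidates(web, data))
        for seed in range(5):
            new = add_false_links(web, data, 2, np.random.default_rng(seed))
            added = set(new.links) - set(web.links)
            assert len(added) == 2
            assert added <= cands
            assert validate_web(new) == []


class TestOmitLinks:
    def test_k0_identity(self, chain3):
        assert omit_links(chain3[0], 0) is chain3[0]

    def test_consumers_keep_a_resource(self, small_testset):
        web = small_testset.web
        for seed in range(5):
            new = omit_links(web, 3, np.random.default_rng(seed))
            assert new.n_links == web.n_links - 3
            for c in new.species:
                if c in web.consumers:
                    assert len(new.resources_of(c)) >= 1

    def test_two_link_consumer_keeps_one(self):
        web = FoodWeb(("a", "b", "c"), (("c", "a"), ("c", "b")))
        new = omit_links(web, 1, np.random.default_rng(0))
        assert len(new.resources_of("c")) == 1

    def test_replicate_draws_are_distinct(self, small_testset):
        web = small_testset.web
        seen = {
            omit_links(web, 2, np.random.default_rng(seed)).links
            for seed in range(10)
        }
        assert len(seen) > 1

    def test_cannot_omit_all(self, chain3):
        with pytest.raises(ValueError):
            omit_links(chain3[0], 2)


class TestOmitSpecies:
    def test_k0_identity(self, chain3):
        web, data = chain3
        assert omit_species(web, data, 0) == (web, data)

    def test_top_predator_removal(self, small_testset):
        web, data = small_testset.web, small_testset.data
        top = [
            s for s in web.species
            if not web.consumers_of(s) and not web.is_basal(s)
        ]
        k = 1
        for seed in range(20):
            new_web, new_data = omit_species(web, data, k, np.random.default_rng(seed))
            dropped = set(web.species) - set(new_web.species)
            assert len(dropped) == 1
            assert set(new_data.species) == set(new_web.species)
            kept_links = {
                l for l in web.links if not (set(l) & dropped)
            }
            assert set(new_web.links) == kept_links

    def test_cap(self, small_testset):
        web, data = small_testset.web, small_testset.data
        cap = round_half_up(0.2 * web.n_species)
        with pytest.raises(ValueError, match="cap"):
            omit_species(web, data, cap + 1, np.random.default_rng(0))


class TestTrophicSimilarity:
    def test_identical_roles(self):
        web = FoodWeb(
            ("x", "a", "b", "p"),
            (("a", "x"), ("b", "x"), ("p", "a"), ("p", "b")),
        )
        sp, J = trophic_similarity(web)
        i, j = sp.index("a"), sp.index("b")
        assert J[i, j] == pytest.approx(1.0)
        assert np.allclose(np.diag(J), 1.0)
        assert np.allclose(J, J.T)

    def test_disjoint(self):
        web = FoodWeb(("a", "b", "c", "d"), (("b", "a"), ("d", "c")))
        sp, J = trophic_similarity(web)
        assert J[sp.index("a"), sp.index("c")] == 0.0

    def test_half_overlap_tagged_by_role(self):
        # A: prey {x}, predators {p}; B: prey {x}, predators {}
        web = FoodWeb(("x", "A", "B", "p"), (("A", "x"), ("B", "x"), ("p", "A")))
        sp, J = trophic_similarity(web)
        assert J[sp.index("A"), sp.index("B")] == pytest.approx(0.5)


class TestAggregation:
    def fivespecies(self):
        # two identical herbivores, a third partial overlap, two plants
        web = FoodWeb(
            ("p1", "p2", "h1", "h2", "h3"),
            (
                ("h1", "p1"), ("h1", "p2"),
                ("h2", "p1"), ("h2", "p2"),
                ("h3", "p1"),
            ),
        )
        data = dataset_with_means(
            web, {"p1": 0.0, "p2": 0.0, "h1": 3.0, "h2": 3.0, "h3": 3.0}
        )
        return web, data

    def test_threshold_one_is_identity(self):
        web, data = self.fivespecies()
        ts = aggregate(web, data, 1.0)
        assert ts.web == web
        assert ts.mapping == {s: s for s in web.species}

    def test_identical_species_merge(self):
        web, data = self.fivespecies()
        ts = aggregate(web, data, 0.999)
        assert "h1+h2" in ts.web.species
        assert ts.mapping["h1"] == ts.mapping["h2"] == "h1+h2"

    def test_merge_sequence_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        web, data = self.fivespecies()
        sp, J = trophic_similarity(web)
        Z = average(squareform(1.0 - J, checks=False))
        from isoweb.perturb import _asbc_merge_sequence

        merge_sims = sorted(1.0 - Z[:, 2], reverse=True)
        ours = [s for s, _ in _asbc_merge_sequence(web, 0.0)]
        assert np.allclose(sorted(ours, reverse=True), merge_sims, atol=1e-12)

    def test_pooled_replicates(self):
        web, data = self.fivespecies()
        ts = aggregate(web, data, 0.999)
        n1 = data.n_replicates("h1", "d13C") + data.n_replicates("h2", "d13C")
        assert ts.data.n_replicates("h1+h2", "d13C") == n1

    def test_cluster_count_monotone_in_threshold(self):
        web, data = self.fivespecies()
        counts = [
            aggregate(web, data, t).web.n_species
            for t in (1.0, 0.9, 0.7, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_aggregated_true_diets(self):
        diets = TrueDiets(
            {("c", "a"): 0.3, ("c", "b"): 0.2, ("c", "d"): 0.5}
        )
        mapping = {"a": "a+b", "b": "a+b", "c": "c", "d": "d"}
        agg = aggregated_true_diets(diets, mapping)
        assert agg.proportions == {("c", "a+b"): pytest.approx(0.5), ("c", "d"): 0.5}
        assert sum(agg.proportions.values()) == pytest.approx(1.0)

    def test_aggregated_consumers_excluded(self):
        diets = TrueDiets({("c1", "a"): 1.0, ("c2", "a"): 1.0})
        mapping = {"c1": "c1+c2", "c2": "c1+c2", "a": "a"}
        assert aggregated_true_diets(diets, mapping).proportions == {}

    def test_identity_mapping_returns_original(self):
        diets = TrueDiets({("c", "a"): 0.4, ("c", "b"): 0.6})
        agg = aggregated_true_diets(diets, {"c": "c", "a": "a", "b": "b"})
        assert agg.proportions == diets.proportions

    def test_sweep_emits_one_set_per_merge(self):
        web, data = self.fivespecies()
        sets = aggregation_sweep(web, data)
        assert len(sets) >= 1
        counts = [s.web.n_species for s in sets]
        assert counts == sorted(counts, reverse=True)
        for s in sets:
            assert validate_web(s.web) == []


class TestSuite:
    def test_counts_and_validity(self, small_testset):
        web, data, diets = small_testset.web, small_testset.data, small_testset.diets
        frac, reps = 0.1, 2
        suite = perturbation_suite(
            web, data, diets, fraction=frac, replicates=reps, seed=0
        )
        max_l = round_half_up(frac * web.n_links)
        max_s = round_half_up(frac * web.n_species)
        n_agg = sum(1 for t in suite if t.kind == "aggregate")
        assert len(suite) == (2 * max_l + max_s) * reps + n_agg
        for t in suite:
            assert validate_web(t.web) == []
            if t.kind == "false_links":
                added = set(t.web.links) - set(web.links)
                assert all(t.true_diets.proportions[l] == 0.0 for l in added)

    def test_fraction_zero_empty(self, small_testset):
        assert perturbation_suite(
            small_testset.web, small_testset.data, small_testset.diets,
            fraction=0.0, replicates=10, seed=0,
        ) == []
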