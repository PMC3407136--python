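import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoweb import (
    FoodWeb,
    IsotopeDataset,
    NicheModelConfig,
    PriorConfig,
    make_test_set,
)
from isoweb.model import (
    IsoWebModel,
    ParameterState,
    consumer_means,
    log_likelihood,
    log_posterior,
    log_prior,
)
from isoweb.priors import ElementTEFPrior
from isoweb.simulate import propagate_means
from isoweb._kernel import logpost_flat

E2 = ("d13C", "d15N")


def state_from_truth(ts):
    """ParameterState holding the generating truth of a TestSet."""
    basal = {
        (s, e): ts.means[(s, e)] for s in ts.web.basal for e in E2
    }
    sigma2 = {(s, e): 1.0 for s in ts.web.species for e in E2}
    return ParameterState(
        basal_means=basal,
        sigma2=sigma2,
        diets=dict(ts.diets.proportions),
        tefs=dict(ts.tefs.values),
        tau={"d13C": 1.3, "d15N": 1.0},
    )


@pytest.fixture(scope="module")
def toy():
    return make_test_set(NicheModelConfig(S=8, C=0.12, seed=6), n=4, variances=1.0, seed=6)


class TestConsumerMeans:
    def test_no_consumers_returns_basal(self):
        web = FoodWeb(("a", "b"), ())
        st = ParameterState(
            {("a", "d13C"): -10.0, ("b", "d13C"): -20.0},
            {("a", "d13C"): 1.0, ("b", "d13C"): 1.0},
            {},
            {},
            {"d13C": 1.0},
        )
        assert consumer_means(st, web) == st.basal_means

    def test_single_resource_identity_link(self):
        web = FoodWeb(("p", "h"), (("h", "p"),))
        st = ParameterState(
            {("p", "d13C"): -17.0},
            {("p", "d13C"): 1.0, ("h", "d13C"): 1.0},
            {("h", "p"): 1.0},
            {("h", "p", "d13C"): 0.0},
            {"d13C": 1.0},
        )
        assert consumer_means(st, web)[("h", "d13C")] == pytest.approx(-17.0)

    def test_matches_simulation_propagation(self, toy):
        st = state_from_truth(toy)
        got = consumer_means(st, toy.web)
        for key, v in toy.means.items():
            assert got[key] == pytest.approx(v, abs=1e-10)

    def test_cannibal_self_link_closed_form(self):
        web = FoodWeb(("r", "c"), (("c", "r"), ("c", "c")))
        st = ParameterState(
            {("r", "d13C"): -20.0},
            {("r", "d13C"): 1.0, ("c", "d13C"): 1.0},
            {("c", "r"): 0.6, ("c", "c"): 0.4},
            {("c", "r", "d13C"): 1.0, ("c", "c", "d13C"): 2.0},
            {"d13C": 1.0},
        )
        # s (0.6) = 0.6 (-20 + 1) + 0.4 * 2  =>  s = (-11.4 + 0.8)/0.6
        expected = (0.6 * (-19.0) + 0.4 * 2.0) / 0.6
        assert consumer_means(st, web)[("c", "d13C")] == pytest.approx(expected)

    def test_pure_self_feeding_rejected(self):
        web = FoodWeb(("c",), (("c", "c"),))
        st = ParameterState(
            {},
            {("c", "d13C"): 1.0},
            {("c", "c"): 1.0},
            {("c", "c", "d13C"): 1.0},
            {"d13C": 1.0},
        )
        with pytest.raises(ValueError):
            consumer_means(st, web)


class TestLogDensities:
    def test_single_observation_at_mode(self):
        web = FoodWeb(("a",), ())
        data = IsotopeDataset(
            pd.DataFrame([{"species": "a", "element": "d13C", "value": -7.0}])
        )
        st = ParameterState(
            {("a", "d13C"): -7.0}, {("a", "d13C"): 1.0}, {}, {}, {"d13C": 1.0}
        )
        assert log_likelihood(st, web, data) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_replicate_additivity(self):
        web = FoodWeb(("a",), ())
        one = IsotopeDataset(
            pd.DataFrame([{"species": "a", "element": "d13C", "value": -5.0}])
        )
        two = IsotopeDataset(
            pd.DataFrame(
                [{"species": "a", "element": "d13C", "value": -5.0}] * 2
            )
        )
        st = ParameterState(
            {("a", "d13C"): -6.0}, {("a", "d13C"): 2.0}, {}, {}, {"d13C": 1.0}
        )
        assert log_likelihood(st, web, two) == pytest.approx(
            2 * log_likelihood(st, web, one)
        )

    def test_likelihood_matches_bruteforce(self, toy):
        st = state_from_truth(toy)
        means = consumer_means(st, toy.web)
        brute = 0.0
        for sp in toy.web.species:
            for e in E2:
                for x in toy.data.values(sp, e):
                    brute += stats.norm.logpdf(
                        x, means[(sp, e)], np.sqrt(st.sigma2[(sp, e)])
                    )
        assert log_likelihood(st, toy.web, toy.data) == pytest.approx(brute)

    def test_dirichlet_barycentre_term(self):
        """Dirichlet(1,..,1) density at any interior point is (M-1)!."""
        M = 4
        web = FoodWeb(
            tuple(f"r{i}" for i in range(M)) + ("c",),
            tuple(("c", f"r{i}") for i in range(M)),
        )
        prior = PriorConfig.default(("d13C",))
        st = ParameterState(
            {(f"r{i}", "d13C"): 0.0 for i in range(M)},
            {(s, "d13C"): 1.0 for s in web.species},
            {("c", f"r{i}"): 1.0 / M for i in range(M)},
            {("c", f"r{i}", "d13C"): 0.8 for i in range(M)},
            {"d13C": 1.0},
        )
        lp = log_prior(st, web, prior)
        st2 = ParameterState(
            st.basal_means, st.sigma2, dict(st.diets), dict(st.tefs), st.tau
        )
        # moving along the simplex does not change the flat Dirichlet term
        st2.diets[("c", "r0")], st2.diets[("c", "r1")] = 0.4, 0.1
        assert log_prior(st2, web, prior) == pytest.approx(lp)
        # and the term itself equals log (M-1)! plus the non-diet terms
        st_nodiet = ParameterState(
            st.basal_means, st.sigma2, {("c", f"r{i}"): 1.0 / M for i in range(M)},
            st.tefs, st.tau,
        )
        base = log_prior(st_nodiet, web, prior)
        assert base == pytest.approx(lp)

    def test_tef_at_prior_mean_term(self):
        web = FoodWeb(("r", "c"), (("c", "r"),))
        prior = PriorConfig.default(("d13C",))
        st = ParameterState(
            {("r", "d13C"): 0.0},
            {("r", "d13C"): 1.0, ("c", "d13C"): 1.0},
            {("c", "r"): 1.0},
            {("c", "r", "d13C"): 0.8},
            {"d13C": 2.0},
        )
        st_off = ParameterState(
            st.basal_means, st.sigma2, st.diets, {("c", "r", "d13C"): 0.8 + 2.0}, st.tau
        )
        # density drop from mean to mean+1sd is exactly 1/2
        assert log_prior(st, web, prior) - log_prior(st_off, web, prior) == pytest.approx(0.5)

    def test_uniform_family_support(self):
        web = FoodWeb(("r", "c"), (("c", "r"),))
        prior = PriorConfig.default(E2, family="uniform")
        st = ParameterState(
            {("r", e): 0.0 for e in E2},
            {(s, e): 1.0 for s in web.species for e in E2},
            {("c", "r"): 1.0},
            {("c", "r", "d13C"): 5.0, ("c", "r", "d15N"): 3.4},
            {e: 1.0 for e in E2},
        )
        assert log_prior(st, web, prior) == -np.inf
        st_in = ParameterState(
            st.basal_means, st.sigma2, st.diets,
            {("c", "r", "d13C"): 0.4, ("c", "r", "d15N"): 3.4}, st.tau,
        )
        assert np.isfinite(log_prior(st_in, web, prior))

    def test_posterior_composition_and_support(self, toy):
        prior = PriorConfig.default(E2)
        st = state_from_truth(toy)
        lp = log_posterior(st, toy.web, toy.data, prior)
        assert lp == pytest.approx(
            log_prior(st, toy.web, prior) + log_likelihood(st, toy.web, toy.data),
            abs=1e-10,
        )
        bad = ParameterState(
            st.basal_means,
            {k: -1.0 for k in st.sigma2},
            st.diets,
            st.tefs,
            st.tau,
        )
        assert log_posterior(bad, toy.web, toy.data, prior) == -np.inf

    def test_relabel_invariance(self, toy):
        prior = PriorConfig.default(E2)
        st = state_from_truth(toy)
        lp = log_posterior(st, toy.web, toy.data, prior)
        ren = {s: f"X_{s}" for s in toy.web.species}
        web2 = toy.web.relabel(ren)
        m2 = toy.data.measurements
        m2["species"] = m2["species"].map(ren)
        data2 = IsotopeDataset(m2)
        st2 = ParameterState(
            {(ren[s], e): v for (s, e), v in st.basal_means.items()},
            {(ren[s], e): v for (s, e), v in st.sigma2.items()},
            {(ren[c], ren[r]): v for (c, r), v in st.diets.items()},
            {(ren[c], ren[r], e): v for (c, r, e), v in st.tefs.items()},
            st.tau,
        )
        assert log_posterior(st2, web2, data2, prior) == pytest.approx(lp)


class TestKernelAgainstReference:
    """The compiled sampler target must equal the numpy reference density."""

    @pytest.mark.parametrize("family", ["normal", "uniform"])
    def test_random_states(self, toy, family):
        prior = PriorConfig.default(E2, family=family)
        model = IsoWebModel(toy.web, toy.data, prior)
        args = model.arrays.kernel_args(True)
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(20):
            theta = model.initial_theta(rng, jitter=1.0)
            ref = model.logpost_unconstrained(theta)
            got = logpost_flat(theta, args)
            if not np.isfinite(ref):
                assert not np.isfinite(got)
                continue
            assert got == pytest.approx(ref, rel=1e-9, abs=1e-7)
            checked += 1
        assert checked >= 10

    def test_fixed_tef_sd_variant(self, toy):
        prior = PriorConfig(
            tef={
                e: ElementTEFPrior(mean=m, fixed_sd=0.5)
                for e, m in (("d13C", 0.8), ("d15N", 3.4))
            }
        )
        model = IsoWebModel(toy.web, toy.data, prior)
        args = model.arrays.kernel_args(True)
        rng = np.random.default_rng(5)
        for _ in range(5):
            theta = model.initial_theta(rng, jitter=0.7)
            assert logpost_flat(theta, args) == pytest.approx(
                model.logpost_unconstrained(theta), rel=1e-9, abs=1e-7
            )

    def test_prior_only_variant(self, toy):
        model = IsoWebModel(toy.web, toy.data)
        args = model.arrays.kernel_args(False)
        rng = np.random.default_rng(6)
        theta = model.initial_theta(rng, jitter=0.5)
        assert logpost_flat(theta, args) == pytest.approx(
            model.logpost_unconstrained(theta, prior_only=True), rel=1e-9, abs=1e-7
        )

    def test_cannibal_web_consistency(self):
        web = FoodWeb(("r", "c"), (("c", "r"), ("c", "c")))
        rng = np.random.default_rng(2)
        rows = [
            {"species": s, "element": e, "value": float(v)}
            for s in web.species
            for e in E2
            for v in rng.normal(0, 1, 4)
        ]
        data = IsotopeDataset(pd.DataFrame(rows))
        model = IsoWebModel(web, data)
        args = model.arrays.kernel_args(True)
        for _ in range(5):
            theta = model.initial_theta(rng, jitter=0.8)
            assert logpost_flat(theta, args) == pytest.approx(
                model.logpost_unconstrained(theta), rel=1e-9, abs=1e-7
            )


class TestModelConstruction:
    def test_missing_data_cell_rejected(self, toy):
        m = toy.data.measurements
        m = m[~((m.species == toy.web.species[0]) & (m.element == "d15N"))]
        with pytest.raises(ValueError, match="missing"):
            IsoWebModel(toy.web, IsotopeDataset(m))

    def test_cyclic_web_rejected(self, toy):
        web = FoodWeb(("A", "B"), (("A", "B"), ("B", "A")))
        with pytest.raises(ValueError, match="cycle"):
            IsoWebModel(web, toy.data)

    def test_state_roundtrip_through_flat_vector(self, toy):
        model = IsoWebModel(toy.web, toy.data)
        st = state_from_truth(toy)
        back = model.arrays.unflatten(model.arrays.flatten(st))
        for k, v in st.diets.items():
            assert back.diets[k] == pytest.approx(v, abs=1e-10)
        for k, v in st.tefs.items():
            assert back.tefs[k] == pytest.approx(v, abs=1e-10)
        for k, v in st.basal_means.items():
            assert back.basal_means[k] == pytest.approx(v)
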