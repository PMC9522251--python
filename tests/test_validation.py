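import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cisgrn.grn import RegulatoryLink
from cisgrn.simulate import LinkCohortConfig, simulate_link_cohort
from cisgrn.validation import (
    KnockdownExperiment,
    cohort_summary,
    expected_links,
    observed_links,
    oe_ratio,
    permutation_p,
)


def link(tf, target, bound=True, enh="e1", motif="M1"):
    return RegulatoryLink(tf, target, enh, bound, motif)


class TestExpectedLinks:
    def test_printed_formula(self):
        # (10/100)*(50/100)*(20/50)*100 = 2.0
        assert expected_links(100, 10, 50, 20) == pytest.approx(2.0)

    def test_degenerate_limit(self):
        assert expected_links(100, 100, 100, 17) == pytest.approx(17.0)

    def test_zero_ndge(self):
        assert expected_links(100, 0, 50, 20) == 0.0

    def test_zero_ncis_with_positive_ncistf_rejected(self):
        with pytest.raises(ValueError):
            expected_links(100, 10, 0, 5)

    def test_zero_ncis_zero_ncistf_ok(self):
        assert expected_links(100, 10, 0, 0) == 0.0

    @given(st.integers(1, 10_000), st.data())
    def test_equals_simplified_form(self, nge, data):
        ndge = data.draw(st.integers(0, nge))
        ncis = data.draw(st.integers(1, nge))
        ncis_tf = data.draw(st.integers(0, ncis))
        assert expected_links(nge, ndge, ncis, ncis_tf) == pytest.approx(
            ndge * ncis_tf / nge, rel=1e-12)


class TestObservedLinks:
    UNIVERSE = {"a", "b", "c", "d", "t"}

    def test_intersection_counting(self):
        exp = KnockdownExperiment.make("t", ["a", "b", "c"])
        links = [link("t", "b"), link("t", "d")]
        assert observed_links(exp, links, "bound", self.UNIVERSE) == 1

    def test_empty_de_set(self):
        exp = KnockdownExperiment.make("t", [])
        assert observed_links(exp, [link("t", "a")], "bound", self.UNIVERSE) == 0

    def test_multiple_footprints_counted_once(self):
        exp = KnockdownExperiment.make("t", ["a"])
        links = [link("t", "a", enh=f"e{i}") for i in range(3)]
        assert observed_links(exp, links, "bound", self.UNIVERSE) == 1

    def test_class_separation(self):
        exp = KnockdownExperiment.make("t", ["a", "b"])
        links = [link("t", "a", bound=True), link("t", "b", bound=False)]
        assert observed_links(exp, links, "bound", self.UNIVERSE) == 1
        assert observed_links(exp, links, "unbound", self.UNIVERSE) == 1

    def test_non_tf_target_ignored(self):
        exp = KnockdownExperiment.make("t", ["a"])
        links = [link("t", "not_a_tf")]
        assert observed_links(exp, links, "bound", self.UNIVERSE) == 0


class TestOeRatio:
    def test_ratio(self):
        universe = {f"g{i}" for i in range(100)} | {"t"}
        detfs = [f"g{i}" for i in range(10)]
        links = [link("t", f"g{i}") for i in range(4)]
        exp = KnockdownExperiment.make("t", detfs)
        res = oe_ratio(exp, links, universe)
        assert res.nge == 101
        assert res.ndge == 10
        assert res.ncis == 4
        cr = res.by_class["bound"]
        assert cr.ncis_tf == 4
        assert cr.observed == 4
        assert cr.expected == pytest.approx(10 * 4 / 101)
        assert cr.ratio == pytest.approx(4 / (10 * 4 / 101))

    def test_missing_ratio_when_no_targets(self):
        universe = {"t", "a"}
        exp = KnockdownExperiment.make("t", ["a"])
        res = oe_ratio(exp, [], universe)
        assert res.by_class["bound"].ratio is None
        assert res.by_class["unbound"].ratio is None

    def test_unknown_knockdown_rejected(self):
        with pytest.raises(ValueError):
            oe_ratio(KnockdownExperiment.make("zz", []), [], {"a"})

    def test_observed_bounded(self):
        universe = {f"g{i}" for i in range(50)} | {"t"}
        rng = np.random.default_rng(0)
        for _ in range(20):
            detfs = [f"g{i}" for i in rng.choice(50, rng.integers(0, 30),
                                                 replace=False)]
            targets = [f"g{i}" for i in rng.choice(50, rng.integers(0, 30),
                                                   replace=False)]
            links = [link("t", t) for t in targets]
            res = oe_ratio(KnockdownExperiment.make("t", detfs), links, universe)
            cr = res.by_class["bound"]
            assert cr.observed <= min(res.ndge, cr.ncis_tf)


class TestPermutationP:
    def _setup(self, n_targets=20, n_de=15, nge=60):
        universe = {f"g{i}" for i in range(nge)} | {"t"}
        links = [link("t", f"g{i}") for i in range(n_targets)]
        exp = KnockdownExperiment.make("t", [f"g{i}" for i in range(n_de)])
        return exp, links, universe

    def test_extreme_case_min_p(self):
        # observed is maximal and far above the null mean
        exp, links, universe = self._setup(n_targets=10, n_de=10, nge=500)
        p = permutation_p(exp, links, universe, n_perm=99, seed=0)
        assert p["bound"] == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self):
        exp, links, universe = self._setup()
        a = permutation_p(exp, links, universe, n_perm=200, seed=5)
        b = permutation_p(exp, links, universe, n_perm=200, seed=5)
        assert a == b

    def test_mc_mean_matches_closed_form(self):
        exp, links, universe = self._setup(n_targets=20, n_de=15, nge=99)
        res = oe_ratio(exp, links, universe)
        from cisgrn.validation import _resample_observed
        rng = np.random.default_rng(7)
        sim = _resample_observed(20, res.nge, res.ndge, 10_000, rng)
        expected = res.by_class["bound"].expected
        se = sim.std(ddof=1) / np.sqrt(len(sim))
        assert abs(sim.mean() - expected) < 3 * se

    def test_full_null_runs(self):
        exp, links, universe = self._setup()
        p = permutation_p(exp, links, universe, n_perm=50, seed=1, null="full")
        assert 0 < p["bound"] <= 1

    def test_bad_scheme_rejected(self):
        exp, links, universe = self._setup()
        with pytest.raises(ValueError):
            permutation_p(exp, links, universe, n_perm=10, null="bogus")


class TestCohortSummary:
    def _result(self, tf, bound_ratio):
        universe = {f"g{i}" for i in range(100)} | {tf}
        n_obs = int(bound_ratio)  # craft observed to hit the wanted ratio
        links = [link(tf, f"g{i}") for i in range(10)]
        exp = KnockdownExperiment.make(tf, [f"g{i}" for i in range(10)])
        return oe_ratio(exp, links, universe)

    def test_mean_of_defined_ratios(self):
        from cisgrn.validation import ClassResult, LinkEnrichmentResult
        r1 = LinkEnrichmentResult("t1", 10, 2, 5)
        r1.by_class = {"bound": ClassResult(3, 2, 1.0, 2.0),
                       "unbound": ClassResult(0, 0, 0.0, None)}
        r2 = LinkEnrichmentResult("t2", 10, 2, 5)
        r2.by_class = {"bound": ClassResult(3, 4, 1.0, 4.0),
                       "unbound": ClassResult(2, 1, 0.5, 2.0)}
        means, table = cohort_summary([r1, r2])
        assert means["bound"] == pytest.approx(3.0)
        assert means["unbound"] == pytest.approx(2.0)  # only the defined one
        assert len(table) == 2

    def test_all_undefined_rejected(self):
        from cisgrn.validation import ClassResult, LinkEnrichmentResult
        r = LinkEnrichmentResult("t", 10, 0, 0)
        r.by_class = {"bound": ClassResult(0, 0, 0.0, None),
                      "unbound": ClassResult(0, 0, 0.0, None)}
        with pytest.raises(ValueError):
            cohort_summary([r])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestLinkCohorts:
    def test_null_cohort_near_one(self):
        cfg = LinkCohortConfig(seed=3, n_tfs=1000, bound_targets_per_kd=150,
                               unbound_targets_per_kd=150, de_base_rate=0.3,
                               planted_enrichment_factor=1.0)
        universe, links, experiments = simulate_link_cohort(cfg)
        results = [oe_ratio(e, links, universe) for e in experiments]
        means, _ = cohort_summary(results)
        assert 0.8 <= means["bound"] <= 1.25
        assert 0.8 <= means["unbound"] <= 1.25

    def test_planted_factor_lifts_bound_ratio(self):
        cfg = LinkCohortConfig(seed=4, n_tfs=2000, bound_targets_per_kd=12,
                               unbound_targets_per_kd=12, de_base_rate=0.04,
                               planted_enrichment_factor=10.0)
        universe, links, experiments = simulate_link_cohort(cfg)
        results = [oe_ratio(e, links, universe) for e in experiments]
        means, _ = cohort_summary(results)
        assert means["bound"] > 4.0
        assert means["bound"] > means["unbound"]
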