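"""Permutation enrichment tests, differential test, colocalization chi-square."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import regiondiff as rd
from regiondiff import (
    Contingency2x2,
    RandomizationPolicy,
    RegionSet,
    SyntheticConfig,
    colocalization_table,
    diff_perm_test,
    make_scenario,
    perm_test,
    yates_chi2,
)
from regiondiff.stats import _empirical_p, _threshold_at_p05
from conftest import random_genome, random_region_set


# ---------------------------------------------------------------- primitives


class TestEmpiricalP:
    def test_add_one_estimator_greater(self):
        null = np.array([0, 1, 2, 3, 4] * 4)  # n=20
        # observed 3: 8 entries >= 3
        assert _empirical_p(null, 3, "greater") == pytest.approx(9 / 21)
        assert _empirical_p(null, 100, "greater") == pytest.approx(1 / 21)

    def test_less_mirrors_greater(self):
        null = np.arange(20)
        assert _empirical_p(null, 0, "less") == pytest.approx(2 / 21)
        assert _empirical_p(null, -5, "less") == pytest.approx(1 / 21)

    def test_two_sided_caps_at_one(self):
        null = np.arange(20)
        assert _empirical_p(null, 10, "two_sided") <= 1.0
        assert _empirical_p(null, 10, "two_sided") == pytest.approx(
            min(1.0, 2 * min(_empirical_p(null, 10, "greater"), _empirical_p(null, 10, "less")))
        )

    def test_never_zero(self):
        null = np.zeros(1000, dtype=int)
        assert _empirical_p(null, 10**9, "greater") == pytest.approx(1 / 1001)


def test_threshold_at_p05_matches_direct_search():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(20, 400))
        null = rng.poisson(8, size=n)
        c = _threshold_at_p05(null)
        def p_of(c_):
            return (1 + int((null >= c_).sum())) / (n + 1)
        assert p_of(c) <= 0.05
        assert c == 0 or p_of(c - 1) > 0.05  # minimality


# ---------------------------------------------------------------- perm_test


class TestPermTest:
    def test_degenerate_null_reports_undefined_z(self, toy_genome):
        rng = np.random.default_rng(1)
        q = random_region_set(toy_genome, 10, rng, "q")
        empty = RegionSet("e", toy_genome, [])
        res = perm_test(q, empty, toy_genome, RandomizationPolicy(seed=0), n_perm=100)
        assert res.observed == 0
        assert res.null_sd == 0.0
        assert res.z is None
        assert res.p_empirical == 1.0

    def test_saturated_reference_gives_z_zero(self, toy_genome):
        """Observed equals every null draw exactly -> z undefined (sd=0),
        and observed == null_mean."""
        rng = np.random.default_rng(1)
        q = random_region_set(toy_genome, 10, rng, "q")
        whole = RegionSet("all", toy_genome, [("chr1", 0, 1000), ("chr2", 0, 500)])
        res = perm_test(q, whole, toy_genome, RandomizationPolicy(seed=0), n_perm=100)
        assert res.observed == res.null_mean == 10
        assert res.z is None  # sd = 0 is the undefined-marker state

    def test_planted_enrichment_beats_every_null_draw(self):
        """f=0.9 planted enrichment, n_perm=199: observed exceeds all null
        draws, so the add-one empirical p is exactly 1/200."""
        cfg = SyntheticConfig(planted_fraction=0.9, seed=123)
        b = make_scenario("enriched", cfg)
        policy = RandomizationPolicy(seed=7)
        res = perm_test(
            b.queries["query_1"], b.reference, b.genome, policy,
            n_perm=199, keep_null=True,
        )
        assert res.null_counts.max() < res.observed  # oracle check
        assert res.p_empirical == pytest.approx(1 / 200)
        assert res.z is not None and res.z > 10

    def test_invariant_under_query_reordering(self, toy_genome):
        rng = np.random.default_rng(9)
        rows = [tuple(iv) for iv in random_region_set(toy_genome, 20, rng, "q")]
        q1 = RegionSet("q", toy_genome, rows)
        q2 = RegionSet("q", toy_genome, rows[::-1])
        r = random_region_set(toy_genome, 20, rng, "r")
        policy = RandomizationPolicy(seed=5)
        a = perm_test(q1, r, toy_genome, policy, n_perm=100)
        b = perm_test(q2, r, toy_genome, policy, n_perm=100)
        assert (a.observed, a.null_mean, a.p_empirical) == (
            b.observed, b.null_mean, b.p_empirical
        )

    def test_n_perm_bounds(self, toy_genome):
        rng = np.random.default_rng(1)
        q = random_region_set(toy_genome, 5, rng, "q")
        r = random_region_set(toy_genome, 5, rng, "r")
        with pytest.raises(ValueError, match="n_perm"):
            perm_test(q, r, toy_genome, RandomizationPolicy(seed=0), n_perm=10)
        with pytest.warns(UserWarning, match="small"):
            perm_test(q, r, toy_genome, RandomizationPolicy(seed=0), n_perm=50)

    def test_z_and_p_rank_coherent(self):
        """Across instances, larger z goes with smaller (or tied) empirical p."""
        rng = np.random.default_rng(14)
        results = []
        for f in (0.0, 0.3, 0.6, 0.9):
            b = make_scenario(
                "enriched",
                SyntheticConfig(planted_fraction=f, n_query=150, seed=int(rng.integers(1e6))),
            )
            res = perm_test(
                b.queries["query_1"], b.reference, b.genome,
                RandomizationPolicy(seed=3), n_perm=200,
            )
            results.append((res.z if res.z is not None else -np.inf, res.p_empirical))
        zs = [z for z, _ in results]
        ps = [p for _, p in results]
        for i in range(len(results)):
            for j in range(len(results)):
                if zs[i] > zs[j]:
                    assert ps[i] <= ps[j]


# ---------------------------------------------------------------- diff test


class TestDiffPermTest:
    @pytest.mark.filterwarnings("ignore:n_perm")
    def test_identical_queries_have_zero_observed_diff(self, toy_genome):
        rng = np.random.default_rng(4)
        for trial in range(10):
            g = random_genome(rng)
            q = random_region_set(g, int(rng.integers(1, 40)), rng, "q")
            r = random_region_set(g, int(rng.integers(1, 40)), rng, "r")
            res = diff_perm_test(
                q, q, r, g, RandomizationPolicy(seed=trial), n_perm=20
            )
            assert res.observed_diff == 0

    def test_planted_difference_beats_every_null_draw(self):
        cfg = SyntheticConfig(planted_fraction=0.9, seed=77)
        b = make_scenario("differential", cfg)
        res = diff_perm_test(
            b.queries["query_1"], b.queries["query_2"], b.reference, b.genome,
            RandomizationPolicy(seed=11), n_perm=199, keep_null=True,
        )
        assert res.observed_diff > res.null_diffs.max()  # oracle check
        assert res.p_empirical == pytest.approx(1 / 200)

    def test_first_only_variant_fixes_second_count(self):
        b = make_scenario("differential", SyntheticConfig(planted_fraction=0.5, seed=5))
        res = diff_perm_test(
            b.queries["query_1"], b.queries["query_2"], b.reference, b.genome,
            RandomizationPolicy(seed=2), n_perm=100, randomize="first_only",
            keep_null=True,
        )
        # null diffs shifted by the fixed observed_2
        assert res.randomize == "first_only"
        assert np.all(res.null_diffs >= -res.observed_2)

    def test_reproducible_given_seed(self):
        b = make_scenario("differential", SyntheticConfig(planted_fraction=0.4, seed=6))
        args = (
            b.queries["query_1"], b.queries["query_2"], b.reference, b.genome,
            RandomizationPolicy(seed=13),
        )
        r1 = diff_perm_test(*args, n_perm=100, keep_null=True)
        r2 = diff_perm_test(*args, n_perm=100, keep_null=True)
        assert np.array_equal(r1.null_diffs, r2.null_diffs)
        assert r1.p_empirical == r2.p_empirical


# ---------------------------------------------------------------- chi-square


class TestYatesChi2:
    def test_closed_form_fixture(self):
        stat, p, df = yates_chi2(Contingency2x2(30, 70, 10, 90))
        assert stat == pytest.approx(11.28125, abs=1e-9)
        assert df == 1

    def test_proportional_table_is_zero(self):
        stat, p, _ = yates_chi2(Contingency2x2(10, 10, 10, 10))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_continuity_term_clamped_at_zero(self):
        # |ad - bc| = 2 < N/2 = 20 -> statistic clamps to 0, not negative
        stat, _, _ = yates_chi2(Contingency2x2(11, 9, 10, 10))
        assert stat == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            yates_chi2(Contingency2x2(5, 0, 5, 0))

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(100)
        checked = 0
        while checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(0, 200, size=4))
            t = Contingency2x2(a, b, c, d)
            if min(t.margins()) == 0:
                continue
            stat, p, _ = yates_chi2(t)
            ref = chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)
            checked += 1


# ---------------------------------------------------------------- coloc


class TestColocalizationTable:
    @pytest.fixture
    def coloc_fixture(self, desk_genome):
        """Hand-placed sets: 30/100 of set_1 and 10/100 of set_2 land on
        companion territory."""
        comp_rows = [("chr1", i * 10_000, i * 10_000 + 1_000) for i in range(100)]
        companions = RegionSet("comp", desk_genome, comp_rows)
        s1_rows = [("chr1", i * 10_000 + 500, i * 10_000 + 900) for i in range(30)]
        s1_rows += [("chr2", i * 10_000, i * 10_000 + 400) for i in range(70)]
        s2_rows = [("chr1", i * 10_000 + 500, i * 10_000 + 900) for i in range(10)]
        s2_rows += [("chr2", i * 10_000, i * 10_000 + 400) for i in range(90)]
        return (
            RegionSet("s1", desk_genome, s1_rows),
            RegionSet("s2", desk_genome, s2_rows),
            companions,
        )

    def test_constructed_counts(self, coloc_fixture):
        s1, s2, comp = coloc_fixture
        t = colocalization_table(s1, s2, [comp], mode="any")
        assert (t.a, t.b, t.c, t.d) == (30, 70, 10, 90)
        stat, p, _ = yates_chi2(t)
        assert stat == pytest.approx(11.28125, abs=1e-9)

    def test_any_mode_equals_union(self, desk_genome):
        rng = np.random.default_rng(55)
        s1 = random_region_set(desk_genome, 80, rng, "s1")
        s2 = random_region_set(desk_genome, 80, rng, "s2")
        c1 = random_region_set(desk_genome, 50, rng, "c1")
        c2 = random_region_set(desk_genome, 50, rng, "c2")
        union = RegionSet(
            "u", desk_genome, [tuple(iv) for iv in c1] + [tuple(iv) for iv in c2]
        )
        t_any = colocalization_table(s1, s2, [c1, c2], mode="any")
        t_union = colocalization_table(s1, s2, [union], mode="any")
        assert t_any == t_union

    def test_whole_genome_companion_saturates_then_chi2_errors(self, toy_genome):
        rng = np.random.default_rng(5)
        s1 = random_region_set(toy_genome, 20, rng, "s1")
        s2 = random_region_set(toy_genome, 20, rng, "s2")
        whole = RegionSet("w", toy_genome, [("chr1", 0, 1000), ("chr2", 0, 500)])
        t = colocalization_table(s1, s2, [whole])
        assert t.b == t.d == 0
        with pytest.raises(ValueError, match="zero margin"):
            yates_chi2(t)

    def test_empty_inputs_rejected(self, toy_genome):
        rng = np.random.default_rng(5)
        s = random_region_set(toy_genome, 5, rng, "s")
        empty = RegionSet("e", toy_genome, [])
        with pytest.raises(ValueError, match="empty region set"):
            colocalization_table(empty, s, [s])
        with pytest.raises(ValueError, match="companion"):
            colocalization_table(s, s, [])


def test_bh_adjust_matches_hand_computation():
    p = [0.01, 0.04, 0.03, 0.50]
    adj = rd.bh_adjust(p)
    # sorted p .01/.03/.04/.50 -> p*(n/rank) = .04/.06/.0533/.50; the
    # step-up pass pulls .06 down to .0533
    assert adj == pytest.approx([0.04, 0.16 / 3, 0.16 / 3, 0.50])
    assert np.all(adj >= np.asarray(p) - 1e-12)
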