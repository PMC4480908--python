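"""Representation factor, Yates chi-square, exact oracle, set combinators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methylshift.enrichment import (
    ContingencyTable,
    combine_gene_sets,
    cross_list_overlap,
    exact_overlap_p,
    gene_set_enrichment,
    overlap_enrichment,
    read_gmt,
    representation_factor,
    write_gmt,
    yates_chi_square,
)


def random_table(rng, n_max=500):
    n = int(rng.integers(20, n_max))
    r1 = int(rng.integers(1, n))
    c1 = int(rng.integers(1, n))
    a = int(rng.integers(max(0, r1 + c1 - n), min(r1, c1) + 1))
    return ContingencyTable(a, r1 - a, c1 - a, n - r1 - c1 + a)


class TestYatesChiSquare:
    def test_exact_independence_gives_zero(self):
        chi2, p = yates_chi_square(ContingencyTable(10, 10, 10, 10))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_hand_evaluated_cross_table(self):
        chi2, p = yates_chi_square(ContingencyTable(20, 5, 5, 20))
        assert chi2 == pytest.approx(15.68, abs=1e-9)
        assert p == pytest.approx(7.5013e-5, rel=1e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            yates_chi_square(ContingencyTable(0, 0, 10, 10))

    def test_matches_scipy_continuity_corrected_chi2(self, rng):
        for _ in range(50):
            t = random_table(rng)
            if min(t.margins) == 0:
                continue
            chi2, p = yates_chi_square(t)
            ref = stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_yates_never_exceeds_uncorrected_chi2(self, rng):
        for _ in range(100):
            t = random_table(rng)
            if min(t.margins) == 0:
                continue
            chi2, _ = yates_chi_square(t)
            ref = stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)
            assert chi2 <= ref.statistic + 1e-12

    def test_invariant_under_transposition_and_row_column_swap(self, rng):
        for _ in range(50):
            t = random_table(rng)
            if min(t.margins) == 0:
                continue
            chi2, _ = yates_chi_square(t)
            transposed = ContingencyTable(t.a, t.c, t.b, t.d)
            swapped = ContingencyTable(t.d, t.c, t.b, t.a)
            assert yates_chi_square(transposed)[0] == pytest.approx(chi2, rel=1e-12)
            assert yates_chi_square(swapped)[0] == pytest.approx(chi2, rel=1e-12)


class TestExactOverlapP:
    def test_known_table(self):
        # frozen from two-sided hypergeometric summation (minimum-likelihood);
        # scipy.stats.fisher_exact agrees
        assert exact_overlap_p(ContingencyTable(10, 10, 20, 60)) == pytest.approx(0.05338, abs=1e-4)

    def test_independence_gives_p_one(self):
        assert exact_overlap_p(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_fisher_exact(self, rng):
        for _ in range(100):
            t = random_table(rng)
            ref = stats.fisher_exact([[t.a, t.b], [t.c, t.d]]).pvalue
            assert exact_overlap_p(t) == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_doubling_method_bounded_by_one(self):
        assert exact_overlap_p(ContingencyTable(5, 5, 5, 5), method="doubling") <= 1.0


class TestRepresentationFactor:
    def test_observed_equal_expected_gives_rf_one(self):
        expected, rf = representation_factor(6, 20, 30, 100)
        assert expected == pytest.approx(6.0) and rf == pytest.approx(1.0)

    def test_arithmetic_example(self):
        expected, rf = representation_factor(10, 20, 30, 100)
        assert expected == pytest.approx(6.0) and rf == pytest.approx(10 / 6)

    def test_published_margins_under_assumed_universe(self):
        expected, rf = representation_factor(139, 1554, 1845, 40000)
        assert expected == pytest.approx(71.678, abs=1e-2)
        assert rf == pytest.approx(1.939, abs=1e-3)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            representation_factor(0, 60, 60, 100)

    @given(
        size_a=st.integers(1, 200),
        size_b=st.integers(1, 200),
        n_extra=st.integers(0, 500),
        frac=st.floats(0, 1),
    )
    def test_rf_times_expected_is_observed_exactly(self, size_a, size_b, n_extra, frac):
        observed = round(frac * min(size_a, size_b))
        universe = size_a + size_b - observed + n_extra
        expected, rf = representation_factor(observed, size_a, size_b, universe)
        assert rf * expected == pytest.approx(observed, rel=1e-12)
        assert (rf > 1) == (observed > expected)


class TestGeneSetEnrichment:
    UNIVERSE = {f"g{i}" for i in range(100)}

    def test_worked_example(self):
        query = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(10, 40)}
        res = gene_set_enrichment(query, target, self.UNIVERSE)
        assert res.observed == 10
        assert res.rf == pytest.approx(10 / 6)
        assert res.chi2 == pytest.approx(3.6458, abs=1e-3)
        assert res.p_chi2 == pytest.approx(0.0562, abs=1e-3)

    def test_perfect_overlap_is_maximal(self):
        target = {f"g{i}" for i in range(25)}
        res = gene_set_enrichment(target, target, self.UNIVERSE)
        assert res.rf == pytest.approx(len(self.UNIVERSE) / len(target))
        assert res.p_exact < 1e-15

    def test_target_intersected_with_universe(self):
        query = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(10, 40)} | {"not_a_gene"}
        res = gene_set_enrichment(query, target, self.UNIVERSE)
        assert res.size_target == 30

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gene_set_enrichment({"alien"}, {"g1"}, self.UNIVERSE)

    def test_random_query_mean_rf_is_one(self, rng):
        universe = sorted(self.UNIVERSE)
        target = {f"g{i}" for i in range(30)}
        rfs = [
            gene_set_enrichment(set(rng.choice(universe, 20, replace=False)), target, self.UNIVERSE).rf
            for _ in range(1000)
        ]
        assert np.mean(rfs) == pytest.approx(1.0, abs=0.03)

    def test_small_expected_cell_warns_and_reports_exact(self):
        res = overlap_enrichment(2, 4, 5, 1000)
        assert any("expected cell" in w for w in res.warnings)
        assert 0 < res.p_exact <= 1


class TestCrossListOverlap:
    def test_published_positive_margins(self):
        res = cross_list_overlap(
            {f"a{i}" for i in range(1554)},
            {f"a{i}" for i in range(139)} | {f"b{i}" for i in range(1845 - 139)},
            40000,
        )
        assert res.observed == 139
        assert res.rf == pytest.approx(1.939, abs=1e-3)
        assert res.p_chi2 < 1e-15

    def test_overlap_at_expectation_is_null(self):
        # 20 x 30 in 100, overlap 6 = expectation
        res = overlap_enrichment(6, 20, 30, 100)
        assert res.rf == pytest.approx(1.0)
        assert res.p_chi2 > 0.8


class TestCombineGeneSets:
    def test_intersection_and_union(self):
        sets = [{"g1", "g2"}, {"g2", "g3"}]
        assert combine_gene_sets(sets, "all") == {"g2"}
        assert combine_gene_sets(sets, "at_least_one") == {"g1", "g2", "g3"}

    def test_lattice_bounds_over_four_component_sets(self, rng):
        pool = [f"g{i}" for i in range(50)]
        sets = [set(rng.choice(pool, int(rng.integers(10, 40)), replace=False)) for _ in range(4)]
        all_ = combine_gene_sets(sets, "all")
        any_ = combine_gene_sets(sets, "at_least_one")
        assert len(all_) <= min(len(s) for s in sets)
        assert max(len(s) for s in sets) <= len(any_)
        for s in sets:
            assert all_ <= s <= any_


def test_gmt_round_trip(tmp_path):
    sets = {"setA": {"g1", "g2"}, "setB": {"g3"}}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
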