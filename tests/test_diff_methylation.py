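"""Sequencing-arm caller, array peak acceptance, presence/absence scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylshift.diff_methylation import (
    ArrayPeakConfig,
    ArrayReplicateScores,
    call_array_peaks,
    call_diffmeth_seq,
    score_presence_absence,
)
from methylshift.genomic_features import CountMatrix
from methylshift.simulate import SimulationConfig, simulate_experiment

KD = ["kd_siRNA1:enriched", "kd_siRNA2:enriched"]
CTRL = ["kd_control:enriched"]


def make_counts(a, b, lib_a=10000, lib_b=10000):
    df = pd.DataFrame({"A": a, "B": b}, index=[f"g{i}" for i in range(len(a))])
    return CountMatrix(df, pd.Series({"A": lib_a, "B": lib_b}))


class TestSeqCaller:
    def test_equal_counts_equal_libraries_is_null(self):
        cm = make_counts([50], [50])
        calls = call_diffmeth_seq(cm, ["A"], ["B"], return_all=True)
        assert calls[0].p_raw == pytest.approx(1.0) and calls[0].p_adj == pytest.approx(1.0)
        assert not call_diffmeth_seq(cm, ["A"], ["B"], alpha=0.05)

    def test_extreme_split_matches_exact_binomial_oracle(self):
        cm = make_counts([100], [10])
        call = call_diffmeth_seq(cm, ["A"], ["B"], return_all=True)[0]
        expected = stats.binomtest(100, 110, 0.5).pvalue
        assert call.p_raw == pytest.approx(expected, rel=1e-12)
        assert expected < 1e-15
        assert call.direction == "hyper" and call.effect > 0

    def test_library_size_proportional_expectation(self):
        # twice the library depth in A: a 2:1 count split is the null split
        cm = make_counts([100], [50], lib_a=20000, lib_b=10000)
        call = call_diffmeth_seq(cm, ["A"], ["B"], return_all=True)[0]
        assert call.p_raw > 0.9

    def test_zero_count_genes_skipped(self):
        cm = make_counts([0, 30], [0, 10])
        calls = call_diffmeth_seq(cm, ["A"], ["B"], return_all=True)
        assert [c.gene_id for c in calls] == ["g1"]

    def test_swapping_conditions_flips_directions_preserves_p(self, rng):
        counts = rng.poisson(80, size=(200, 2))
        cm = make_counts(counts[:, 0], counts[:, 1] + 1)
        fwd = call_diffmeth_seq(cm, ["A"], ["B"], return_all=True)
        rev = call_diffmeth_seq(cm, ["B"], ["A"], return_all=True)
        for f, r in zip(fwd, rev):
            assert f.p_raw == pytest.approx(r.p_raw, rel=1e-9)
            assert f.p_adj == pytest.approx(r.p_adj, rel=1e-9)
            if f.effect != 0.0:
                assert {f.direction, r.direction} == {"hyper", "hypo"}

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        counts = rng.poisson(60, size=(300, 2))
        cm = make_counts(counts[:, 0] + 1, counts[:, 1] + 1)
        calls = call_diffmeth_seq(cm, ["A"], ["B"], return_all=True)
        df = pd.DataFrame([(c.p_raw, c.p_adj) for c in calls], columns=["p", "q"]).sort_values("p")
        assert (df.q.diff().dropna() >= -1e-12).all()
        assert (df.q <= 1.0).all() and (df.q >= df.p - 1e-12).all()

    def test_null_simulation_raw_p_calibration(self):
        """No planted shift: raw p uniform (GOF at 1%) and ~5% below 0.05."""
        cfg = SimulationConfig(n_genes=2000, n_responsive=0, library_size=2_000_000, seed=0)
        ds = simulate_experiment(cfg)
        calls = call_diffmeth_seq(ds.seq_counts, KD, CTRL, return_all=True)
        p = np.array([c.p_raw for c in calls])
        assert 0.035 <= (p <= 0.05).mean() <= 0.065
        observed, _ = np.histogram(p, bins=10, range=(0, 1))
        chi2 = ((observed - len(p) / 10) ** 2 / (len(p) / 10)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=9)


class TestArrayPeaks:
    def test_two_of_three_pass(self):
        genes = [ArrayReplicateScores("g", (3.1, 0.5, 2.4))]
        assert call_array_peaks(genes) == {"g"}

    def test_strict_cutoff_boundary(self):
        genes = [ArrayReplicateScores("g", (2.0, 2.0, 2.0))]
        assert call_array_peaks(genes) == set()

    def test_all_pass_fail_patterns_match_enumeration(self):
        # scores 3 (pass) / 1 (fail) in every 2^3 pattern
        genes = [
            ArrayReplicateScores("".join(map(str, bits)), tuple(3.0 if b else 1.0 for b in bits))
            for bits in itertools.product((0, 1), repeat=3)
        ]
        enriched = call_array_peaks(genes)
        for g in genes:
            assert (g.gene_id in enriched) == (sum(s > 2.0 for s in g.scores) >= 2)

    def test_replicate_count_mismatch_names_gene(self):
        genes = [ArrayReplicateScores("gX", (3.0, 3.0))]
        with pytest.raises(ValueError, match="gX"):
            call_array_peaks(genes, ArrayPeakConfig(replicate_count=3))


class TestPresenceAbsence:
    @pytest.mark.parametrize(
        "control, treatment, lost, gained, unchanged",
        [
            ({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, {"g1"}, {"g4"}, {"g2", "g3"}),
            ({"g1"}, {"g1"}, set(), set(), {"g1"}),
            ({"a", "b", "c", "d", "e"}, {"v", "w", "x", "y", "z", "q", "r"},
             {"a", "b", "c", "d", "e"}, {"v", "w", "x", "y", "z", "q", "r"}, set()),
        ],
    )
    def test_set_arithmetic(self, control, treatment, lost, gained, unchanged):
        assert score_presence_absence(control, treatment) == (lost, gained, unchanged)

    def test_outputs_pairwise_disjoint(self, rng):
        universe = [f"g{i}" for i in range(100)]
        control = set(rng.choice(universe, 40, replace=False))
        treatment = set(rng.choice(universe, 40, replace=False))
        lost, gained, unchanged = score_presence_absence(control, treatment)
        assert not (lost & gained or lost & unchanged or gained & unchanged)
        assert lost | unchanged == control and gained | unchanged == treatment
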