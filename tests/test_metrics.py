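from __future__ import annotations

import numpy as np
import pytest

from oracles import fdrp_oracle, mhl_oracle, pdr_oracle, pm_oracle, qfdrp_oracle
from wshclock import metrics
from wshclock.io import MethylationRead, SampleMethylome
from wshclock.metrics import (
    HeterogeneityLocus,
    MetricParams,
    assemble_score_matrix,
    compute_fdrp,
    compute_mhl,
    compute_pdr,
    compute_pm,
    compute_qfdrp,
    score_sample,
)

from conftest import make_read, make_reads, random_read_set

QUARTET = (10, 25, 40, 55)
RELAXED = MetricParams(min_depth=1, fdrp_max_reads=None, fdrp_window_bp=None)
NO_SUBSAMPLE = MetricParams(fdrp_max_reads=None, fdrp_window_bp=None)


class TestPDR:
    def test_all_concordant(self):
        reads = make_reads(["MMMM"] * 10)
        assert compute_pdr(reads) == 0.0

    def test_half_discordant(self):
        reads = make_reads(["MMMM"] * 5 + ["MMUM"] * 5)
        assert compute_pdr(reads) == pytest.approx(0.5)

    def test_short_reads_ineligible(self):
        reads = make_reads(["MM"] * 10)
        assert compute_pdr(reads) is None

    def test_min_depth(self):
        reads = make_reads(["MMMM"] * 9)
        assert compute_pdr(reads) is None
        assert compute_pdr(reads, MetricParams(min_depth=9)) == 0.0


class TestPM:
    def test_single_epiallele(self):
        reads = make_reads(["MUMU"] * 16)
        assert compute_pm(reads, QUARTET) == 0.0

    def test_uniform_sixteen_patterns(self):
        import itertools

        patterns = ["".join(p) for p in itertools.product("MU", repeat=4)]
        reads = make_reads(patterns)
        assert compute_pm(reads, QUARTET) == pytest.approx(0.9375)

    def test_two_epialleles(self):
        reads = make_reads(["MMMM"] * 5 + ["UUUU"] * 5)
        assert compute_pm(reads, QUARTET) == pytest.approx(0.5)

    def test_partial_coverage_excluded(self):
        reads = make_reads(["MMMM"] * 10 + ["MMM"] * 4)
        # the 3-call reads do not cover the quartet and are ignored
        assert compute_pm(reads, QUARTET) == 0.0

    def test_requires_four_positions(self):
        with pytest.raises(ValueError):
            compute_pm(make_reads(["MMMM"] * 10), (10, 25, 40))


class TestMHL:
    def test_fully_methylated_is_one(self):
        reads = make_reads(["MMMM"] * 10)
        assert compute_mhl(reads) == 1.0

    def test_fully_unmethylated_is_zero(self):
        reads = make_reads(["UUUU"] * 10)
        assert compute_mhl(reads) == 0.0

    def test_single_read_mu(self):
        reads = make_reads(["MU"])
        assert compute_mhl(reads, MetricParams(min_depth=1)) == pytest.approx(1 / 6)

    def test_mixed_lengths_match_oracle(self, rng):
        reads = make_reads(["MUM", "MM", "UMMMU", "M"], positions=(10, 25, 40, 55, 70))
        params = MetricParams(min_depth=1)
        assert compute_mhl(reads, params) == pytest.approx(
            mhl_oracle(reads, min_depth=1), abs=1e-12
        )


class TestFDRP:
    def test_identical_reads(self):
        reads = make_reads(["MUMU"] * 10)
        assert compute_fdrp(reads, 10, NO_SUBSAMPLE) == 0.0

    def test_one_mismatch_pair(self):
        reads = make_reads(["MMMM", "MMUM"])
        assert compute_fdrp(reads, 10, RELAXED) == 1.0

    def test_two_identical_one_different(self):
        reads = make_reads(["MMMM", "MMMM", "MMUM"])
        assert compute_fdrp(reads, 10, RELAXED) == pytest.approx(2 / 3)

    def test_window_restricts_comparison(self):
        # difference at pos 200 is outside the 50 bp window around anchor 10
        reads = [
            make_read((10, 200), "MM", read_id="a"),
            make_read((10, 200), "MU", read_id="b"),
        ]
        params = MetricParams(min_depth=1, fdrp_max_reads=None, fdrp_window_bp=50)
        assert compute_fdrp(reads, 10, params) == 0.0

    def test_subsampling_deterministic(self):
        reads = make_reads(["MMMM" if i % 2 else "MUMU" for i in range(60)])
        params = MetricParams(fdrp_max_reads=20, rng_seed=5, fdrp_window_bp=None)
        first = compute_fdrp(reads, 10, params)
        second = compute_fdrp(reads, 10, params)
        assert first == second


class TestQFDRP:
    def test_concordant_pair_contributes_zero(self):
        reads = make_reads(["MUMU", "MUMU"])
        assert compute_qfdrp(reads, 10, RELAXED) == 0.0

    def test_one_in_four(self):
        reads = make_reads(["MMMM", "MMUM"])
        assert compute_qfdrp(reads, 10, RELAXED) == pytest.approx(0.25)

    def test_three_reads_mean(self):
        reads = make_reads(["MMMM", "MMMM", "MMUM"])
        assert compute_qfdrp(reads, 10, RELAXED) == pytest.approx(1 / 6)


class TestOracleEquivalence:
    """Each kernel equals independent brute-force enumeration on random input."""

    N_SETS = 250  # per metric; the acceptance suite runs the full 1000

    def test_all_kernels_match_oracles(self, rng):
        params = MetricParams(min_depth=2, pdr_min_cpgs_per_read=4,
                              fdrp_max_reads=None, fdrp_window_bp=50)
        checked = {"pdr": 0, "pm": 0, "mhl": 0, "fdrp": 0, "qfdrp": 0}
        for _ in range(self.N_SETS):
            reads, anchor = random_read_set(rng)
            cases = {
                "pdr": (compute_pdr(reads, params), pdr_oracle(reads, 4, 2)),
                "mhl": (compute_mhl(reads, params), mhl_oracle(reads, 2)),
                "fdrp": (compute_fdrp(reads, anchor, params),
                         fdrp_oracle(reads, anchor, 50, 2)),
                "qfdrp": (compute_qfdrp(reads, anchor, params),
                          qfdrp_oracle(reads, anchor, 50, 2)),
            }
            full = [r for r in reads if r.n_calls >= 4]
            if full:
                quartet = full[0].positions[:4]
                covering = [r for r in reads if set(quartet) <= set(r.positions)]
                cases["pm"] = (compute_pm(covering, quartet, params),
                               pm_oracle(covering, quartet, 2))
            for name, (got, expected) in cases.items():
                if expected is None:
                    assert got is None, name
                else:
                    assert got == pytest.approx(expected, abs=1e-12), name
                    checked[name] += 1
        assert all(v > 20 for v in checked.values()), checked


class TestInvariants:
    def test_scores_in_unit_interval_and_qfdrp_le_fdrp(self, rng):
        params = MetricParams(min_depth=2, fdrp_max_reads=None, fdrp_window_bp=None)
        for _ in range(200):
            reads, anchor = random_read_set(rng)
            f = compute_fdrp(reads, anchor, params)
            q = compute_qfdrp(reads, anchor, params)
            for v in (compute_pdr(reads, params), compute_mhl(reads, params), f, q):
                if v is not None:
                    assert 0.0 <= v <= 1.0
            if f is not None:
                assert q <= f + 1e-12

    def test_pm_bounded_by_uniform_maximum(self, rng):
        params = MetricParams(min_depth=2)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            reads = make_reads(
                ["".join(rng.choice(["M", "U"], size=4)) for _ in range(n)]
            )
            v = compute_pm(reads, QUARTET, params)
            assert v <= 0.9375 + 1e-12

    def test_read_order_invariance(self, rng):
        params = MetricParams(min_depth=2, fdrp_max_reads=None, fdrp_window_bp=None)
        reads, anchor = random_read_set(rng)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        relabeled = [
            MethylationRead(r.chrom, f"x{i}", r.positions, r.states)
            for i, r in enumerate(shuffled)
        ]
        for fn in (compute_pdr, compute_mhl):
            assert fn(reads, params) == fn(relabeled, params)
        assert compute_fdrp(reads, anchor, params) == compute_fdrp(relabeled, anchor, params)
        assert compute_qfdrp(reads, anchor, params) == compute_qfdrp(relabeled, anchor, params)


class TestScoreSample:
    def _sample(self, reads):
        return SampleMethylome("s1", 30.0, reads, [])

    def test_fully_methylated_limits(self):
        reads = make_reads(["MMMM"] * 12)
        sample = self._sample(reads)
        for metric, expected in [("pdr", 0.0), ("pm", 0.0), ("mhl", 1.0),
                                 ("fdrp", 0.0), ("qfdrp", 0.0)]:
            scores = score_sample(sample, metric, NO_SUBSAMPLE).scores
            assert scores, metric
            assert all(v == expected for v in scores.values()), metric

    def test_fully_unmethylated_limits(self):
        reads = make_reads(["UUUU"] * 12)
        sample = self._sample(reads)
        for metric, expected in [("pdr", 0.0), ("pm", 0.0), ("mhl", 0.0),
                                 ("fdrp", 0.0), ("qfdrp", 0.0)]:
            scores = score_sample(sample, metric, NO_SUBSAMPLE).scores
            assert all(v == expected for v in scores.values()), metric

    def test_empty_sample(self):
        scores = score_sample(self._sample([]), "pdr").scores
        assert scores == {}

    def test_unsorted_reads_rejected(self):
        reads = [
            make_read((100, 115), "MM", read_id="a"),
            make_read((10, 25), "MU", read_id="b"),
        ]
        with pytest.raises(ValueError, match="sorted"):
            score_sample(self._sample(reads), "pdr")

    def test_pm_anchors_are_runs_of_four_covered_cpgs(self):
        reads = make_reads(["MMMMM"] * 12, positions=(10, 25, 40, 55, 70))
        scores = score_sample(self._sample(reads), "pm").scores
        anchors = sorted(loc.anchor for loc in scores)
        assert anchors == [(10, 25, 40, 55), (25, 40, 55, 70)]

    def test_kernel_agreement_on_random_sample(self, rng):
        """score_sample at every anchor equals the brute-force oracle."""
        reads = []
        for i in range(200):
            start = int(rng.integers(1, 40))
            n = int(rng.integers(1, 6))
            pos = tuple(range(start, start + n))
            states = "".join(rng.choice(["M", "U"], size=n))
            reads.append(MethylationRead("chr1", f"r{i}", pos, states))
        reads.sort(key=lambda r: (r.chrom, r.start))
        sample = self._sample(reads)
        params = MetricParams(min_depth=3, fdrp_max_reads=None, fdrp_window_bp=50)
        for metric, oracle in [("pdr", None), ("mhl", None), ("fdrp", None), ("qfdrp", None)]:
            scores = score_sample(sample, metric, params).scores
            assert scores
            for locus, value in scores.items():
                pos = locus.anchor[0]
                covering = [r for r in reads if pos in r.positions]
                if metric == "pdr":
                    expected = pdr_oracle(covering, 4, 3)
                elif metric == "mhl":
                    expected = mhl_oracle(covering, 3)
                elif metric == "fdrp":
                    expected = fdrp_oracle(covering, pos, 50, 3)
                else:
                    expected = qfdrp_oracle(covering, pos, 50, 3)
                assert value == pytest.approx(expected, abs=1e-12), (metric, locus)


class TestAssembleMatrix:
    def _scores(self, sample_id, mapping):
        return metrics.SampleScores(
            sample_id,
            "pdr",
            {HeterogeneityLocus("pdr", "chr1", (p,)): v for p, v in mapping.items()},
        )

    def test_union_semantics_with_na(self):
        m = assemble_score_matrix(
            [self._scores("s1", {10: 0.1, 25: 0.2, 40: 0.3}),
             self._scores("s2", {10: 0.4, 25: 0.5, 40: 0.6, 55: 0.7})]
        )
        assert m.shape == (4, 2)
        assert np.isnan(m.loc["chr1:55", "s1"])
        assert m.loc["chr1:55", "s2"] == 0.7

    def test_single_sample(self):
        m = assemble_score_matrix([self._scores("s1", {10: 0.1})])
        assert m.shape == (1, 1)

    def test_metric_mixing_rejected(self):
        a = self._scores("s1", {10: 0.1})
        b = metrics.SampleScores("s2", "mhl", {HeterogeneityLocus("mhl", "chr1", (10,)): 0.5})
        with pytest.raises(ValueError, match="mix"):
            assemble_score_matrix([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_score_matrix([])
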