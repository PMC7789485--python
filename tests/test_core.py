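"""Methylome-core unit tests: contexts, QC, weighted levels, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dielmeth import GenomeModel, classify_context
from dielmeth.core import (
    contexts_in_sequence,
    conversion_rate,
    coverage_filter,
    make_windows,
    pool_calls,
    replicate_correlation,
    weighted_methylation,
)

from conftest import toy_calls


def _genome(seq: str, chrom: str = "chr1") -> GenomeModel:
    return GenomeModel(seqs={chrom: seq})


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGTA", 2, "+", "CG"),
            ("ACAGT", 2, "+", "CHG"),
            ("ACGTA", 3, "-", "CG"),  # G read as C on the minus strand
            ("ACATT", 2, "+", "CHH"),
            ("ACGTA", 1, "+", "not-a-cytosine"),
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert classify_context(_genome(seq), "chr1", pos, strand) == expected

    def test_truncated_context_is_chh_by_convention(self):
        # C two bases from the 3' end with no G following: CHG undecidable
        assert classify_context(_genome("AACA"), "chr1", 3, "+") == "CHH"
        assert classify_context(_genome("AAC"), "chr1", 3, "+") == "CHH"
        # but a terminal CG dinucleotide is still decidable
        assert classify_context(_genome("AACG"), "chr1", 3, "+") == "CG"
        # minus strand truncation at the contig start
        assert classify_context(_genome("GAAA"), "chr1", 1, "-") == "CHH"

    def test_unknown_chrom_raises(self):
        with pytest.raises(KeyError):
            classify_context(_genome("ACGT"), "chrX", 1, "+")

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        g = _genome(seq)
        pos0, minus, ctx = contexts_in_sequence(seq)
        names = np.array(["CG", "CHG", "CHH"])
        for p, m, c in zip(pos0, minus, ctx):
            strand = "-" if m else "+"
            assert classify_context(g, "chr1", int(p) + 1, strand) == names[c]
        # every emitted position really is a cytosine on its strand
        n_c = seq.count("C") + seq.count("G")
        assert len(pos0) == n_c


class TestConversionRate:
    def test_fully_converted_control(self):
        calls = toy_calls([("chrC", i + 1, "+", "CHH", 0, 10) for i in range(5)])
        assert conversion_rate(calls, "chrC") == 1.0

    def test_matches_weighted_arithmetic(self):
        # 13 methylated of 1000 control reads -> rate 0.987
        calls = toy_calls(
            [("chrC", 1, "+", "CG", 13, 500), ("chrC", 2, "+", "CHH", 0, 500)]
        )
        assert conversion_rate(calls, "chrC") == pytest.approx(0.987)

    def test_zero_coverage_control_is_qc_failure(self):
        calls = toy_calls([("chrC", 1, "+", "CG", 0, 0)])
        assert np.isnan(conversion_rate(calls, "chrC"))


class TestCoverageFilter:
    def test_min_zero_is_identity(self):
        calls = toy_calls([("chr1", 1, "+", "CG", 0, 3), ("chr1", 5, "+", "CG", 1, 0)])
        kept, frac = coverage_filter(calls, min_reads=0)
        assert len(kept) == 2 and frac == 1.0

    def test_threshold_counts(self):
        calls = toy_calls(
            [("chr1", i + 1, "+", "CG", 0, t) for i, t in enumerate((3, 4, 5))]
        )
        kept, frac = coverage_filter(calls, min_reads=4)
        assert len(kept) == 2
        assert frac == pytest.approx(2 / 3)

    def test_poisson_retention_matches_tail(self):
        rng = np.random.default_rng(42)
        tot = rng.poisson(10, size=20000)
        calls = toy_calls(
            [("chr1", i + 1, "+", "CHH", 0, int(t)) for i, t in enumerate(tot)]
        )
        _, frac = coverage_filter(calls, min_reads=4)
        expected = float(stats.poisson.sf(3, 10))
        se = np.sqrt(expected * (1 - expected) / 20000)
        assert abs(frac - expected) < 4 * se


class TestWeightedMethylation:
    def test_count_sum_not_mean_of_ratios(self):
        calls = toy_calls(
            [("chr1", 10, "+", "CG", 3, 10), ("chr1", 20, "+", "CG", 1, 10)]
        )
        assert weighted_methylation(calls, ("chr1", 0, 100), "CG") == pytest.approx(0.2)

    def test_no_cytosines_is_undefined(self):
        calls = toy_calls([("chr1", 10, "+", "CG", 3, 10)])
        assert np.isnan(weighted_methylation(calls, ("chr1", 0, 100), "CHH"))

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError):
            weighted_methylation(toy_calls([]), ("chr1", 50, 50), "CG")

    def test_random_region_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(1, 2000), size=50, replace=False))
        tot = rng.integers(0, 30, 50)
        met = rng.binomial(tot, 0.3)
        ctx = rng.choice(["CG", "CHG", "CHH"], 50)
        calls = toy_calls(
            [
                ("chr1", int(p), "+", c, int(m), int(t))
                for p, c, m, t in zip(pos, ctx, met, tot)
            ]
        )
        for _ in range(25):
            a = int(rng.integers(0, 1900))
            b = a + int(rng.integers(10, 400))
            for c in ("CG", "CHG", "CHH"):
                # independent per-record summation oracle
                num = den = 0
                for p, cc, m, t in zip(pos, ctx, met, tot):
                    if a < p <= b and cc == c:
                        num += m
                        den += t
                got = weighted_methylation(calls, ("chr1", a, b), c)
                if den == 0:
                    assert np.isnan(got)
                else:
                    assert got == num / den  # exact, same integer sums

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_coverage_weighted_mean_of_ratios(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        tot = rng.integers(1, 50, n)
        met = rng.binomial(tot, rng.random())
        calls = toy_calls(
            [
                ("chr1", i + 1, "+", "CG", int(m), int(t))
                for i, (m, t) in enumerate(zip(met, tot))
            ]
        )
        level = weighted_methylation(calls, ("chr1", 0, n + 1), "CG")
        ratios = met / tot
        assert level == pytest.approx(np.average(ratios, weights=tot))


class TestMakeWindows:
    def test_tiling_with_trailing_partial(self):
        calls = toy_calls([("chr1", 1, "+", "CG", 1, 2)])
        wt = make_windows(calls, {"chr1": 250}, width=100)
        cg = wt[wt["context"] == "CG"]
        assert list(zip(cg["start"], cg["end"])) == [(0, 100), (100, 200), (200, 250)]

    def test_sliding_window_count_closed_form(self):
        wt = make_windows(toy_calls([]), {"chr1": 1_000_000}, width=500_000, step=100_000)
        cg = wt[wt["context"] == "CG"]
        full = cg[(cg["end"] - cg["start"]) == 500_000]
        # ceil((L - width)/step) + 1 full windows, trailing partials kept
        assert len(full) == (1_000_000 - 500_000) // 100_000 + 1
        assert len(cg) == 10

    def test_window_level_consistent_with_region_level(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(40):
            t = int(rng.integers(1, 20))
            rows.append(("chr1", int(rng.integers(1, 100)), "+", "CG", int(rng.integers(0, t + 1)), t))
        calls = toy_calls(rows)
        wt = make_windows(calls, {"chr1": 100}, width=100)
        w = wt[(wt["context"] == "CG") & (wt["start"] == 0)].iloc[0]
        assert w["level"] == pytest.approx(
            weighted_methylation(calls, ("chr1", 0, 100), "CG")
        )

    def test_invariant_under_record_permutation(self):
        rng = np.random.default_rng(9)
        rows = [
            ("chr1", int(p), "+", "CHH", 1, 3)
            for p in rng.choice(np.arange(1, 500), 60, replace=False)
        ]
        calls = toy_calls(rows)
        shuffled = calls.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = make_windows(calls, {"chr1": 500})
        b = make_windows(shuffled, {"chr1": 500})
        pd.testing.assert_frame_equal(a, b)

    def test_partition_conserves_totals(self):
        # genome-wide level from summed windows equals one spanning window
        rng = np.random.default_rng(13)
        rows = [
            ("chr1", int(p), "+", "CG", int(m), 10)
            for p, m in zip(
                rng.choice(np.arange(1, 1000), 100, replace=False),
                rng.integers(0, 11, 100),
            )
        ]
        calls = toy_calls(rows)
        tiled = make_windows(calls, {"chr1": 1000}, width=100)
        spanning = make_windows(calls, {"chr1": 1000}, width=1000)
        cg_t = tiled[tiled["context"] == "CG"]
        cg_s = spanning[spanning["context"] == "CG"]
        assert cg_t["sum_meth"].sum() == cg_s["sum_meth"].iloc[0]
        assert cg_t["sum_total"].sum() == cg_s["sum_total"].iloc[0]


class TestReplicateCorrelation:
    def _windows(self, levels):
        rows = [
            ("chr1", i * 100, (i + 1) * 100, "CG", 5, int(l * 100), 100, l)
            for i, l in enumerate(levels)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "context",
                "n_cytosines", "sum_meth", "sum_total", "level",
            ],
        )

    def test_identical_replicates(self):
        w = self._windows([0.1, 0.5, 0.9, 0.3])
        assert replicate_correlation(w, w, "CG") == pytest.approx(1.0)

    def test_anticorrelated_replicates(self):
        w1 = self._windows([0.1, 0.5, 0.9, 0.3])
        w2 = self._windows([0.9, 0.5, 0.1, 0.7])
        assert replicate_correlation(w1, w2, "CG") == pytest.approx(-1.0)

    def test_insufficient_pairs_undefined(self):
        w = self._windows([0.5])
        assert np.isnan(replicate_correlation(w, w, "CG"))


def test_pool_calls_sums_counts():
    a = toy_calls([("chr1", 1, "+", "CG", 1, 5), ("chr1", 4, "-", "CHH", 2, 8)])
    b = toy_calls([("chr1", 1, "+", "CG", 3, 6), ("chr1", 4, "-", "CHH", 0, 2)])
    pooled = pool_calls([a, b])
    assert pooled["n_meth"].tolist() == [4, 2]
    assert pooled["n_total"].tolist() == [11, 10]
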