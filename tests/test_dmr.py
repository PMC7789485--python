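"""Fisher-exact engine, BH adjustment and DMR-calling tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dielmeth import GenomeModel, bh_adjust, call_dmrs, fisher_exact
from dielmeth.dmr import (
    classify_dmr_features,
    dmr_density_summary,
    dmr_transitions,
    feature_distribution,
    fisher_exact_many,
    merge_dmrs,
)


def fisher_oracle(a, b, c, d) -> float:
    """Independent two-sided oracle: exact rational enumeration over the
    hypergeometric support at fixed margins (ties within 1e-7 included)."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    den = comb(n, k)
    obs = Fraction(comb(r1, a) * comb(r2, c), den)
    total = Fraction(0)
    for x in range(max(0, k - r2), min(r1, k) + 1):
        w = Fraction(comb(r1, x) * comb(r2, k - x), den)
        if w <= obs * Fraction(10_000_001, 10_000_000):
            total += w
    return float(min(total, Fraction(1)))


class TestFisherExact:
    def test_extreme_table_closed_form(self):
        # [[0,10],[10,0]]: only the two extreme tables qualify
        assert fisher_exact([[0, 10], [10, 0]]) == pytest.approx(
            2 / comb(20, 10), abs=1e-15
        )

    def test_balanced_table_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_empty_margin_convention(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact([[0, 5], [0, 7]]) == 1.0

    def test_negative_entry_raises(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            r1, r2 = rng.integers(1, 31, 2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            tab = [[a, int(r1) - a], [c, int(r2) - c]]
            assert fisher_exact(tab) == pytest.approx(
                fisher_oracle(a, int(r1) - a, c, int(r2) - c), abs=1e-12
            )

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            r1, r2 = rng.integers(1, 200, 2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            mine = fisher_exact([[a, int(r1) - a], [c, int(r2) - c]])
            ref = stats.fisher_exact([[a, int(r1) - a], [c, int(r2) - c]])[1]
            assert mine == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_vectorised_path_matches_scalar(self):
        rng = np.random.default_rng(6)
        r1 = rng.integers(1, 500, 200)
        r2 = rng.integers(1, 500, 200)
        a = rng.binomial(r1, 0.3)
        c = rng.binomial(r2, 0.4)
        many = fisher_exact_many(a, r1, c, r2)
        for i in range(200):
            scalar = fisher_exact([[a[i], r1[i] - a[i]], [c[i], r2[i] - c[i]]])
            assert many[i] == pytest.approx(scalar, rel=1e-9, abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_hand_computation(self):
        # q_i = min_j>=i p_j * m / j -> all 0.03 here
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_sorted_p(self, ps):
        q = bh_adjust(sorted(ps))
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all((q >= np.sort(ps) - 1e-12) & (q <= 1 + 1e-12))


def _window_table(rows):
    """rows: (chrom, start, context, n_cyt, meth, total)"""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "context", "n_cytosines", "sum_meth", "sum_total"]
    )
    df["end"] = df["start"] + 100
    with np.errstate(invalid="ignore"):
        df["level"] = np.where(
            df["sum_total"] > 0, df["sum_meth"] / df["sum_total"].clip(lower=1), np.nan
        )
    return df[
        ["chrom", "start", "end", "context", "n_cytosines", "sum_meth", "sum_total", "level"]
    ]


class TestCallDmrs:
    def test_identical_counts_give_no_dmrs(self):
        w = _window_table([("chr1", i * 100, "CHH", 10, 50, 200) for i in range(20)])
        assert len(call_dmrs(w, w)) == 0

    def test_strong_chh_window_called_hyper(self):
        wa = _window_table([("chr1", 0, "CHH", 10, 100, 200)])
        wb = _window_table([("chr1", 0, "CHH", 10, 20, 200)])
        out = call_dmrs(wa, wb, group_a="A", group_b="B")
        assert len(out) == 1
        r = out.iloc[0]
        assert r["direction"] == "hyper" and r["delta"] == pytest.approx(0.4)
        # p-value far below any alpha: hypergeometric enumeration agrees
        assert r["p_value"] == pytest.approx(fisher_oracle(100, 100, 20, 180), rel=1e-9)

    def test_cg_below_threshold_not_a_dmr_despite_tiny_p(self):
        # delta = 0.35 < 0.4 CG threshold
        wa = _window_table([("chr1", 0, "CG", 10, 750, 1000)])
        wb = _window_table([("chr1", 0, "CG", 10, 400, 1000)])
        assert len(call_dmrs(wa, wb)) == 0

    def test_min_cytosines_gate(self):
        wa = _window_table([("chr1", 0, "CHH", 3, 100, 200)])
        wb = _window_table([("chr1", 0, "CHH", 3, 20, 200)])
        assert len(call_dmrs(wa, wb, min_cytosines=4)) == 0

    def test_mismatched_grids_raise(self):
        wa = _window_table([("chr1", 0, "CHH", 10, 100, 200)])
        wb = _window_table([("chr1", 100, "CHH", 10, 20, 200)])
        with pytest.raises(ValueError):
            call_dmrs(wa, wb)

    def test_group_swap_flips_direction_and_delta(self):
        rng = np.random.default_rng(8)
        rows_a, rows_b = [], []
        for i in range(30):
            t = 300
            rows_a.append(("chr1", i * 100, "CHH", 8, int(rng.binomial(t, 0.3)), t))
            rows_b.append(("chr1", i * 100, "CHH", 8, int(rng.binomial(t, 0.1)), t))
        wa, wb = _window_table(rows_a), _window_table(rows_b)
        ab = call_dmrs(wa, wb)
        ba = call_dmrs(wb, wa)
        assert len(ab) == len(ba) and len(ab) > 0
        merged = ab.merge(wb[["chrom", "start"]], on=["chrom", "start"])
        np.testing.assert_allclose(
            ab.sort_values("start")["delta"].to_numpy(),
            -ba.sort_values("start")["delta"].to_numpy(),
        )
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [
            flip[d] for d in ab.sort_values("start")["direction"]
        ] == list(ba.sort_values("start")["direction"])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(10)
        rows_a, rows_b = [], []
        for i in range(200):
            t = 200
            pa = rng.uniform(0, 0.6)
            rows_a.append(("chr1", i * 100, "CHH", 6, int(rng.binomial(t, pa)), t))
            rows_b.append(("chr1", i * 100, "CHH", 6, int(rng.binomial(t, 0.1)), t))
        wa, wb = _window_table(rows_a), _window_table(rows_b)
        counts = [
            len(call_dmrs(wa, wb, thresholds={"CG": 0.4, "CHG": 0.2, "CHH": th}))
            for th in (0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zero_coverage_input_gives_no_dmrs(self):
        w = _window_table([("chr1", 0, "CHH", 0, 0, 0)])
        out = call_dmrs(w, w)
        assert len(out) == 0
        assert dmr_density_summary({"cmp": out})["n_dmrs"].sum() == 0


def _toy_genome():
    genes = pd.DataFrame(
        [
            ("g1", "chr1", 10_000, 13_000, "+"),
            ("g2", "chr1", 30_000, 33_000, "-"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    exons = pd.DataFrame(
        [
            ("g1", "chr1", 10_000, 11_000, "+"),
            ("g1", "chr1", 12_000, 13_000, "+"),
            ("g2", "chr1", 30_000, 33_000, "-"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    return GenomeModel(seqs={"chr1": ""}, genes=genes, exons=exons)


def _dmr_rows(intervals):
    rows = []
    for (start, end) in intervals:
        rows.append(
            {
                "chrom": "chr1",
                "start": start,
                "end": end,
                "context": "CHH",
                "group_a": "A",
                "group_b": "B",
                "n_cytosines": 5,
                "meth_a": 10,
                "total_a": 50,
                "meth_b": 40,
                "total_b": 50,
                "m_a": 0.2,
                "m_b": 0.8,
                "delta": -0.6,
                "direction": "hypo",
                "p_value": 1e-9,
                "q_value": 1e-8,
            }
        )
    from dielmeth.dmr import DMR_COLUMNS

    return pd.DataFrame(rows, columns=DMR_COLUMNS)


class TestClassifyDmrFeatures:
    def test_feature_classes(self):
        g = _toy_genome()
        dmrs = _dmr_rows(
            [
                (10_100, 10_200),  # inside exon of g1
                (9_000, 9_100),  # 1 kb upstream of plus-strand TSS -> promoter
                (11_040, 11_140),  # 60 bp intron + 40 bp exon -> intron
                (33_500, 33_600),  # upstream of minus-strand g2 (right side)
                (13_500, 13_600),  # downstream of g1
                (60_000, 60_100),  # intergenic
            ]
        )
        out = classify_dmr_features(dmrs, g)
        assert list(out["feature"]) == [
            "exon",
            "promoter",
            "intron",
            "promoter",
            "downstream",
            "intergenic",
        ]
        dist = feature_distribution(out)
        assert int(dist.loc["CHH", "promoter"]) == 2
        assert int(dist.sum().sum()) == len(dmrs)


class TestDmrTransitions:
    def test_single_comparison_state_decays_to_unchanged(self):
        d1 = _dmr_rows([(0, 100)])
        d1["direction"] = "hyper"
        d2 = _dmr_rows([])
        mats = dmr_transitions([("c1", d1), ("c2", d2)], "CHH")
        assert mats["c1->c2"].loc["hyper", "unchanged"] == 1

    def test_row_sums_conserve_source_states(self):
        rng = np.random.default_rng(12)
        sets = []
        for name in ("c1", "c2", "c3"):
            ivs = [(int(s) * 100, int(s) * 100 + 100) for s in rng.choice(50, 10, replace=False)]
            d = _dmr_rows(ivs)
            d["direction"] = rng.choice(["hyper", "hypo"], len(d))
            sets.append((name, d))
        mats = dmr_transitions(sets, "CHH")
        union_windows = set()
        for _, d in sets:
            union_windows |= set(zip(d["chrom"], d["start"]))
        for mat in mats.values():
            assert mat.to_numpy().sum() == len(union_windows)


def test_merge_dmrs_pools_counts():
    d = _dmr_rows([(0, 100), (100, 200), (400, 500)])
    merged = merge_dmrs(d, gap=0)
    assert len(merged) == 2
    first = merged.iloc[0]
    assert (first["start"], first["end"]) == (0, 200)
    assert first["total_a"] == 100 and first["meth_a"] == 20
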