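import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweepscan as ss

import oracles


def _windows(values, chrom="chr1", step=50_000, window=500_000, col="weighted_fst"):
    n = len(values)
    starts = 1 + step * np.arange(n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window - 1,
            "n_snps": 10,
            col: values,
        }
    )


class TestRankThreshold:
    def test_top_five_percent_of_hundred(self):
        thr, idx = ss.rank_threshold(np.arange(1, 101), 0.05, "top")
        assert thr == 96
        assert list(idx) == [95, 96, 97, 98, 99]

    def test_total_tie_selects_all(self):
        thr, idx = ss.rank_threshold(np.full(40, 3.3), 0.05, "top")
        assert thr == 3.3 and len(idx) == 40

    def test_nan_excluded_before_ranking(self):
        v = [1.0, math.nan, 2.0, 3.0, math.nan]
        thr, idx = ss.rank_threshold(v, 0.4, "top")
        assert thr == 2.0 and list(idx) == [2, 3]

    def test_all_undefined_errors(self):
        with pytest.raises(ValueError, match="defined"):
            ss.rank_threshold([math.nan, math.nan], 0.05, "top")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(size=200), 2)  # rounding forces ties
        v[rng.random(200) < 0.1] = np.nan
        for tail in ("top", "bottom"):
            thr, idx = ss.rank_threshold(v, 0.05, tail)
            othr, oidx = oracles.percentile_select(list(v), 0.05, tail)
            assert thr == othr
            assert list(idx) == oidx


class TestWindowSelection:
    def test_fst_selection_monotone_in_fraction(self):
        rng = np.random.default_rng(6)
        w = _windows(rng.normal(size=300))
        _, big = ss.select_fst_windows(w, 0.10)
        _, small = ss.select_fst_windows(w, 0.02)
        assert set(small["start"]) <= set(big["start"])

    def test_ratio_tails_symmetric_for_symmetric_values(self):
        vals = np.concatenate([np.arange(1, 41), -np.arange(1, 41)])
        w = _windows(vals, col="log_ratio")
        tails = ss.select_ratio_windows(w, 0.05)
        hi = tails["high"][1]["log_ratio"].to_numpy()
        lo = tails["low"][1]["log_ratio"].to_numpy()
        assert sorted(hi) == sorted(-lo)
        assert tails["high"][0] == -tails["low"][0]

    def test_single_defined_window_in_both_tails(self):
        vals = np.full(10, np.nan)
        vals[3] = 0.5
        w = _windows(vals, col="log_ratio")
        tails = ss.select_ratio_windows(w, 0.025)
        assert list(tails["high"][1]["start"]) == list(tails["low"][1]["start"])
        assert tails["high"][1]["both_tails"].all()

    def test_nearly_one_fraction_selects_all_but_lowest(self):
        w = _windows(np.arange(100, dtype=float))
        _, sel = ss.select_fst_windows(w, 0.99)
        assert len(sel) == 99
        assert 0.0 not in set(sel["weighted_fst"])


class TestMergeWindows:
    def _selected(self, starts, chrom="chr1", window=500_000):
        starts = np.asarray(starts)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + window - 1,
                "value": 1.0,
                "source_stat": "fst",
                "tail": "top",
            }
        )

    def test_overlapping_windows_merge(self):
        out = ss.merge_windows(self._selected([1, 50_001]))
        assert len(out) == 1
        assert out.at[0, "start"] == 1 and out.at[0, "end"] == 550_000
        assert out.at[0, "n_windows"] == 2

    def test_different_chromosomes_never_merge(self):
        sel = pd.concat(
            [self._selected([1]), self._selected([1], chrom="chr2")],
            ignore_index=True,
        )
        assert len(ss.merge_windows(sel)) == 2

    def test_book_ended_windows_merge(self):
        sel = self._selected([1, 500_001], window=500_000)
        assert len(ss.merge_windows(sel)) == 1

    def test_peak_value_is_max_member(self):
        sel = self._selected([1, 50_001])
        sel["value"] = [0.3, 0.9]
        out = ss.merge_windows(sel)
        assert out.at[0, "peak_value"] == 0.9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_sweep_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = 1 + 50_000 * np.sort(
            rng.choice(100, size=rng.integers(1, 30), replace=False)
        )
        sel = self._selected(starts)
        out = ss.merge_windows(sel)
        expect = oracles.merge_intervals(
            [("chr1", int(s), int(s) + 499_999) for s in starts]
        )
        got = [
            (r["chrom"], r["start"], r["end"]) for _, r in out.iterrows()
        ]
        assert got == expect


class TestGenesInRegions:
    def _regions(self, ivs):
        return pd.DataFrame(ivs, columns=["chrom", "start", "end"])

    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def test_one_bp_overlap_counts(self):
        genes = self._genes([("g1", "chr1", 100, 200), ("g2", "chr1", 100, 199)])
        regions = self._regions([("chr1", 200, 300)])
        assert ss.genes_in_regions(regions, genes) == {"g1"}

    def test_chromosome_mismatch_warns(self):
        genes = self._genes([("g1", "chrX", 1, 10)])
        regions = self._regions([("chr1", 1, 10)])
        with pytest.warns(UserWarning, match="chromosome"):
            assert ss.genes_in_regions(regions, genes) == set()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(12)
        genes = self._genes(
            [
                (f"g{i}", "chr1", int(s), int(s) + 500)
                for i, s in enumerate(rng.integers(1, 50_000, 50))
            ]
        )
        regions = self._regions(
            [("chr1", int(s), int(s) + 2_000) for s in rng.integers(1, 50_000, 10)]
        )
        a = ss.genes_in_regions(regions, genes)
        b = ss.genes_in_regions(
            regions.sample(frac=1, random_state=1),
            genes.sample(frac=1, random_state=2),
        )
        assert a == b

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(19)
        genes = self._genes(
            [
                (f"g{i}", f"chr{1 + i % 2}", int(s), int(s + rng.integers(100, 5_000)))
                for i, s in enumerate(rng.integers(1, 200_000, 100))
            ]
        )
        regions = self._regions(
            [
                (f"chr{1 + i % 2}", int(s), int(s + rng.integers(500, 20_000)))
                for i, s in enumerate(rng.integers(1, 200_000, 30))
            ]
        )
        expect = oracles.genes_overlapping(
            [tuple(r) for r in regions.itertuples(index=False)],
            [tuple(g) for g in genes.itertuples(index=False)],
        )
        assert ss.genes_in_regions(regions, genes) == expect


class TestIntersectCandidates:
    def test_disjoint_sets_empty(self):
        c = ss.intersect_candidates({"a"}, {"b"}, {"c"})
        assert c.intersection_genes == set()

    def test_subset_case(self):
        c = ss.intersect_candidates({"a", "b"}, {"a", "b", "c"}, set())
        assert c.intersection_genes == {"a", "b"}

    def test_matches_set_algebra(self):
        rng = np.random.default_rng(23)
        pool = [f"g{i}" for i in range(50)]
        f = {g for g in pool if rng.random() < 0.4}
        h = {g for g in pool if rng.random() < 0.3}
        lo = {g for g in pool if rng.random() < 0.3}
        c = ss.intersect_candidates(f, h, lo)
        assert c.intersection_genes == f & (h | lo)
        assert c.intersection_high == f & h
        assert c.intersection_low == f & lo
        assert c.intersection_genes <= f
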