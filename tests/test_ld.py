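import math

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan.ld import _r2_block

import oracles
from conftest import make_dataset


def _variants(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"s{i}" for i in range(len(positions))],
            "ref": "A",
            "alt": "G",
        }
    )


class TestPairR2:
    def test_perfect_coupling(self):
        a = np.array([1, 1, 1, 0, 0, 0] * 5)
        assert ss.pair_r2(a, a) == pytest.approx(1.0)
        assert ss.pair_r2(a, 1 - a) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        # equal AB / Ab / aB / ab gametes -> D = 0
        a = np.array([1, 1, 0, 0] * 10)
        b = np.array([1, 0, 1, 0] * 10)
        assert ss.pair_r2(a, b) == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_undefined(self):
        assert math.isnan(ss.pair_r2(np.ones(20), np.arange(20) % 2))

    def test_matches_contingency_table_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = (rng.random(40) < rng.uniform(0.2, 0.8)).astype(np.int8)
            b = (rng.random(40) < rng.uniform(0.2, 0.8)).astype(np.int8)
            a[rng.random(40) < 0.1] = -1
            got = ss.pair_r2(a, b)
            expect = oracles.hap_r2(a, b)
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)


class TestPairR2Genotype:
    def test_identical_and_flipped_dosages(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        assert ss.pair_r2_genotype(g, g) == pytest.approx(1.0)
        assert ss.pair_r2_genotype(g, 2 - g) == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        assert math.isnan(ss.pair_r2_genotype(np.full(10, 2), np.arange(10) % 3))

    def test_close_to_haplotype_r2_under_hwe(self):
        # haplotypes with real LD, randomly paired into diploids
        rng = np.random.default_rng(5)
        freqs = np.array([0.5, 0.1, 0.1, 0.3])  # AB, Ab, aB, ab
        draws = rng.choice(4, size=20_000, p=freqs)
        hap = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])[draws]
        hap_r2 = ss.pair_r2(hap[:, 0], hap[:, 1])
        geno = hap[0::2] + hap[1::2]
        got = ss.pair_r2_genotype(geno[:, 0], geno[:, 1])
        assert got == pytest.approx(hap_r2, abs=0.02)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.integers(0, 3, 30).astype(np.int8)
            b = rng.integers(0, 3, 30).astype(np.int8)
            a[rng.random(30) < 0.15] = -1
            got = ss.pair_r2_genotype(a, b)
            expect = oracles.geno_r2(a, b)
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)


class TestDecayCurve:
    def test_two_sites_in_perfect_ld(self):
        h = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        curve = ss.decay_curve(h, _variants([100, 600]), max_dist=10_000)
        populated = curve[curve["n_pairs"] > 0]
        assert len(populated) == 1
        assert populated.iloc[0]["bin_start"] == 0
        assert populated.iloc[0]["mean_r2"] == pytest.approx(1.0)

    def test_distance_cap_excludes_far_pairs(self):
        h = np.array([[1, 1], [0, 0]], dtype=np.int8)
        curve = ss.decay_curve(h, _variants([100, 500_000]), max_dist=10_000)
        assert curve["n_pairs"].sum() == 0

    def test_cross_chromosome_pairs_excluded(self):
        h = np.array([[1, 1], [0, 0], [1, 0], [0, 1]], dtype=np.int8)
        var = pd.concat(
            [_variants([100], "chr1"), _variants([200], "chr2")],
            ignore_index=True,
        )
        curve = ss.decay_curve(h, var, max_dist=10_000)
        assert curve["n_pairs"].sum() == 0

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(11)
        n_sites = 50
        h = (rng.random((60, n_sites)) < rng.uniform(0.2, 0.8, n_sites)).astype(
            np.int8
        )
        h[rng.random(h.shape) < 0.05] = -1
        pos = np.sort(rng.choice(40_000, n_sites, replace=False)) + 1
        var = _variants(pos)
        bin_bp = 1_000
        curve = ss.decay_curve(h, var, max_dist=20_000, bin_bp=bin_bp)
        sums = {}
        counts = {}
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                d = pos[j] - pos[i]
                if not 0 < d <= 20_000:
                    continue
                r2 = oracles.hap_r2(h[:, i], h[:, j])
                if math.isnan(r2):
                    continue
                b = (d - 1) // bin_bp
                sums[b] = sums.get(b, 0.0) + r2
                counts[b] = counts.get(b, 0) + 1
        for _, row in curve.iterrows():
            b = row["bin_start"] // bin_bp
            assert row["n_pairs"] == counts.get(b, 0)
            if b in counts:
                assert row["mean_r2"] == pytest.approx(
                    sums[b] / counts[b], abs=1e-12
                )

    def test_r2_block_handles_missingness(self):
        rng = np.random.default_rng(21)
        X = rng.integers(0, 2, (40, 12)).astype(np.int8)
        X[rng.random(X.shape) < 0.2] = -1
        block = _r2_block(X, slice(0, 12), slice(0, 12))
        for i in range(12):
            for j in range(12):
                expect = oracles.hap_r2(X[:, i], X[:, j])
                if math.isnan(expect):
                    assert math.isnan(block[i, j])
                else:
                    assert block[i, j] == pytest.approx(expect, abs=1e-12)


class TestR2Distribution:
    def test_perfect_ld_mass_in_top_bin(self):
        h = np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.int8)
        out = ss.r2_distribution(h, _variants([100, 200, 300]), n_bins=10)
        assert out["n_pairs"] == 3
        assert out["histogram"]["n_pairs"].iloc[-1] == 3
        assert out["n_zero"] == 0

    def test_zero_count_is_exact(self):
        # balanced gametes at every pair -> integer D = 0 exactly
        a = np.array([1, 1, 0, 0] * 5, dtype=np.int8)
        b = np.array([1, 0, 1, 0] * 5, dtype=np.int8)
        h = np.column_stack([a, b])
        out = ss.r2_distribution(h, _variants([100, 200]))
        assert out["n_pairs"] == 1
        assert out["n_zero"] == 1

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(17)
        h = (rng.random((30, 20)) < 0.5).astype(np.int8)
        pos = np.arange(1, 21) * 100
        out = ss.r2_distribution(h, _variants(pos), max_dist=5_000, n_bins=5)
        vals = []
        for i in range(20):
            for j in range(i + 1, 20):
                r2 = oracles.hap_r2(h[:, i], h[:, j])
                if not math.isnan(r2):
                    vals.append(r2)
        assert out["n_pairs"] == len(vals)
        expect_bins = np.minimum((np.array(vals) * 5).astype(int), 4)
        assert list(out["histogram"]["n_pairs"]) == [
            int((expect_bins == b).sum()) for b in range(5)
        ]


class TestInvariants:
    def test_r2_in_unit_interval(self):
        rng = np.random.default_rng(2)
        h = (rng.random((50, 40)) < rng.uniform(0.1, 0.9, 40)).astype(np.int8)
        curve = ss.decay_curve(h, _variants(np.arange(1, 41) * 500))
        ok = curve["mean_r2"].dropna()
        assert ((ok >= 0) & (ok <= 1 + 1e-12)).all()

    def test_decay_on_founder_mosaic(self):
        cfg = ss.SimConfig(
            seed=4, n_chrom=1, chrom_len_bp=1_000_000, sweep_regions=(),
            missing_rate=0.0,
        )
        ds, _ = ss.simulate_dataset(cfg)
        sub = ds.take_samples(ds.sample_indices("pop1"))
        curve = ss.decay_curve(
            sub.haplotypes, sub.variants, max_dist=300_000, bin_bp=10_000
        )
        near = curve.loc[curve["bin_start"] == 0, "mean_r2"].iloc[0]
        far = curve.loc[curve["bin_start"] == 100_000, "mean_r2"].iloc[0]
        assert near > far
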