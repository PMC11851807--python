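import numpy as np
import pandas as pd
import pytest

from sweepscan import GenotypeDataset, SimConfig, simulate_dataset


def make_dataset(
    geno,
    populations=None,
    positions=None,
    chrom="chr1",
    haplotypes=None,
):
    """Build a GenotypeDataset from a raw matrix with minimal metadata."""
    geno = np.asarray(geno, dtype=np.int8)
    n, s = geno.shape
    if populations is None:
        populations = ["popA"] * (n // 2) + ["popB"] * (n - n // 2)
    if positions is None:
        positions = np.arange(1, s + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"s{j}" for j in range(s)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n)],
            "population": populations,
        }
    )
    return GenotypeDataset(variants, samples, geno, haplotypes)


def random_dataset(seed, n_samples=20, n_sites=200, missing=0.1, span=100_000):
    """Random polymorphic dataset with planted missingness."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_sites)
    geno = rng.binomial(2, p, size=(n_samples, n_sites)).astype(np.int8)
    if missing > 0:
        geno[rng.random(geno.shape) < missing] = -1
    positions = np.sort(rng.choice(span, n_sites, replace=False)) + 1
    return make_dataset(geno, positions=positions)


@pytest.fixture(scope="session")
def default_sim():
    """The standard planted-sweep scenario (shared, read-only)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples x 2 biallelic sites with one ./. call, plus a pops map."""
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "chr1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t./.\n"
        "chr1\t200\tv2\tC\tT\t.\t.\t.\tGT\t1/1\t0/0\t0/1\n"
    )
    pops = tmp_path / "pops.tsv"
    pops.write_text("s1\tQinC\ns2\tQinC\ns3\tBR\n")
    return vcf, pops
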