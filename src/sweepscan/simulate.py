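"""Two-population synthetic genotype generator with planted sweeps.

Allele frequencies follow the Balding-Nichols divergence model: an
ancestral frequency ``p_anc ~ Uniform(0.05, 0.95)`` per site, and each
population draws ``p_i ~ Beta(p_anc (1-F)/F, (1-p_anc)(1-F)/F)``, whose
mean is ``p_anc`` and variance ``F p_anc (1 - p_anc)``.  ``F = 0`` copies
the ancestral frequency exactly and ``F = 1`` fixes a Bernoulli draw.

Sweeps are planted one-sidedly: inside a configured sweep region
population 2 uses the elevated ``F_sweep`` instead of ``F_neutral``, and
its frequency is additionally shrunk toward the nearest allele-fixation
boundary by ``diversity_scale`` — raising differentiation and depleting
population-2 diversity, the signature the window scan looks for.

Haplotypes get linkage structure from founder-mosaic copying: per
population, ``n_founder_haplotypes`` founders are drawn site-wise
Bernoulli(p_i) and each sample haplotype copies a founder, switching to a
random founder between adjacent SNPs with probability
``1 - exp(-recomb_rate * gap_bp)`` (capped at 0.5).  This yields
distance-decaying r^2 adequate for exercising the LD machinery; it is not
a coalescent model.  Setting ``n_founder_haplotypes=None`` disables the
founder layer and draws genotypes i.i.d. Binomial(2, p_i) — the mode used
for validating the frequency model itself, since founder sampling at
small founder counts adds extra frequency drift in both populations.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream,
so outputs are reproducible (and fixture files byte-identical) for a
fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from . import io_qc


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: interval, drift parameter and diversity depletion."""

    chrom: str
    start: int
    end: int
    f_sweep: float = 0.5
    diversity_scale: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.f_sweep <= 1:
            raise ValueError("f_sweep must lie in [0, 1]")
        if not 0 < self.diversity_scale <= 1:
            raise ValueError("diversity_scale must lie in (0, 1]")
        if self.start > self.end:
            raise ValueError("sweep start > end")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-population simulation.

    Defaults define the package's standard study scenario: 50 + 50
    diploid samples, two 10 Mb chromosomes at ~1 SNP/kb, moderate neutral
    divergence (F = 0.05), one 400 kb sweep per chromosome (F_sweep = 0.5,
    diversity_scale = 0.3, aligned to the 50 kb window grid), 2% missing
    calls, and founder-mosaic LD from 20 founders at a switch rate of
    1e-5 per bp.
    """

    n_pop1: int = 50
    n_pop2: int = 50
    n_chrom: int = 2
    chrom_len_bp: int = 10_000_000
    snp_density: float = 1e-3
    f_neutral: float = 0.05
    sweep_regions: tuple[SweepSpec, ...] = (
        SweepSpec("chr1", 2_000_001, 2_400_000),
        SweepSpec("chr2", 5_000_001, 5_400_000),
    )
    missing_rate: float = 0.02
    n_founder_haplotypes: int | None = 20
    recomb_rate: float = 1e-5
    seed: int = 0
    pop_names: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        if not 0 <= self.f_neutral <= 1:
            raise ValueError("f_neutral must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_founder_haplotypes is not None and self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes must be >= 2")
        ivs = sorted(
            (s.chrom, s.start, s.end) for s in self.sweep_regions
        )
        for a, b in zip(ivs, ivs[1:]):
            if a[0] == b[0] and b[1] <= a[2]:
                raise ValueError("sweep regions overlap")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    config: SimConfig
    frequencies: pd.DataFrame  # chrom,pos,p_anc,p1,p2,in_sweep
    genes: pd.DataFrame  # gene_id,chrom,start,end,strand,in_sweep


# ---------------------------------------------------------------------------
# frequency model
# ---------------------------------------------------------------------------


def _balding_nichols(
    p_anc: np.ndarray, f: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one population frequency per site under drift parameter *f*."""
    p = np.asarray(p_anc, dtype=float)
    f = np.broadcast_to(np.asarray(f, dtype=float), p.shape)
    out = np.empty_like(p)
    zero = f == 0
    one = f == 1
    mid = ~zero & ~one
    out[zero] = p[zero]
    if one.any():
        out[one] = (rng.random(one.sum()) < p[one]).astype(float)
    if mid.any():
        scale = (1.0 - f[mid]) / f[mid]
        out[mid] = rng.beta(p[mid] * scale, (1.0 - p[mid]) * scale)
    return out


def simulate_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Site positions and per-population frequencies under the model.

    Returns a table with ``chrom, pos, p_anc, p1, p2, in_sweep``; sweep
    drift and diversity depletion apply to population 2 only.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frames = []
    for chrom in cfg.chrom_names:
        n_sites = int(round(cfg.chrom_len_bp * cfg.snp_density))
        pos = np.sort(
            rng.choice(cfg.chrom_len_bp, size=n_sites, replace=False)
        ) + 1
        p_anc = rng.uniform(0.05, 0.95, n_sites)
        in_sweep = np.zeros(n_sites, dtype=bool)
        f2 = np.full(n_sites, cfg.f_neutral)
        scale2 = np.ones(n_sites)
        for sw in cfg.sweep_regions:
            if sw.chrom != chrom:
                continue
            m = (pos >= sw.start) & (pos <= sw.end)
            in_sweep |= m
            f2[m] = sw.f_sweep
            scale2[m] = sw.diversity_scale
        p1 = _balding_nichols(p_anc, cfg.f_neutral, rng)
        p2 = _balding_nichols(p_anc, f2, rng)
        # deplete pop-2 diversity: shrink toward the nearest fixation boundary
        boundary = np.round(p2)
        p2 = boundary + scale2 * (p2 - boundary)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "p_anc": p_anc,
                    "p1": p1,
                    "p2": p2,
                    "in_sweep": in_sweep,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# haplotypes and genotypes
# ---------------------------------------------------------------------------


def simulate_haplotypes(
    cfg: SimConfig,
    freqs: pd.DataFrame,
    n_samples: int,
    pop: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder-mosaic haplotypes (2 * n_samples x n_sites) for one population.

    ``pop`` is 1 or 2 and selects the frequency column.  With
    ``recomb_rate = 0`` every haplotype is an exact copy of one founder.
    """
    if cfg.n_founder_haplotypes is None:
        raise ValueError("founder mosaic disabled (n_founder_haplotypes=None)")
    k = cfg.n_founder_haplotypes
    p = freqs[f"p{pop}"].to_numpy()
    n_haps = 2 * n_samples
    cols = []
    for chrom, grp in freqs.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        founders = (rng.random((k, idx.size)) < p[idx]).astype(np.int8)
        gaps = np.diff(pos)
        switch_p = np.minimum(1.0 - np.exp(-cfg.recomb_rate * gaps), 0.5)
        switches = rng.random((n_haps, idx.size - 1)) < switch_p
        seg = np.concatenate(
            [np.zeros((n_haps, 1), dtype=np.int64), np.cumsum(switches, axis=1)],
            axis=1,
        )
        # founder choice per (haplotype, segment); segment 0 included
        choice = rng.integers(0, k, size=(n_haps, idx.size))
        founder_idx = np.take_along_axis(choice, seg, axis=1)
        cols.append(founders[founder_idx, np.arange(idx.size)[None, :]])
    return np.concatenate(cols, axis=1)


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Full simulation: frequencies, haplotypes/genotypes, missingness, genes."""
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_frequencies(cfg, rng)
    n_sites = len(freqs)
    n_total = cfg.n_pop1 + cfg.n_pop2

    if cfg.n_founder_haplotypes is not None:
        h1 = simulate_haplotypes(cfg, freqs, cfg.n_pop1, 1, rng)
        h2 = simulate_haplotypes(cfg, freqs, cfg.n_pop2, 2, rng)
        haps = np.concatenate([h1, h2], axis=0)
        geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    else:
        g1 = rng.binomial(
            2, freqs["p1"].to_numpy()[None, :], size=(cfg.n_pop1, n_sites)
        )
        g2 = rng.binomial(
            2, freqs["p2"].to_numpy()[None, :], size=(cfg.n_pop2, n_sites)
        )
        geno = np.concatenate([g1, g2], axis=0).astype(np.int8)
        haps = None

    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(mask, MISSING, geno).astype(np.int8)
        if haps is not None:
            haps = np.where(np.repeat(mask, 2, axis=0), MISSING, haps).astype(
                np.int8
            )

    ref = np.full(n_sites, "A")
    alt = np.full(n_sites, "G")
    variants = pd.DataFrame(
        {
            "chrom": freqs["chrom"],
            "pos": freqs["pos"],
            "id": [
                f"snp_{c}_{p}" for c, p in zip(freqs["chrom"], freqs["pos"])
            ],
            "ref": ref,
            "alt": alt,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"{cfg.pop_names[0]}_{i:03d}" for i in range(cfg.n_pop1)]
            + [f"{cfg.pop_names[1]}_{i:03d}" for i in range(cfg.n_pop2)],
            "population": [cfg.pop_names[0]] * cfg.n_pop1
            + [cfg.pop_names[1]] * cfg.n_pop2,
        }
    )
    ds = GenotypeDataset(variants, samples, geno, haps)
    truth = SimTruth(cfg, freqs, toy_genes(cfg))
    return ds, truth


def toy_genes(cfg: SimConfig, spacing: int = 100_000, length: int = 20_000) -> pd.DataFrame:
    """Gene bodies tiled every *spacing* bp, offset so none straddles a
    sweep boundary aligned to the 50 kb grid; flags genes fully inside a
    sweep."""
    rows = []
    for chrom in cfg.chrom_names:
        i = 0
        while True:
            start = i * spacing + 40_001
            end = start + length - 1
            if end > cfg.chrom_len_bp:
                break
            in_sweep = any(
                sw.chrom == chrom and start >= sw.start and end <= sw.end
                for sw in cfg.sweep_regions
            )
            rows.append(
                (f"GENE_{chrom}_{i:04d}", chrom, start, end, "+", in_sweep)
            )
            i += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "in_sweep"]
    )


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def write_fixture(cfg: SimConfig, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write VCF + population map + GFF3 + truth tables for one simulation.

    Outputs are byte-identical for identical configs (no timestamps).
    Returns a dict of paths: ``vcf, pops, gff3, truth_genes, truth_sites``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth = simulate_dataset(cfg)

    paths = {
        "vcf": outdir / "sim.vcf",
        "pops": outdir / "pops.tsv",
        "gff3": outdir / "genes.gff3",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
    }
    io_qc.write_vcf(
        ds, paths["vcf"], {c: cfg.chrom_len_bp for c in cfg.chrom_names}
    )
    ds.samples.to_csv(paths["pops"], sep="\t", header=False, index=False)
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for c in cfg.chrom_names:
            fh.write(f"##sequence-region {c} 1 {cfg.chrom_len_bp}\n")
        for _, g in truth.genes.iterrows():
            fh.write(
                f"{g['chrom']}\tsweepscan_sim\tgene\t{g['start']}\t{g['end']}"
                f"\t.\t{g['strand']}\t.\tID={g['gene_id']}\n"
            )
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.frequencies.to_csv(
        paths["truth_sites"], sep="\t", index=False, float_format="%.6g"
    )
    return paths
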