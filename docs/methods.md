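# Methods

## Statistical model

### Fixation index

At a biallelic site let population *i* (i = 1, 2) have `n_i` observed
alleles (two per non-missing diploid call) with alt-allele frequency
`p_i`, and let `p̄` be the pooled frequency. The per-site statistic is
the two-level ANOVA form on allele indicators with r = 2 groups:

```
MSP = n1 (p1 − p̄)² + n2 (p2 − p̄)²                 (between, / (r−1) = 1)
MSG = [n1 p1 (1−p1) + n2 p2 (1−p2)] / (n1 + n2 − 2)  (within)
nc  = (n1 + n2) − (n1² + n2²) / (n1 + n2)
Fst = (MSP − MSG) / (MSP + (nc − 1)·MSG)
```

This is the Cockerham variance-components estimator restricted to one
allele-level layer; it is *not* the full three-component (â, b̂, ĉ)
diploid estimator that VCFtools implements, which additionally models
within-individual departures from Hardy–Weinberg. Differences from
VCFtools output are therefore expected and intentional; the simpler form
has exact closed-form values for hand-checkable cases (a fixed difference
with n1 = n2 = 20 gives MSP = 10, MSG = 0, nc = 20, Fst = 1; matched
p1 = p2 = 0.5 gives Fst = −1/19). Sites where either population has
fewer than two observed alleles, or which are monomorphic overall
(denominator 0), are undefined and carry NaN. Negative per-site values
are retained unclamped: percentile ranking operates on raw values and
clamping would bias the window sums.

The windowed "weighted" Fst is the ratio-of-sums estimator: per-site
numerators `MSP − MSG` and denominators `MSP + (nc − 1)·MSG` are summed
over the defined sites in a window before dividing. A per-window mean of
per-site ratios is available (`mode="mean"`) but the ratio of sums is the
default, being far less noisy at sites with small denominators.

### Nucleotide diversity and the θπ ratio

Site heterozygosity uses the unbiased estimator
`h = 2 p (1 − p) · n/(n − 1)`, identical to the pairwise-difference form
`c_ref · c_alt / C(n, 2)`. Window diversity is `π = Σ h_j / L` with `L`
the full window span in bp — also for windows only partially covered by
SNPs, the convention of windowed-π tools. The contrast statistic is the
natural log of the per-window ratio, `ln(π₁ / π₂)`. Windows where either
π is zero are excluded from ranking rather than pseudo-counted; an
optional pseudocount mode adds ε to both terms for users who prefer to
keep every window.

### Window grid

Windows are 1-based inclusive `[s, s + W − 1]` with starts
`s = 1, 1 + step, …` anchored at position 1 per chromosome, up to the
last start not exceeding the final SNP position (the last window may
extend past it). Defaults W = 500 kb, step = 50 kb. Because Fst and π use
the same grid, the per-window log ratio needs no re-alignment; misaligned
grids raise an error rather than being silently joined.

### Linkage disequilibrium

For phased input, r² between two sites is `D² / (pA qA pB qB)` with
`D = pAB − pA·pB` estimated from haplotype counts. Implementation-wise
this equals the squared Pearson correlation of the two binary columns
over jointly observed entries, which is the single kernel used for both
modes — for unphased input the same kernel on 0/1/2 dosages is the
composite (Rogers–Huff) r², allele-label invariant and within sampling
error of the haplotype value under Hardy–Weinberg pairing. Decay curves
bin all same-chromosome pairs with `0 < d ≤ 300 kb` into 1 kb bins
(means are raw, unsmoothed). Pairs with a monomorphic member are
excluded entirely, not counted as r² = 0; exact r² = 0 counts come from
the integer-count numerator `n·ΣAB − ΣA·ΣB` being zero, which is exact in
double precision at these sample sizes (genotype mode uses |r²| < 1e-12).

## Quality control semantics

Filters run in the fixed order mind → geno → maf (sample missingness
first, as PLINK does), and the order is recorded in the report. Removal
is strict: a sample/site is removed when its missing fraction is
**greater than** the threshold, and a site when its MAF is **strictly
below** the cutoff — at-threshold items are retained in both cases.
Allele frequencies are pooled over all samples and computed from observed
alleles only. Each removed item is recorded once, under the first filter
that removed it, so removing a high-missingness sample can legitimately
rescue a site from the geno filter (covered by a dedicated test).
Multiallelic and non-SNP records are skipped at read time rather than
split, matching chip-style biallelic input. Phasing and imputation are
out of scope; phased input is used as-is and unphased input falls back to
genotype-mode r².

## Selection scan

`rank_threshold` selects `k = ⌈fraction · n_defined⌉` windows from the
requested tail after dropping undefined values; the threshold is the
least extreme selected value and all ties with it are included (k may
grow), recorded in output metadata. Defaults: top 5% for Fst, 2.5% per
tail for the log θπ ratio. Selected windows overlapping or book-ended on
the same chromosome merge into regions (peak value = max member); genes
overlap a region with ≥ 1 bp on closed intervals (GFF3 1-based inclusive;
BED converted from 0-based half-open at read time). The candidate set is
`Fst ∩ (ratio_high ∪ ratio_low)`, consistent with a three-set Venn
reading of the two statistics; per-tail intersections are reported
alongside. The ranked unit is the window, not the SNP.

## The simulator

### What it emulates

Two populations diverged from a shared ancestor. Per site,
`p_anc ~ Uniform(0.05, 0.95)`; each population draws its frequency from
the Balding–Nichols distribution
`Beta(p_anc(1−F)/F, (1−p_anc)(1−F)/F)`, mean `p_anc`, variance
`F·p_anc(1−p_anc)`. Limits are exact: F = 0 copies `p_anc`, F = 1 fixes
a Bernoulli draw. Sweeps are one-sided: inside a configured region
population 2 uses `F_sweep` instead of `F_neutral` and its frequency is
then shrunk toward the nearest fixation boundary by `diversity_scale`
(`p → b + s·(p − b)`, b = round(p)), producing the joint high-Fst /
low-π₂ signature the scan targets and giving sweeps a definite direction
in the ratio (high tail = diversity lost in population 2).

LD comes from founder-mosaic copying: K founder haplotypes per
population are drawn site-wise Bernoulli(p), and each sample haplotype
copies a founder, re-choosing uniformly between adjacent SNPs with
probability `1 − exp(−ρ·gap_bp)` capped at 0.5. Genotypes are haplotype
sums; missingness is i.i.d. Closed-form moments make every layer
testable (Beta variance, binomial missingness, exact founder copies at
ρ = 0).

### Defaults (the standard scenario)

| parameter | default | why |
|---|---|---|
| samples | 50 + 50 | desk-scale yet ≥ 100 alleles/population for stable per-site Fst |
| genome | 2 chromosomes × 10 Mb, 1 SNP/kb | ~400 windows on the 500/50 kb grid — enough for 5%/2.5% tails to mean 20/10 windows |
| F_neutral | 0.05 | moderate breed-level background differentiation |
| sweeps | one 400 kb region per chromosome, F_sweep = 0.5, diversity_scale = 0.3 | 4% of the genome, so a top-5% window selection *can* cover both sweeps entirely; boundaries on the 50 kb grid |
| missing_rate | 0.02 | typical post-genotyping chip missingness |
| founders K | 20 | strong short-range LD (E[r²] ~ 1/K near d = 0) against the ~1/(2N) far-pair baseline |
| ρ (switch rate) | 1e-5 /bp | several-fold r² drop between the 0–10 kb and 100–110 kb bins |
| genes | tiled every 100 kb, 20 kb bodies at +40 kb offsets | no gene straddles a grid-aligned sweep boundary, so the in/out-of-sweep truth partition is exact (8 in-sweep vs 192 outside genes) |

`n_founder_haplotypes=None` switches to i.i.d. `Binomial(2, p_i)`
genotypes with no LD layer. The founder layer adds extra site-frequency
drift of order `p(1−p)/K` in *both* populations, which would shift mean
Fst away from 0 even at F = 0; the drift-recovery checks therefore use
the i.i.d. mode, while the LD and sweep-recovery checks use the mosaic.

### What it does not emulate

No coalescent genealogy, recombination-map or mutation-rate realism, no
chip ascertainment bias, no inbreeding / Hardy–Weinberg departure within
populations, no linked-selection footprint shape (sweeps have hard
edges). Passing tests show the pipeline machinery is correct and the
statistics behave as designed under the stated generative model — not
that thresholds tuned here transfer to real cattle data.

## Numerical and testing choices

- Undefined values are NaN throughout and excluded from ranking, window
  pooling and LD bins; they are never silently zeroed.
- All brute-force oracles in the test suite are scalar Python loops,
  independent of the vectorised implementations they check.
- The drift-recovery check sizes itself so that the "centred at 0 within
  3 SE" assertion at F = 0 is a fair test: the per-site statistic is a
  ratio estimator with a small-sample Jensen bias of order
  `(E[F(1, df)] − 1)/nc ≈ 1e-4` at 50 + 50 samples, while 3 SE of the
  mean over the ~10⁴ sites of one 10 Mb chromosome is ≈ 4e-4 — the bias
  sits well inside the band rather than dominating it.
- End-to-end runs use the default scenario sizes above; the full test
  suite finishes in well under a minute on one CPU.

## Known limitations

- Only r = 2 populations; no multi-population Fst, no haplotype-based
  scans (XP-EHH, iHS), no Tajima's D.
- MAF filtering is pooled across populations (per-population MAF is not
  implemented).
- The PED/MAP reader determines the alt allele as the file-wide minor
  allele (ties broken alphabetically to the later allele), so datasets
  where the VCF alt is the major allele will recode to the complementary
  dosage; the cross-format test constructs minor-alt data.
- Region merging treats book-ended windows as one region; with a 50 kb
  step and 500 kb windows selected windows are almost always overlapping
  anyway.
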