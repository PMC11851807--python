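"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops over
scalars, independent of the vectorised code paths under test.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def site_counts(column, rows=None):
    """(observed allele count, alt count) of one genotype column."""
    n = alt = 0
    it = column if rows is None else column[rows]
    for g in it:
        if g != MISSING:
            n += 2
            alt += int(g)
    return n, alt


def fst_parts(n1, a1, n2, a2):
    """(num, den) of the two-level ANOVA Fst; (nan, nan) if undefined."""
    if n1 < 2 or n2 < 2:
        return math.nan, math.nan
    p1, p2 = a1 / n1, a2 / n2
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    nc = ntot - (n1 * n1 + n2 * n2) / ntot
    return msp - msg, msp + (nc - 1) * msg


def heterozygosity(n, alt):
    """Pairwise-difference form: c_ref * c_alt / C(n, 2)."""
    if n < 2:
        return math.nan
    return alt * (n - alt) / (n * (n - 1) / 2)


def window_pi(positions, het, start, window_bp):
    """Sum of heterozygosities of sites in [start, start+window-1] / span."""
    total = 0.0
    for p, h in zip(positions, het):
        if start <= p <= start + window_bp - 1 and not math.isnan(h):
            total += h
    return total / window_bp


def window_fst(positions, nums, dens, start, window_bp):
    """Ratio-of-sums over defined sites in the window; nan if none."""
    ns = ds = 0.0
    any_def = False
    for p, nu, de in zip(positions, nums, dens):
        if start <= p <= start + window_bp - 1:
            if not math.isnan(de) and de > 0:
                ns += nu
                ds += de
                any_def = True
    return ns / ds if any_def else math.nan


def hap_r2(col_a, col_b):
    """r^2 from the 2x2 haplotype contingency table (missing excluded)."""
    n = nA = nB = nAB = 0
    for a, b in zip(col_a, col_b):
        if a < 0 or b < 0:
            continue
        n += 1
        nA += a
        nB += b
        nAB += a * b
    if n < 2:
        return math.nan
    pA, pB, pAB = nA / n, nB / n, nAB / n
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return math.nan
    d = pAB - pA * pB
    return d * d / denom


def geno_r2(col_a, col_b):
    """Squared Pearson correlation over jointly observed dosages."""
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a >= 0 and b >= 0]
    if len(pairs) < 2:
        return math.nan
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    n = len(pairs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in pairs)
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx <= 0 or syy <= 0:
        return math.nan
    return sxy * sxy / (sxx * syy)


def percentile_select(values, fraction, tail):
    """Sort-based tail selection with inclusive ties.

    Returns (threshold, sorted index list).
    """
    defined = [(v, i) for i, v in enumerate(values) if not math.isnan(v)]
    k = math.ceil(fraction * len(defined))
    ordered = sorted(defined, reverse=(tail == "top"))
    threshold = ordered[k - 1][0]
    if tail == "top":
        sel = [i for v, i in defined if v >= threshold]
    else:
        sel = [i for v, i in defined if v <= threshold]
    return threshold, sorted(sel)


def merge_intervals(intervals):
    """Sweep-line union of closed intervals, merging book-ended ones.

    *intervals* is a list of (chrom, start, end); output sorted likewise.
    """
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur = None
        for s, e in ivs:
            if cur and s <= cur[1] + 1:
                cur[1] = max(cur[1], e)
            else:
                if cur:
                    out.append((chrom, cur[0], cur[1]))
                cur = [s, e]
        if cur:
            out.append((chrom, cur[0], cur[1]))
    return out


def genes_overlapping(regions, genes):
    """Quadratic closed-interval overlap: gene ids hitting any region."""
    hits = set()
    for gid, gc, gs, ge in genes:
        for rc, rs, re in regions:
            if gc == rc and gs <= re and ge >= rs:
                hits.add(gid)
                break
    return hits
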