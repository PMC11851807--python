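"""Pairwise linkage disequilibrium (r^2) and distance-decay curves.

For phased data r^2 is the classic ``D^2 / (pA qA pB qB)`` on haplotype
frequencies; for unphased data the composite (Rogers-Huff style) squared
Pearson correlation of dosage vectors is used.  Both reduce to a squared
Pearson correlation over jointly observed entries, which is what the
vectorised kernel computes: for 0/1 haplotype columns the correlation
numerator ``n * sum(ab) - sum(a) sum(b)`` equals ``n^2 D``, so the two
forms coincide and an exact-integer zero numerator identifies r^2 = 0
exactly.  Pairs where either column is monomorphic (zero variance) are
undefined and excluded from curves and histograms.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

_CHUNK = 256


def _pair_corr2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over jointly observed (>= 0) entries."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        return float("nan")
    num = n * (a @ b) - a.sum() * b.sum()
    va = n * (a @ a) - a.sum() ** 2
    vb = n * (b @ b) - b.sum() ** 2
    if va <= 0 or vb <= 0:
        return float("nan")
    return num * num / (va * vb)


def pair_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Haplotype r^2 between two binary columns (-1 entries = missing).

    Returns NaN when either site is monomorphic among the jointly
    observed haplotypes.
    """
    return _pair_corr2(hap_a, hap_b)


def pair_r2_genotype(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Composite r^2: squared Pearson correlation of 0/1/2 dosages.

    Allele-label invariant (``g -> 2 - g`` leaves it unchanged); NaN when
    either dosage vector has zero variance.
    """
    return _pair_corr2(geno_a, geno_b)


def _r2_block(X: np.ndarray, rows: slice, cols: slice) -> np.ndarray:
    """r^2 between every column in *rows* and every column in *cols*.

    ``X`` is sites-in-columns with -1 for missing; handles missingness
    pairwise via mask matrix products.  Returns a (len rows, len cols)
    matrix with NaN where undefined.
    """
    A = X[:, rows]
    B = X[:, cols]
    MA = (A >= 0).astype(np.float64)
    MB = (B >= 0).astype(np.float64)
    Az = np.where(A >= 0, A, 0).astype(np.float64)
    Bz = np.where(B >= 0, B, 0).astype(np.float64)
    n = MA.T @ MB
    sA = Az.T @ MB
    sB = MA.T @ Bz
    sAB = Az.T @ Bz
    sA2 = (Az * Az).T @ MB
    sB2 = MA.T @ (Bz * Bz)
    num = n * sAB - sA * sB
    va = n * sA2 - sA * sA
    vb = n * sB2 - sB * sB
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (num * num) / (va * vb)
    r2[(va <= 0) | (vb <= 0) | (n < 2)] = np.nan
    return r2


def _iter_pairs(positions: np.ndarray, X: np.ndarray, max_dist: int):
    """Yield (distances, r2) arrays for all pairs within *max_dist*.

    ``positions`` sorted ascending, one chromosome at a time.
    """
    S = len(positions)
    for lo in range(0, S, _CHUNK):
        hi = min(lo + _CHUNK, S)
        far = np.searchsorted(positions, positions[hi - 1] + max_dist, "right")
        if far <= lo + 1:
            continue
        r2 = _r2_block(X, slice(lo, hi), slice(lo, far))
        d = positions[lo:far][None, :] - positions[lo:hi][:, None]
        keep = (d > 0) & (d <= max_dist)
        yield d[keep], r2[keep]


def decay_curve(
    haps: np.ndarray,
    variants: pd.DataFrame,
    max_dist: int = 300_000,
    bin_bp: int = 1_000,
) -> pd.DataFrame:
    """Distance-binned mean r^2 over all same-chromosome pairs.

    Parameters
    ----------
    haps
        Haplotype (2n x S, 0/1) or dosage (n x S, 0/1/2) matrix with -1
        for missing; columns follow *variants* order.
    variants
        Table with ``chrom`` and ``pos`` columns, positions sorted within
        chromosome.
    max_dist, bin_bp
        Pairs farther apart than *max_dist* are skipped; bins of width
        *bin_bp* tile ``[0, max_dist]``.

    Returns a table of ``bin_start, bin_end, mean_r2, n_pairs`` (NaN mean
    for empty bins).  Undefined pairs (monomorphic member) are excluded.
    """
    n_bins = math.ceil(max_dist / bin_bp)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        X = haps[:, idx]
        for d, r2 in _iter_pairs(pos, X, max_dist):
            ok = ~np.isnan(r2)
            if not ok.any():
                continue
            b = np.minimum((d[ok] - 1) // bin_bp, n_bins - 1).astype(np.int64)
            sums += np.bincount(b, weights=r2[ok], minlength=n_bins)
            counts += np.bincount(b, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = bin_bp * np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": np.minimum(starts + bin_bp, max_dist),
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )


def r2_distribution(
    haps: np.ndarray,
    variants: pd.DataFrame,
    max_dist: int = 300_000,
    n_bins: int = 10,
    zero_tol: float = 0.0,
) -> dict:
    """Histogram of r^2 over all defined pairs within *max_dist*.

    Returns ``{"histogram": DataFrame(bin_start, bin_end, n_pairs),
    "n_zero": int, "n_pairs": int}``.  ``n_zero`` counts pairs with
    exactly zero r^2 (integer haplotype counts make the zero exact); for
    genotype-mode input pass ``zero_tol=1e-12``.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_zero = 0
    total = 0
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        X = haps[:, idx]
        for _, r2 in _iter_pairs(pos, X, max_dist):
            r2 = r2[~np.isnan(r2)]
            if r2.size == 0:
                continue
            total += r2.size
            n_zero += int((r2 <= zero_tol).sum())
            b = np.minimum((r2 * n_bins).astype(np.int64), n_bins - 1)
            counts += np.bincount(b, minlength=n_bins)
    hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "n_pairs": counts}
    )
    return {"histogram": hist, "n_zero": n_zero, "n_pairs": total}


def plot_decay(curve: pd.DataFrame, path: str) -> None:
    """Write a PNG of the decay curve (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    mid = (curve["bin_start"] + curve["bin_end"]) / 2 / 1_000
    ax.plot(mid, curve["mean_r2"], lw=1)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
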