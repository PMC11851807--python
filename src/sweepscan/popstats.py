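"""Per-site and windowed differentiation and diversity statistics.

Fst here is the two-level allele-indicator ANOVA form for r = 2
populations: at a site with observed allele counts ``n1, n2`` and alt
frequencies ``p1, p2``,

    MSP = n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2          (between, / (r-1) = 1)
    MSG = [n1 p1 (1-p1) + n2 p2 (1-p2)] / (n1 + n2 - 2)  (within)
    nc  = (n1 + n2) - (n1^2 + n2^2) / (n1 + n2)
    Fst = (MSP - MSG) / (MSP + (nc - 1) MSG)

with ``pbar`` the pooled frequency.  Alleles are the observations (two per
non-missing diploid call).  The windowed "weighted" Fst is the
ratio-of-sums estimator: per-site numerators and denominators are pooled
over a window before dividing.  Per-window nucleotide diversity sums the
unbiased site heterozygosity ``h = 2 p (1 - p) n / (n - 1)`` over SNPs in
the window and divides by the full window span in bp.  Windows tile each
chromosome from position 1 on a fixed start grid (1-based inclusive), so
the Fst and pi grids align and their per-window log ratio is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset

DEFAULT_WINDOW_BP = 500_000
DEFAULT_STEP_BP = 50_000


@dataclass
class SiteFstComponents:
    """ANOVA pieces of the fixation index at one site."""

    n1: int
    n2: int
    p1: float
    p2: float
    msg: float
    msp: float
    nc: float
    fst: float  # NaN when undefined


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def fst_components(n1, alt1, n2, alt2):
    """Vectorised Fst numerator/denominator from allele counts.

    Parameters are arrays of observed allele counts and alt-allele counts
    for the two populations.  Returns ``(num, den)`` with ``num = MSP -
    MSG`` and ``den = MSP + (nc - 1) MSG``; entries where either
    population has fewer than two observed alleles, or the site is
    monomorphic overall (den = 0), are NaN in ``num / den`` terms wherever
    division would be taken, but the raw sums are returned so callers can
    pool them.  Sites with ``n < 2`` get num = den = NaN outright.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.asarray(alt1, dtype=float) / n1
        p2 = np.asarray(alt2, dtype=float) / n2
        ntot = n1 + n2
        pbar = (n1 * p1 + n2 * p2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = ntot - (n1**2 + n2**2) / ntot
        num = msp - msg
        den = msp + (nc - 1) * msg
    invalid = (n1 < 2) | (n2 < 2)
    num = np.where(invalid, np.nan, num)
    den = np.where(invalid, np.nan, den)
    return num, den


def site_fst(counts1: tuple[int, int], counts2: tuple[int, int]) -> SiteFstComponents:
    """Fst ANOVA components at a single site.

    ``counts1`` / ``counts2`` are ``(observed allele count, alt count)``
    per population.  ``fst`` is NaN when either count is below two or the
    site is monomorphic overall (0/0).
    """
    n1, alt1 = counts1
    n2, alt2 = counts2
    if n1 < 2 or n2 < 2:
        return SiteFstComponents(n1, n2, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
    p1, p2 = alt1 / n1, alt2 / n2
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    nc = ntot - (n1**2 + n2**2) / ntot
    den = msp + (nc - 1) * msg
    fst = (msp - msg) / den if den > 0 else np.nan
    return SiteFstComponents(n1, n2, p1, p2, msg, msp, nc, fst)


def site_heterozygosity(n: int, alt_count: int) -> float:
    """Unbiased heterozygosity ``2 p (1-p) n / (n-1)`` of one site.

    Equals the pairwise-difference form ``c0 c1 / C(n, 2)``; NaN when
    fewer than two alleles were observed.
    """
    if n < 2:
        return float("nan")
    p = alt_count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def _het_array(n: np.ndarray, alt: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(alt, dtype=float) / n
        h = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return np.where(n < 2, np.nan, h)


def site_fst_table(
    ds: GenotypeDataset, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-site Fst components for two populations as a DataFrame."""
    n1, alt1 = ds.allele_counts(pop_a)
    n2, alt2 = ds.allele_counts(pop_b)
    num, den = fst_components(n1, alt1, n2, alt2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, alt1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(n2 > 0, alt2 / np.maximum(n2, 1), np.nan)
        fst = np.where(den > 0, num / den, np.nan)
    ntot = (n1 + n2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        pbar = (n1 * p1 + n2 * p2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        nc = ntot - (n1**2 + n2**2) / ntot
    return pd.DataFrame(
        {
            "chrom": ds.variants["chrom"],
            "pos": ds.variants["pos"],
            "n1": n1,
            "n2": n2,
            "p1": p1,
            "p2": p2,
            "MSG": msg,
            "MSP": msp,
            "nc": nc,
            "fst_num": num,
            "fst_den": den,
            "fst": fst,
        }
    )


# ---------------------------------------------------------------------------
# window machinery
# ---------------------------------------------------------------------------


def window_grid(max_pos: int, window_bp: int, step_bp: int) -> np.ndarray:
    """Window start positions 1, 1+step, ... not exceeding *max_pos*."""
    if max_pos < 1:
        return np.array([], dtype=np.int64)
    n = (max_pos - 1) // step_bp + 1
    return 1 + step_bp * np.arange(n, dtype=np.int64)


def _window_sums(
    pos: np.ndarray, values: np.ndarray, starts: np.ndarray, window_bp: int
):
    """Sum *values* (NaN-skipped) over sites falling in each window.

    Returns ``(sums, n_sites, n_defined)`` per window via prefix sums;
    ``pos`` must be sorted ascending.
    """
    defined = ~np.isnan(values)
    vals = np.where(defined, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    cdef = np.concatenate([[0], np.cumsum(defined.astype(np.int64))])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window_bp - 1, side="right")
    sums = csum[hi] - csum[lo]
    n_def = cdef[hi] - cdef[lo]
    n_sites = hi - lo
    return sums, n_sites, n_def


def windowed_pi(
    ds: GenotypeDataset,
    population: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp for one population.

    ``pi = sum of site heterozygosities / window_bp``; windows with no
    SNPs report ``pi = 0`` and ``empty = True``.  Sites where fewer than
    two alleles were observed contribute nothing.
    """
    n, alt = ds.allele_counts(population)
    h = _het_array(n, alt)
    frames = []
    for chrom, grp in ds.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        starts = window_grid(int(pos.max()), window_bp, step_bp)
        sums, n_sites, _ = _window_sums(pos, h[idx], starts, window_bp)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_bp - 1,
                    "n_snps": n_sites,
                    "pi": sums / window_bp,
                    "empty": n_sites == 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def windowed_fst(
    ds: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    mode: str = "weighted",
) -> pd.DataFrame:
    """Sliding-window Fst between two populations.

    ``mode="weighted"`` (default) pools per-site numerators and
    denominators across the window (ratio of sums); ``mode="mean"``
    averages per-site ratios instead.  Windows with no defined site get
    NaN and ``undefined = True``.
    """
    if mode not in {"weighted", "mean"}:
        raise ValueError(f"unknown mode {mode!r}")
    n1, alt1 = ds.allele_counts(pop_a)
    n2, alt2 = ds.allele_counts(pop_b)
    num, den = fst_components(n1, alt1, n2, alt2)
    defined = ~np.isnan(den) & (den > 0)
    num = np.where(defined, num, np.nan)
    den = np.where(defined, den, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = num / den

    frames = []
    for chrom, grp in ds.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        starts = window_grid(int(pos.max()), window_bp, step_bp)
        num_s, n_sites, n_def = _window_sums(pos, num[idx], starts, window_bp)
        den_s, _, _ = _window_sums(pos, den[idx], starts, window_bp)
        with np.errstate(invalid="ignore", divide="ignore"):
            if mode == "weighted":
                w = np.where(n_def > 0, num_s / den_s, np.nan)
            else:
                ratio_s, _, _ = _window_sums(pos, ratio[idx], starts, window_bp)
                w = np.where(n_def > 0, ratio_s / n_def, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_bp - 1,
                    "n_snps": n_def,
                    "weighted_fst": w,
                    "undefined": n_def == 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def log_theta_pi_ratio(
    pi_a: pd.DataFrame, pi_b: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Natural-log per-window diversity ratio ``ln(pi_a / pi_b)``.

    The two window tables must share the same (chrom, start) grid.  The
    ratio is NaN wherever either pi is zero, and such windows are meant to
    be excluded from ranking; ``pseudocount`` adds a constant to both
    numerator and denominator instead (off by default).
    """
    key = ["chrom", "start"]
    if len(pi_a) != len(pi_b) or not (
        pi_a[key].reset_index(drop=True).equals(pi_b[key].reset_index(drop=True))
    ):
        raise ValueError("window grids of the two pi tables do not align")
    a = pi_a["pi"].to_numpy() + pseudocount
    b = pi_b["pi"].to_numpy() + pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        lr = np.where((a > 0) & (b > 0), np.log(a / b), np.nan)
    out = pi_a[["chrom", "start", "end"]].copy()
    out["pi_a"] = pi_a["pi"].to_numpy()
    out["pi_b"] = pi_b["pi"].to_numpy()
    out["log_ratio"] = lr
    return out


def window_stats(
    ds: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> pd.DataFrame:
    """Combined per-window table: weighted Fst, pi per population, log ratio."""
    fst = windowed_fst(ds, pop_a, pop_b, window_bp, step_bp)
    pa = windowed_pi(ds, pop_a, window_bp, step_bp)
    pb = windowed_pi(ds, pop_b, window_bp, step_bp)
    ratio = log_theta_pi_ratio(pa, pb)
    out = fst[["chrom", "start", "end", "n_snps", "weighted_fst"]].copy()
    out["pi_a"] = ratio["pi_a"]
    out["pi_b"] = ratio["pi_b"]
    out["log_ratio"] = ratio["log_ratio"]
    return out
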