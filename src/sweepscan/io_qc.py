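"""Genotype input/output and PLINK-equivalent quality control.

Readers accept VCF v4.x (via cyvcf2) or PLINK text PED/MAP and attach
population labels from a two-column TSV.  The QC filters mirror PLINK's
``--mind`` / ``--geno`` / ``--maf``: a sample or site is removed when its
missing fraction is strictly greater than the threshold, and a site is
removed when its minor-allele frequency is strictly below the MAF cutoff
(at-threshold items are retained in both cases).  Allele frequencies use
observed alleles only, pooled over all samples.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .dataset import MISSING, DatasetError, GenotypeDataset, QCReport

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


class QCError(ValueError):
    """Raised when a filter empties the dataset."""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_pop_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-column sample_id -> population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise DatasetError(f"population map {path} needs 2 columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "population"]
    first = df.iloc[0]
    if first["sample_id"].lower() in {"sample_id", "sample"} or first[
        "population"
    ].lower() in {"population", "pop"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df["sample_id"].duplicated().any():
        raise DatasetError("duplicate sample_id in population map")
    return df


def _attach_populations(
    sample_ids: list[str], pop_map: pd.DataFrame
) -> pd.DataFrame:
    lookup = dict(zip(pop_map["sample_id"], pop_map["population"]))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise DatasetError(
            f"sample(s) absent from population map: {', '.join(missing)}"
        )
    return pd.DataFrame(
        {"sample_id": sample_ids, "population": [lookup[s] for s in sample_ids]}
    )


def read_vcf(
    path: str | os.PathLike, pop_map: str | os.PathLike | pd.DataFrame
) -> GenotypeDataset:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    Multiallelic and non-SNP records are skipped (count logged); missing
    calls (``./.``) map to the missing code.  Haplotypes are attached when
    every non-missing call in the file is phased.
    """
    if isinstance(pop_map, pd.DataFrame):
        pops = pop_map
    else:
        pops = read_pop_map(pop_map)
    vcf = VCF(str(path))
    samples = _attach_populations(list(vcf.samples), pops)
    n = len(samples)

    records, dosages, haps = [], [], []
    all_phased = True
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        gt = np.array([g[:2] for g in v.genotypes], dtype=np.int8)
        phased = [bool(g[2]) for g in v.genotypes]
        call_missing = (gt < 0).any(axis=1)
        dose = np.where(call_missing, MISSING, gt.clip(0).sum(axis=1))
        if not all(
            p or m for p, m in zip(phased, call_missing)
        ):  # any unphased non-missing call
            all_phased = False
        hap = gt.reshape(2 * n).copy()
        hap[np.repeat(call_missing, 2)] = MISSING
        records.append(
            (v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0])
        )
        dosages.append(dose.astype(np.int8))
        haps.append(hap)
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    geno = (
        np.array(dosages, dtype=np.int8).T
        if dosages
        else np.empty((n, 0), dtype=np.int8)
    )
    hap_mat = (
        np.array(haps, dtype=np.int8).T if (haps and all_phased) else None
    )
    return GenotypeDataset(variants, samples, geno, hap_mat)


def read_ped_map(
    ped: str | os.PathLike,
    map_path: str | os.PathLike,
    pop_map: str | os.PathLike | pd.DataFrame,
) -> GenotypeDataset:
    """Load PLINK text PED/MAP, recoding allele pairs to alt dosage.

    The alt allele at each site is the minor allele observed in the file
    (ties broken toward the lexicographically later allele); ``0 0`` means
    missing.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, dtype=str, comment="#"
    )
    if mp.shape[1] < 4:
        raise DatasetError("MAP file needs 4 columns (chrom id cM pos)")
    n_sites = len(mp)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_sites:
                raise DatasetError(
                    f"PED line {line_no}: {len(fields)} fields, expected "
                    f"{6 + 2 * n_sites} for {n_sites} MAP sites"
                )
            sample_ids.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype="U1"))
    alleles = np.array(allele_rows)  # n_samples x 2*n_sites
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]

    geno = np.full((len(sample_ids), n_sites), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(n_sites):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise DatasetError(f"site {j}: more than two alleles")
        if len(uniq) == 0:
            refs.append("N")
            alts.append("N")
            continue
        if len(uniq) == 1:
            ref, alt = uniq[0], "N"
        else:
            # minor allele = alt; on a tie take the later one alphabetically
            (u0, u1), (c0, c1) = uniq, counts
            if c0 < c1:
                alt = u0
            elif c1 < c0:
                alt = u1
            else:
                alt = max(u0, u1)
            ref = u0 if alt == u1 else u1
        refs.append(ref)
        alts.append(alt)
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        dose = (a1[:, j] == alt).astype(np.int8) + (a2[:, j] == alt).astype(
            np.int8
        )
        geno[:, j] = np.where(miss, MISSING, dose)

    variants = pd.DataFrame(
        {
            "chrom": mp.iloc[:, 0].astype(str),
            "pos": mp.iloc[:, 3].astype(int),
            "id": mp.iloc[:, 1].astype(str),
            "ref": refs,
            "alt": alts,
        }
    )
    if isinstance(pop_map, pd.DataFrame):
        pops = pop_map
    else:
        pops = read_pop_map(pop_map)
    samples = _attach_populations(sample_ids, pops)
    return GenotypeDataset(variants, samples, geno)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_vcf(
    ds: GenotypeDataset,
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write the dataset as an uncompressed VCF v4.2.

    Phased output (``a|b``) is emitted when the dataset carries haplotypes,
    genotype output (``a/b``) otherwise; missing calls become ``.|.`` /
    ``./.``.
    """
    chroms = list(dict.fromkeys(ds.variants["chrom"]))
    if contig_lengths is None:
        contig_lengths = {
            c: int(ds.variants.loc[ds.variants["chrom"] == c, "pos"].max())
            for c in chroms
        }
    phased = ds.haplotypes is not None
    sep = "|" if phased else "/"
    gt_codes = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: f".{sep}."}

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples["sample_id"])
            + "\n"
        )
        var = ds.variants
        for j in range(ds.n_sites):
            if phased:
                h = ds.haplotypes[:, j]
                calls = [
                    f".{sep}."
                    if h[2 * i] < 0 or h[2 * i + 1] < 0
                    else f"{h[2 * i]}{sep}{h[2 * i + 1]}"
                    for i in range(ds.n_samples)
                ]
            else:
                calls = [gt_codes[int(g)] for g in ds.genotypes[:, j]]
            fh.write(
                f"{var.at[j, 'chrom']}\t{var.at[j, 'pos']}\t{var.at[j, 'id']}\t"
                f"{var.at[j, 'ref']}\t{var.at[j, 'alt']}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def _check_threshold(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def filter_mind(
    ds: GenotypeDataset, max_missing: float = 0.1
) -> tuple[GenotypeDataset, QCReport]:
    """Drop samples whose missing-call fraction exceeds *max_missing*."""
    _check_threshold("mind", max_missing)
    miss = (ds.genotypes == MISSING).mean(axis=1) if ds.n_sites else np.zeros(
        ds.n_samples
    )
    keep = miss <= max_missing
    if not keep.any():
        raise QCError("empty dataset: mind filter removed every sample")
    removed = [
        (sid, "mind")
        for sid in ds.samples.loc[~keep, "sample_id"]
    ]
    out = ds.take_samples(np.flatnonzero(keep))
    report = QCReport(
        ds.n_sites, out.n_sites, ds.n_samples, out.n_samples,
        removed_samples=removed, filter_order=["mind"],
        thresholds={"mind": max_missing},
    )
    return out, report


def filter_geno(
    ds: GenotypeDataset, max_missing: float = 0.1
) -> tuple[GenotypeDataset, QCReport]:
    """Drop sites whose missing-call fraction exceeds *max_missing*."""
    _check_threshold("geno", max_missing)
    miss = (ds.genotypes == MISSING).mean(axis=0) if ds.n_samples else np.zeros(
        ds.n_sites
    )
    keep = miss <= max_missing
    if not keep.any():
        raise QCError("empty dataset: geno filter removed every site")
    removed = [(vid, "geno") for vid in ds.variants.loc[~keep, "id"]]
    out = ds.take_sites(np.flatnonzero(keep))
    report = QCReport(
        ds.n_sites, out.n_sites, ds.n_samples, out.n_samples,
        removed_sites=removed, filter_order=["geno"],
        thresholds={"geno": max_missing},
    )
    return out, report


def filter_maf(
    ds: GenotypeDataset, min_maf: float = 0.05
) -> tuple[GenotypeDataset, QCReport]:
    """Drop sites with pooled minor-allele frequency below *min_maf*.

    Frequencies are computed from observed alleles only; a site with no
    observed calls has MAF 0 and is removed whenever ``min_maf > 0``.
    """
    _check_threshold("maf", min_maf)
    n, alt = ds.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    if not keep.any():
        raise QCError("empty dataset: maf filter removed every site")
    removed = [(vid, "maf") for vid in ds.variants.loc[~keep, "id"]]
    out = ds.take_sites(np.flatnonzero(keep))
    report = QCReport(
        ds.n_sites, out.n_sites, ds.n_samples, out.n_samples,
        removed_sites=removed, filter_order=["maf"],
        thresholds={"maf": min_maf},
    )
    return out, report


def apply_qc(
    ds: GenotypeDataset,
    mind: float = 0.1,
    geno: float = 0.1,
    maf: float = 0.05,
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC chain in the fixed order mind -> geno -> maf."""
    ds1, r1 = filter_mind(ds, mind)
    ds2, r2 = filter_geno(ds1, geno)
    ds3, r3 = filter_maf(ds2, maf)
    return ds3, r1.merge(r2).merge(r3)
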