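"""Core in-memory containers for biallelic SNP genotype data.

The central object is :class:`GenotypeDataset`, a sample x site matrix of
alt-allele dosages (0/1/2, with -1 for a missing call) plus two pandas
tables of variant and sample metadata.  All downstream statistics operate
on this container; readers in :mod:`sweepscan.io_qc` build it from VCF or
PLINK text PED/MAP input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")
SAMPLE_COLUMNS = ("sample_id", "population")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class GenotypeDataset:
    """Biallelic SNP genotypes with variant and sample metadata.

    Parameters
    ----------
    variants
        One row per site with columns ``chrom, pos, id, ref, alt``;
        positions are 1-based and strictly increasing within a chromosome.
    samples
        One row per sample with columns ``sample_id, population``.
    genotypes
        ``n_samples x n_sites`` int8 matrix of alt-allele dosages in
        ``{0, 1, 2}`` with :data:`MISSING` (-1) for no-calls.
    haplotypes
        Optional phased ``2 * n_samples x n_sites`` matrix with alleles in
        ``{0, 1}`` and -1 where the underlying call is missing.  Rows
        ``2i`` and ``2i + 1`` are the two haplotypes of sample ``i``.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise DatasetError(f"variants table lacks column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise DatasetError(f"samples table lacks column {col!r}")
        n_samp, n_site = self.genotypes.shape
        if len(self.samples) != n_samp or len(self.variants) != n_site:
            raise DatasetError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} sites"
            )
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise DatasetError("genotype values outside {missing, 0, 1, 2}")
        if self.samples["sample_id"].duplicated().any():
            raise DatasetError("duplicate sample_id")
        if (self.samples["population"].astype(str) == "").any():
            raise DatasetError("empty population label")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise DatasetError(
                    f"positions not strictly increasing on {chrom}"
                )
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * n_samp, n_site):
                raise DatasetError("haplotype matrix shape mismatch")
            if not np.isin(self.haplotypes, (-1, 0, 1)).all():
                raise DatasetError("haplotype values outside {-1, 0, 1}")

    # -- basic accessors ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to *population*."""
        idx = np.flatnonzero(
            (self.samples["population"] == population).to_numpy()
        )
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in dataset")
        return idx

    def allele_counts(self, population: str | None = None):
        """Observed allele count and alt-allele count per site.

        Returns ``(n, alt)`` where ``n`` is twice the number of non-missing
        diploid calls and ``alt`` the summed dosage, both length
        ``n_sites``.  Missing calls contribute to neither.
        """
        g = self.genotypes
        if population is not None:
            g = g[self.sample_indices(population)]
        observed = g != MISSING
        n = 2 * observed.sum(axis=0)
        alt = np.where(observed, g, 0).sum(axis=0)
        return n.astype(np.int64), alt.astype(np.int64)

    # -- subsetting -----------------------------------------------------

    def take_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        haps = None
        if self.haplotypes is not None:
            hap_idx = np.repeat(2 * idx, 2) + np.tile([0, 1], idx.size)
            haps = self.haplotypes[hap_idx]
        return GenotypeDataset(
            self.variants.copy(),
            self.samples.iloc[idx],
            self.genotypes[idx],
            haps,
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeDataset(
            self.variants.iloc[idx],
            self.samples.copy(),
            self.genotypes[:, idx],
            haps,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        """Exact equality of metadata and genotype matrices."""
        return (
            self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class QCReport:
    """Accounting of a quality-control pass.

    ``removed_sites`` / ``removed_samples`` record ``(identifier, reason)``
    pairs, each item listed once under the first filter that removed it
    (reasons: ``geno``, ``mind``, ``maf``).
    """

    n_sites_in: int
    n_sites_out: int
    n_samples_in: int
    n_samples_out: int
    removed_sites: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    filter_order: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites_out > self.n_sites_in:
            raise DatasetError("n_sites_out > n_sites_in")
        if self.n_samples_out > self.n_samples_in:
            raise DatasetError("n_samples_out > n_samples_in")

    def merge(self, other: "QCReport") -> "QCReport":
        """Chain this report with a report of a subsequent filter."""
        return QCReport(
            n_sites_in=self.n_sites_in,
            n_sites_out=other.n_sites_out,
            n_samples_in=self.n_samples_in,
            n_samples_out=other.n_samples_out,
            removed_sites=self.removed_sites + other.removed_sites,
            removed_samples=self.removed_samples + other.removed_samples,
            filter_order=self.filter_order + other.filter_order,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def summary(self) -> dict:
        return {
            "n_sites_in": self.n_sites_in,
            "n_sites_out": self.n_sites_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_sites_removed": len(self.removed_sites),
            "n_samples_removed": len(self.removed_samples),
            "filter_order": self.filter_order,
            "thresholds": self.thresholds,
        }

    def removed_frame(self) -> pd.DataFrame:
        rows = [("site", i, r) for i, r in self.removed_sites] + [
            ("sample", i, r) for i, r in self.removed_samples
        ]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])
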