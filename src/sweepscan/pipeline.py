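"""End-to-end orchestration: qc -> fst/pi/ratio -> ld -> scan -> report.

The pipeline is configured by a YAML (or plain dict) with full defaults
mirroring the standard run: mind/geno/maf = 0.1/0.1/0.05, 500 kb windows
with 50 kb steps, top-5% Fst and 2.5% + 2.5% theta-pi-ratio tails, and a
300 kb LD distance cap.  Every run writes per-stage TSVs plus a JSON
manifest recording input digests, parameters, per-stage counts and
timestamps; reruns with identical inputs differ only in timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_qc, ld, popstats, scan

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "vcf": None,
    "pops": None,
    "genes": None,  # GFF3 or BED; optional
    "pop_a": None,  # default: first two populations in the sample table
    "pop_b": None,
    "mind": 0.1,
    "geno": 0.1,
    "maf": 0.05,
    "window_bp": 500_000,
    "step_bp": 50_000,
    "fst_fraction": 0.05,
    "ratio_fraction": 0.025,
    "ld": {"enabled": True, "population": None, "max_dist": 300_000, "bin_bp": 1_000},
    "out": "sweepscan_out",
}


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration before any compute."""


def load_config(source: str | os.PathLike | dict) -> dict:
    """Merge a YAML file or dict over the defaults and validate it."""
    if isinstance(source, dict):
        user = dict(source)
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    cfg["ld"] = {**DEFAULT_CONFIG["ld"], **(user.get("ld") or {})}
    for key in ("mind", "geno", "maf"):
        v = cfg[key]
        if not (isinstance(v, (int, float)) and 0 <= v <= 1):
            raise ConfigError(f"{key} must lie in [0, 1], got {v!r}")
    for key in ("fst_fraction", "ratio_fraction"):
        v = cfg[key]
        if not (isinstance(v, (int, float)) and 0 < v < 1):
            raise ConfigError(f"{key} must lie in (0, 1), got {v!r}")
    for key in ("window_bp", "step_bp"):
        if int(cfg[key]) <= 0:
            raise ConfigError(f"{key} must be positive")
    if cfg["vcf"] is None or cfg["pops"] is None:
        raise ConfigError("config must name 'vcf' and 'pops' inputs")
    for key in ("vcf", "pops", "genes"):
        if cfg[key] is not None and not Path(cfg[key]).exists():
            raise ConfigError(f"missing input {key}: {cfg[key]}")
    return cfg


def _digest(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: str | os.PathLike | dict) -> dict:
    """Execute the full scan and return the run manifest (also written to
    ``<out>/manifest.json``)."""
    cfg = load_config(config)
    outdir = Path(cfg["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sweepscan",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "config": {
            k: v for k, v in cfg.items() if k not in ("ld",)
        },
        "ld": cfg["ld"],
        "inputs": {
            k: {"path": str(cfg[k]), "sha256": _digest(cfg[k])}
            for k in ("vcf", "pops", "genes")
            if cfg[k] is not None
        },
        "stages": {},
    }

    # --- load + qc
    ds = io_qc.read_vcf(cfg["vcf"], cfg["pops"])
    ds_qc, report = io_qc.apply_qc(ds, cfg["mind"], cfg["geno"], cfg["maf"])
    manifest["stages"]["qc"] = report.summary()
    report.removed_frame().to_csv(outdir / "qc_removed.tsv", sep="\t", index=False)
    log.info(
        "qc: %d/%d sites, %d/%d samples retained",
        report.n_sites_out, report.n_sites_in,
        report.n_samples_out, report.n_samples_in,
    )

    pops = ds_qc.populations
    pop_a = cfg["pop_a"] or pops[0]
    pop_b = cfg["pop_b"] or next(p for p in pops if p != pop_a)

    # --- windowed statistics
    windows = popstats.window_stats(
        ds_qc, pop_a, pop_b, int(cfg["window_bp"]), int(cfg["step_bp"])
    )
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    manifest["stages"]["windows"] = {
        "pop_a": pop_a,
        "pop_b": pop_b,
        "n_windows": int(len(windows)),
        "n_fst_defined": int(windows["weighted_fst"].notna().sum()),
        "n_ratio_defined": int(windows["log_ratio"].notna().sum()),
    }

    # --- LD decay
    if cfg["ld"]["enabled"]:
        ld_pop = cfg["ld"]["population"] or pop_a
        idx = ds_qc.sample_indices(ld_pop)
        sub = ds_qc.take_samples(idx)
        if sub.haplotypes is not None:
            mat, mode, zero_tol = sub.haplotypes, "haplotype", 0.0
        else:
            mat, mode, zero_tol = sub.genotypes, "genotype", 1e-12
        curve = ld.decay_curve(
            mat, sub.variants, int(cfg["ld"]["max_dist"]), int(cfg["ld"]["bin_bp"])
        )
        curve.to_csv(outdir / "ld_decay.tsv", sep="\t", index=False)
        dist = ld.r2_distribution(
            mat, sub.variants, int(cfg["ld"]["max_dist"]), zero_tol=zero_tol
        )
        dist["histogram"].to_csv(outdir / "ld_hist.tsv", sep="\t", index=False)
        manifest["stages"]["ld"] = {
            "population": ld_pop,
            "mode": mode,
            "n_pairs": int(dist["n_pairs"]),
            "n_r2_zero": int(dist["n_zero"]),
        }

    # --- selection scan
    fst_thr, fst_sel = scan.select_fst_windows(windows, cfg["fst_fraction"])
    ratio_sel = scan.select_ratio_windows(windows, cfg["ratio_fraction"])
    fst_regions = scan.merge_windows(fst_sel)
    high_regions = scan.merge_windows(ratio_sel["high"][1])
    low_regions = scan.merge_windows(ratio_sel["low"][1])
    regions = pd.concat(
        [fst_regions, high_regions, low_regions], ignore_index=True
    )
    regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    scan.regions_to_bed(regions, outdir / "regions.bed")
    manifest["stages"]["scan"] = {
        "fst_threshold": fst_thr,
        "ratio_high_threshold": ratio_sel["high"][0],
        "ratio_low_threshold": ratio_sel["low"][0],
        "n_fst_windows": int(len(fst_sel)),
        "n_ratio_high_windows": int(len(ratio_sel["high"][1])),
        "n_ratio_low_windows": int(len(ratio_sel["low"][1])),
        "n_regions": int(len(regions)),
    }

    # --- gene mapping
    if cfg["genes"] is not None:
        gpath = str(cfg["genes"])
        genes = (
            scan.read_bed(gpath)
            if gpath.endswith(".bed")
            else scan.read_gff3(gpath)
        )
        cand = scan.intersect_candidates(
            scan.genes_in_regions(fst_regions, genes),
            scan.genes_in_regions(high_regions, genes),
            scan.genes_in_regions(low_regions, genes),
        )
        for name, s in (
            ("genes_fst.txt", cand.fst_genes),
            ("genes_ratio_high.txt", cand.ratio_high_genes),
            ("genes_ratio_low.txt", cand.ratio_low_genes),
            ("genes_intersection.txt", cand.intersection_genes),
        ):
            (outdir / name).write_text("\n".join(sorted(s)) + "\n")
        manifest["stages"]["genes"] = {
            "n_genes_annotation": int(len(genes)),
            "n_fst_genes": len(cand.fst_genes),
            "n_ratio_high_genes": len(cand.ratio_high_genes),
            "n_ratio_low_genes": len(cand.ratio_low_genes),
            "n_intersection_genes": len(cand.intersection_genes),
        }

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
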