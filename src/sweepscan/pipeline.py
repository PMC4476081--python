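"""End-to-end orchestration: (simulate|read) -> qc -> fst scan + varld -> annotate.

The pipeline is deterministic under a fixed seed and writes every module's
table as TSV plus a JSON run manifest (config hash, seed, per-stage record
counts).  All numeric defaults are the module defaults; a YAML config file or
keyword overrides adjust them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    intervals_to_bed, make_intervals, method_concordance, overlap_genes,
)
from .dataset import GenotypeDataset
from .io import read_plink, read_population_table, read_vcf, write_plink
from .qc import heterozygosity_summary, run_qc
from .scan import FstScanModel, SmoothingConfig
from .simulate import (
    SimConfig, Sweep, LdDivergentRegion, simulate_dataset, truth_to_frame,
)
from .varld import VarLDConfig, VarLDModel

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; unknown keys in a config file are rejected."""

    output_dir: str = "sweepscan_out"
    seed: int = 0
    # input: either PED/MAP or VCF (+ population table), or a simulate block
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    populations: str | None = None
    simulate: dict | None = None
    # qc
    n_autosomes: int = 29
    max_missing_rate: float = 0.025
    min_maf: float = 0.01
    # scan
    window_snps: int = 20
    degree: int = 1
    robustness_iters: int = 0
    k_sd: float = 3.0
    chart_scope: str = "chromosome"
    borderline_fraction: float = 0.9
    # varld
    varld_window_snps: int | None = None  # None -> window_snps
    varld_threshold_sd: float = 3.0
    varld_standardization: str = "zscore"
    # annotation
    annotation: str | None = None
    flank_bp: int = 250_000
    proximity_bp: int = 500_000
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_dataset(cfg: PipelineConfig) -> tuple[GenotypeDataset, pd.DataFrame | None]:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        sweeps = [Sweep(**s) for s in sim.pop("sweeps", [])]
        regions = [LdDivergentRegion(**r) for r in sim.pop("ld_divergent", [])]
        ds, truth = simulate_dataset(SimConfig(sweeps=sweeps, ld_divergent=regions, **sim))
        return ds, truth_to_frame(truth)
    pops = read_population_table(cfg.populations) if cfg.populations else None
    if cfg.vcf:
        if pops is None:
            raise ValueError("a population table is required with --vcf")
        return read_vcf(cfg.vcf, pops), None
    if cfg.ped and cfg.map:
        return read_plink(cfg.ped, cfg.map, pops), None
    raise ValueError("provide ped+map, vcf, or a simulate block")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full scan; returns the run manifest (also written as JSON)."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(vars(cfg), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }

    def stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception:
            log.error("stage %r failed", name)
            raise
        manifest["stages"][name] = {"seconds": round(time.time() - t, 3)}
        return result

    ds, truth = stage("load", lambda: _load_dataset(cfg))
    manifest["stages"]["load"]["n_snps"] = ds.n_snps
    manifest["stages"]["load"]["n_samples"] = ds.n_samples
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_plink(ds, out / "simulated.ped", out / "simulated.map")

    def do_qc():
        filtered, report = run_qc(
            ds, n_autosomes=cfg.n_autosomes,
            max_missing_rate=cfg.max_missing_rate, min_maf=cfg.min_maf,
            impute=False,
        )
        # heterozygosity reflects observed calls, before imputation fills gaps
        het = heterozygosity_summary(filtered)
        het.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        from .qc import impute_missing

        qcd, n_imp = impute_missing(filtered)
        report.n_imputed_cells = n_imp
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        return qcd, report

    qcd, report = stage("qc", do_qc)
    manifest["stages"]["qc"].update(
        {"n_retained": report.n_retained, "reconciles": report.reconciles()}
    )

    def do_scan():
        model = FstScanModel(
            qcd,
            smoothing=SmoothingConfig(
                window_snps=cfg.window_snps, degree=cfg.degree,
                robustness_iters=cfg.robustness_iters,
            ),
            k_sd=cfg.k_sd, chart_scope=cfg.chart_scope,
            borderline_fraction=cfg.borderline_fraction,
        )
        res = model.fit()
        res.to_tsv(out / "fst_track.tsv", out / "chart_limits.tsv", out / "peaks.tsv")
        return res

    scan_res = stage("fst_scan", do_scan)
    manifest["stages"]["fst_scan"].update(
        {
            "n_snps_scanned": len(scan_res.track),
            "n_outlier_snps": scan_res.n_outlier_snps,
            "n_outlier_peaks": len(scan_res.outlier_peaks),
        }
    )

    def do_varld():
        vcfg = VarLDConfig(
            window_snps=cfg.varld_window_snps or cfg.window_snps,
            threshold_sd=cfg.varld_threshold_sd,
            standardization=cfg.varld_standardization,
        )
        res = VarLDModel(qcd, vcfg).fit()
        res.to_tsv(out / "varld_windows.tsv")
        return res

    varld_res = stage("varld", do_varld)
    manifest["stages"]["varld"].update(
        {
            "n_windows": len(varld_res.windows),
            "n_significant_windows": int(varld_res.windows["significant"].sum()),
        }
    )

    def do_annotate():
        chart_snps = scan_res.significant_snps
        varld_snps = varld_res.significant_snps
        iv_chart = make_intervals(chart_snps, cfg.flank_bp, source="control_chart")
        iv_varld = make_intervals(varld_snps, cfg.flank_bp, source="varld")
        intervals = pd.concat([iv_chart, iv_varld], ignore_index=True)
        intervals_to_bed(intervals, out / "intervals.bed")
        conc = method_concordance(chart_snps, varld_snps, cfg.proximity_bp)
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
        hits = None
        if cfg.annotation:
            hits = overlap_genes(intervals, cfg.annotation)
            hits.to_csv(out / "gene_hits.tsv", sep="\t", index=False)
        return intervals, conc, hits

    intervals, conc, hits = stage("annotate", do_annotate)
    manifest["stages"]["annotate"].update(
        {
            "n_intervals": len(intervals),
            "n_gene_hits": None if hits is None else len(hits),
            "n_concordant_chromosomes": int(
                conc["status"].isin(["exact", "regional"]).sum()
            ),
        }
    )

    if cfg.plots:
        def do_plots():
            from .plots import chromosome_triptych, manhattan_pair
            plot_dir = out / "plots"
            plot_dir.mkdir(exist_ok=True)
            for chrom in scan_res.limits["chromosome"]:
                chromosome_triptych(
                    scan_res, chrom, plot_dir / f"chr{chrom}_triptych.png"
                )
            manhattan_pair(scan_res, varld_res, plot_dir / "manhattan.png")
        stage("plots", do_plots)

    manifest["seconds_total"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
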