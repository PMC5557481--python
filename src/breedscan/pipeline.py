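"""End-to-end orchestration of the synthetic demonstration pipeline.

Stages run in dependency order: simulate -> qc -> pedigree-stats -> ld-ne
-> roh -> fst-scan.  The two-cluster panel feeds QC, LD and the F_ST scan;
the gene-dropped pedigree feeds the pedigree statistics and the ROH stage,
whose report includes the correlation and regression slope of the genomic
inbreeding coefficient (F_ROH) on the pedigree coefficient (F_pedigree).
All thresholds used are logged with their provenance (default or
user-set), and a single JSON + TSV report bundle is written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fst, ld, plink, roh, synth
from .pedigree import ne_from_inbreeding_trend
from .qc import QCThresholds, apply_qc

logger = logging.getLogger("breedscan.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed or a dependency was not produced."""


@dataclass
class RunConfig:
    outdir: str = "breedscan_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_qc: bool = True
    run_pedigree: bool = True
    run_ld: bool = True
    run_roh: bool = True
    run_fst: bool = True
    # simulation scale
    n_per_cluster: int = 60
    n_snps: int = 3000
    n_chromosomes: int = 6
    chromosome_length_bp: int = 60_000_000
    fst_background: float = 0.05
    n_outlier_loci: int = 4
    fst_outlier: float = 0.4
    missing_rate: float = 0.01
    genedrop_founders: int = 30
    genedrop_generations: int = 8
    # chip-like marker density (~50 SNP/Mb) so ROH length filters behave
    # as they would on a high-density array
    genedrop_snps: int = 3000
    genedrop_chromosomes: int = 3
    genedrop_chromosome_length_bp: int = 20_000_000
    # analysis parameters
    qc: QCThresholds = field(default_factory=QCThresholds)
    generation_interval_years: float = 4.5
    ld_max_distance_bp: int = 20_000_000
    ld_maf_min: float = 0.1
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    fst_window_sizes: tuple = (9, 13, 17)
    fst_tail_fraction: float = 0.0005
    fst_merge_distance_bp: int = 1_000_000


def _log_params(cfg: RunConfig, user_set: set) -> list:
    rows = []
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        provenance = "user" if f.name in user_set else "default"
        if dataclasses.is_dataclass(value):
            value = dataclasses.asdict(value)
        elif isinstance(value, tuple):
            value = list(value)
        rows.append({"parameter": f.name, "value": value, "provenance": provenance})
        logger.info("parameter %s = %r (%s)", f.name, value, provenance)
    return rows


def run_pipeline(config: RunConfig | None = None, user_set: set | None = None) -> dict:
    """Run all enabled stages; returns (and writes) the report bundle."""
    cfg = config or RunConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "parameters": _log_params(cfg, user_set or set())}
    artifacts: dict = {}

    def require(key: str, producer: str):
        if key not in artifacts:
            raise StageError(f"stage requires output of disabled stage '{producer}'")
        return artifacts[key]

    if cfg.run_simulate:
        try:
            _stage_simulate(cfg, outdir, artifacts, report)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"stage 'simulate' failed: {exc}") from exc

    if cfg.run_qc:
        panel = require("panel", "simulate")
        filtered, qc_report = apply_qc(panel.genotypes, cfg.qc)
        qc_report.to_json(outdir / "qc_report.json")
        artifacts["qc_panel"] = filtered
        report["qc"] = json.loads(qc_report.to_json())

    if cfg.run_pedigree:
        sim = require("genedrop", "simulate")
        ped = sim.pedigree
        fvals = ped.inbreeding_coefficients()
        ne = ne_from_inbreeding_trend(ped, cfg.generation_interval_years)
        report["pedigree"] = {
            "n_individuals": len(ped),
            "mean_f": float(np.mean(list(fvals.values()))),
            "max_f": float(max(fvals.values())),
            "ne": ne.ne,
            "delta_f_per_generation": ne.delta_f_per_generation,
            "ne_defined": ne.defined,
        }
        artifacts["pedigree_f"] = fvals

    if cfg.run_ld:
        panel = require("qc_panel", "qc")
        pairs = ld.pairwise_r2(panel, maf_min=cfg.ld_maf_min,
                               max_distance_bp=cfg.ld_max_distance_bp)
        bins = ld.bin_ld(pairs, ld.default_bin_edges(1_000, cfg.ld_max_distance_bp, 15),
                         n_samples=panel.n_samples)
        ne_tab = ld.estimate_ne_from_ld(bins, n_samples=panel.n_samples, alpha=1)
        ne_tab.to_csv(outdir / "ld_ne.tsv", sep="\t", index=False)
        report["ld"] = {
            "n_pairs": int(len(pairs)),
            "n_bins": len(bins),
            "mean_r2_nearest_bin": bins[0].mean_r2 if bins else None,
        }

    if cfg.run_roh:
        sim = require("genedrop", "simulate")
        fvals = require("pedigree_f", "pedigree")
        # F_ROH denominator: the extent of the simulated genome
        params = dataclasses.replace(
            cfg.roh_params,
            genome_denominator_bp=cfg.genedrop_chromosomes * cfg.genedrop_chromosome_length_bp,
        )
        segs = roh.detect_roh(sim.genotypes, params)
        roh.segments_to_frame(segs).to_csv(outdir / "roh_segments.tsv", sep="\t", index=False)
        froh = roh.f_roh(segs, params, sample_ids=sim.genotypes.sample_ids)
        ids = sim.genotypes.sample_ids
        x = np.array([fvals[i] for i in ids])
        y = np.array([froh[i] for i in ids])
        if x.std() > 0 and y.std() > 0:
            corr = float(np.corrcoef(x, y)[0, 1])
            slope = float(np.polyfit(x, y, 1)[0])
        else:
            corr, slope = float("nan"), float("nan")
        report["roh"] = {
            "n_segments": len(segs),
            "mean_f_roh": float(np.mean(y)),
            "corr_f_pedigree_f_roh": corr,
            "slope_f_roh_on_f_pedigree": slope,
        }

    if cfg.run_fst:
        panel = require("qc_panel", "qc")
        twoc = require("two_cluster", "simulate")
        # map the surviving panel samples back to their cluster labels
        label_of = dict(zip(twoc.genotypes.sample_ids, twoc.cluster_labels))
        labels = np.array([label_of[s] for s in panel.sample_ids])
        loci = fst.wc_fst_per_locus(panel, labels)
        loci.to_csv(outdir / "fst_loci.tsv", sep="\t", index=False)
        windows = {k: fst.window_fst(loci, k) for k in cfg.fst_window_sizes}
        regions = fst.top_windows_and_regions(
            windows, cfg.fst_tail_fraction, cfg.fst_merge_distance_bp
        )
        report["fst"] = {
            "mean_theta": float(np.nanmean(loci["theta"])),
            "n_windows": {int(k): int(len(v)) for k, v in windows.items()},
            "n_regions": len(regions),
            "regions": [
                {
                    "chrom": r.chrom,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "max_theta_by_k": r.max_theta_by_k,
                }
                for r in regions
            ],
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_simulate(cfg: RunConfig, outdir: Path, artifacts: dict, report: dict) -> None:
    sim_cfg = synth.SimConfig(
        n_individuals=cfg.n_per_cluster,
        n_snps=cfg.n_snps,
        n_chromosomes=cfg.n_chromosomes,
        chromosome_length_bp=cfg.chromosome_length_bp,
        fst_background=cfg.fst_background,
        n_outlier_loci=cfg.n_outlier_loci,
        fst_outlier=cfg.fst_outlier,
        missing_rate=cfg.missing_rate,
        seed=cfg.seed,
    )
    twoc = synth.simulate_two_cluster_genotypes(sim_cfg)
    plink.write_ped_map(twoc.genotypes, outdir / "panel.ped", outdir / "panel.map")
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("id,cluster,q_cluster1\n")
        for sid, lab in zip(twoc.genotypes.sample_ids, twoc.cluster_labels):
            fh.write(f"{sid},{lab + 1},{1.0 - float(lab):.3f}\n")
    gened = synth.simulate_pedigree_with_genedrop(
        n_founders=cfg.genedrop_founders,
        n_generations=cfg.genedrop_generations,
        n_snps=cfg.genedrop_snps,
        n_chromosomes=cfg.genedrop_chromosomes,
        chromosome_length_bp=cfg.genedrop_chromosome_length_bp,
        seed=cfg.seed + 1,
        generation_interval_years=cfg.generation_interval_years,
    )
    plink.write_pedigree_csv(gened.pedigree.to_frame(), outdir / "pedigree.csv")
    synth.write_ground_truth(
        outdir / "ground_truth.json",
        outlier_indices=twoc.outlier_indices,
        outlier_positions={
            "chrom": twoc.map.chrom[twoc.outlier_indices],
            "bp": twoc.map.bp[twoc.outlier_indices],
        },
        fst_background=cfg.fst_background,
        fst_outlier=cfg.fst_outlier,
    )
    artifacts["panel"] = twoc
    artifacts["two_cluster"] = twoc
    artifacts["genedrop"] = gened
    report["simulate"] = {
        "panel_samples": twoc.genotypes.n_samples,
        "panel_snps": twoc.genotypes.n_snps,
        "pedigree_individuals": len(gened.pedigree),
        "outlier_loci": twoc.outlier_indices.tolist(),
    }
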