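"""End-to-end driver: simulation -> methylome profiling -> DMS/DMR calling
-> annotation/DMG -> DE/DEDMG -> landscape, with a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .counts import simulate_methylomes
from .dmr import call_dms, filter_sites, merge_dms, dmr_summary
from .expression import simulate_expression
from .genome import generate_genome
from .integrate import (DEThresholds, annotate_dmrs, call_dmgs, de_test,
                        intersect_dedmg, tmm_factors)
from .io import write_allc, write_design, write_dmr_bed, write_fasta, write_gff3
from .landscape import (call_peaks, dmr_density, feature_density,
                        methylation_regression, pca_windows,
                        proximity_categories, proximity_effect,
                        shared_peak_windows)
from .methylome import (estimate_nonconversion, metaplot, subcontext_summary,
                        weighted_level, window_profile)
from .scenario import ScenarioConfig
from .truth import apply_treatment, simulate_truth

logger = logging.getLogger("epimem")


@dataclass
class RunConfig:
    """All stage parameters, serialized alongside every run for provenance."""

    contexts: tuple[str, ...] = ("CGN", "CHG", "CHH")
    fdr: float = 0.003
    min_coverage: int = 30
    permutations: int = 1000
    merge_gap: int = 250
    window: int = 50_000
    flank: int = 2000
    body_bins: int = 20
    flank_bin: int = 100
    promoter_len: int = 2000
    deg_p: float = 0.05
    deg_fc: float = 1.5
    deg_use_adjusted: bool = False
    site_q: float = 0.01
    proximity_edges: tuple[int, int, int] = (2000, 5000, 10_000)
    peak_floor: int = 10
    peak_quantile: float = 0.99
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, source: str) -> "RunConfig":
        if "\n" not in source and not source.lstrip().startswith("{"):
            with open(source) as fh:
                source = fh.read()
        d = json.loads(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("contexts", "proximity_edges"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not logger.handlers:
        logger.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(out_dir / "pipeline.log")
    logger.addHandler(fh)


def run_pipeline(scenario: ScenarioConfig, config: RunConfig | None = None,
                 out_dir=None, groups=None, write_allc_files: bool = False) -> dict:
    """Run the full synthetic-study analysis and write the output bundle.

    Returns a results dict; writes TSV/BED/JSON outputs plus a manifest with
    the config hash, seed and per-stage counts under ``out_dir``.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir) if out_dir is not None else Path("epimem_run")
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    t0 = time.time()
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "scenario_seed": scenario.seed,
        "versions": {"epimem": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "outputs": [],
        "stages": {},
    }
    results: dict = {"manifest": manifest}
    groups = list(groups) if groups is not None else list(scenario.groups)

    def _emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        manifest["outputs"].append(name)

    def _finish_manifest() -> None:
        manifest["runtime_s"] = round(time.time() - t0, 2)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "simulate"
    try:
        genome = generate_genome(scenario)
        truth = apply_treatment(simulate_truth(genome, scenario), scenario)
        table = simulate_methylomes(truth, scenario, groups=groups)
        counts_expr, expr_truth = simulate_expression(genome, scenario)
        design = table.design()
        manifest["stages"][stage] = {
            "sites": len(truth.sites), "samples": len(design),
            "genes": len(genome.genes),
        }
        logger.info("simulate: %d sites, %d samples", len(truth.sites), len(design))
        _emit("genome.fa", lambda p: write_fasta(genome.sequences, p))
        _emit("features.gff3",
              lambda p: write_gff3(genome.features, p, genome.chrom_lengths))
        _emit("design.tsv", lambda p: write_design(design, p))
        _emit("scenario.json", lambda p: scenario.to_json(p))
        _emit("config.json", lambda p: Path(p).write_text(config.to_json() + "\n"))
        if write_allc_files:
            for s in table.sample_ids:
                _emit(f"allc_{s}.tsv", lambda p, s=s: write_allc(table, s, p))

        stage = "methylome"
        eps = estimate_nonconversion(table, scenario.chloroplast)
        levels = {
            ctx: weighted_level(table, context=ctx,
                                exclude_chroms=[scenario.chloroplast])
            for ctx in config.contexts
        }
        profile = window_profile(table, window=config.window)
        per_sample_profile = window_profile(table, window=config.window,
                                            per_sample=True)
        sub = subcontext_summary(table)
        meta = metaplot(table, genome.genes, body_bins=config.body_bins,
                        flank=config.flank, flank_bin=config.flank_bin)
        manifest["stages"][stage] = {"epsilon": eps, "levels": levels}
        logger.info("methylome: eps=%.5f levels=%s", eps,
                    {k: round(v, 4) for k, v in levels.items()})
        _emit("window_profile.tsv",
              lambda p: profile.to_csv(p, sep="\t", index=False))
        _emit("subcontext.tsv", lambda p: sub.to_csv(p, sep="\t", index=False))
        _emit("metaplot_genes.tsv", lambda p: meta.to_csv(p, sep="\t", index=False))
        results.update({"epsilon": eps, "levels": levels, "profile": profile,
                        "subcontext": sub, "metaplot": meta})

        stage = "dmr"
        dmrs_by_group: dict[str, pd.DataFrame] = {}
        dms_by_group: dict[str, pd.DataFrame] = {}
        cold, warm = scenario.conditions[0], scenario.conditions[1]
        for group in groups:
            ctrl = table.samples_where(group=group, condition=cold)
            trt = table.samples_where(group=group, condition=warm)
            if len(ctrl) < 2 or len(trt) < 2:
                raise ValueError(
                    f"group {group!r} needs >= 2 replicates per condition "
                    f"(got {len(ctrl)} vs {len(trt)})"
                )
            dms_parts, dmr_parts = [], []
            for ctx in config.contexts:
                mat = filter_sites(table, ctx, ctrl, trt,
                                   min_pooled_cov=config.min_coverage)
                dms = call_dms(mat, fdr=config.fdr, B=config.permutations,
                               seed=config.seed)
                dmrs = merge_dms(dms, gap=config.merge_gap)
                dms_parts.append(dms)
                dmr_parts.append(dmrs)
            nonempty = [d for d in dms_parts if len(d)] or dms_parts[:1]
            dms_by_group[group] = pd.concat(nonempty, ignore_index=True)
            nonempty = [d for d in dmr_parts if len(d)] or dmr_parts[:1]
            dmrs_by_group[group] = pd.concat(nonempty, ignore_index=True)
            logger.info("dmr[%s]: %d DMSs -> %d DMRs", group,
                        len(dms_by_group[group]), len(dmrs_by_group[group]))
            _emit(f"dmrs_{group}.bed",
                  lambda p, g=group: write_dmr_bed(dmrs_by_group[g], p))
        summary = dmr_summary(dmrs_by_group)
        manifest["stages"][stage] = {
            g: len(d) for g, d in dmrs_by_group.items()
        }
        _emit("dmr_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))
        results.update({"dms": dms_by_group, "dmrs": dmrs_by_group,
                        "dmr_summary": summary})

        stage = "integrate"
        sample_meta = {sid: (g, c) for sid, g, c, _ in scenario.samples()}
        thresholds = DEThresholds(p=config.deg_p, fc=config.deg_fc,
                                  use_adjusted=config.deg_use_adjusted)
        gene_stats_by_group: dict[str, pd.DataFrame] = {}
        dmg_by_group, dedmg_by_group, overlap_by_group = {}, {}, {}
        for group in groups:
            cols = [s for s in counts_expr.columns if sample_meta[s][0] == group]
            sub_counts = counts_expr[cols]
            expr_design = pd.DataFrame({
                "sample": cols,
                "condition": [sample_meta[s][1] for s in cols],
            })
            gene_stats = de_test(sub_counts, expr_design,
                                 tmm_factors(sub_counts), thresholds)
            gene_stats_by_group[group] = gene_stats
            universe = set(gene_stats.index)
            deg_set = set(gene_stats.index[gene_stats["deg"]])
            ann = annotate_dmrs(dmrs_by_group[group], genome.genes,
                                promoter_len=config.promoter_len)
            dmg_sets = call_dmgs(ann)
            dmg_by_group[group] = dmg_sets
            dedmg, overlap = intersect_dedmg(dmg_sets, deg_set, universe)
            dedmg_by_group[group] = dedmg
            overlap_by_group[group] = overlap
            logger.info("integrate[%s]: %d DEGs, %d DMGs, %d DEDMGs "
                        "(RF=%.2f p=%.3g)", group, len(deg_set),
                        len(dmg_sets.get("any", ())), len(dedmg),
                        overlap.representation_factor, overlap.p)
            _emit(f"gene_stats_{group}.tsv",
                  lambda p, g=group: gene_stats_by_group[g].to_csv(p, sep="\t"))
        gene_stats = gene_stats_by_group[groups[0]]
        manifest["stages"][stage] = {
            "degs": {g: int(s["deg"].sum()) for g, s in gene_stats_by_group.items()},
            "dedmgs": {g: len(v) for g, v in dedmg_by_group.items()},
        }
        results.update({"gene_stats": gene_stats_by_group,
                        "expr_truth": expr_truth,
                        "dmg": dmg_by_group, "dedmg": dedmg_by_group,
                        "overlap": overlap_by_group})

        stage = "landscape"
        chrom_lengths = {c: L for c, L in genome.chrom_lengths.items()
                         if c != scenario.chloroplast}
        dens_by_group = {
            g: dmr_density(d[d["context"] == "CHG"], chrom_lengths,
                           window=config.window)
            for g, d in dmrs_by_group.items()
        }
        peaks = call_peaks(dens_by_group, floor=config.peak_floor,
                           quantile=config.peak_quantile)
        shared = shared_peak_windows(peaks)
        dens = feature_density(genome.features, chrom_lengths, window=config.window)
        reg = methylation_regression(
            profile[profile["chrom"] != scenario.chloroplast], dens)
        prox = proximity_categories(genome.genes,
                                    genome.features_of_type("dispersed_repeat"))
        prox_expr = proximity_effect(gene_stats, prox, value="mean_norm")
        prox_lfc = proximity_effect(gene_stats, prox, value="abs_log2fc")
        lvl = per_sample_profile[(per_sample_profile["context"] == "CGN")
                                 & (per_sample_profile["chrom"] != scenario.chloroplast)]
        mat = lvl.pivot_table(index="sample", columns=["chrom", "window"],
                              values="level")
        pca = pca_windows(mat) if len(mat) >= 2 else None
        manifest["stages"][stage] = {
            "shared_peaks": [f"{c}:{w}" for c, w in shared],
            "r_squared": {k: v.r_squared for k, v in reg.items()},
        }
        logger.info("landscape: %d shared CHG peak windows", len(shared))
        _emit("peaks.tsv", lambda p: peaks.to_csv(p, sep="\t", index=False))
        _emit("regression.json", lambda p: Path(p).write_text(json.dumps(
            {k: dataclasses.asdict(v) for k, v in reg.items()}, indent=2)))
        _emit("proximity.tsv",
              lambda p: prox.to_csv(p, sep="\t"))
        if pca is not None:
            _emit("pca_scores.tsv", lambda p: pca["scores"].to_csv(p, sep="\t"))
        results.update({"peaks": peaks, "shared_peaks": shared,
                        "regression": reg, "proximity": prox,
                        "proximity_expression": prox_expr,
                        "proximity_lfc": prox_lfc, "pca": pca})
    except Exception as exc:
        manifest["failed_stage"] = stage
        _finish_manifest()
        raise PipelineError(stage, exc) from exc

    manifest["stages"]["total_outputs"] = len(manifest["outputs"])
    _finish_manifest()
    return results
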