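"""Full synthetic-to-report pipeline orchestration.

``run_pipeline`` drives the stages in order: sample QC, splice-junction
counting, differential expression with DEG set algebra, methylome
quantitation (global / features / tiles), tile and CGI differential
methylation, HyperD/HypoD classification, and expression-methylation
integration. Every numeric threshold comes from the
:class:`~gvoomics.config.AnalysisConfig`; the run log records thresholds,
seeds, excluded samples and per-stage row counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, dmr_domains, integration, methylome_quant, synthetic_data
from .config import AnalysisConfig
from .genomic_io import MethylomeSample, parse_sam, write_table
from .splice_counter import SpliceCountResult, build_intron_catalog, count_samples

__all__ = ["PipelineResult", "run_pipeline", "simulate_bundle", "SimulatedInputs"]


@dataclass
class SimulatedInputs:
    """Everything gen_* produced for one run, with truth attached."""

    annotation: synthetic_data.AnnotationBundle
    sam_by_sample: Dict[str, str]
    read_truth: Dict[str, synthetic_data.ReadSetTruth]
    methylomes: Dict[str, MethylomeSample]
    methylome_truth: synthetic_data.MethylomeTruth
    planted_degs: Dict[str, Dict[str, float]]   # genotype -> gene -> log2fc


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    included_samples: List[str]
    splice: Optional[SpliceCountResult]
    de_results: Dict[str, list]
    venn: Optional[diffexpr.VennSummary]
    global_methylation: pd.DataFrame
    feature_methylation: pd.DataFrame
    bimodality: Dict[str, methylome_quant.BimodalitySummary]
    dmr_tiles: Dict[str, dmr_domains.DMRTestResult]
    dmr_cgis: Dict[str, dmr_domains.DMRTestResult]
    dmr_common: pd.DataFrame
    dmr_context: Dict[str, Dict[str, int]]
    domain_tally: pd.DataFrame
    integration_summary: pd.DataFrame
    log: dict


DEFAULT_SIM = {
    "n_genes": 30,
    "n_reads_per_sample": 8000,
    "n_per_genotype": {"WT": 4, "Het": 4, "Null": 4},
    "coverage_mean": 10.0,
    "contamination": {"WT#4": 0.25},
    "n_planted_degs": 8,
    "deg_log2fc": 2.0,
    "n_planted_dmr_tiles": 10,
    "dmr_shift": 30.0,
}


def simulate_bundle(params: Optional[dict] = None, seed: int = 0,
                    ) -> SimulatedInputs:
    """Generate the full joint input set (annotation, reads, methylomes).

    RNA and methylome samples share ids, emulating paired profiling of
    the same oocyte pools. Planted DEGs partially overlap between the
    two mutant genotypes; planted DMR tiles shift domain methylation in
    the affected genotype.
    """
    p = {**DEFAULT_SIM, **(params or {})}
    rng = np.random.default_rng(seed)
    bundle = synthetic_data.gen_annotation(
        n_genes=p["n_genes"], share_intron_pair=True,
        seed=int(rng.integers(2 ** 31)))

    plan = synthetic_data.default_methylome_plan()
    # plant DMR shifts on 10-kb-aligned windows inside autosomal domains
    tiles = methylome_quant.build_genome_tiles(plan.chrom_lengths)
    autosomal = [t for t in tiles if t.chrom != "chrX"]
    n_dmr = p["n_planted_dmr_tiles"]
    pick = rng.choice(len(autosomal), size=2 * n_dmr, replace=False)
    oocyte_means = plan.oocyte_means()
    positions = plan.cpg_positions()
    planted = []
    for k, idx in enumerate(pick):
        genotype = "Het" if k < n_dmr else "Null"
        tile = autosomal[idx]
        pos = positions[tile.chrom]
        lo = np.searchsorted(pos, tile.start, side="left")
        hi = np.searchsorted(pos, tile.end, side="right")
        # shift toward the free pole so the planted delta is achievable
        sign = 1.0 if oocyte_means[tile.chrom][lo:hi].mean() < 0.5 else -1.0
        planted.append(synthetic_data.PlantedDMR(
            tile, sign * p["dmr_shift"], (genotype,)))
    methylomes, meth_truth = synthetic_data.gen_methylomes(
        plan=plan, n_per_genotype=p["n_per_genotype"],
        coverage_mean=p["coverage_mean"], contamination=p["contamination"],
        planted_dmrs=planted, seed=int(rng.integers(2 ** 31)))

    genes = sorted(m.gene_id for m in bundle.models if m.gene_id != "G001alt")
    n_deg = min(p["n_planted_degs"], len(genes) // 2)
    half = n_deg // 2
    het_genes = genes[:n_deg]
    null_genes = genes[half:half + n_deg]  # overlaps het_genes by half
    lfc = p["deg_log2fc"]
    planted_degs = {
        "Het": {g: (lfc if i % 2 == 0 else -lfc)
                for i, g in enumerate(het_genes)},
        "Null": {g: (lfc if i % 2 == 0 else -lfc)
                 for i, g in enumerate(null_genes)},
    }
    base_weight = {g: float(w) for g, w in zip(
        genes, np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(genes))))}

    sam_by_sample = {}
    read_truth = {}
    for sample_id, genotype in sorted(meth_truth.genotypes.items()):
        weights = dict(base_weight)
        for g, fc in planted_degs.get(genotype, {}).items():
            weights[g] = weights[g] * 2.0 ** fc
        sam, truth = synthetic_data.gen_spliced_reads(
            bundle, n_reads=p["n_reads_per_sample"], gene_weights=weights,
            sample_id=sample_id, seed=int(rng.integers(2 ** 31)))
        sam_by_sample[sample_id] = sam
        read_truth[sample_id] = truth

    return SimulatedInputs(bundle, sam_by_sample, read_truth, methylomes,
                           meth_truth, planted_degs)


def _load_manifest_inputs(manifest: dict) -> Tuple[SimulatedInputs, dict]:
    if "simulate" in manifest:
        sim = dict(manifest["simulate"])
        seed = int(sim.pop("seed", 0))
        return simulate_bundle(sim, seed=seed), {"mode": "simulate",
                                                 "seed": seed}
    raise ValueError("manifest must contain a 'simulate' block or explicit "
                     "inputs (gtf/sam/reports/regions)")


def run_pipeline(config: AnalysisConfig, manifest: dict,
                 out_dir) -> PipelineResult:
    """Execute the full analysis and write its output tables and run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": {}}
    stage = "inputs"
    try:
        sim, meta = _load_manifest_inputs(manifest)
        log["inputs"] = meta

        # ------------------------------------------------------------------
        stage = "qc"
        plan = sim.methylome_truth.plan
        x_cgis = [iv for iv, kind in plan.cgis if kind == "x_cgi"]
        qc_rows = []
        for sample_id in sorted(sim.methylomes):
            report = methylome_quant.qc_sample(
                sim.methylomes[sample_id], x_cgis,
                x_cgi_max=config.x_cgi_max,
                min_mapped_reads=config.min_mapped_reads,
                cov_min=config.cov_min)
            qc_rows.append(vars(report))
        qc = pd.DataFrame(qc_rows)
        included = sorted(qc.loc[qc["included"], "sample_id"])
        excluded = sorted(set(qc["sample_id"]) - set(included))
        write_table(qc, out / "qc_report.tsv")
        write_table(pd.DataFrame({"sample_id": included}),
                    out / "included_samples.tsv")
        log["stages"]["qc"] = {"n_samples": len(qc), "included": included,
                               "excluded": [
                                   {"sample_id": s,
                                    "reason": qc.set_index("sample_id")
                                    .loc[s, "reason"]} for s in excluded]}

        # ------------------------------------------------------------------
        stage = "splice_counting"
        catalog = build_intron_catalog(sim.annotation.models)
        streams = {s: parse_sam(io.StringIO(sim.sam_by_sample[s]))
                   for s in included}
        splice = count_samples(streams, catalog)
        splice.counts.reset_index().to_csv(out / "splice_counts.tsv",
                                           sep="\t", index=False)
        write_table(splice.stats_frame(), out / "splice_stats.tsv")
        log["stages"]["splice_counting"] = {
            "n_genes": int(splice.counts.shape[0]),
            "n_samples": int(splice.counts.shape[1]),
            "total_records": int(sum(s.total_records for s in splice.stats))}

        # ------------------------------------------------------------------
        stage = "differential_expression"
        genotypes = pd.Series({s: sim.methylome_truth.genotypes[s]
                               for s in included}, name="genotype")
        de_results = {}
        for test_level in ("Het", "Null"):
            results, dropped = diffexpr.wald_test(
                splice.counts, genotypes, ref_level="WT",
                test_level=test_level, log2fc_min=config.log2fc_min,
                padj_max=config.padj_max, pseudo_count=config.pseudo_count)
            de_results[test_level] = results
            write_table(diffexpr.results_frame(results),
                        out / f"de_{test_level.lower()}_vs_wt.tsv")
            log["stages"][f"de_{test_level}"] = {
                "n_tested": len(results), "n_dropped_allzero": len(dropped),
                "n_degs": sum(r.is_deg for r in results)}
        venn, _deg_lists = diffexpr.deg_sets(de_results["Het"],
                                             de_results["Null"])
        write_table([vars(venn)], out / "deg_venn.tsv")

        # ------------------------------------------------------------------
        stage = "methylome_quantitation"
        included_meth = [sim.methylomes[s] for s in included]
        pools = methylome_quant.pool_by_genotype(included_meth)
        glob_rows = []
        for s in included_meth:
            for context in ("CpG", "CHG", "CHH"):
                try:
                    value = methylome_quant.global_methylation(s, context)
                except ValueError:
                    value = None
                glob_rows.append({"sample_id": s.sample_id,
                                  "genotype": s.genotype, "context": context,
                                  "methylation_pct": value})
        global_meth = pd.DataFrame(glob_rows)
        write_table(global_meth, out / "global_methylation.tsv")

        feature_sets = {
            "maternal_gDMR": [iv for iv, k in plan.gdmrs if k == "maternal_gdmr"],
            "paternal_gDMR": [iv for iv, k in plan.gdmrs if k == "paternal_gdmr"],
            "CGI": [iv for iv, k in plan.cgis if k == "oocyte_cgi"],
            "X_CGI": x_cgis,
        }
        feat_rows = []
        for genotype, pool in sorted(pools.items()):
            for set_name, ivs in feature_sets.items():
                for fm in methylome_quant.weighted_methylation(
                        pool, ivs, cov_min=config.cov_min):
                    feat_rows.append({
                        "feature_set": set_name, "feature_id": fm.feature_id,
                        "chrom": fm.interval.chrom, "start": fm.interval.start,
                        "end": fm.interval.end, "genotype": genotype,
                        "methylation_pct": fm.methylation,
                        "n_cpgs_used": fm.n_cpgs_used})
        feature_meth = pd.DataFrame(feat_rows)
        write_table(feature_meth, out / "feature_methylation.tsv")

        cpg_tiles = methylome_quant.build_cpg_tiles(
            plan.cpg_positions(), n_per_tile=config.tile_cpg_n)
        bimodality = {}
        bim_rows = []
        for genotype, pool in sorted(pools.items()):
            values = [fm.methylation for fm in
                      methylome_quant.weighted_methylation(
                          pool, cpg_tiles, cov_min=config.cov_min)]
            summary = methylome_quant.bimodality_summary(
                values, low=config.bimodal_low, high=config.bimodal_high,
                flag_min=config.bimodal_flag_min)
            bimodality[genotype] = summary
            bim_rows.append({"genotype": genotype, **vars(summary)})
        write_table(pd.DataFrame(bim_rows), out / "tile_bimodality.tsv")
        log["stages"]["methylome_quantitation"] = {
            "n_cpg_tiles": len(cpg_tiles),
            "n_features": int(len(feature_meth))}

        # ------------------------------------------------------------------
        stage = "differential_methylation"
        genome_tiles = methylome_quant.build_genome_tiles(
            plan.chrom_lengths, width=config.tile_width)
        inform = methylome_quant.informative_tiles(
            included_meth, genome_tiles, cov_min=config.cov_min,
            min_cpgs=config.min_cpgs)
        dmr_tiles = {}
        dmr_cgis = {}
        all_cgis = [iv for iv, k in plan.cgis]
        for test_level in ("Het", "Null"):
            res = dmr_domains.call_dmrs(
                inform, pools["WT"], pools[test_level],
                q_max=config.dmr_q_max, delta_min=config.dmr_delta_min,
                cov_min=config.cov_min)
            dmr_tiles[test_level] = res
            write_table(res.table, out / f"dmr_10kb_{test_level.lower()}.tsv")
            res_cgi = dmr_domains.call_dmrs(
                all_cgis, pools["WT"], pools[test_level],
                q_max=config.cgi_q_max, delta_min=config.cgi_delta_min,
                cov_min=config.cov_min)
            dmr_cgis[test_level] = res_cgi
            write_table(res_cgi.table,
                        out / f"dmr_cgi_{test_level.lower()}.tsv")
            log["stages"][f"dmr_{test_level}"] = {
                "n_informative_tiles": len(inform),
                "n_tile_dmrs": len(res.records),
                "n_cgi_dmrs": len(res_cgi.records),
                "multiple_testing": res.note}
        common = dmr_domains.intersect_dmrs(dmr_tiles["Het"].records,
                                            dmr_tiles["Null"].records)
        write_table(common, out / "dmr_common.tsv")
        dmr_context = {}
        ctx_rows = []
        for test_level, res in dmr_tiles.items():
            counts = dmr_domains.annotate_context(
                res.records, sim.annotation.models,
                promoter_window=config.promoter_window)
            dmr_context[test_level] = counts
            ctx_rows.append({"comparison": f"{test_level}_vs_WT", **counts})
        write_table(pd.DataFrame(ctx_rows), out / "dmr_context.tsv")

        # ------------------------------------------------------------------
        stage = "domain_classification"
        domains = [iv for iv, _cls in plan.domains]
        classes = [cls for _iv, cls in plan.domains]
        dom_records, dom_tally = dmr_domains.classify_domains(
            domains, classes, pools, cov_min=config.cov_min,
            hyperd_min=config.hyperd_min, hypod_max=config.hypod_max)
        dom_rows = []
        for r in dom_records:
            for genotype in sorted(pools):
                dom_rows.append({
                    "domain_id": r.domain_id, "class": r.domain_class,
                    "chrom": r.interval.chrom, "start": r.interval.start,
                    "end": r.interval.end, "genotype": genotype,
                    "methylation_pct": r.methylation[genotype],
                    "status": r.status[genotype]})
        write_table(pd.DataFrame(dom_rows), out / "domain_classification.tsv")
        write_table(dom_tally, out / "domain_tally.tsv")

        # ------------------------------------------------------------------
        stage = "integration"
        gene_models = [m for m in sim.annotation.models
                       if m.gene_id != "G001alt"]
        int_rows = []
        for test_level in ("Het", "Null"):
            deltas = integration.gene_body_deltas(
                pools["WT"], pools[test_level], gene_models,
                cov_min=config.cov_min)
            records = integration.build_records(de_results[test_level], deltas)
            usable = [r for r in records if r.meth_delta is not None]
            if len(usable) >= 3:
                try:
                    rho, pval = integration.spearman(
                        [r.log2fc for r in usable],
                        [r.meth_delta for r in usable])
                except ValueError:
                    rho, pval = None, None
            else:
                rho, pval = None, None
            candidates = integration.quadrant_candidates(
                records, fraction=config.top_fraction)
            count, pct = integration.delta_threshold_summary(
                records, delta_min=config.integration_delta_min)
            int_rows.append({
                "comparison": f"{test_level}_vs_WT",
                "n_genes_with_meth": len(usable),
                "spearman_rho": rho, "spearman_p": pval,
                "n_quadrant_candidates": len(candidates),
                "quadrant_candidates": ",".join(candidates),
                "n_degs_large_delta": count, "pct_degs_large_delta": pct})
            write_table(pd.DataFrame([vars(r) for r in records]),
                        out / f"integration_{test_level.lower()}_vs_wt.tsv")
        integration_summary = pd.DataFrame(int_rows)
        write_table(integration_summary, out / "integration_summary.tsv")

    except Exception as exc:
        log["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=False)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)

    return PipelineResult(
        qc=qc, included_samples=included, splice=splice,
        de_results=de_results, venn=venn, global_methylation=global_meth,
        feature_methylation=feature_meth, bimodality=bimodality,
        dmr_tiles=dmr_tiles, dmr_cgis=dmr_cgis, dmr_common=common,
        dmr_context=dmr_context, domain_tally=dom_tally,
        integration_summary=integration_summary, log=log)
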