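"""End-to-end orchestration: files in, report bundle out.

Stages run in order: dmr -> annotate -> expression -> chromatin -> triple
-> motif. Missing optional inputs (ATAC peaks, motifs) skip the dependent
stages with a notice in the summary. Every run writes its resolved
configuration and a JSON summary of all headline statistics next to its
output tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import annotation as ann
from . import chromatin, dmr, expression as expr_mod, motifs, readwrite, triple
from .config import PipelineConfig

log = logging.getLogger(__name__)

STAGES = ("dmr", "annotate", "expression", "chromatin", "triple", "motif")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 stages: Optional[Sequence[str]] = None) -> dict:
    """Run the integrative analysis and write outputs under ``outdir``.

    Returns the summary dict (also written as summary.json). ``stages``
    restricts the run to a prefix of the stage order (later stages are
    skipped).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    wanted = set(stages) if stages is not None else set(STAGES)
    summary: dict = {"seed": config.seed, "stages_run": [], "notices": []}

    records = gene_models = genome = None
    dmrs = links = expr = peaks = overlaps = None

    # ---- dmr ------------------------------------------------------------
    if "dmr" in wanted:
        try:
            records = readwrite.read_methylation_counts(
                config.methylation_group1, config.methylation_group2)
            site_stats = dmr.site_wald_test(records, config.dmr)
            dmrs = dmr.call_dmrs(site_stats, config.dmr)
            readwrite.write_dmr_table(dmrs, outdir / "dmrs.tsv")
            readwrite.write_dmr_bed(dmrs, outdir / "dmrs.bed")
            for col, name in (("mu1", "smoothed_mu_epithelial.bedgraph"),
                              ("mu2", "smoothed_mu_fiber.bedgraph")):
                readwrite.write_bedgraph(site_stats, col, outdir / name)
            summary["dmr"] = {
                "n_sites_tested": int(len(site_stats)),
                "n_sites_significant": int(site_stats.is_significant.sum())
                if len(site_stats) else 0,
                "n_dmrs": int(len(dmrs)),
                "n_hyper": int((dmrs.direction == "hyper").sum()),
                "n_hypo": int((dmrs.direction == "hypo").sum()),
            }
            summary["stages_run"].append("dmr")
        except Exception as exc:
            raise StageError("dmr", exc) from exc

    # ---- annotate -------------------------------------------------------
    index = None
    if "annotate" in wanted and dmrs is not None:
        try:
            gene_models = readwrite.read_gene_models(config.genes,
                                                     config.gene_format)
            genome = readwrite.read_genome_fasta(config.genome)
            sizes = {c: len(s) for c, s in genome.items()}
            cgis = readwrite.read_bed_intervals(config.cgi) if config.cgi else {}
            reps = readwrite.read_bed_intervals(config.repeats) \
                if config.repeats else {}
            index = ann.FeatureIndex(gene_models, cgis, reps, sizes,
                                     config.annotation)
            dmrs = ann.annotate_dmrs(dmrs, index)
            links = ann.map_dmr_to_genes(dmrs, gene_models, config.annotation,
                                         sizes)
            readwrite.write_dmr_table(dmrs, outdir / "dmrs_annotated.tsv")
            links.to_csv(outdir / "dmr_gene_links.tsv", sep="\t", index=False)
            summary["annotate"] = {
                "category_counts": {k: int(v) for k, v in
                                    dmrs.category.value_counts().items()},
                "n_links": int(len(links)),
            }
            features = {cat: index.category_intervals(cat)
                        for cat in ("promoter", "cgi", "cgi_shore", "repeat")}
            summary["methylome"] = dmr.methylome_summary(records, features)
            if len(dmrs):
                null = ann.random_null_test(dmrs, index, n_draws=100,
                                            seed=config.seed)
                summary["annotate"]["random_null"] = {
                    "chi2": null["chi2"], "p_value": null["p_value"],
                    "percent_difference": null["percent_difference"],
                }
                try:
                    summary["annotate"]["hyper_vs_hypo"] = \
                        ann.compare_hyper_hypo_distributions(dmrs)
                except ValueError as exc:
                    summary["notices"].append(f"hyper-vs-hypo skipped: {exc}")
            summary["stages_run"].append("annotate")
        except Exception as exc:
            raise StageError("annotate", exc) from exc

    # ---- expression -----------------------------------------------------
    if "expression" in wanted and links is not None and config.expression:
        try:
            expr = readwrite.read_expression_table(config.expression)
            expr = expr_mod.classify_degs(expr, config.thresholds.deg_log2fc,
                                          config.thresholds.deg_q)
            summary["expression"] = {"deg_counts": {
                k: int(v) for k, v in expr.deg_class.value_counts().items()}}
            for scope in ("promoter_and_genebody", "promoter_only"):
                summ = expr_mod.average_gene_methylation(dmrs, links, scope)
                summ.to_csv(outdir / f"gene_methylation_{scope}.tsv",
                            sep="\t", index=False)
                block: dict = {"n_genes_with_dmrs": int(len(summ))}
                try:
                    block["correlation"] = \
                        expr_mod.correlate_methylation_expression(summ, expr)
                except ValueError as exc:
                    block["correlation"] = None
                    summary["notices"].append(f"{scope} correlation: {exc}")
                block["association"] = \
                    expr_mod.methylation_expression_association(summ, expr)
                summary["expression"][scope] = block
                # quadrant gene lists (for external enrichment tools)
                joined = summ.merge(expr[expr.deg_class != "not_de"],
                                    on="gene_id")
                for md in ("increase", "decrease"):
                    for dc in ("epithelial_preferred", "fiber_preferred"):
                        sel = joined[(joined.meth_direction == md)
                                     & (joined.deg_class == dc)]
                        readwrite.write_gene_list(
                            sorted(sel.gene_id),
                            outdir / f"genes_{scope}_{md}_{dc}.txt")
            summary["stages_run"].append("expression")
        except Exception as exc:
            raise StageError("expression", exc) from exc
    elif "expression" in wanted and not config.expression:
        summary["notices"].append("no expression table; expression stage skipped")

    # ---- chromatin ------------------------------------------------------
    if "chromatin" in wanted and dmrs is not None and config.atac:
        try:
            peaks = readwrite.read_atac_peaks(config.atac)
            peaks = chromatin.classify_peaks(peaks, config.thresholds.atac_q)
            overlaps = chromatin.overlap_dmrs_with_peaks(dmrs, peaks)
            overlaps.to_csv(outdir / "dmr_peak_overlaps.tsv", sep="\t",
                            index=False)
            stats = chromatin.methylation_accessibility_stats(
                overlaps, config.thresholds.atac_q)
            stats["n_dmrs_without_overlap"] = int(len(dmrs) - len(overlaps))
            summary["chromatin"] = stats
            summary["stages_run"].append("chromatin")
        except Exception as exc:
            raise StageError("chromatin", exc) from exc
    elif "chromatin" in wanted and not config.atac:
        summary["notices"].append(
            "no ATAC peak table; chromatin and triple stages skipped")

    # ---- triple ---------------------------------------------------------
    if "triple" in wanted and overlaps is not None and expr is not None:
        try:
            summary["triple"] = {}
            for scope in ("promoter_and_genebody", "promoter_only"):
                sites = triple.classify_triple_sites(overlaps, links, expr,
                                                     scope)
                sites.to_csv(outdir / f"triple_sites_{scope}.tsv", sep="\t",
                             index=False)
                rollup = triple.per_gene_rollup(sites)
                rollup.to_csv(outdir / f"triple_genes_{scope}.tsv", sep="\t",
                              index=False)
                if sites.empty:
                    summary["triple"][scope] = {"n_sites": 0}
                    continue
                assoc = triple.triple_association(sites)
                assoc["n_genes_concordant"] = int(
                    rollup.has_concordant_site.sum())
                summary["triple"][scope] = assoc
            summary["stages_run"].append("triple")
        except Exception as exc:
            raise StageError("triple", exc) from exc

    # ---- motif ----------------------------------------------------------
    if ("motif" in wanted and links is not None and expr is not None
            and genome is not None and config.motifs):
        try:
            motif_models = readwrite.read_jaspar_pfms(config.motifs)
            seq_sets, gene_maps = motifs.extract_region_sequences(
                dmrs, links, expr, genome)
            summary["motif"] = {}
            for key in ("hypo_fiber", "hyper_epithelial"):
                seqs = seq_sets[key]
                readwrite.write_fasta_sequences(seqs,
                                                outdir / f"regions_{key}.fa")
                if not seqs:
                    summary["motif"][key] = {"n_sequences": 0}
                    continue
                control = motifs.shuffle_sequences(seqs, seed=config.seed)
                enr = motifs.motif_enrichment(seqs, control, motif_models,
                                              config.thresholds.motif_p)
                enr = motifs.annotate_tf_expression(
                    enr, expr, config.thresholds.tf_fpkm)
                enr.to_csv(outdir / f"motif_enrichment_{key}.tsv", sep="\t",
                           index=False)
                top = enr.iloc[0] if len(enr) else None
                summary["motif"][key] = {
                    "n_sequences": len(seqs),
                    "n_motifs_tested": int(len(motif_models)),
                    "n_motifs_reported": int(len(enr)),
                    "top_motif": None if top is None else {
                        "motif_id": top.motif_id,
                        "adjusted_p": float(top.adjusted_p)},
                }
            summary["stages_run"].append("motif")
        except Exception as exc:
            raise StageError("motif", exc) from exc
    elif "motif" in wanted and not config.motifs:
        summary["notices"].append("no motif database; motif stage skipped")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return summary


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
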