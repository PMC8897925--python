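"""Built-in validation experiments.

The published genome-scale results of the study this package models
(headline correlations and genome-wide counts) require the deposited
sequencing data; these experiments are the package's property-based
substitutes, run entirely on the synthetic generator:

* the published 2x2 quadrant counts re-tested with the package's
  chi-square (the printed counts are inputs);
* parameter recovery of injected methylation->expression and
  methylation->accessibility couplings through the full pipeline;
* power and false-discovery of the DMR caller on planted regions, and its
  behaviour on a null methylome;
* exact agreement of segmentation, interval annotation and overlap
  matching with naive reference implementations on randomised instances;
* exact-enumeration checks of the PWM p-value dynamic programme;
* calibration of the random-placement distribution null;
* recovery of a motif planted into half of the primary sequences.

Every experiment is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import annotation as A
from . import chromatin as C
from . import dmr as D
from . import expression as E
from . import motifs as M
from .config import AnnotationParams, DmrParams, SimConfig
from .models import MotifModel
from .stats import chi2_2x2
from .synthetic import (calibrate_atac_noise, calibrate_expression_noise,
                        make_annotation, simulate_atac, simulate_expression,
                        simulate_methylomes, true_gene_methylation)

#: published quadrant counts (genes by methylation direction x DEG class)
PUBLISHED_QUADRANTS = {
    "promoter_and_genebody": [[814, 249], [63, 159]],
    "promoter_only": [[208, 58], [15, 30]],
}


def printed_quadrant_chisquare() -> dict:
    """Chi-square tests on the published quadrant tables."""
    out = {}
    for scope, table in PUBLISHED_QUADRANTS.items():
        chi2, p = chi2_2x2(table)
        out[scope] = {"chi2": chi2, "p_value": p,
                      "n": int(sum(map(sum, table)))}
    return out


# ---------------------------------------------------------------------------
# coupling recovery


def coupling_recovery_config(seed: int) -> SimConfig:
    """Study conditions for coupling recovery: ~1000 differentially
    expressed genes carrying at least one called DMR, couplings targeting
    r = -0.4 (expression) and r = -0.86 (accessibility)."""
    return SimConfig(
        seed=seed, genome_length=18_000_000, cpg_rate=0.05, n_genes=1900,
        n_planted_dmrs=1800, dmr_span_range=(200, 300), effect_size=0.4,
        dispersion_phi=0.1, coverage_mean=30, dmr_in_gene_fraction=0.95,
        expr_coupling_slope=-2.5, atac_coupling_slope=-2.5,
        atac_noise_sd=calibrate_atac_noise(-2.5, 0.4, -0.86),
        dmr_min_cpgs=8,
    )


def coupling_recovery(seed: int) -> dict:
    """Full-pipeline recovery of the injected couplings."""
    cfg = coupling_recovery_config(seed)
    ann = make_annotation(cfg)
    records, truth = simulate_methylomes(cfg, ann)
    gene_truth = true_gene_methylation(ann, truth)
    with_dmr = gene_truth[gene_truth.n_truth_dmrs > 0]
    sd = calibrate_expression_noise(with_dmr.true_avg_dm.to_numpy(),
                                    cfg.expr_coupling_slope, -0.4)
    cfg = replace(cfg, expr_noise_sd=sd)
    expr_tab, _ = simulate_expression(cfg, ann, truth)
    peaks_tab = simulate_atac(cfg, ann, truth)

    params = DmrParams()
    dmrs = D.call_dmrs(D.site_wald_test(records, params), params)
    links = A.map_dmr_to_genes(dmrs, ann.genes, AnnotationParams(),
                               ann.chrom_sizes)
    expr = E.classify_degs(expr_tab)
    summ = E.average_gene_methylation(dmrs, links)
    corr = E.correlate_methylation_expression(summ, expr)
    assoc = E.methylation_expression_association(summ, expr)
    overlaps = C.overlap_dmrs_with_peaks(dmrs, C.classify_peaks(peaks_tab))
    atac = C.methylation_accessibility_stats(overlaps)
    return {
        "r_expression": corr["r"], "n_expression": corr["n"],
        "expr_target": -0.4,
        "r_atac": atac["correlation_all"]["r"],
        "n_atac": atac["correlation_all"]["n"],
        "atac_target": -0.86,
        "quadrant_chi2": assoc["chi2"], "quadrant_p": assoc["p_value"],
        "n_dmrs_called": int(len(dmrs)),
    }


# ---------------------------------------------------------------------------
# DMR power and null behaviour


def match_called_to_planted(dmrs: pd.DataFrame, truth: pd.DataFrame
                            ) -> tuple[float, float]:
    """(sensitivity at >= 50 % reciprocal overlap, false-discovery fraction)."""
    tp = 0
    for t in truth.itertuples():
        sub = dmrs[(dmrs.chrom == t.chrom) & (dmrs.start < t.end)
                   & (dmrs.end > t.start)]
        for d in sub.itertuples():
            ov = min(d.end, t.end) - max(d.start, t.start)
            if ov >= 0.5 * max(d.end - d.start, t.end - t.start):
                tp += 1
                break
    fp = 0
    for d in dmrs.itertuples():
        sub = truth[(truth.chrom == d.chrom) & (truth.start < d.end)
                    & (truth.end > d.start)]
        if sub.empty:
            fp += 1
    sens = tp / len(truth) if len(truth) else float("nan")
    fdr = fp / len(dmrs) if len(dmrs) else 0.0
    return sens, fdr


def dmr_power_study(seed: int) -> dict:
    """Planted-region recovery: delta 0.4, 200 bp, 30x, 3+3 replicates,
    phi 0.1, regions planted in CpG-dense neighbourhoods."""
    cfg = SimConfig(seed=seed, genome_length=4_000_000, cpg_rate=0.06,
                    n_genes=200, n_planted_dmrs=150, dmr_span_range=(200, 200),
                    effect_size=0.4, dispersion_phi=0.1, coverage_mean=30,
                    dmr_min_cpgs=8)
    ann = make_annotation(cfg)
    records, truth = simulate_methylomes(cfg, ann)
    params = DmrParams()
    dmrs = D.call_dmrs(D.site_wald_test(records, params), params)
    sens, fdr = match_called_to_planted(dmrs, truth)
    return {"sensitivity": sens, "false_discovery_fraction": fdr,
            "n_planted": int(len(truth)), "n_called": int(len(dmrs))}


def dmr_null_study(seed: int) -> dict:
    """Null methylome (no planted effects): DMR calls per 1e5 CpGs."""
    cfg = SimConfig(seed=seed, genome_length=5_000_000, cpg_rate=0.04,
                    n_genes=50, n_planted_dmrs=0, effect_size=0.0,
                    dispersion_phi=0.1, coverage_mean=30, dmr_min_cpgs=4)
    ann = make_annotation(cfg)
    records, _ = simulate_methylomes(cfg, ann)
    params = DmrParams()
    stats = D.site_wald_test(records, params)
    dmrs = D.call_dmrs(stats, params)
    n_cpg = int(len(stats))
    return {"n_cpgs": n_cpg, "n_calls": int(len(dmrs)),
            "calls_per_100k_cpgs": 1e5 * len(dmrs) / n_cpg}


# ---------------------------------------------------------------------------
# reference-implementation agreement


def _segment_reference(stats: pd.DataFrame, params: DmrParams) -> list[tuple]:
    """Naive loop-based re-statement of the segmentation rule."""
    sub = stats.sort_values("pos")
    pos = sub.pos.tolist()
    sig = sub.is_significant.tolist()
    mu1, mu2 = sub.mu1.tolist(), sub.mu2.tolist()
    sig_idx = [i for i, s in enumerate(sig) if s]
    if not sig_idx:
        return []
    chains: list[list[int]] = [[sig_idx[0]]]
    for i in sig_idx[1:]:
        if pos[i] - pos[chains[-1][-1]] - 1 < params.dis_merge:
            chains[-1].append(i)
        else:
            chains.append([i])
    out = []
    for chain in chains:
        first, last = pos[chain[0]], pos[chain[-1]]
        members = [i for i in range(len(pos)) if first <= pos[i] <= last]
        if last - first + 1 < params.minlen or len(members) < params.min_cg:
            continue
        frac = sum(sig[i] for i in members) / len(members)
        if frac < params.pct_sig:
            continue
        diff = sum(mu2[i] - mu1[i] for i in members) / len(members)
        out.append((first, last + 1, len(members), round(frac, 9),
                    round(diff, 9)))
    return out


def segmentation_oracle_agreement(seed: int, n_instances: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, 31))
        pos = np.sort(rng.choice(600, size=n, replace=False))
        sig = rng.random(n) < 0.5
        stats = pd.DataFrame({
            "chrom": "chr1", "pos": pos,
            "mu1": rng.uniform(0, 1, n), "mu2": rng.uniform(0, 1, n),
            "is_significant": sig,
        })
        params = DmrParams(minlen=int(rng.choice([20, 50])),
                           min_cg=int(rng.choice([2, 3])),
                           dis_merge=int(rng.choice([50, 100])))
        got = [(r.start, r.end, r.n_cg, round(r.frac_sig, 9),
                round(r.diff_methyl, 9))
               for r in D.call_dmrs(stats, params).itertuples()]
        agree += got == _segment_reference(stats, params)
    return {"n_instances": n_instances, "n_agree": agree,
            "agreement": agree / n_instances}


def annotation_oracle_agreement(seed: int, n_intervals: int = 1000) -> dict:
    cfg = SimConfig(seed=seed, genome_length=1_500_000, cpg_rate=0.02,
                    n_genes=120, n_planted_dmrs=0, coverage_mean=5,
                    n_replicates_per_group=1)
    ann = make_annotation(cfg)
    params = AnnotationParams()
    index = A.FeatureIndex(ann.genes, ann.cgis, ann.repeats, ann.chrom_sizes,
                           params)
    # naive per-interval scan over every raw feature interval
    feats: list[tuple[str, int, int]] = []
    up = params.promoter_upstream
    for g in ann.genes:
        ps, pe = g.promoter(up, ann.chrom_sizes[g.chrom])
        feats.append(("promoter", ps, pe))
        fe = g.first_exon
        feats.append(("first_exon", fe[0], fe[1]))
        for s, e in g.other_exons:
            feats.append(("other_exon", s, e))
        fi = g.first_intron
        if fi:
            feats.append(("first_intron", fi[0], fi[1]))
        for s, e in g.other_introns:
            feats.append(("other_intron", s, e))
        for s, e in g.utr5:
            feats.append(("utr5", s, e))
        for s, e in g.utr3:
            feats.append(("utr3", s, e))
    for s, e in ann.cgis["chr1"]:
        feats.append(("cgi", s, e))
        feats.append(("cgi_shore", max(0, s - params.cgi_shore), s))
        feats.append(("cgi_shore", e,
                      min(e + params.cgi_shore, ann.chrom_sizes["chr1"])))
    for s, e in ann.repeats["chr1"]:
        feats.append(("repeat", s, e))

    rng = np.random.default_rng(seed + 1)
    size = ann.chrom_sizes["chr1"]
    starts = rng.integers(0, size - 500, n_intervals)
    lens = rng.integers(1, 500, n_intervals)
    got = index.query_many("chr1", starts, starts + lens)
    prio = list(params.category_priority)
    agree = 0
    for s, L, cat in zip(starts, lens, got):
        hit = {c for c, fs, fe in feats if fs < s + L and fe > s}
        expected = next((c for c in prio if c in hit), "intergenic")
        agree += cat == expected
    return {"n_instances": n_intervals, "n_agree": int(agree),
            "agreement": agree / n_intervals}


def overlap_oracle_agreement(seed: int, n: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    d_start = rng.integers(0, 100_000, n)
    dmrs = pd.DataFrame({
        "chrom": "chr1", "start": d_start,
        "end": d_start + rng.integers(50, 400, n),
        "diff_methyl": rng.uniform(-0.5, 0.5, n),
    })
    dmrs["direction"] = np.where(dmrs.diff_methyl > 0, "hyper", "hypo")
    p_start = rng.integers(0, 100_000, n)
    peaks = C.classify_peaks(pd.DataFrame({
        "chrom": "chr1", "start": p_start,
        "end": p_start + rng.integers(100, 800, n),
        "name": [f"p{i}" for i in range(n)],
        "log2fc": rng.normal(0, 1, n),
        "qvalue": rng.choice([0.01, 0.2], n),  # coarse grid forces ties
    }))
    got = C.overlap_dmrs_with_peaks(dmrs, peaks)
    got_map = {r.dmr_id: (r.peak_id, r.overlap_bp) for r in got.itertuples()}
    expected = {}
    for i, d in dmrs.iterrows():
        best = None
        for j, p in peaks.iterrows():
            ov = min(d.end, p.end) - max(d.start, p.start)
            if ov <= 0:
                continue
            key = (-ov, p.qvalue, p.start, j)
            if best is None or key < best[0]:
                best = (key, j, ov)
        if best is not None:
            expected[i] = (best[1], best[2])
    agree = int(got_map == expected)
    return {"n_instances": n, "agreement": float(agree),
            "n_matched": len(got_map)}


# ---------------------------------------------------------------------------
# PWM enumeration


def pwm_enumeration_check(seed: int, max_width: int = 8) -> dict:
    """Max |DP tail - enumeration tail| over random matrices, widths
    1..max_width, evaluated on the discretised score grid (exact match
    expected); also verifies the float-score sandwich within one bin per
    position."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for width in range(1, max_width + 1):
        lo = rng.normal(0, 1.5, size=(4, width))
        bg = rng.dirichlet(np.ones(4) * 5)
        tab = M.pwm_score_pvalue_table(lo, bg)
        word_scores = np.zeros(1, dtype=np.int64)
        word_probs = np.ones(1)
        for j in range(width):
            word_scores = (word_scores[:, None]
                           + tab.qmatrix[:, j][None, :]).ravel()
            word_probs = (word_probs[:, None] * bg[None, :]).ravel()
        order = np.argsort(word_scores)[::-1]
        sorted_scores = word_scores[order]
        tails = np.cumsum(word_probs[order])
        # evaluate at every distinct achievable score
        distinct, idx = np.unique(sorted_scores[::-1], return_index=True)
        for s in distinct:
            enum_tail = tails[np.searchsorted(-sorted_scores, -s,
                                              side="right") - 1]
            dp = float(tab.pvalue_int(np.array([int(s)]))[0])
            worst = max(worst, abs(dp - float(enum_tail)))
            n_checked += 1
    return {"max_abs_error": worst, "n_scores_checked": n_checked,
            "max_width": max_width}


# ---------------------------------------------------------------------------
# random-placement null calibration


def null_calibration(seed: int, n_reps: int = 200, n_obs: int = 150,
                     n_draws: int = 200) -> dict:
    """Self-null test: observed sets drawn by the null generator itself;
    empirical chi-square rejection rate at alpha = 0.05."""
    cfg = SimConfig(seed=seed, genome_length=2_000_000, n_genes=150,
                    n_planted_dmrs=0, effect_size=0.0, coverage_mean=5,
                    n_replicates_per_group=1)
    ann = make_annotation(cfg)
    index = A.FeatureIndex(ann.genes, ann.cgis, ann.repeats, ann.chrom_sizes)
    rng = np.random.default_rng(seed + 10)
    lengths = rng.integers(100, 400, size=n_obs)
    rejections = 0
    for _ in range(n_reps):
        frames = []
        for chrom, s, e in A.draw_random_intervals(lengths, index.chrom_sizes,
                                                   n_obs, rng):
            cats = index.query_many(chrom, s, e)
            frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e,
                                        "category": cats}))
        obs = pd.concat(frames, ignore_index=True)
        res = A.random_null_test(obs, index, n_draws=n_draws, rng=rng)
        rejections += res["p_value"] < 0.05
    return {"n_reps": n_reps, "rejection_rate": rejections / n_reps}


# ---------------------------------------------------------------------------
# planted motif


def planted_motif_study(seed: int, n_seqs: int = 50, seq_len: int = 200
                        ) -> dict:
    """A consensus word inserted into half the primary sequences must rank
    first among distractor motifs after BH adjustment."""
    rng = np.random.default_rng(seed)
    consensus = "TGACGTCA"
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 20
    planted = MotifModel("MA9999.1", "PLANTED", counts + 0.5)
    distractors = [
        MotifModel(f"MA{i:04d}.1", f"TF{i}",
                   rng.integers(0, 15, size=(4, 8)).astype(float) + 1)
        for i in range(7)
    ]
    primary = []
    for i in range(n_seqs):
        s = "".join(rng.choice(list("ACGT"), seq_len))
        if i < n_seqs // 2:
            off = int(rng.integers(0, seq_len - len(consensus)))
            s = s[:off] + consensus + s[off + len(consensus):]
        primary.append((f"seq{i}", s))
    control = M.shuffle_sequences(primary, seed=seed)
    enr = M.motif_enrichment(primary, control, [planted] + distractors)
    rank = int(enr.index[enr.motif_id == "MA9999.1"][0]) + 1
    adj = float(enr.loc[enr.motif_id == "MA9999.1", "adjusted_p"].iloc[0])
    return {"planted_rank": rank, "planted_adjusted_p": adj,
            "n_motifs": len(enr)}


# ---------------------------------------------------------------------------
# determinism


def determinism_check(seed: int, workdir) -> dict:
    """Two full pipeline runs with the same seed must write byte-identical
    summary JSON."""
    from pathlib import Path

    from .config import PipelineConfig
    from .pipeline import run_pipeline
    from .readwrite import write_bundle, write_jaspar_pfms
    from .synthetic import simulate_bundle

    workdir = Path(workdir)
    cfg = SimConfig(seed=seed, genome_length=1_200_000, cpg_rate=0.05,
                    n_genes=100, n_planted_dmrs=60, dmr_span_range=(200, 300),
                    effect_size=0.4, dispersion_phi=0.1, coverage_mean=30,
                    dmr_min_cpgs=8)
    bundle = simulate_bundle(cfg)
    paths = write_bundle(bundle, workdir / "data")
    rng = np.random.default_rng(seed)
    motif_models = [
        MotifModel(f"MA{i:04d}.1", f"TF{i}",
                   rng.integers(0, 15, size=(4, 8)).astype(float) + 1)
        for i in range(4)
    ]
    write_jaspar_pfms(motif_models, workdir / "data" / "motifs.jaspar")
    config = PipelineConfig(
        genome=paths["genome"], genes=paths["genes"],
        methylation_group1=paths["methylation"]["group1"],
        methylation_group2=paths["methylation"]["group2"],
        cgi=paths["cgi"], repeats=paths["repeats"],
        expression=paths["expression"], atac=paths["atac"],
        motifs=str(workdir / "data" / "motifs.jaspar"), seed=seed)
    run_pipeline(config, workdir / "run1")
    run_pipeline(config, workdir / "run2")
    b1 = (workdir / "run1" / "summary.json").read_bytes()
    b2 = (workdir / "run2" / "summary.json").read_bytes()
    return {"identical": b1 == b2, "n_bytes": len(b1)}
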