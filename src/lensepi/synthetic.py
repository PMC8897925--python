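"""Synthetic multi-omic data generator.

Emulates the data structure of a two-state lens differentiation study at
toy scale: a Mb-scale genome with CpG-island-like regions, non-overlapping
gene models on both strands, replicate CpG methylomes drawn from a
beta-binomial model with planted differentially methylated regions, and
expression/ATAC tables whose fold changes are coupled to the planted
methylation effects through tunable linear couplings.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import GROUP1, GROUP2, AnnotationParams, SimConfig
from .models import GeneModel, Interval

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class SyntheticAnnotation:
    """Genome sequences plus the gene/CGI/repeat annotation built on them."""

    genome: dict[str, str]
    genes: list[GeneModel]
    cgis: dict[str, list[Interval]]
    repeats: dict[str, list[Interval]]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def cpg_positions(self, chrom: str) -> np.ndarray:
        seq = np.frombuffer(self.genome[chrom].encode(), dtype=np.uint8)
        is_c = seq[:-1] == ord("C")
        is_g = seq[1:] == ord("G")
        return np.nonzero(is_c & is_g)[0]


# ---------------------------------------------------------------------------
# sequence generation


def _generate_sequence(length: int, segments: list[tuple[int, int, float]],
                       rng: np.random.Generator) -> np.ndarray:
    """Generate a base sequence (uint8 codes 0..3) of ``length`` bp.

    ``segments`` lists (start, end, cpg_rate) covering [0, length). CpGs are
    planted explicitly as a renewal process (a step emits "CG" with
    probability r2 = rate/(1-rate), else a single random base), then any
    accidental C..G adjacency between single bases is broken by mutating the
    G to A/T, so the realised CpG-start set is exactly the planted set and
    the per-bp CpG rate matches the requested rate in expectation.
    """
    seq = np.empty(length, dtype=np.uint8)
    planted = np.zeros(length, dtype=bool)
    for seg_start, seg_end, rate in segments:
        seg_len = seg_end - seg_start
        if seg_len <= 0:
            continue
        r2 = rate / (1.0 - rate) if rate > 0 else 0.0
        # draw more than enough steps, then cut
        n_draw = int(seg_len * 1.05) + 16
        flags = rng.random(n_draw) < r2
        singles = rng.integers(0, 4, size=n_draw)
        lengths = 1 + flags.astype(np.int64)
        ends = np.cumsum(lengths)
        n_steps = int(np.searchsorted(ends, seg_len, side="left")) + 1
        flags, singles = flags[:n_steps], singles[:n_steps]
        starts = ends[:n_steps] - lengths[:n_steps]
        buf_len = int(ends[n_steps - 1])
        buf = np.empty(buf_len, dtype=np.uint8)
        pmask = np.zeros(buf_len, dtype=bool)
        buf[starts[~flags]] = singles[~flags]
        cg_starts = starts[flags]
        buf[cg_starts] = _C
        buf[cg_starts + 1] = _G
        pmask[cg_starts] = True
        buf = buf[:seg_len]
        pmask = pmask[:seg_len]
        if len(buf) and pmask[-1]:  # trailing CG lost its G to the cut
            pmask[-1] = False
            buf[-1] = rng.choice([_A, _C, _T])
        seq[seg_start:seg_end] = buf
        planted[seg_start:seg_end] = pmask
    # break accidental CpGs (G never introduced, so one pass suffices)
    acc = (seq[:-1] == _C) & (seq[1:] == _G) & ~planted[:-1]
    idx = np.nonzero(acc)[0]
    seq[idx + 1] = rng.choice([_A, _T], size=idx.size)
    return seq


def _codes_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def _place_nonoverlapping(n: int, lengths: np.ndarray, chrom_len: int,
                          rng: np.random.Generator, min_gap: int = 0,
                          what: str = "intervals") -> list[Interval]:
    """Place ``n`` non-overlapping intervals of given lengths uniformly-ish.

    Uses a stick-breaking construction: random gaps (Dirichlet over the
    leftover space) between intervals in random order. Raises ValueError if
    the chromosome is too short.
    """
    if n == 0:
        return []
    total = int(lengths.sum()) + min_gap * (n + 1)
    leftover = chrom_len - total
    if leftover < 0:
        raise ValueError(
            f"chromosome of {chrom_len} bp too short to place {n} {what} "
            f"totalling {total} bp"
        )
    gaps = rng.dirichlet(np.ones(n + 1)) * leftover
    out = []
    cursor = 0.0
    for i in range(n):
        cursor += gaps[i] + min_gap
        start = int(cursor)
        out.append((start, start + int(lengths[i])))
        cursor = start + int(lengths[i])
    return out


def _split_lengths(total: int, mins: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Partition ``total`` into len(mins) parts, each >= its minimum."""
    slack = total - int(mins.sum())
    if slack < 0:
        raise ValueError("span too small for requested structure")
    extra = rng.multinomial(slack, rng.dirichlet(np.ones(len(mins))))
    return mins + extra


def _build_gene(gene_id: str, chrom: str, start: int, end: int,
                rng: np.random.Generator) -> GeneModel:
    strand = rng.choice(["+", "-"])
    span = end - start
    max_ex = max(2, min(6, span // 400))
    n_ex = int(rng.integers(1, max_ex + 1)) if span >= 400 else 1
    if n_ex == 1:
        exons = [(start, end)]
    else:
        mins = np.empty(2 * n_ex - 1, dtype=np.int64)
        mins[0::2] = 100   # exons
        mins[1::2] = 60    # introns
        parts = _split_lengths(span, mins, rng)
        bounds = start + np.concatenate([[0], np.cumsum(parts)])
        exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, 2 * n_ex - 1, 2)]
    # CDS: trim UTRs off the transcript ends (strand-aware)
    first = exons[0] if strand == "+" else exons[-1]
    last = exons[-1] if strand == "+" else exons[0]
    u5 = int(rng.integers(20, max(21, (first[1] - first[0]) // 2)))
    u3 = int(rng.integers(20, max(21, (last[1] - last[0]) // 2)))
    if strand == "+":
        cds_lo, cds_hi = exons[0][0] + u5, exons[-1][1] - u3
    else:
        cds_lo, cds_hi = exons[0][0] + u3, exons[-1][1] - u5
    cds = [(max(s, cds_lo), min(e, cds_hi)) for s, e in exons]
    cds = [(s, e) for s, e in cds if s < e]
    return GeneModel(gene_id, chrom, strand, start, end, exons=exons, cds=cds)


def make_annotation(config: SimConfig) -> SyntheticAnnotation:
    """Generate genome sequences, gene models, CGIs and repeats."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom_lens = np.full(config.n_chroms, config.genome_length // config.n_chroms)
    chrom_lens[0] += config.genome_length - chrom_lens.sum()
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    # distribute genes/CGIs/repeats over chromosomes proportionally to length
    def _counts(total: int) -> np.ndarray:
        if total == 0:
            return np.zeros(config.n_chroms, dtype=int)
        return rng.multinomial(total, chrom_lens / chrom_lens.sum())

    gene_counts = _counts(config.n_genes)
    cgi_counts = _counts(config.n_cgis_effective)
    rep_counts = _counts(config.n_repeats_effective)

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    cgis: dict[str, list[Interval]] = {}
    repeats: dict[str, list[Interval]] = {}
    gi = 0
    cgi_rate = min(0.15, config.cpg_rate * config.cgi_rate_multiplier)
    for ci, chrom in enumerate(chroms):
        L = int(chrom_lens[ci])
        n_cgi = int(cgi_counts[ci])
        cgi_iv = _place_nonoverlapping(
            n_cgi, rng.integers(300, 801, size=n_cgi), L, rng,
            min_gap=AnnotationParams().cgi_shore, what="CpG islands")
        cgis[chrom] = cgi_iv
        segments: list[tuple[int, int, float]] = []
        cursor = 0
        for s, e in cgi_iv:
            segments.append((cursor, s, config.cpg_rate))
            segments.append((s, e, cgi_rate))
            cursor = e
        segments.append((cursor, L, config.cpg_rate))
        genome[chrom] = _codes_to_str(_generate_sequence(L, segments, rng))

        n_g = int(gene_counts[ci])
        glens = rng.integers(2000, 6001, size=n_g)
        # 2.5 kb head gap leaves room for a full upstream promoter
        try:
            spans = _place_nonoverlapping(n_g, glens, L, rng, min_gap=2500,
                                          what="genes")
        except ValueError as exc:
            raise ValueError(f"genome too short to place {config.n_genes} genes") from exc
        for s, e in spans:
            genes.append(_build_gene(f"gene{gi:05d}", chrom, s, e, rng))
            gi += 1

        n_r = int(rep_counts[ci])
        rep_iv = []
        for w in rng.integers(200, 1501, size=n_r):
            st = int(rng.integers(0, L - int(w)))
            rep_iv.append((st, st + int(w)))
        repeats[chrom] = sorted(rep_iv)
    return SyntheticAnnotation(genome=genome, genes=genes, cgis=cgis, repeats=repeats)


# ---------------------------------------------------------------------------
# methylomes


def sample_beta_binomial(n: np.ndarray, mu: np.ndarray, phi: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Beta-binomial draws parameterised by mean mu and dispersion phi.

    alpha = mu (1-phi)/phi, beta = (1-mu)(1-phi)/phi; phi -> 0 reduces to
    the plain binomial exactly.
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), np.shape(n))
    if phi == 0.0:
        return rng.binomial(n, mu)
    scale = (1.0 - phi) / phi
    p = rng.beta(np.maximum(mu * scale, 1e-12), np.maximum((1.0 - mu) * scale, 1e-12))
    return rng.binomial(n, p)


def _plant_dmrs(config: SimConfig, annotation: SyntheticAnnotation,
                rng: np.random.Generator) -> pd.DataFrame:
    """Choose planted DMR intervals anchored on CpGs, mostly inside genes."""
    lo, hi = config.dmr_span_range
    cpg = {c: annotation.cpg_positions(c) for c in annotation.genome}
    sizes = annotation.chrom_sizes
    by_chrom_genes: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)
    placed: dict[str, list[Interval]] = {c: [] for c in annotation.genome}
    rows = []
    promoter_up = AnnotationParams().promoter_upstream
    for k in range(config.n_planted_dmrs):
        ok = False
        for _ in range(400):
            span = int(rng.integers(lo, hi + 1))
            in_gene = rng.random() < config.dmr_in_gene_fraction and annotation.genes
            if in_gene:
                gene = annotation.genes[int(rng.integers(len(annotation.genes)))]
                chrom = gene.chrom
                if rng.random() < 0.3:
                    w_lo, w_hi = gene.promoter(promoter_up, sizes[chrom])
                else:
                    w_lo, w_hi = gene.start, gene.end
            else:
                chrom = list(annotation.genome)[
                    int(rng.integers(len(annotation.genome)))]
                w_lo, w_hi = 0, sizes[chrom]
            pos = cpg[chrom]
            j0, j1 = np.searchsorted(pos, [w_lo, w_hi - span])
            if j1 <= j0:
                continue
            start = int(pos[int(rng.integers(j0, j1))])
            end = min(start + span, sizes[chrom])
            n_in = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            if n_in < config.dmr_min_cpgs:
                continue
            sep = config.dmr_min_separation
            if any(s < end + sep and start - sep < e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            sign = 1.0 if rng.random() < config.hyper_fraction else -1.0
            rows.append({"dmr_id": f"planted{k:05d}", "chrom": chrom,
                         "start": start, "end": end,
                         "effect": sign * config.effect_size, "n_cpg": n_in})
            ok = True
            break
        if not ok:
            raise RuntimeError(
                "could not place all planted DMRs; genome too small or too "
                "CpG-poor for the requested configuration"
            )
    truth = pd.DataFrame(
        rows, columns=["dmr_id", "chrom", "start", "end", "effect", "n_cpg"])
    return truth.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_methylomes(
    config: SimConfig, annotation: SyntheticAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate CpG methylomes with planted DMRs.

    Returns (records, truth): ``records`` is a long cytosine-record table
    (chrom, pos, context, group, replicate, n_meth, n_total); ``truth``
    lists every planted interval with its signed methylation effect.
    Read totals are Poisson(coverage_mean) clipped to >= 1; methylated
    counts are beta-binomial(total, mu_site, phi) where mu_site is the base
    level outside planted DMRs and base + effect (clamped to [0.02, 0.98])
    inside, for group 2 only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    truth = _plant_dmrs(config, annotation, rng)
    frames = []
    n_rep = config.n_replicates_per_group
    for chrom in annotation.genome:
        pos = annotation.cpg_positions(chrom)
        n_sites = pos.size
        if n_sites == 0:
            continue
        mu1 = np.full(n_sites, config.base_methylation)
        mu2 = mu1.copy()
        tr = truth[truth.chrom == chrom]
        for _, row in tr.iterrows():
            mask = (pos >= row.start) & (pos < row.end)
            mu2[mask] = np.clip(config.base_methylation + row.effect, 0.02, 0.98)
        for group, mu in ((GROUP1, mu1), (GROUP2, mu2)):
            for rep in range(n_rep):
                totals = np.maximum(
                    rng.poisson(config.coverage_mean, size=n_sites), 1)
                meth = sample_beta_binomial(totals, mu, config.dispersion_phi, rng)
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos, "context": "CG",
                    "group": group, "replicate": rep,
                    "n_meth": meth, "n_total": totals,
                }))
    if frames:
        records = pd.concat(frames, ignore_index=True)
        records = records.sort_values(
            ["chrom", "pos", "group", "replicate"]).reset_index(drop=True)
    else:
        records = pd.DataFrame(
            columns=["chrom", "pos", "context", "group", "replicate",
                     "n_meth", "n_total"])
    return records, truth


# ---------------------------------------------------------------------------
# coupled expression and ATAC tables


def true_gene_methylation(annotation: SyntheticAnnotation, truth: pd.DataFrame,
                          promoter_upstream: int = 2000) -> pd.DataFrame:
    """Per gene, the mean planted effect over DMRs overlapping its promoter
    or gene body (0 if none)."""
    sizes = annotation.chrom_sizes
    rows = []
    for gene in annotation.genes:
        ps, pe = gene.promoter(promoter_upstream, sizes[gene.chrom])
        lo = min(ps, gene.start)
        hi = max(pe, gene.end)
        tr = truth[(truth.chrom == gene.chrom)
                   & (truth.start < hi) & (truth.end > lo)]
        effects = [
            row.effect for _, row in tr.iterrows()
            if (row.start < gene.end and row.end > gene.start)
            or (row.start < pe and row.end > ps)
        ]
        rows.append({"gene_id": gene.gene_id,
                     "true_avg_dm": float(np.mean(effects)) if effects else 0.0,
                     "n_truth_dmrs": len(effects)})
    return pd.DataFrame(rows)


def simulate_expression(
    config: SimConfig, annotation: SyntheticAnnotation, truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the differential-expression table.

    log2FC (fiber/epi) = expr_coupling_slope * true_avg_dm + noise; FPKMs
    are back-computed from a log-normal epithelial baseline so that
    fpkm_fiber / fpkm_epi = 2**log2FC. q-values are truth-linked: genes
    with |log2FC| > 0.4 are significant with probability ``deg_sig_prob``.
    Returns (expression table, per-gene truth table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    gene_truth = true_gene_methylation(annotation, truth)
    n = len(gene_truth)
    dm = gene_truth.true_avg_dm.to_numpy()
    log2fc = config.expr_coupling_slope * dm + rng.normal(0, config.expr_noise_sd, n)
    fpkm1 = np.exp(rng.normal(np.log(10.0), 1.0, n))
    fpkm2 = fpkm1 * np.exp2(log2fc)
    big = np.abs(log2fc) > 0.4
    sig = big & (rng.random(n) < config.deg_sig_prob)
    q = np.where(sig, rng.uniform(1e-6, 0.049, n), rng.uniform(0.051, 1.0, n))
    expr = pd.DataFrame({
        "gene_id": gene_truth.gene_id,
        "fpkm_group1": np.round(fpkm1, 4),
        "fpkm_group2": np.round(fpkm2, 4),
        "log2fc": np.round(log2fc, 6),
        "qvalue": np.round(q, 6),
    })
    return expr, gene_truth


def simulate_atac(config: SimConfig, annotation: SyntheticAnnotation,
                  truth: pd.DataFrame) -> pd.DataFrame:
    """Simulate an ATAC peak table: one differential peak spanning each
    planted DMR plus stable background peaks elsewhere."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    sizes = annotation.chrom_sizes
    rows = []
    for i, row in truth.iterrows():
        pad_l = int(rng.integers(50, 301))
        pad_r = int(rng.integers(50, 301))
        log2fc = (config.atac_coupling_slope * row.effect
                  + rng.normal(0, config.atac_noise_sd))
        rows.append({
            "chrom": row.chrom,
            "start": max(0, row.start - pad_l),
            "end": min(sizes[row.chrom], row.end + pad_r),
            "name": f"peak_dmr{i:05d}",
            "log2fc": round(float(log2fc), 6),
            "qvalue": round(float(rng.uniform(1e-6, 0.049)), 6),
        })
    planted_by_chrom: dict[str, list[Interval]] = {}
    for _, row in truth.iterrows():
        planted_by_chrom.setdefault(row.chrom, []).append((row.start, row.end))
    chroms = list(annotation.genome)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    n_bg = config.n_background_peaks_effective
    k = 0
    attempts = 0
    while k < n_bg and attempts < 50 * n_bg + 100:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        w = int(rng.integers(200, 801))
        if sizes[chrom] <= w:
            continue
        s = int(rng.integers(0, sizes[chrom] - w))
        if any(s < e and ps < s + w for ps, e in planted_by_chrom.get(chrom, [])):
            continue
        rows.append({
            "chrom": chrom, "start": s, "end": s + w,
            "name": f"peak_bg{k:05d}",
            "log2fc": round(float(rng.normal(0, config.atac_noise_sd)), 6),
            "qvalue": round(float(rng.uniform(0.051, 1.0)), 6),
        })
        k += 1
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "log2fc", "qvalue"])
    return peaks.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# coupling calibration


def calibrate_expression_noise(dm_values, slope: float, target_r: float,
                               deg_log2fc: float = 0.4, n_sim: int = 400_000,
                               seed: int = 12345) -> float:
    """Noise SD giving Pearson |r| = |target_r| between per-gene planted
    methylation change and log2FC *after* the DEG magnitude filter.

    ``dm_values`` are the per-gene true average methylation changes the
    generator actually produced (genes averaging several planted regions
    can sit anywhere between -effect and +effect, which dilutes the
    correlation, and selecting genes with |log2FC| > cutoff — the DEG
    definition — changes it further). The study condition "coupling
    targeting r" is therefore defined on the selected set; this solves for
    the noise level by bisection on a large fixed-seed resample of the
    realised truth column.
    """
    dm_values = np.asarray(dm_values, dtype=float)
    if dm_values.size == 0 or (dm_values == 0).all():
        raise ValueError("no genes with planted methylation changes")
    rng = np.random.default_rng(seed)
    dm = rng.choice(dm_values, size=n_sim, replace=True)
    noise = rng.normal(0.0, 1.0, size=n_sim)
    target = abs(target_r)

    def realised(sd: float) -> float:
        y = slope * dm + sd * noise
        sel = np.abs(y) > deg_log2fc
        return abs(float(np.corrcoef(dm[sel], y[sel])[0, 1]))

    lo, hi = 1e-3, 50.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realised(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_atac_noise(slope: float, effect_size: float, target_r: float) -> float:
    """Closed-form noise SD for a target correlation with a symmetric
    two-point effect distribution (no selection on the ATAC side)."""
    r = abs(target_r)
    if not 0 < r < 1:
        raise ValueError("target_r must be in (0, 1)")
    return abs(slope) * effect_size * np.sqrt(1.0 / r**2 - 1.0)


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, in memory."""

    config: SimConfig
    annotation: SyntheticAnnotation
    records: pd.DataFrame
    truth: pd.DataFrame
    expression: pd.DataFrame
    gene_truth: pd.DataFrame
    peaks: pd.DataFrame


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Run the full generator: annotation, methylomes, expression, ATAC."""
    annotation = make_annotation(config)
    records, truth = simulate_methylomes(config, annotation)
    expression, gene_truth = simulate_expression(config, annotation, truth)
    peaks = simulate_atac(config, annotation, truth)
    return SyntheticBundle(config, annotation, records, truth,
                           expression, gene_truth, peaks)
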