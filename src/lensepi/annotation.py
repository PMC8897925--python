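"""Strand-aware genomic-feature annotation of DMRs.

Assigns each region to the highest-priority feature category it overlaps
(promoter > utr5 > first exon > first intron > other exon > other intron >
utr3 > CGI > CGI shore > repeat > intergenic), links regions to genes via
promoter/gene-body overlap, and provides the random-placement null for the
category distribution plus the hyper-vs-hypo distribution comparison.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import CATEGORY_PRIORITY, AnnotationParams
from .models import GeneModel, Interval
from .stats import chi2_contingency_nocorr

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def classify_context(sequence: str, pos: int, strand: str) -> str:
    """Cytosine context at ``pos`` on ``strand``: CG, CHG, CHH, CHH_trunc
    or not_C.

    Looks at the two bases 3' of the cytosine on its strand; on the minus
    strand the cytosine appears as G in the reference and 3' runs leftward
    on the complement. ``CHH_trunc`` flags cytosines whose 3' context is
    cut off by the sequence edge.
    """
    if not 0 <= pos < len(sequence):
        raise IndexError(f"position {pos} outside sequence of length {len(sequence)}")
    if strand == "+":
        if sequence[pos] != "C":
            return "not_C"
        nxt = sequence[pos + 1] if pos + 1 < len(sequence) else None
        nxt2 = sequence[pos + 2] if pos + 2 < len(sequence) else None
    elif strand == "-":
        if sequence[pos] != "G":
            return "not_C"
        nxt = sequence[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        nxt2 = sequence[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt is None:
        return "CHH_trunc"
    if nxt == "G":
        return "CG"
    if nxt2 is None:
        return "CHH_trunc"
    return "CHG" if nxt2 == "G" else "CHH"


def _merge(intervals: list[Interval]) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping intervals into disjoint sorted arrays."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted(intervals)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


class FeatureIndex:
    """Merged per-category interval arrays supporting fast overlap queries."""

    def __init__(self, genes: Sequence[GeneModel],
                 cgis: dict[str, list[Interval]] | None,
                 repeats: dict[str, list[Interval]] | None,
                 chrom_sizes: dict[str, int],
                 params: AnnotationParams | None = None,
                 split_promoter: bool = False):
        self.params = params or AnnotationParams()
        self.chrom_sizes = dict(chrom_sizes)
        self.split_promoter = split_promoter
        raw: dict[str, dict[str, list[Interval]]] = {}

        def add(cat: str, chrom: str, iv: Optional[Interval]) -> None:
            if iv is None:
                return
            s, e = iv
            if s < e:
                raw.setdefault(cat, {}).setdefault(chrom, []).append((s, e))

        up = self.params.promoter_upstream
        prox = self.params.proximal_promoter
        for g in genes:
            size = self.chrom_sizes.get(g.chrom)
            prom = g.promoter(up, size)
            add("promoter", g.chrom, prom)
            if split_promoter:
                ps, pe = prom
                if g.strand == "+":
                    add("promoter_proximal", g.chrom, (max(ps, g.start - prox), pe))
                    add("promoter_distal", g.chrom, (ps, max(ps, g.start - prox)))
                else:
                    add("promoter_proximal", g.chrom, (ps, min(pe, g.end + prox)))
                    add("promoter_distal", g.chrom, (min(pe, g.end + prox), pe))
            for iv in g.utr5:
                add("utr5", g.chrom, iv)
            for iv in g.utr3:
                add("utr3", g.chrom, iv)
            add("first_exon", g.chrom, g.first_exon)
            for iv in g.other_exons:
                add("other_exon", g.chrom, iv)
            add("first_intron", g.chrom, g.first_intron)
            for iv in g.other_introns:
                add("other_intron", g.chrom, iv)
        shore = self.params.cgi_shore
        for chrom, ivs in (cgis or {}).items():
            size = self.chrom_sizes.get(chrom, None)
            for s, e in ivs:
                add("cgi", chrom, (s, e))
                lo = max(0, s - shore)
                hi = min(e + shore, size) if size is not None else e + shore
                add("cgi_shore", chrom, (lo, s))
                add("cgi_shore", chrom, (e, hi))
        for chrom, ivs in (repeats or {}).items():
            for iv in ivs:
                add("repeat", chrom, iv)

        self._merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for cat, by_chrom in raw.items():
            self._merged[cat] = {c: _merge(iv) for c, iv in by_chrom.items()}

    def category_intervals(self, cat: str) -> dict[str, list[Interval]]:
        """Merged intervals of one category (for summaries and exports)."""
        out = {}
        for chrom, (s, e) in self._merged.get(cat, {}).items():
            out[chrom] = list(zip(s.tolist(), e.tolist()))
        return out

    def _overlaps(self, cat: str, chrom: str, qs: np.ndarray,
                  qe: np.ndarray) -> np.ndarray:
        entry = self._merged.get(cat, {}).get(chrom)
        if entry is None:
            return np.zeros(qs.shape, dtype=bool)
        starts, ends = entry
        idx = np.searchsorted(starts, qe, side="left")
        prev = idx - 1
        ok = idx > 0
        res = np.zeros(qs.shape, dtype=bool)
        res[ok] = ends[prev[ok]] > qs[ok]
        return res

    def query_many(self, chrom: str, starts: np.ndarray,
                   ends: np.ndarray) -> np.ndarray:
        """Highest-priority overlapping category for each query interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if (starts < 0).any() or (ends > size).any() or (starts >= ends).any():
            raise ValueError(f"query interval outside {chrom} bounds")
        cats = np.full(starts.shape, "intergenic", dtype=object)
        unassigned = np.ones(starts.shape, dtype=bool)
        for cat in self.params.category_priority:
            if cat == "intergenic" or not unassigned.any():
                break
            hit = self._overlaps(cat, chrom, starts, ends) & unassigned
            cats[hit] = cat
            unassigned &= ~hit
        return cats

    def query(self, chrom: str, start: int, end: int) -> str:
        return str(self.query_many(chrom, np.array([start]), np.array([end]))[0])


def annotate_interval(interval: tuple[str, int, int], index: FeatureIndex) -> str:
    """Category of a single (chrom, start, end) interval."""
    chrom, start, end = interval
    return index.query(chrom, start, end)


def annotate_dmrs(dmrs: pd.DataFrame, index: FeatureIndex) -> pd.DataFrame:
    """Add a ``category`` column to a DMR table."""
    out = dmrs.copy()
    cats = np.empty(len(out), dtype=object)
    for chrom, sub in out.groupby("chrom"):
        cats[out.index.get_indexer(sub.index)] = index.query_many(
            chrom, sub.start.to_numpy(), sub.end.to_numpy())
    out["category"] = cats
    return out


def map_dmr_to_genes(dmrs: pd.DataFrame, genes: Sequence[GeneModel],
                     params: AnnotationParams | None = None,
                     chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Link DMRs to genes by >= 1 bp overlap of promoter or gene body.

    Returns one row per (DMR, gene) pair with columns dmr_id (the DMR's
    row index), gene_id and location in {promoter, genebody}; a DMR
    overlapping both features of the same gene records location=promoter.
    """
    params = params or AnnotationParams()
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        size = (chrom_sizes or {}).get(g.chrom)
        tree = trees.setdefault(g.chrom, IntervalTree())
        ps, pe = g.promoter(params.promoter_upstream, size)
        if ps < pe:
            tree.addi(ps, pe, (i, "promoter"))
        tree.addi(g.start, g.end, (i, "genebody"))
    rows = []
    for dmr_id, row in dmrs.iterrows():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits: dict[int, str] = {}
        for iv in tree.overlap(row.start, row.end):
            gi, loc = iv.data
            if loc == "promoter":
                hits[gi] = "promoter"  # promoter precedence within a gene
            elif gi not in hits:
                hits[gi] = loc
        for gi, loc in hits.items():
            rows.append((dmr_id, genes[gi].gene_id, loc))
    out = pd.DataFrame(rows, columns=["dmr_id", "gene_id", "location"])
    return out.sort_values(["dmr_id", "gene_id"]).reset_index(drop=True)


def draw_random_intervals(lengths: np.ndarray, chrom_sizes: dict[str, int],
                          n: int, rng: np.random.Generator
                          ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Draw ``n`` intervals uniformly over the genome, lengths resampled
    (with replacement) from ``lengths``.

    Chromosomes are chosen proportionally to length, starts uniformly in
    [0, chrom_len - L]. Lengths longer than the chosen chromosome are
    redrawn (capped); returns per-chromosome (chrom, starts, ends) blocks.
    """
    lengths = np.asarray(lengths)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    draw_len = rng.choice(lengths, size=n, replace=True)
    draw_chrom = rng.choice(len(chroms), size=n, p=weights)
    out = []
    for ci, chrom in enumerate(chroms):
        mask = draw_chrom == ci
        if not mask.any():
            continue
        L = draw_len[mask]
        size = chrom_sizes[chrom]
        bad = L >= size
        for _ in range(100):
            if not bad.any():
                break
            L = L.copy()
            L[bad] = rng.choice(lengths, size=int(bad.sum()), replace=True)
            bad = L >= size
        if bad.any():
            raise ValueError(f"chromosome {chrom} shorter than every DMR length")
        starts = (rng.random(L.size) * (size - L)).astype(np.int64)
        out.append((chrom, starts, starts + L))
    return out


def random_null_test(annotated_dmrs: pd.DataFrame, index: FeatureIndex,
                     n_draws: int = 100, seed: int = 0,
                     rng: np.random.Generator | None = None) -> dict:
    """Random-placement null for the DMR category distribution.

    Draws ``n_draws`` x |DMRs| intervals uniformly over the genome with
    lengths resampled (with replacement) from the observed DMR lengths,
    annotates them, and compares observed category counts to the expected
    counts (null mean scaled to |DMRs|) with a Pearson goodness-of-fit
    chi-square; categories with expected count < 1 are pooled. Also reports
    the observed-minus-expected percentage difference per category.
    """
    if annotated_dmrs.empty:
        raise ValueError("no DMRs to test")
    rng = rng if rng is not None else np.random.default_rng(seed)
    lengths = (annotated_dmrs.end - annotated_dmrs.start).to_numpy()
    n_obs = len(annotated_dmrs)
    null_counts: dict[str, int] = {}
    for chrom, starts, ends in draw_random_intervals(lengths, index.chrom_sizes,
                                                     n_draws * n_obs, rng):
        cats = index.query_many(chrom, starts, ends)
        for c, n in zip(*np.unique(cats, return_counts=True)):
            null_counts[c] = null_counts.get(c, 0) + int(n)
    expected = {c: n / n_draws for c, n in null_counts.items()}
    observed = annotated_dmrs.category.value_counts().to_dict()
    all_cats = [c for c in CATEGORY_PRIORITY
                if c in expected or c in observed]
    obs_v = np.array([observed.get(c, 0) for c in all_cats], dtype=float)
    exp_v = np.array([expected.get(c, 0.0) for c in all_cats])
    # pool categories with expected < 1 to keep the chi-square valid
    pool = exp_v < 1.0
    if pool.sum() and pool.sum() < len(all_cats):
        obs_use = np.concatenate([obs_v[~pool], [obs_v[pool].sum()]])
        exp_use = np.concatenate([exp_v[~pool], [exp_v[pool].sum()]])
    else:
        obs_use, exp_use = obs_v, exp_v
    # guard: rescale tiny totals mismatch from pooling arithmetic
    exp_use = exp_use * obs_use.sum() / exp_use.sum()
    from scipy import stats as sps
    chi2, p = sps.chisquare(obs_use, exp_use)
    pct_diff = {c: 100.0 * (observed.get(c, 0) / n_obs - expected.get(c, 0.0) / n_obs)
                for c in all_cats}
    return {
        "observed": {c: int(observed.get(c, 0)) for c in all_cats},
        "expected": {c: float(expected.get(c, 0.0)) for c in all_cats},
        "percent_difference": pct_diff,
        "chi2": float(chi2),
        "p_value": float(p),
        "n_dmrs": n_obs,
        "n_draws": n_draws,
    }


def compare_hyper_hypo_distributions(annotated_dmrs: pd.DataFrame) -> dict:
    """Category-distribution comparison between hyper- and hypomethylated
    regions: category x direction contingency, Pearson chi-square (no
    continuity correction) and per-category percentage-point differences.
    """
    for direction in ("hyper", "hypo"):
        if (annotated_dmrs.direction == direction).sum() == 0:
            raise ValueError(f"no DMRs with direction {direction!r}")
    table = pd.crosstab(annotated_dmrs.category, annotated_dmrs.direction)
    table = table.reindex(columns=["hyper", "hypo"], fill_value=0)
    chi2, p, dof = chi2_contingency_nocorr(table.to_numpy())
    pct = table / table.sum(axis=0)
    pct_point_diff = (100.0 * (pct.hyper - pct.hypo)).to_dict()
    return {
        "table": {cat: {"hyper": int(r.hyper), "hypo": int(r.hypo)}
                  for cat, r in table.iterrows()},
        "percentage_point_difference": pct_point_diff,
        "chi2": chi2,
        "p_value": p,
        "dof": dof,
    }
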