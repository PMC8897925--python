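"""PWM scanning with exact score-distribution p-values and motif
enrichment against shuffled backgrounds.

The scanner scores both strands with a log-odds matrix (base-2, with
pseudocount); hit p-values come from the exact distribution of the
discretised score under a zero-order background model, computed by dynamic
programming over motif columns. Enrichment compares, per motif, the number
of primary vs shuffled-control sequences containing at least one hit, with
a one-sided Fisher's exact test and Benjamini-Hochberg adjustment across
motifs. Enriched motifs are finally filtered by the expression of the
transcription factor's gene (total FPKM across the two states >= 1 by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .models import MotifModel

log = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> -1."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def pfm_to_pwm(counts: np.ndarray, pseudocount: float = 0.25,
               background: Optional[np.ndarray] = None) -> np.ndarray:
    """Log-odds matrix (bits): log2 of pseudocounted column frequency over
    background frequency."""
    counts = np.asarray(counts, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")
    col_tot = counts.sum(axis=0)
    freq = (counts + pseudocount) / (col_tot + 4 * pseudocount)
    return np.log2(freq / bg[:, None])


def estimate_background(sequences: Sequence[str]) -> np.ndarray:
    """Zero-order background from a sequence set (pseudocount 1 per base)."""
    counts = np.ones(4, dtype=float)
    for s in sequences:
        codes = encode(s)
        for b, n in zip(*np.unique(codes[codes >= 0], return_counts=True)):
            counts[b] += n
    return counts / counts.sum()


@dataclass
class ScoreDistribution:
    """Exact distribution of the discretised PWM score under a zero-order
    background; maps integer score bins to tail probabilities."""

    qmatrix: np.ndarray     # 4 x w integer bin scores
    bin_width: float
    offset: int             # minimum achievable integer score
    tail: np.ndarray        # tail[k] = P(score_bins >= offset + k)

    def pvalue_int(self, int_scores: np.ndarray) -> np.ndarray:
        k = np.asarray(int_scores) - self.offset
        k = np.clip(k, 0, self.tail.size - 1)
        out = self.tail[k]
        return np.where(np.asarray(int_scores) - self.offset >= self.tail.size,
                        0.0, out)

    def min_int_score_below(self, p_threshold: float) -> int:
        """Smallest integer score whose tail p-value is < p_threshold
        (one past the end when no score qualifies)."""
        idx = np.nonzero(self.tail < p_threshold)[0]
        if idx.size == 0:
            return self.offset + self.tail.size
        return self.offset + int(idx[0])


def pwm_score_pvalue_table(log_odds: np.ndarray,
                           background: Optional[np.ndarray] = None,
                           bin_width: float = 0.01) -> ScoreDistribution:
    """Exact tail probabilities of the discretised PWM score.

    Each cell score is rounded to ``bin_width``-bit bins; the score
    distribution of a random background word is the convolution of the
    per-column distributions, computed exactly on the integer bin grid.
    Tail probabilities are monotone non-increasing in score.
    """
    lo = np.asarray(log_odds, dtype=float)
    if not np.isfinite(lo).all():
        raise ValueError("log-odds matrix must be finite")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    q = np.rint(lo / bin_width).astype(np.int64)
    w = q.shape[1]
    col_min = q.min(axis=0)
    col_max = q.max(axis=0)
    offset = int(col_min.sum())
    size = int((col_max - col_min).sum()) + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    reach = 1
    for j in range(w):
        new = np.zeros(size)
        base = int(col_min[j])
        for b in range(4):
            sh = int(q[b, j]) - base
            new[sh:sh + reach] += bg[b] * pmf[:reach]
        reach += int(col_max[j] - col_min[j])
        pmf = new
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(qmatrix=q, bin_width=bin_width, offset=offset,
                             tail=tail)


def _scan_int_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Integer window scores at every offset (windows with non-ACGT get
    the minimum representable value)."""
    w = q.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    acc = np.zeros(n, dtype=np.int64)
    for j in range(w):
        c = codes[j:j + n]
        bad = c < 0
        valid &= ~bad
        acc += q[np.where(bad, 0, c), j]
    acc[~valid] = np.iinfo(np.int64).min
    return acc


def call_motif_hits(sequences: Sequence[tuple[str, str]], motif: MotifModel,
                    p_threshold: float = 1e-4,
                    background: Optional[np.ndarray] = None,
                    both_strands: bool = True,
                    table: Optional[ScoreDistribution] = None) -> pd.DataFrame:
    """Scan sequences for motif hits with exact p < ``p_threshold``.

    ``sequences`` is a list of (sequence_id, sequence). Offsets are
    forward-strand window start positions; reverse-strand windows are
    scored with the reverse-complemented matrix at the same forward
    coordinates. Sequences shorter than the motif yield no hits.
    """
    bg = estimate_background([s for _, s in sequences]) \
        if background is None else np.asarray(background, float)
    if table is None:
        table = pwm_score_pvalue_table(motif.log_odds() if background is None
                                       else pfm_to_pwm(motif.counts,
                                                       motif.pseudocount, bg),
                                       bg)
    q = table.qmatrix
    q_rc = q[::-1, ::-1]
    rows = []
    for seq_id, seq in sequences:
        codes = encode(seq)
        for strand, mat in (("+", q), ("-", q_rc)) if both_strands else (("+", q),):
            scores = _scan_int_scores(codes, mat)
            if scores.size == 0:
                continue
            pvals = table.pvalue_int(scores)
            hit_idx = np.nonzero(pvals < p_threshold)[0]
            for i in hit_idx:
                rows.append((seq_id, int(i), strand,
                             float(scores[i] * table.bin_width),
                             float(pvals[i])))
    return pd.DataFrame(rows, columns=["sequence_id", "offset", "strand",
                                       "score", "p_value"])


# ---------------------------------------------------------------------------
# shuffles


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving all dinucleotide counts.

    Picks a random last out-edge per vertex until the chosen edges form an
    arborescence toward the final character, then walks a random Euler
    path.
    """
    if len(seq) <= 2:
        return seq
    chars = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last_char = seq[-1]
    verts = [c for c in chars if c != last_char and edges[c]]
    for _ in range(2000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in verts}
        # chosen last edges must all lead (transitively) to last_char
        ok = True
        for v in verts:
            seen = set()
            cur = v
            while cur != last_char:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return seq
    walk_edges: dict[str, list[str]] = {}
    for c in chars:
        rest = list(edges[c])
        if c in last_edge:
            rest.remove(last_edge[c])
        order = [rest[i] for i in rng.permutation(len(rest))]
        if c in last_edge:
            order.append(last_edge[c])
        walk_edges[c] = order
    out = [seq[0]]
    ptr = {c: 0 for c in chars}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_sequences(sequences: Sequence[tuple[str, str]],
                      mode: str = "mononucleotide",
                      seed: int = 0) -> list[tuple[str, str]]:
    """Per-sequence shuffles preserving composition.

    ``mononucleotide`` preserves length and 1-mer counts; ``dinucleotide``
    additionally preserves all 16 adjacency counts (Euler-path shuffle).
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for name, seq in sequences:
        if mode == "mononucleotide":
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            shuf = arr[rng.permutation(arr.size)].tobytes().decode()
        elif mode == "dinucleotide":
            shuf = _dinucleotide_shuffle(seq, rng)
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        out.append((f"{name}|shuffled", shuf))
    return out


# ---------------------------------------------------------------------------
# enrichment


def motif_enrichment(primary: Sequence[tuple[str, str]],
                     control: Sequence[tuple[str, str]],
                     motif_models: Sequence[MotifModel],
                     p_threshold: float = 1e-4) -> pd.DataFrame:
    """Per-motif enrichment of primary vs control sequences.

    Counts sequences with >= 1 hit on either strand in each set, tests
    enrichment with a one-sided (greater) Fisher's exact test, and adjusts
    across motifs with Benjamini-Hochberg. Background base frequencies are
    estimated jointly from both sets. Results are sorted by adjusted then
    raw p.
    """
    if not primary or not control:
        raise ValueError("both sequence sets must be non-empty")
    bg = estimate_background([s for _, s in primary] + [s for _, s in control])
    rows = []
    for m in motif_models:
        table = pwm_score_pvalue_table(
            pfm_to_pwm(m.counts, m.pseudocount, bg), bg)
        hp = call_motif_hits(primary, m, p_threshold, background=bg, table=table)
        hc = call_motif_hits(control, m, p_threshold, background=bg, table=table)
        a = int(hp.sequence_id.nunique())
        b = int(hc.sequence_id.nunique())
        ctab = [[a, len(primary) - a], [b, len(control) - b]]
        fisher_p = float(sps.fisher_exact(ctab, alternative="greater")[1])
        rows.append({"motif_id": m.motif_id, "tf_name": m.tf_name,
                     "n_primary_with_hit": a, "n_control_with_hit": b,
                     "n_primary": len(primary), "n_control": len(control),
                     "fisher_p": fisher_p})
    df = pd.DataFrame(rows)
    df["adjusted_p"] = multipletests(df.fisher_p, method="fdr_bh")[1]
    return df.sort_values(["adjusted_p", "fisher_p", "motif_id"]) \
        .reset_index(drop=True)


def count_target_genes(hits: pd.DataFrame, seq_gene_map: dict[str, set[str]]) -> int:
    """Distinct genes whose linked region sequences carry >= 1 hit."""
    genes: set[str] = set()
    for sid in hits.sequence_id.unique():
        genes |= seq_gene_map.get(sid, set())
    return len(genes)


def annotate_tf_expression(enrichment: pd.DataFrame, expression: pd.DataFrame,
                           fpkm_cutoff: float = 1.0,
                           alias: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Filter enriched motifs by transcription-factor expression.

    TF names are matched to gene_ids case-insensitively (optionally via an
    alias table); heterodimer names like "ARNT::HIF1A" match if either
    component does. Motifs whose TF gene has fpkm_group1 + fpkm_group2
    below the cutoff are dropped; motifs with no matching gene are retained
    and flagged unmapped.
    """
    expr = expression.copy()
    if "deg_class" not in expr.columns:
        from .expression import classify_degs

        expr = classify_degs(expr)
    by_name = {str(g).upper(): row for g, row in
               expr.set_index("gene_id").iterrows()}
    alias_uc = {k.upper(): v.upper() for k, v in (alias or {}).items()}
    out_rows = []
    for _, row in enrichment.iterrows():
        parts = [p.strip().upper() for p in
                 str(row.tf_name).replace("::", ":").split(":") if p.strip()]
        matched = []
        for p in parts:
            key = alias_uc.get(p, p)
            if key in by_name:
                matched.append((key, by_name[key]))
        rec = row.to_dict()
        if not matched:
            rec.update(tf_gene=None, tf_total_fpkm=None,
                       tf_deg_class=None, tf_unmapped=True)
            out_rows.append(rec)
            continue
        totals = [(float(g.fpkm_group1 + g.fpkm_group2), name, g)
                  for name, g in matched]
        best_total, best_name, best = max(totals, key=lambda t: t[0])
        if best_total < fpkm_cutoff:
            continue  # TF not expressed in either state
        rec.update(tf_gene=best_name, tf_total_fpkm=best_total,
                   tf_deg_class=best.deg_class, tf_unmapped=False)
        out_rows.append(rec)
    return pd.DataFrame(out_rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# region sequence extraction


def extract_region_sequences(dmrs: pd.DataFrame, links: pd.DataFrame,
                             expression: pd.DataFrame,
                             genome: dict[str, str],
                             scope: str = "promoter_and_genebody"
                             ) -> tuple[dict[str, list[tuple[str, str]]],
                                        dict[str, dict[str, set[str]]]]:
    """The two motif-analysis sequence sets.

    ``hypo_fiber``: sequences of demethylated regions (diff_methyl < 0)
    linked to fiber-preferred genes; ``hyper_epithelial``: methylated
    regions (diff_methyl > 0) linked to epithelial-preferred genes.
    Sequences are uppercase; names record coordinates. Returns
    (sequence sets, per-set sequence -> linked-gene maps).
    """
    from .expression import classify_degs

    if "deg_class" not in expression.columns:
        expression = classify_degs(expression)
    use_links = links if scope == "promoter_and_genebody" else \
        links[links.location == "promoter"]
    joined = use_links.merge(expression[["gene_id", "deg_class"]], on="gene_id")
    sets: dict[str, list[tuple[str, str]]] = {"hypo_fiber": [],
                                              "hyper_epithelial": []}
    gene_maps: dict[str, dict[str, set[str]]] = {"hypo_fiber": {},
                                                 "hyper_epithelial": {}}
    for (key, direction, deg_class) in (
            ("hypo_fiber", "hypo", "fiber_preferred"),
            ("hyper_epithelial", "hyper", "epithelial_preferred")):
        sel = joined[joined.deg_class == deg_class]
        for dmr_id, group in sel.groupby("dmr_id"):
            d = dmrs.loc[dmr_id]
            if d.direction != direction:
                continue
            if d.chrom not in genome:
                raise KeyError(f"DMR contig {d.chrom!r} absent from genome")
            seq = genome[d.chrom][int(d.start):int(d.end)].upper()
            name = f"{d.chrom}:{int(d.start)}-{int(d.end)}"
            sets[key].append((name, seq))
            gene_maps[key][name] = set(group.gene_id)
    return sets, gene_maps
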