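"""DMR x ATAC-peak overlap and methylation-accessibility statistics.

Peaks are classed opening (log2FC > 0, q < 0.05), closing (log2FC < 0,
q < 0.05) or stable (otherwise; q = 0.05 falls in stable so the partition
is total). A DMR is matched to the single overlapping peak with the most
shared bases (ties: smaller q, then leftmost, then input order); regions
without any >= 1 bp overlap are counted but not matched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import chi2_contingency_nocorr, pearson_with_p

PEAK_CLASSES = ("opening", "closing", "stable")


def classify_peaks(peaks: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    out = peaks.copy()
    sig = out.qvalue < q_cutoff
    out["peak_class"] = np.select(
        [(out.log2fc > 0) & sig, (out.log2fc < 0) & sig],
        ["opening", "closing"], default="stable")
    return out


def overlap_dmrs_with_peaks(dmrs: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Match each DMR to its best overlapping peak (>= 1 bp).

    Returns one row per DMR with at least one overlap: dmr_id (DMR row
    index), peak_id (peak row index), overlap_bp, peak_class, peak_log2fc,
    peak_qvalue, dmr_direction, diff_methyl.
    """
    if "peak_class" not in peaks.columns:
        peaks = classify_peaks(peaks)
    rows = []
    for chrom, dsub in dmrs.groupby("chrom"):
        psub = peaks[peaks.chrom == chrom]
        if psub.empty:
            continue
        ps = psub.start.to_numpy()
        pe = psub.end.to_numpy()
        pq = psub.qvalue.to_numpy()
        pidx = psub.index.to_numpy()
        for dmr_id, d in dsub.iterrows():
            ov = np.minimum(pe, d.end) - np.maximum(ps, d.start)
            cand = np.nonzero(ov > 0)[0]
            if cand.size == 0:
                continue
            # max overlap, then min q, then leftmost start, then input order
            order = sorted(cand.tolist(),
                           key=lambda k: (-ov[k], pq[k], ps[k], pidx[k]))
            best = order[0]
            rows.append((dmr_id, int(pidx[best]), int(ov[best]),
                         psub.peak_class.iloc[best],
                         float(psub.log2fc.iloc[best]),
                         float(psub.qvalue.iloc[best]),
                         d.direction, float(d.diff_methyl)))
    return pd.DataFrame(rows, columns=[
        "dmr_id", "peak_id", "overlap_bp", "peak_class", "peak_log2fc",
        "peak_qvalue", "dmr_direction", "diff_methyl"])


def correlate_overlaps(overlaps: pd.DataFrame) -> dict:
    """Pearson r between diff_methyl and peak log2FC over matched pairs;
    raises ValueError when fewer than 3 pairs are available."""
    r, p, n = pearson_with_p(overlaps.diff_methyl, overlaps.peak_log2fc)
    return {"r": r, "p_value": p, "n": n}


def methylation_accessibility_stats(overlaps: pd.DataFrame,
                                    q_cutoff: float = 0.05) -> dict:
    """Direction x peak-class contingency plus correlations.

    Emits the 2x3 table (hyper/hypo x opening/closing/stable) with a
    Pearson chi-square (no correction; skipped on degenerate margins), and
    the diff_methyl vs peak-log2FC Pearson correlation overall and within
    the significant-peak (q < q_cutoff) stratum. Correlations that cannot
    be computed (n < 3 or zero variance) are reported as None.
    """
    table = pd.DataFrame(0, index=["hyper", "hypo"], columns=list(PEAK_CLASSES))
    for (d, c), n in overlaps.groupby(["dmr_direction", "peak_class"]).size().items():
        table.loc[d, c] = int(n)
    out: dict = {
        "table": {d: {c: int(table.loc[d, c]) for c in PEAK_CLASSES}
                  for d in ("hyper", "hypo")},
        "n_overlapping": int(len(overlaps)),
    }
    try:
        chi2, p, dof = chi2_contingency_nocorr(table.to_numpy())
        out["chi2"], out["chi2_p_value"], out["dof"] = chi2, p, dof
    except ValueError:
        out["chi2"], out["chi2_p_value"], out["dof"] = None, None, None
    for key, sub in (("correlation_all", overlaps),
                     ("correlation_significant",
                      overlaps[overlaps.peak_qvalue < q_cutoff])):
        try:
            out[key] = correlate_overlaps(sub)
        except ValueError:
            out[key] = {"r": None, "p_value": None, "n": int(len(sub))}
    return out
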