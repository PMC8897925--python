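"""Per-gene methylation-change summaries and their relation to expression.

Each gene's methylation change is the unweighted mean ``diff_methyl``
(fiber minus epithelial, proportion units) over the DMRs linked to its
promoter and/or gene body; this is correlated with the gene's expression
log2 fold change and cross-tabulated as a 2x2 quadrant association
(methylation up/down x expression class), tested with a Pearson chi-square
without continuity correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import chi2_2x2, pearson_with_p

DEG_CLASSES = ("epithelial_preferred", "fiber_preferred", "not_de")


def classify_degs(expression: pd.DataFrame, log2fc_cutoff: float = 0.4,
                  q_cutoff: float = 0.05) -> pd.DataFrame:
    """Label genes fiber_preferred / epithelial_preferred / not_de.

    Strict inequalities: fiber_preferred iff log2fc > cutoff and q < q_cutoff;
    epithelial_preferred iff log2fc < -cutoff and q < q_cutoff. Genes with
    missing q-values are not_de.
    """
    out = expression.copy()
    q_ok = out.qvalue < q_cutoff  # NaN compares False
    out["deg_class"] = np.select(
        [(out.log2fc > log2fc_cutoff) & q_ok,
         (out.log2fc < -log2fc_cutoff) & q_ok],
        ["fiber_preferred", "epithelial_preferred"],
        default="not_de",
    )
    return out


def average_gene_methylation(dmrs: pd.DataFrame, links: pd.DataFrame,
                             scope: str = "promoter_and_genebody",
                             weight: str | None = None) -> pd.DataFrame:
    """Per-gene mean diff_methyl over in-scope linked DMRs.

    ``scope`` is "promoter_and_genebody" or "promoter_only". The default is
    an unweighted mean; ``weight`` may name a DMR column (e.g. ``n_cg``)
    for a weighted variant. Genes without in-scope DMRs are absent.
    """
    if scope not in ("promoter_and_genebody", "promoter_only"):
        raise ValueError(f"unknown scope {scope!r}")
    use = links if scope == "promoter_and_genebody" else \
        links[links.location == "promoter"]
    if use.empty:
        return pd.DataFrame(columns=["gene_id", "scope", "n_dmrs",
                                     "avg_diff_methyl", "meth_direction"])
    joined = use.merge(dmrs[["diff_methyl"]].assign(
        _w=dmrs[weight] if weight else 1.0),
        left_on="dmr_id", right_index=True)

    def _agg(g: pd.DataFrame) -> pd.Series:
        avg = float(np.average(g.diff_methyl, weights=g._w))
        return pd.Series({"n_dmrs": len(g), "avg_diff_methyl": avg})

    summ = joined.groupby("gene_id").apply(_agg, include_groups=False).reset_index()
    summ["n_dmrs"] = summ.n_dmrs.astype(int)
    summ["scope"] = scope
    summ["meth_direction"] = np.select(
        [summ.avg_diff_methyl > 0, summ.avg_diff_methyl < 0],
        ["increase", "decrease"], default="zero")
    return summ[["gene_id", "scope", "n_dmrs", "avg_diff_methyl", "meth_direction"]]


def _join_degs(summaries: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    if "deg_class" not in expression.columns:
        expression = classify_degs(expression)
    degs = expression[expression.deg_class != "not_de"]
    return summaries.merge(degs, on="gene_id")


def correlate_methylation_expression(summaries: pd.DataFrame,
                                     expression: pd.DataFrame) -> dict:
    """Pearson correlation between per-gene avg_diff_methyl and log2FC over
    differentially expressed genes with >= 1 in-scope DMR."""
    joined = _join_degs(summaries, expression)
    r, p, n = pearson_with_p(joined.avg_diff_methyl, joined.log2fc)
    return {"r": r, "p_value": p, "n": n}


def methylation_expression_association(summaries: pd.DataFrame,
                                       expression: pd.DataFrame) -> dict:
    """2x2 quadrant association: methylation direction x DEG class.

    Rows: increase / decrease in average methylation (fiber vs epithelial);
    columns: epithelial_preferred / fiber_preferred. Genes whose average
    change is exactly zero are excluded and counted separately. Pearson
    chi-square without continuity correction; skipped (None) on a zero
    margin.
    """
    joined = _join_degs(summaries, expression)
    n_zero = int((joined.meth_direction == "zero").sum())
    use = joined[joined.meth_direction != "zero"]
    table = np.zeros((2, 2), dtype=int)
    for i, md in enumerate(("increase", "decrease")):
        for j, dc in enumerate(("epithelial_preferred", "fiber_preferred")):
            table[i, j] = int(((use.meth_direction == md)
                               & (use.deg_class == dc)).sum())
    result: dict = {
        "table": table.tolist(),
        "row_labels": ["increase", "decrease"],
        "col_labels": ["epithelial_preferred", "fiber_preferred"],
        "n": int(table.sum()),
        "n_zero_excluded": n_zero,
    }
    row_sums = table.sum(axis=1)
    result["row_percentages"] = [
        (100.0 * table[i] / row_sums[i]).tolist() if row_sums[i] else [0.0, 0.0]
        for i in range(2)
    ]
    try:
        chi2, p = chi2_2x2(table)
        result["chi2"], result["p_value"] = chi2, p
    except ValueError:
        result["chi2"], result["p_value"] = None, None
    return result
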