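"""Joint classification of DMR sites by methylation, chromatin and
expression direction.

A qualifying site is a (DMR, gene) pair where the DMR (a) is matched to a
differential ATAC peak (opening or closing, q < 0.05) and (b) overlaps the
promoter or gene body of a differentially expressed gene. Each site falls
in one of four combinations — (hypo, opening), (hypo, closing),
(hyper, opening), (hyper, closing) — crossed with the host gene's class.

A site is *concordant* when it follows the canonical inverse-methylation
pattern: hypo + opening in a fiber-preferred gene, or hyper + closing in
an epithelial-preferred gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import classify_degs
from .stats import chi2_2x2

COMBOS = (("hypo", "opening"), ("hypo", "closing"),
          ("hyper", "opening"), ("hyper", "closing"))


def classify_triple_sites(overlaps: pd.DataFrame, links: pd.DataFrame,
                          expression: pd.DataFrame,
                          scope: str = "promoter_and_genebody") -> pd.DataFrame:
    """Build the qualifying (DMR, gene) site table.

    ``overlaps`` comes from the chromatin module (best peak per DMR),
    ``links`` from the annotation module. A DMR matched only to a stable
    peak is excluded; so are genes that are not differentially expressed.
    """
    if scope not in ("promoter_and_genebody", "promoter_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if "deg_class" not in expression.columns:
        expression = classify_degs(expression)
    diff_peaks = overlaps[overlaps.peak_class.isin(["opening", "closing"])]
    use_links = links if scope == "promoter_and_genebody" else \
        links[links.location == "promoter"]
    sites = diff_peaks.merge(use_links, on="dmr_id")
    degs = expression[expression.deg_class != "not_de"][["gene_id", "deg_class"]]
    sites = sites.merge(degs, on="gene_id")
    sites = sites.rename(columns={"dmr_direction": "meth_direction",
                                  "peak_class": "chromatin_direction"})
    sites["combo"] = (sites.meth_direction + "_" + sites.chromatin_direction
                      + "_" + sites.deg_class.str.replace("_preferred", ""))
    sites["concordant"] = (
        ((sites.meth_direction == "hypo")
         & (sites.chromatin_direction == "opening")
         & (sites.deg_class == "fiber_preferred"))
        | ((sites.meth_direction == "hyper")
           & (sites.chromatin_direction == "closing")
           & (sites.deg_class == "epithelial_preferred"))
    )
    cols = ["dmr_id", "gene_id", "location", "meth_direction",
            "chromatin_direction", "deg_class", "combo", "concordant",
            "diff_methyl", "peak_log2fc"]
    return sites[cols].sort_values(["dmr_id", "gene_id"]).reset_index(drop=True)


def triple_association(sites: pd.DataFrame) -> dict:
    """2x2 association between host-gene class and site concordance.

    Rows: epithelial_preferred / fiber_preferred; columns: concordant /
    discordant. Pearson chi-square without continuity correction; skipped
    (None) on an empty margin.
    """
    if sites.empty:
        raise ValueError("no qualifying sites")
    table = np.zeros((2, 2), dtype=int)
    for i, dc in enumerate(("epithelial_preferred", "fiber_preferred")):
        sub = sites[sites.deg_class == dc]
        table[i, 0] = int(sub.concordant.sum())
        table[i, 1] = int((~sub.concordant).sum())
    out: dict = {
        "table": table.tolist(),
        "row_labels": ["epithelial_preferred", "fiber_preferred"],
        "col_labels": ["concordant", "discordant"],
        "n_sites": int(table.sum()),
        "combo_counts": sites.combo.value_counts().to_dict(),
        "n_distinct_dmrs": int(sites.dmr_id.nunique()),
    }
    try:
        chi2, p = chi2_2x2(table)
        out["chi2"], out["p_value"] = chi2, p
    except ValueError:
        out["chi2"], out["p_value"] = None, None
    return out


def per_gene_rollup(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-gene site counts by combination plus a concordant-site flag."""
    if sites.empty:
        return pd.DataFrame(columns=["gene_id", "deg_class", "n_sites",
                                     "has_concordant_site"])
    combo_counts = (sites.pivot_table(index="gene_id", columns="combo",
                                      values="dmr_id", aggfunc="count",
                                      fill_value=0)
                    .add_prefix("n_"))
    base = sites.groupby("gene_id").agg(
        deg_class=("deg_class", "first"),
        n_sites=("dmr_id", "count"),
        has_concordant_site=("concordant", "any"),
    )
    out = base.join(combo_counts).reset_index()
    return out.sort_values("gene_id").reset_index(drop=True)
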