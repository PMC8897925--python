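"""Domain objects shared across modules.

Tabular data (cytosine records, DMRs, peaks, expression) travel as pandas
DataFrames with documented column sets; structured per-entity objects live
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

Interval = tuple[int, int]

#: column set of a cytosine-record table
CYTOSINE_COLUMNS = ["chrom", "pos", "context", "group", "replicate", "n_meth", "n_total"]
#: column set of a DMR table
DMR_COLUMNS = [
    "chrom", "start", "end", "n_cg", "frac_sig",
    "mean_mu1", "mean_mu2", "diff_methyl", "direction",
]
#: column set of an expression table
EXPRESSION_COLUMNS = ["gene_id", "fpkm_group1", "fpkm_group2", "log2fc", "qvalue"]
#: column set of an ATAC peak table
PEAK_COLUMNS = ["chrom", "start", "end", "name", "log2fc", "qvalue"]


@dataclass
class GeneModel:
    """A strand-aware gene with exon structure and derived features.

    ``exons`` and ``cds`` are sorted lists of 0-based half-open intervals.
    The promoter is the ``promoter_upstream`` bp immediately 5' of the TSS
    on the gene's strand, clipped to the chromosome.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: empty gene span")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, upstream: int = 2000, chrom_length: Optional[int] = None) -> Interval:
        if self.strand == "+":
            s, e = self.start - upstream, self.start
        else:
            s, e = self.end, self.end + upstream
        s = max(0, s)
        if chrom_length is not None:
            e = min(e, chrom_length)
        return (s, max(s, e))

    @property
    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out

    @property
    def first_exon(self) -> Optional[Interval]:
        if not self.exons:
            return None
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def other_exons(self) -> list[Interval]:
        fe = self.first_exon
        return [iv for iv in self.exons if iv != fe]

    @property
    def first_intron(self) -> Optional[Interval]:
        introns = self.introns
        if not introns:
            return None
        return introns[0] if self.strand == "+" else introns[-1]

    @property
    def other_introns(self) -> list[Interval]:
        fi = self.first_intron
        return [iv for iv in self.introns if iv != fi]

    def _utr(self, five_prime: bool) -> list[Interval]:
        """Exonic sequence outside the CDS, on the requested side."""
        if not self.cds:
            return []
        cds_start = self.cds[0][0]
        cds_end = self.cds[-1][1]
        left_of_cds = five_prime if self.strand == "+" else not five_prime
        out = []
        for s, e in self.exons:
            if left_of_cds:
                lo, hi = s, min(e, cds_start)
            else:
                lo, hi = max(s, cds_end), e
            if lo < hi:
                out.append((lo, hi))
        return out

    @property
    def utr5(self) -> list[Interval]:
        return self._utr(five_prime=True)

    @property
    def utr3(self) -> list[Interval]:
        return self._utr(five_prime=False)


@dataclass
class MotifModel:
    """Position frequency matrix with background and derived log-odds.

    ``counts`` is a 4 x width array, rows in A, C, G, T order.
    """

    motif_id: str
    tf_name: str
    counts: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x width")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        col_sums = self.counts.sum(axis=0)
        zero = np.nonzero(col_sums == 0)[0]
        if zero.size:
            raise ValueError(
                f"{self.motif_id}: all-zero count column(s) at position(s) "
                f"{', '.join(map(str, zero.tolist()))}"
            )
        if self.background.shape != (4,) or (self.background <= 0).any():
            raise ValueError(f"{self.motif_id}: background must be 4 positive frequencies")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        from .motifs import pfm_to_pwm  # local import, avoids cycle

        return pfm_to_pwm(self.counts, self.pseudocount, self.background)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))
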