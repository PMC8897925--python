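"""Configuration objects for simulation and pipeline runs.

All genomic coordinates in this package are 0-based half-open. Group 1 is
the lens epithelial state, group 2 the fiber state; every log2 fold change
and methylation difference is oriented fiber/epithelial (group2 vs group1),
so positive ``diff_methyl`` means hypermethylated in fiber cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

GROUP1 = "epithelial"
GROUP2 = "fiber"

#: feature categories in decreasing annotation priority
CATEGORY_PRIORITY = (
    "promoter",
    "utr5",
    "first_exon",
    "first_intron",
    "other_exon",
    "other_intron",
    "utr3",
    "cgi",
    "cgi_shore",
    "repeat",
    "intergenic",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omic data generator.

    The generator emulates the structure of a two-state (epithelial vs
    fiber) study: replicate CpG methylomes with planted differentially
    methylated regions, a coupled differential-expression table and a
    coupled ATAC peak table, all on a toy genome.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 1
    cpg_rate: float = 0.02          # probability per bp that a CpG starts here
    n_genes: int = 200
    n_planted_dmrs: int = 120
    dmr_span_range: tuple[int, int] = (150, 400)
    effect_size: float = 0.4        # methylation-proportion shift in group 2
    base_methylation: float = 0.5
    dispersion_phi: float = 0.1     # beta-binomial overdispersion in [0, 1)
    coverage_mean: float = 30.0     # mean reads per CpG per replicate
    n_replicates_per_group: int = 3
    expr_coupling_slope: float = -2.5   # log2FC units per unit diff.methyl
    expr_noise_sd: float = 2.0
    atac_coupling_slope: float = -2.5
    atac_noise_sd: float = 0.6
    seed: int = 0

    # secondary knobs (kept out of the core signature above)
    hyper_fraction: float = 0.5     # fraction of planted DMRs methylated in fiber
    dmr_in_gene_fraction: float = 0.85  # planted DMRs targeted at promoters/bodies
    cgi_rate_multiplier: float = 5.0
    n_cgis: Optional[int] = None    # default: max(4, n_genes // 3)
    n_repeats: Optional[int] = None  # default: max(4, n_genes // 4)
    n_background_peaks: Optional[int] = None  # default: n_planted_dmrs // 2
    deg_sig_prob: float = 0.9       # P(q < 0.05 | |log2FC| > 0.4) in synthetic tables
    dmr_min_separation: int = 500   # bp between planted DMRs (keeps them distinct)
    dmr_min_cpgs: int = 6           # CpG-density floor for planted regions

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_chroms <= 0:
            raise ValueError("genome_length and n_chroms must be positive")
        if not 0.0 <= self.cpg_rate < 0.5:
            raise ValueError("cpg_rate must be in [0, 0.5)")
        if not 0.0 <= self.base_methylation <= 1.0:
            raise ValueError("base_methylation must be in [0, 1]")
        if not 0.0 <= self.dispersion_phi < 1.0:
            raise ValueError("dispersion_phi must be in [0, 1)")
        lo, hi = self.dmr_span_range
        if lo <= 0 or hi < lo:
            raise ValueError("dmr_span_range must be a positive (lo, hi) pair")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        for name in ("hyper_fraction", "dmr_in_gene_fraction", "deg_sig_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_cgis_effective(self) -> int:
        return self.n_cgis if self.n_cgis is not None else max(4, self.n_genes // 3)

    @property
    def n_repeats_effective(self) -> int:
        return self.n_repeats if self.n_repeats is not None else max(4, self.n_genes // 4)

    @property
    def n_background_peaks_effective(self) -> int:
        if self.n_background_peaks is not None:
            return self.n_background_peaks
        return max(1, self.n_planted_dmrs // 2)


@dataclass
class DmrParams:
    """Region-calling parameters.

    Defaults are the standard DSS-style settings for two-group WGBS
    comparisons: 200 bp smoothing, site p < 1e-5, regions >= 50 bp with
    >= 3 CpGs, merge distance 100 bp, and at least half the CpGs in a
    region individually significant.
    """

    smoothing_span: int = 200
    delta: float = 0.0
    p_threshold: float = 1e-5
    minlen: int = 50
    min_cg: int = 3
    dis_merge: int = 100
    pct_sig: float = 0.5
    dispersion_prior_weight: float = 10.0

    def __post_init__(self) -> None:
        if min(self.smoothing_span, self.minlen, self.min_cg, self.dis_merge) < 0:
            raise ValueError("DmrParams distances/counts must be non-negative")
        if self.delta < 0 or self.p_threshold <= 0:
            raise ValueError("delta must be >= 0 and p_threshold > 0")
        if not 0.0 < self.pct_sig <= 1.0:
            raise ValueError("pct_sig must be in (0, 1]")
        if self.dispersion_prior_weight < 0:
            raise ValueError("dispersion_prior_weight must be non-negative")


@dataclass
class AnnotationParams:
    promoter_upstream: int = 2000
    proximal_promoter: int = 1000
    cgi_shore: int = 2000
    category_priority: Sequence[str] = CATEGORY_PRIORITY

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.proximal_promoter, self.cgi_shore) <= 0:
            raise ValueError("annotation distances must be positive")
        if sorted(self.category_priority) != sorted(CATEGORY_PRIORITY):
            raise ValueError(
                "category_priority must cover every category exactly once"
            )


@dataclass
class Thresholds:
    """Significance cutoffs used across integration stages (strict inequalities)."""

    deg_log2fc: float = 0.4
    deg_q: float = 0.05
    atac_q: float = 0.05
    tf_fpkm: float = 1.0
    motif_p: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.deg_log2fc, self.deg_q, self.atac_q, self.tf_fpkm, self.motif_p) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineConfig:
    """File inputs plus parameters for a full pipeline run."""

    genome: Optional[str] = None
    genes: Optional[str] = None
    gene_format: str = "gtf"        # "gtf" or "bed12"
    methylation_group1: Sequence[str] = field(default_factory=list)
    methylation_group2: Sequence[str] = field(default_factory=list)
    cgi: Optional[str] = None
    repeats: Optional[str] = None
    expression: Optional[str] = None
    atac: Optional[str] = None
    motifs: Optional[str] = None
    dmr: DmrParams = field(default_factory=DmrParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        meth = paths.get("methylation", {})
        return cls(
            genome=paths.get("genome"),
            genes=paths.get("genes"),
            gene_format=paths.get("gene_format", "gtf"),
            methylation_group1=list(meth.get("group1", [])),
            methylation_group2=list(meth.get("group2", [])),
            cgi=paths.get("cgi"),
            repeats=paths.get("repeats"),
            expression=paths.get("expression"),
            atac=paths.get("atac"),
            motifs=paths.get("motifs"),
            dmr=DmrParams(**raw.get("dmr", {})),
            annotation=AnnotationParams(**raw.get("annotation", {})),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "paths": {
                "genome": self.genome,
                "genes": self.genes,
                "gene_format": self.gene_format,
                "methylation": {
                    "group1": list(self.methylation_group1),
                    "group2": list(self.methylation_group2),
                },
                "cgi": self.cgi,
                "repeats": self.repeats,
                "expression": self.expression,
                "atac": self.atac,
                "motifs": self.motifs,
            },
            "dmr": dataclasses.asdict(self.dmr),
            "annotation": {
                "promoter_upstream": self.annotation.promoter_upstream,
                "proximal_promoter": self.annotation.proximal_promoter,
                "cgi_shore": self.annotation.cgi_shore,
                "category_priority": list(self.annotation.category_priority),
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
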