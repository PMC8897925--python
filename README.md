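# lensepi

Integrative epigenomic analysis of lens epithelial-to-fiber
differentiation: whole-genome bisulfite methylation changes linked to
chromatin accessibility and gene-expression changes, with a synthetic
multi-omic data generator for end-to-end validation.

During lens development, anterior epithelial cells differentiate into
elongated fiber cells, a transition accompanied by genome-wide DNA
methylation remodelling. `lensepi` implements the computational side of a
multi-omics comparison of the two cell states:

1. **DMR calling** — a smoothed beta-binomial two-group test on replicate
   CpG count tables. Per-site methylation levels are pooled over a 200 bp
   window across replicates; the across-replicate overdispersion φ is
   estimated by the method of moments and shrunk toward the genome-wide
   median; the group difference is tested with a Wald statistic using the
   beta-binomial variance Var = μ(1−μ)(1 + (N−1)φ)/N summed over the
   replicate-site read chunks in the window. Significant CpGs
   (p < 10⁻⁵) are chained into regions (merge distance < 100 bp) that
   must span ≥ 50 bp, contain ≥ 3 CpGs and have ≥ 50 % significant CpGs.
2. **Genomic annotation** — strand-aware assignment of each region to
   promoter (−2 kb of the TSS), UTRs, first/other exon/intron, CpG
   island/shore, repeat or intergenic, with a length-matched
   random-placement null and a χ² comparison of the hyper- vs
   hypomethylated distributions.
3. **Expression integration** — per-gene average diff.methyl
   (fiber − epithelial) over linked regions, Pearson correlation with the
   gene's log₂FC, and the 2×2 quadrant association (methylation up/down ×
   fiber-/epithelial-preferred; Pearson χ², no continuity correction).
4. **Chromatin integration** — ≥ 1 bp overlap with ATAC peaks classed
   opening / closing / stable, plus the methylation-accessibility
   correlation.
5. **Triple integration** — joint classification of (region, gene) sites
   by methylation, accessibility and expression direction; a site is
   *concordant* when hypo + opening sits in a fiber-preferred gene or
   hyper + closing in an epithelial-preferred gene.
6. **Motif analysis** — region sequences split into demethylated-in-fiber
   / fiber-gene and methylated-in-fiber / epithelial-gene sets, scanned
   with JASPAR PWMs using exact discretised score-distribution p-values,
   enrichment vs shuffled backgrounds by one-sided Fisher tests with BH
   adjustment, and filtering by transcription-factor expression
   (total FPKM ≥ 1).

All of it is exercised on a first-class synthetic generator
(`lensepi.synthetic`) that plants DMRs with known effects into replicate
beta-binomial methylomes and injects tunable couplings into the
expression and ATAC tables, so recovery of every headline statistic can
be measured against ground truth.

## Worked example

```bash
lensepi simulate --outdir demo --seed 11 --genome-length 2000000 \
    --n-genes 150 --n-dmrs 100
lensepi report --config demo/pipeline_config.yaml --outdir demo_out
```

The first command writes a toy study (genome FASTA, GTF, CGI/repeat BED,
six Bismark-like coverage files, expression TSV, ATAC peak BED) plus a
ready pipeline config; the second runs every stage and writes
`demo_out/summary.json`. With the seed above the summary contains:

```
dmr:        88 regions (48 hyper, 40 hypo) from 898 significant CpGs of 42,547 tested
annotation: promoter 20, first_exon 16, first_intron 12, other_exon 24, ...
            random-placement null chi2 = 95.5, p = 3.5e-17
expression: r = -0.42 (n = 60 DEGs with >= 1 region), quadrant table
            [[24, 9], [7, 20]], chi2 = 13.0, p = 3.1e-4
chromatin:  r = -0.85 between diff.methyl and peak log2FC (n = 88)
```

Read: of 100 planted regions, 88 were called; methylation gains in fiber
cells sit in genes whose expression falls (negative correlation, quadrant
association), and regions losing methylation coincide with chromatin that
opens — the inverse-methylation pattern the pipeline is designed to
quantify. The region table is in `demo_out/dmrs.tsv`, per-gene summaries,
site tables, gene lists and motif enrichments alongside it.

The same stages are available programmatically (`lensepi.dmr`,
`lensepi.annotation`, `lensepi.expression`, `lensepi.chromatin`,
`lensepi.triple`, `lensepi.motifs`) on pandas DataFrames.

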