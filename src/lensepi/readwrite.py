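"""Readers and writers for every external format the pipeline touches.

Internal coordinates are uniformly 0-based half-open; the GTF reader/writer
is the only place a +-1 conversion happens. The methylation-count dialect is
a Bismark-coverage-like TSV with 0-based half-open coordinates:

    chrom  start  end  pct_methylated  count_methylated  count_unmethylated

with an optional seventh column giving the cytosine context (default CG).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, MotifModel
from .synthetic import SyntheticBundle

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# methylation counts


def read_methylation_counts(
    paths_group1: Sequence[str | Path],
    paths_group2: Sequence[str | Path],
    group_names: tuple[str, str] = ("epithelial", "fiber"),
) -> pd.DataFrame:
    """Read Bismark-coverage-like TSVs into one cytosine-record table.

    One file per replicate; replicate index is the position in each list.
    Rows are validated (n_meth <= n_total) and sorted by (chrom, pos);
    duplicate (chrom, pos, group, replicate) rows are rejected.
    """
    frames = []
    for group, paths in zip(group_names, (paths_group1, paths_group2)):
        for rep, path in enumerate(paths):
            frames.append(_read_one_coverage(path, group, rep))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "context", "group",
                                     "replicate", "n_meth", "n_total"])
    df = pd.concat(frames, ignore_index=True)
    dup = df.duplicated(subset=["chrom", "pos", "group", "replicate"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ParseError(
            f"duplicate cytosine record at {first.chrom}:{first.pos} "
            f"({first.group} replicate {first.replicate})"
        )
    return df.sort_values(["chrom", "pos", "group", "replicate"]).reset_index(drop=True)


def _read_one_coverage(path: str | Path, group: str, replicate: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (6, 7):
                raise ParseError(f"{path}:{lineno}: expected 6 or 7 columns, "
                                 f"got {len(parts)}")
            try:
                chrom = parts[0]
                pos = int(parts[1])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed line: {exc}") from exc
            context = parts[6] if len(parts) == 7 else "CG"
            if pos < 0:
                raise ParseError(f"{path}:{lineno}: negative position")
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            rows.append((chrom, pos, context, group, replicate,
                         n_meth, n_meth + n_unmeth))
    if not rows:
        log.warning("empty methylation file: %s", path)
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "group",
                                       "replicate", "n_meth", "n_total"])


def write_methylation_counts(records: pd.DataFrame, path: str | Path,
                             group: str, replicate: int) -> None:
    sub = records[(records.group == group) & (records.replicate == replicate)]
    with open(path, "w") as fh:
        for row in sub.itertuples():
            pct = 100.0 * row.n_meth / row.n_total if row.n_total else 0.0
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pct:.6g}\t"
                     f"{row.n_meth}\t{row.n_total - row.n_meth}\t{row.context}\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene model format: {format!r}")


def _read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a minimal GTF (gene/exon/CDS features, gene_id attribute).

    GTF is 1-based inclusive; internal coordinates are 0-based half-open.
    """
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            s, e = int(start) - 1, int(end)  # the only +-1 boundary
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if gid not in spans and gid not in exons:
                order.append(gid)
            if feature == "gene":
                spans[gid] = (chrom, strand, s, e)
            elif feature == "exon":
                exons.setdefault(gid, []).append((s, e))
            elif feature == "CDS":
                cds.setdefault(gid, []).append((s, e))
    out = []
    for gid in order:
        ex = sorted(exons.get(gid, []))
        if gid in spans:
            chrom, strand, s, e = spans[gid]
        elif ex:
            chrom = strand = None  # no gene line: infer from exons (unknown strand)
            raise ParseError(f"{path}: gene {gid} has exons but no gene line")
        else:
            continue
        for xs, xe in ex:
            if xs < s or xe > e:
                raise ParseError(
                    f"{path}: exon [{xs},{xe}) of {gid} outside gene span [{s},{e})")
        out.append(GeneModel(gid, chrom, strand, s, e,
                             exons=ex or [(s, e)], cds=sorted(cds.get(gid, []))))
    return out


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field.split(" ", 1)[1].strip().strip('"')
    return None


def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              source: str = "lensepi") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
            for s, e in g.cds:
                fh.write(f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t0\t{attrs}\n")


def _read_bed12(path: str | Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            thick_s, thick_e = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + off, start + off + sz)
                     for off, sz in zip(starts, sizes)]
            cds = []
            if thick_s < thick_e:
                for s, e in exons:
                    lo, hi = max(s, thick_s), min(e, thick_e)
                    if lo < hi:
                        cds.append((lo, hi))
            out.append(GeneModel(name, chrom, strand, start, end,
                                 exons=exons, cds=cds))
    return out


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            thick_s = g.cds[0][0] if g.cds else g.start
            thick_e = g.cds[-1][1] if g.cds else g.start
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{thick_s}\t{thick_e}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")


# ---------------------------------------------------------------------------
# expression, peaks, plain BED


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV.

    Requires gene_id, fpkm_group1, fpkm_group2 and qvalue columns; log2fc
    (fiber/epi) is computed from the FPKM columns when absent (requires
    both FPKMs > 0). q-values of "NA" become NaN and are retained.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     na_values=["NA", "na", ""])
    needed = {"gene_id", "fpkm_group1", "fpkm_group2"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if "qvalue" not in df.columns:
        raise ParseError(f"{path}: missing column(s) ['qvalue']")
    if df.gene_id.duplicated().any():
        dup = df.gene_id[df.gene_id.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    if "log2fc" not in df.columns:
        if ((df.fpkm_group1 <= 0) | (df.fpkm_group2 <= 0)).any():
            raise ParseError(
                f"{path}: cannot derive log2fc with non-positive FPKM values")
        df["log2fc"] = np.log2(df.fpkm_group2 / df.fpkm_group1)
    return df[["gene_id", "fpkm_group1", "fpkm_group2", "log2fc", "qvalue"]]


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_atac_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED6+2 peak table (chrom, start, end, name, score, strand,
    log2fc, qvalue); 0-based half-open, log2FC oriented fiber/epi."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 columns (BED6+2)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            rows.append((chrom, start, end, name, float(parts[6]), float(parts[7])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "log2fc", "qvalue"])


def write_atac_peaks(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t.\t"
                     f"{row.log2fc:.6g}\t{row.qvalue:.6g}\n")


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            out.setdefault(parts[0], []).append((start, end))
    for iv in out.values():
        iv.sort()
    return out


def write_bed_intervals(intervals: dict[str, list[tuple[int, int]]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# FASTA and JASPAR


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str | Path,
                       width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_jaspar_pfms(path: str | Path) -> list[MotifModel]:
    """Parse a JASPAR-format PFM file (4 count rows per motif) into
    MotifModel objects. Matrix IDs and TF names are both captured."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(MotifModel(motif_id=m.matrix_id or m.name, tf_name=m.name,
                              counts=counts))
    return out


def write_jaspar_pfms(motifs_list: Iterable[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs_list:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:6.0f}" for v in m.counts[i])
                fh.write(f"{base} [{vals} ]\n")


def write_bedgraph(df: pd.DataFrame, value_col: str, path: str | Path) -> None:
    """Write per-position values (chrom, pos, <value_col>) as bedGraph."""
    with open(path, "w") as fh:
        for row in df.itertuples():
            v = getattr(row, value_col)
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{v:.4g}\n")


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """BED4 export of a DMR table with diff_methyl as the name field."""
    with open(path, "w") as fh:
        for row in dmrs.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{row.direction}:{row.diff_methyl:.4f}\n")


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_fasta_sequences(seqs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# DMR tables and bundle export


def write_dmr_table(dmrs: pd.DataFrame, path: str | Path) -> None:
    dmrs.to_csv(path, sep="\t", index=False)


def read_dmr_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, object]:
    """Write a full synthetic study to disk; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    write_genome_fasta(bundle.annotation.genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    write_gtf(bundle.annotation.genes, outdir / "genes.gtf")
    paths["genes"] = str(outdir / "genes.gtf")
    write_bed12(bundle.annotation.genes, outdir / "genes.bed12")
    write_bed_intervals(bundle.annotation.cgis, outdir / "cgi.bed")
    paths["cgi"] = str(outdir / "cgi.bed")
    write_bed_intervals(bundle.annotation.repeats, outdir / "repeats.bed")
    paths["repeats"] = str(outdir / "repeats.bed")
    meth: dict[str, list[str]] = {"group1": [], "group2": []}
    for key, group in (("group1", "epithelial"), ("group2", "fiber")):
        for rep in range(bundle.config.n_replicates_per_group):
            p = outdir / f"meth_{group}_rep{rep}.cov"
            write_methylation_counts(bundle.records, p, group, rep)
            meth[key].append(str(p))
    paths["methylation"] = meth
    write_expression_table(bundle.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    write_atac_peaks(bundle.peaks, outdir / "atac_peaks.bed")
    paths["atac"] = str(outdir / "atac_peaks.bed")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")
    bundle.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    return paths
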