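"""Feature annotation: context calls, category priority, gene linking,
random-placement null and hyper/hypo comparison."""

import numpy as np
import pandas as pd
import pytest

from lensepi.config import AnnotationParams
from lensepi import annotation as A
from lensepi.models import GeneModel

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# context classification


@pytest.mark.parametrize("seq,pos,strand,expected", [
    ("ACGT", 1, "+", "CG"),
    ("CAG", 0, "+", "CHG"),
    ("CAT", 0, "+", "CHH"),
    ("ACGT", 2, "-", "CG"),      # G at 2 is C on minus; 3' base is G (comp C)
    ("AT", 0, "+", "not_C"),
    ("TTC", 2, "+", "CHH_trunc"),
    ("CTA", 0, "+", "CHH"),
])
def test_context_definitions(seq, pos, strand, expected):
    assert A.classify_context(seq, pos, strand) == expected


def test_context_matches_reverse_complement_oracle():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    rc = revcomp(seq)
    n = len(seq)
    for pos in range(n):
        minus = A.classify_context(seq, pos, "-")
        # oracle: classify on the reverse complement's plus strand
        plus_on_rc = A.classify_context(rc, n - 1 - pos, "+")
        assert minus == plus_on_rc


# ---------------------------------------------------------------------------
# category priority


def _toy_index():
    genes = [
        GeneModel("gA", "chr1", "+", 10_000, 16_000,
                  exons=[(10_000, 11_000), (12_000, 13_000), (15_000, 16_000)],
                  cds=[(10_300, 11_000), (12_000, 13_000), (15_000, 15_500)]),
        GeneModel("gB", "chr1", "-", 20_000, 24_000,
                  exons=[(20_000, 21_000), (23_000, 24_000)],
                  cds=[(20_400, 21_000), (23_000, 23_600)]),
    ]
    cgis = {"chr1": [(40_000, 40_600)]}
    repeats = {"chr1": [(50_000, 51_000), (8_500, 8_700)]}
    return genes, cgis, repeats, A.FeatureIndex(
        genes, cgis, repeats, {"chr1": 100_000})


def test_promoter_outranks_other_features():
    genes, _, _, index = _toy_index()
    # gA promoter is [8000, 10000); also overlaps a repeat at [8500, 8700)
    assert index.query("chr1", 8600, 8700) == "promoter"


def test_interval_overlapping_nothing_is_intergenic():
    *_, index = _toy_index()
    assert index.query("chr1", 70_000, 70_100) == "intergenic"


def test_minus_strand_promoter_is_downstream_in_coordinates():
    *_, index = _toy_index()
    # gB spans [20000, 24000) on '-': promoter is [24000, 26000)
    assert index.query("chr1", 25_000, 25_050) == "promoter"
    assert index.query("chr1", 19_500, 19_600) != "promoter"


def test_off_chromosome_query_rejected():
    *_, index = _toy_index()
    with pytest.raises(ValueError):
        index.query("chr1", 99_990, 100_010)
    with pytest.raises(KeyError):
        index.query("chrX", 0, 10)


def _gene_features_oracle(g: GeneModel, up=2000):
    """Independent re-derivation of per-gene features from primary fields."""
    feats = []
    if g.strand == "+":
        feats.append(("promoter", max(0, g.start - up), g.start))
        exon_order = g.exons
    else:
        feats.append(("promoter", g.end, g.end + up))
        exon_order = g.exons[::-1]
    for k, (s, e) in enumerate(exon_order):
        feats.append(("first_exon" if k == 0 else "other_exon", s, e))
    introns = [(a[1], b[0]) for a, b in zip(g.exons, g.exons[1:])]
    intron_order = introns if g.strand == "+" else introns[::-1]
    for k, (s, e) in enumerate(intron_order):
        feats.append(("first_intron" if k == 0 else "other_intron", s, e))
    if g.cds:
        lo, hi = g.cds[0][0], g.cds[-1][1]
        for s, e in g.exons:
            left = (s, min(e, lo))
            right = (max(s, hi), e)
            if left[0] < left[1]:
                feats.append(("utr5" if g.strand == "+" else "utr3", *left))
            if right[0] < right[1]:
                feats.append(("utr3" if g.strand == "+" else "utr5", *right))
    return feats


def test_random_intervals_match_brute_force_annotation(small_bundle):
    ann = small_bundle.annotation
    params = AnnotationParams()
    index = A.FeatureIndex(ann.genes, ann.cgis, ann.repeats, ann.chrom_sizes,
                           params)
    feats: dict[str, list] = {}
    for g in ann.genes:
        for cat, s, e in _gene_features_oracle(g, params.promoter_upstream):
            feats.setdefault(g.chrom, []).append((cat, s, e))
    for chrom, ivs in ann.cgis.items():
        for s, e in ivs:
            feats.setdefault(chrom, []).append(("cgi", s, e))
            feats[chrom].append(("cgi_shore", max(0, s - 2000), s))
            feats[chrom].append(
                ("cgi_shore", e, min(e + 2000, ann.chrom_sizes[chrom])))
    for chrom, ivs in ann.repeats.items():
        for s, e in ivs:
            feats.setdefault(chrom, []).append(("repeat", s, e))

    rng = np.random.default_rng(1)
    chrom = "chr1"
    size = ann.chrom_sizes[chrom]
    starts = rng.integers(0, size - 500, size=1000)
    lens = rng.integers(1, 500, size=1000)
    got = index.query_many(chrom, starts, starts + lens)
    prio = list(params.category_priority)
    for s, L, cat in zip(starts, lens, got):
        hits = {c for c, fs, fe in feats.get(chrom, [])
                if fs < s + L and fe > s}
        expected = next((c for c in prio if c in hits), "intergenic")
        assert cat == expected, (s, L, cat, expected)


# ---------------------------------------------------------------------------
# DMR -> gene links


def _dmr_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "diff_methyl",
                                       "direction"])


def test_minus_strand_promoter_linking():
    g = GeneModel("g1", "chr1", "-", 5000, 8000, exons=[(5000, 8000)])
    far = _dmr_df([("chr1", 100, 200, -0.3, "hypo")])
    near = _dmr_df([("chr1", 8100, 8150, -0.3, "hypo")])
    assert A.map_dmr_to_genes(far, [g]).empty
    links = A.map_dmr_to_genes(near, [g])
    assert len(links) == 1
    assert links.location.iloc[0] == "promoter"


def test_dmr_spanning_two_gene_bodies_links_twice():
    g1 = GeneModel("g1", "chr1", "+", 1000, 2000, exons=[(1000, 2000)])
    g2 = GeneModel("g2", "chr1", "-", 2100, 3000, exons=[(2100, 3000)])
    dmrs = _dmr_df([("chr1", 1900, 2200, 0.3, "hyper")])
    links = A.map_dmr_to_genes(dmrs, [g1, g2])
    assert sorted(links.gene_id) == ["g1", "g2"]


def test_promoter_precedence_within_gene():
    g = GeneModel("g1", "chr1", "+", 5000, 8000, exons=[(5000, 8000)])
    dmrs = _dmr_df([("chr1", 4900, 5100, 0.3, "hyper")])  # spans both
    links = A.map_dmr_to_genes(dmrs, [g])
    assert links.location.tolist() == ["promoter"]


def test_links_match_brute_force_oracle(small_bundle):
    ann = small_bundle.annotation
    rng = np.random.default_rng(2)
    size = ann.chrom_sizes["chr1"]
    starts = rng.integers(0, size - 400, size=1000)
    lens = rng.integers(50, 400, size=1000)
    dmrs = _dmr_df([("chr1", int(s), int(s + L), 0.1, "hyper")
                    for s, L in zip(starts, lens)])
    links = A.map_dmr_to_genes(dmrs, ann.genes, chrom_sizes=ann.chrom_sizes)
    got = {(r.dmr_id, r.gene_id): r.location for r in links.itertuples()}
    expected = {}
    for i, d in dmrs.iterrows():
        for g in ann.genes:
            if g.chrom != d.chrom:
                continue
            ps, pe = g.promoter(2000, ann.chrom_sizes[g.chrom])
            in_prom = d.start < pe and ps < d.end
            in_body = d.start < g.end and g.start < d.end
            if in_prom:
                expected[(i, g.gene_id)] = "promoter"
            elif in_body:
                expected[(i, g.gene_id)] = "genebody"
    assert got == expected


def test_promoter_mirror_symmetry():
    size = 10_000
    g = GeneModel("g", "chr1", "+", 3000, 5000, exons=[(3000, 5000)])
    mirrored = GeneModel("g", "chr1", "-", size - 5000, size - 3000,
                         exons=[(size - 5000, size - 3000)])
    ps, pe = g.promoter(2000, size)
    ms, me = mirrored.promoter(2000, size)
    assert (ms, me) == (size - pe, size - ps)


# ---------------------------------------------------------------------------
# random null + hyper/hypo


def test_null_draw_lengths_come_from_observed_multiset(small_bundle):
    ann = small_bundle.annotation
    lengths = np.array([120, 251, 372])
    rng = np.random.default_rng(3)
    drawn = []
    for chrom, s, e in A.draw_random_intervals(lengths, ann.chrom_sizes,
                                               500, rng):
        drawn.extend((e - s).tolist())
    assert set(drawn) <= set(lengths.tolist())
    assert len(drawn) == 500


def test_single_category_genome_has_zero_percent_difference():
    size = {"chr1": 100_000}
    index = A.FeatureIndex([], {}, {"chr1": [(0, 100_000)]}, size)
    dmrs = pd.DataFrame({"chrom": "chr1", "start": [10, 500, 900],
                         "end": [110, 650, 1100]})
    dmrs = A.annotate_dmrs(dmrs, index)
    assert (dmrs.category == "repeat").all()
    res = A.random_null_test(dmrs, index, n_draws=50, seed=0)
    assert res["percent_difference"]["repeat"] == pytest.approx(0.0)


def test_identical_direction_distributions_give_zero_chi2():
    df = pd.DataFrame({"category": ["promoter"] * 10 + ["first_exon"] * 10,
                       "direction": (["hyper", "hypo"] * 10)})
    res = A.compare_hyper_hypo_distributions(df)
    assert res["chi2"] == pytest.approx(0.0)
    assert res["p_value"] == pytest.approx(1.0)


def test_perfect_association_closed_form():
    df = pd.DataFrame({"category": ["promoter"] * 10 + ["first_exon"] * 10,
                       "direction": ["hyper"] * 10 + ["hypo"] * 10})
    res = A.compare_hyper_hypo_distributions(df)
    assert res["chi2"] == pytest.approx(20.0)
    assert res["p_value"] == pytest.approx(7.744e-6, rel=1e-3)


def test_missing_direction_is_an_error():
    df = pd.DataFrame({"category": ["promoter"] * 5,
                       "direction": ["hyper"] * 5})
    with pytest.raises(ValueError, match="hypo"):
        A.compare_hyper_hypo_distributions(df)


def test_direction_column_sums_conserved():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({
        "category": rng.choice(["promoter", "cgi", "repeat"], 200),
        "direction": rng.choice(["hyper", "hypo"], 200, p=[0.8, 0.2]),
    })
    res = A.compare_hyper_hypo_distributions(df)
    totals = {"hyper": 0, "hypo": 0}
    for counts in res["table"].values():
        totals["hyper"] += counts["hyper"]
        totals["hypo"] += counts["hypo"]
    assert totals["hyper"] == int((df.direction == "hyper").sum())
    assert totals["hypo"] == int((df.direction == "hypo").sum())


def test_category_partition_property(small_bundle):
    ann = small_bundle.annotation
    index = A.FeatureIndex(ann.genes, ann.cgis, ann.repeats, ann.chrom_sizes)
    rng = np.random.default_rng(5)
    starts = rng.integers(0, ann.chrom_sizes["chr1"] - 300, 400)
    dmrs = pd.DataFrame({"chrom": "chr1", "start": starts,
                         "end": starts + 200})
    out = A.annotate_dmrs(dmrs, index)
    assert out.category.value_counts().sum() == len(dmrs)
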