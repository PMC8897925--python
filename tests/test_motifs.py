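"""PWM construction, exact p-value table, scanning, shuffles, enrichment
and TF-expression filtering."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from lensepi.models import MotifModel
from lensepi import motifs as M


def test_uniform_counts_uniform_background_zero_matrix():
    lo = M.pfm_to_pwm(np.full((4, 5), 10.0))
    assert np.allclose(lo, 0.0)


def test_log_odds_direct_arithmetic():
    lo = M.pfm_to_pwm(np.array([[10.0], [0.0], [0.0], [0.0]]))
    assert lo[0, 0] == pytest.approx(np.log2((10.25 / 11) / 0.25), abs=1e-6)
    assert lo[0, 0] == pytest.approx(1.898, abs=1e-3)


def test_doubling_counts_barely_changes_log_odds():
    rng = np.random.default_rng(0)
    counts = rng.integers(2, 40, size=(4, 6)).astype(float)
    a = M.pfm_to_pwm(counts)
    b = M.pfm_to_pwm(2 * counts)
    assert np.abs(a - b).max() < 0.1


def test_zero_background_rejected():
    with pytest.raises(ValueError):
        M.pfm_to_pwm(np.full((4, 2), 1.0), background=np.array([0, .5, .25, .25]))


def test_width_one_table_by_hand():
    # scores (2, 0, 0, 0) in bits, uniform background
    lo = np.array([[2.0], [0.0], [0.0], [0.0]])
    tab = M.pwm_score_pvalue_table(lo)
    s2 = int(round(2.0 / tab.bin_width))
    assert tab.pvalue_int(np.array([s2]))[0] == pytest.approx(0.25)
    assert tab.pvalue_int(np.array([0]))[0] == pytest.approx(1.0)


def test_minimum_score_has_p_one():
    rng = np.random.default_rng(1)
    lo = rng.normal(0, 2, size=(4, 4))
    tab = M.pwm_score_pvalue_table(lo)
    assert tab.pvalue_int(np.array([tab.offset]))[0] == pytest.approx(1.0)
    assert np.all(np.diff(tab.tail) <= 1e-15)  # tail non-increasing


@pytest.mark.parametrize("width", [2, 3, 5])
def test_dp_matches_enumeration_exactly(width):
    rng = np.random.default_rng(width)
    lo = rng.normal(0, 1.5, size=(4, width))
    bg = rng.dirichlet(np.ones(4) * 5)
    tab = M.pwm_score_pvalue_table(lo, bg)
    probs: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=width):
        s = int(sum(tab.qmatrix[b, j] for j, b in enumerate(word)))
        probs[s] = probs.get(s, 0.0) + float(np.prod([bg[b] for b in word]))
    for s in sorted(probs):
        enum_tail = sum(p for t, p in probs.items() if t >= s)
        assert tab.pvalue_int(np.array([s]))[0] == pytest.approx(
            enum_tail, abs=1e-12)


def test_consensus_sequence_yields_hit_at_offset_zero():
    counts = np.zeros((4, 6))
    for j, b in enumerate("TGACGT"):
        counts["ACGT".index(b), j] = 30
    m = MotifModel("m1", "TF1", counts + 0.1)
    hits = M.call_motif_hits([("s1", "TGACGT")], m, p_threshold=1e-2,
                             background=np.full(4, 0.25))
    fw = hits[hits.strand == "+"]
    assert (fw.offset == 0).any()


def test_sequence_shorter_than_motif_yields_no_hits():
    counts = np.full((4, 8), 5.0)
    m = MotifModel("m1", "TF1", counts)
    hits = M.call_motif_hits([("s1", "ACGT")], m, p_threshold=1.0)
    assert hits.empty


def test_hits_mirror_on_reverse_complement():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 25, size=(4, 7)).astype(float) + 0.5
    m = MotifModel("m1", "TF1", counts)
    comp = str.maketrans("ACGT", "TGCA")
    bg = np.full(4, 0.25)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), 60))
        rc = seq.translate(comp)[::-1]
        h1 = M.call_motif_hits([("s", seq)], m, 1e-2, background=bg)
        h2 = M.call_motif_hits([("s", rc)], m, 1e-2, background=bg)
        flip = {"+": "-", "-": "+"}
        mapped = sorted((len(seq) - 7 - o, flip[st], round(sc, 6))
                        for o, st, sc in zip(h2.offset, h2.strand, h2.score))
        direct = sorted((o, st, round(sc, 6))
                        for o, st, sc in zip(h1.offset, h1.strand, h1.score))
        assert mapped == direct


def test_permissive_threshold_reports_every_offset():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 20, size=(4, 5)).astype(float)
    m = MotifModel("m1", "TF1", counts)
    seq = "ACGTACGTACGTACGTACGT"
    hits = M.call_motif_hits([("s", seq)], m, p_threshold=1.5,
                             background=np.full(4, 0.25))
    n_offsets = len(seq) - 5 + 1
    assert len(hits) == 2 * n_offsets  # both strands, every offset


def test_homopolymer_shuffle_is_identity():
    for mode in ("mononucleotide", "dinucleotide"):
        out = M.shuffle_sequences([("s", "AAAA")], mode=mode, seed=0)
        assert out[0][1] == "AAAA"


def test_shuffle_preserves_base_composition():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), 500))
    for mode in ("mononucleotide", "dinucleotide"):
        shuf = M.shuffle_sequences([("s", seq)], mode=mode, seed=1)[0][1]
        assert Counter(shuf) == Counter(seq)
        assert len(shuf) == len(seq)


def test_dinucleotide_shuffle_preserves_adjacency_counts():
    rng = np.random.default_rng(5)
    for trial in range(5):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        shuf = M.shuffle_sequences([("s", seq)], mode="dinucleotide",
                                   seed=trial)[0][1]
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
        assert shuf != seq  # astronomically unlikely to be unchanged


def test_shuffle_deterministic_under_seed():
    seqs = [("a", "ACGTACGGTTAACC"), ("b", "GGGTTTAAACCCGG")]
    x = M.shuffle_sequences(seqs, seed=7)
    y = M.shuffle_sequences(seqs, seed=7)
    assert x == y


def test_fisher_closed_form_for_clean_separation():
    counts = np.zeros((4, 8))
    for j, b in enumerate("TGACGTCA"):
        counts["ACGT".index(b), j] = 30
    planted = MotifModel("mP", "TFP", counts + 0.1)
    rng = np.random.default_rng(6)
    primary = []
    for i in range(10):
        s = "".join(rng.choice(list("ACGT"), 100))
        primary.append((f"p{i}", s[:40] + "TGACGTCA" + s[48:]))
    control = [(f"c{i}", "".join(rng.choice(list("ACGT"), 100)))
               for i in range(10)]
    enr = M.motif_enrichment(primary, control, [planted], p_threshold=1e-4)
    row = enr.iloc[0]
    assert (row.n_primary_with_hit, row.n_control_with_hit) == (10, 0)
    from scipy.special import comb

    assert row.fisher_p == pytest.approx(1 / comb(20, 10), rel=1e-6)


def test_equal_hit_counts_not_enriched():
    from scipy import stats as sps

    p = sps.fisher_exact([[5, 5], [5, 5]], alternative="greater")[1]
    assert p >= 0.5


def test_tf_expression_filter_rules():
    enr = pd.DataFrame({
        "motif_id": ["m1", "m2", "m3"],
        "tf_name": ["SOX2", "ARNT::HIF1A", "NOPE"],
        "n_primary_with_hit": [5, 5, 5], "n_control_with_hit": [0, 0, 0],
        "n_primary": [10, 10, 10], "n_control": [10, 10, 10],
        "fisher_p": [0.01, 0.01, 0.01], "adjusted_p": [0.03, 0.03, 0.03],
    })
    expr = pd.DataFrame({
        "gene_id": ["sox2", "hif1a", "arnt"],
        "fpkm_group1": [0.3, 2.0, 0.1],
        "fpkm_group2": [0.4, 3.0, 0.1],
        "log2fc": [0.4, 0.58, 0.0],
        "qvalue": [0.5, 0.01, 0.9],
    })
    out = M.annotate_tf_expression(enr, expr, fpkm_cutoff=1.0)
    # SOX2 total 0.7 < 1 -> dropped; heterodimer passes via HIF1A;
    # unmapped TF retained with flag
    assert set(out.motif_id) == {"m2", "m3"}
    m2 = out[out.motif_id == "m2"].iloc[0]
    assert m2.tf_gene == "HIF1A" and m2.tf_total_fpkm == pytest.approx(5.0)
    assert bool(out[out.motif_id == "m3"].tf_unmapped.iloc[0])
    assert set(out.motif_id) <= set(enr.motif_id)  # filtered subset


def test_region_sequences_split_by_direction_and_class(small_bundle):
    from lensepi.config import AnnotationParams, DmrParams
    from lensepi import annotation as A, dmr as D
    from lensepi.expression import classify_degs

    b = small_bundle
    dmrs = D.call_dmrs_from_counts(b.records, DmrParams())
    links = A.map_dmr_to_genes(dmrs, b.annotation.genes, AnnotationParams(),
                               b.annotation.chrom_sizes)
    expr = classify_degs(b.expression)
    sets, gene_maps = M.extract_region_sequences(dmrs, links, expr,
                                                 b.annotation.genome)
    assert sets["hypo_fiber"] or sets["hyper_epithelial"]
    for key, direction in (("hypo_fiber", "hypo"),
                           ("hyper_epithelial", "hyper")):
        for name, seq in sets[key]:
            chrom, span = name.split(":")
            s, e = map(int, span.split("-"))
            # extracted sequence equals the genome slice
            assert seq == b.annotation.genome[chrom][s:e].upper()
            match = dmrs[(dmrs.chrom == chrom) & (dmrs.start == s)
                         & (dmrs.end == e)]
            assert (match.direction == direction).all()
            assert gene_maps[key][name]
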