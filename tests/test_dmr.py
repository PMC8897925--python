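"""DMR caller: smoothing arithmetic, dispersion recovery, Wald statistics
and segmentation (including an independent brute-force oracle)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lensepi.config import DmrParams, SimConfig
from lensepi import dmr as D
from lensepi.synthetic import make_annotation, simulate_methylomes

from conftest import make_records


# ---------------------------------------------------------------------------
# smoothing


def test_isolated_cpg_smooths_to_own_proportion():
    recs = make_records([("chr1", 500, "epithelial", 0, 8, 10),
                         ("chr1", 500, "fiber", 0, 5, 10)])
    sm = D.smooth_methylation(recs, DmrParams(smoothing_span=200))
    assert sm.mu1.iloc[0] == pytest.approx(0.8)


def test_window_pooling_arithmetic():
    # sites at 0/50/100 with pooled counts 5/10, 10/10, 0/10: middle = 15/30
    rows = [("chr1", p, "epithelial", 0, m, 10)
            for p, m in ((0, 5), (50, 10), (100, 0))]
    rows += [("chr1", p, "fiber", 0, 5, 10) for p in (0, 50, 100)]
    sm = D.smooth_methylation(make_records(rows), DmrParams(smoothing_span=200))
    middle = sm[sm.pos == 50]
    assert middle.mu1.iloc[0] == pytest.approx(15 / 30)


def test_span_zero_reduces_to_per_site_proportion():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(50):
        rows.append(("chr1", 10 * i, "epithelial", 0,
                     int(rng.integers(0, 11)), 10))
        rows.append(("chr1", 10 * i, "fiber", 0, int(rng.integers(0, 11)), 10))
    recs = make_records(rows)
    sm = D.smooth_methylation(recs, DmrParams(smoothing_span=0))
    per_site = recs[recs.group == "epithelial"].set_index("pos").n_meth / 10
    assert np.allclose(sm.mu1.to_numpy(), per_site.loc[sm.pos].to_numpy())


# ---------------------------------------------------------------------------
# dispersion


def test_identical_replicates_give_zero_raw_dispersion():
    rows = [("chr1", 100, g, r, 5, 10) for g in ("epithelial", "fiber")
            for r in range(3)]
    disp = D.estimate_dispersion(make_records(rows), DmrParams())
    # raw estimate is 0, and with a single site the genome median is 0 too
    assert disp.phi.iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_binomial_data_recovers_near_zero_dispersion():
    cfg = SimConfig(seed=4, genome_length=600_000, cpg_rate=0.02, n_genes=10,
                    n_planted_dmrs=0, effect_size=0.0, dispersion_phi=0.0,
                    coverage_mean=50, dmr_min_cpgs=4)
    records, _ = simulate_methylomes(cfg, make_annotation(cfg))
    assert records.pos.nunique() >= 10_000
    disp = D.estimate_dispersion(records, DmrParams())
    assert np.median(disp.phi) <= 0.02


def test_true_dispersion_recovered():
    cfg = SimConfig(seed=4, genome_length=600_000, cpg_rate=0.02, n_genes=10,
                    n_planted_dmrs=0, effect_size=0.0, dispersion_phi=0.3,
                    coverage_mean=50, dmr_min_cpgs=4)
    records, _ = simulate_methylomes(cfg, make_annotation(cfg))
    disp = D.estimate_dispersion(records, DmrParams())
    assert 0.2 <= np.median(disp.phi) <= 0.4


def test_single_replicate_falls_back_to_prior(caplog):
    rows = [("chr1", 100, "epithelial", 0, 5, 10),
            ("chr1", 100, "fiber", 0, 9, 10)]
    with caplog.at_level("WARNING"):
        disp = D.estimate_dispersion(make_records(rows), DmrParams())
    assert len(disp) == 1  # phi_bar used, no crash


# ---------------------------------------------------------------------------
# Wald test


def test_wald_statistic_direct_arithmetic():
    # mu1=0.8, mu2=0.2, one replicate each, N=100, phi=0:
    # Var = 0.0016 + 0.0016, |wald| = 0.6 / 0.056569 = 10.6066
    recs = make_records([("chr1", 100, "epithelial", 0, 80, 100),
                         ("chr1", 100, "fiber", 0, 20, 100)])
    params = DmrParams(dispersion_prior_weight=1.0)
    stats = D.site_wald_test(recs, params)
    assert abs(stats.wald.iloc[0]) == pytest.approx(10.6066, abs=1e-3)
    assert stats.mu2.iloc[0] - stats.mu1.iloc[0] == pytest.approx(-0.6)


def test_equal_groups_give_zero_wald_p_one():
    recs = make_records([("chr1", 100, "epithelial", 0, 5, 10),
                         ("chr1", 100, "fiber", 0, 5, 10)])
    stats = D.site_wald_test(recs, DmrParams())
    assert stats.wald.iloc[0] == pytest.approx(0.0)
    assert stats.p_value.iloc[0] == pytest.approx(1.0)


def test_higher_dispersion_shrinks_wald():
    def wald_at(phi_weighting):
        # two sites so the genome-median prior equals the per-site value
        rows = []
        for pos in (100, 5000):
            for rep, m in ((0, 70), (1, 75), (2, 80)):
                rows.append(("chr1", pos, "epithelial", rep,
                             int(m * phi_weighting), 100))
            for rep, m in ((0, 30), (1, 25), (2, 20)):
                rows.append(("chr1", pos, "fiber", rep, m, 100))
        return rows

    recs = make_records(wald_at(1.0))
    base = D.site_wald_test(recs, DmrParams())
    # same counts, larger prior weight toward a raised phi via direct check:
    # doubling phi* strictly decreases |wald| in the variance formula
    mu, n, phi = 0.5, 300.0, 0.1
    var = lambda p: mu * (1 - mu) * (n + p * (3 * 100**2 - n)) / n**2
    w = lambda p: 0.4 / np.sqrt(2 * var(p))
    assert w(0.2) < w(0.1)
    assert np.isfinite(base.wald).all()


# ---------------------------------------------------------------------------
# segmentation


def _stats_from_positions(sig_positions, other_positions=()):
    rows = []
    for p in sig_positions:
        rows.append(("chr1", p, 0.8, 0.2, True))
    for p in other_positions:
        rows.append(("chr1", p, 0.5, 0.5, False))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "mu1", "mu2",
                                     "is_significant"])
    df["phi"] = 0.1
    df["wald"] = np.where(df.is_significant, 10.0, 0.0)
    df["p_value"] = np.where(df.is_significant, 1e-9, 0.9)
    return df.sort_values("pos").reset_index(drop=True)


def test_short_candidate_dropped_far_candidate_kept():
    stats = _stats_from_positions([0, 20, 40, 200, 220, 260])
    dmrs = D.call_dmrs(stats, DmrParams())
    assert len(dmrs) == 1
    assert (dmrs.start.iloc[0], dmrs.end.iloc[0]) == (200, 261)


def test_gap_below_merge_chains_into_one_region():
    stats = _stats_from_positions([0, 20, 40, 60, 120])
    dmrs = D.call_dmrs(stats, DmrParams())
    assert len(dmrs) == 1
    row = dmrs.iloc[0]
    assert (row.start, row.end, row.n_cg, row.frac_sig) == (0, 121, 5, 1.0)


def test_minlen_boundary_span_is_inclusive():
    # CpGs at 0/25/49: span = 49 - 0 + 1 = 50 passes minlen=50
    dmrs = D.call_dmrs(_stats_from_positions([0, 25, 49]), DmrParams())
    assert len(dmrs) == 1


def test_no_significant_sites_no_dmrs():
    stats = _stats_from_positions([], other_positions=[10, 20, 30])
    assert D.call_dmrs(stats, DmrParams()).empty
    assert D.call_dmrs(stats.iloc[0:0], DmrParams()).empty


def brute_force_segmentation(stats, params):
    """Independent loop-based oracle for the chaining semantics."""
    out = []
    sub = stats.sort_values("pos")
    pos = sub.pos.tolist()
    sig = sub.is_significant.tolist()
    mu1 = sub.mu1.tolist()
    mu2 = sub.mu2.tolist()
    sig_idx = [i for i, s in enumerate(sig) if s]
    if not sig_idx:
        return out
    chains = [[sig_idx[0]]]
    for i in sig_idx[1:]:
        if pos[i] - pos[chains[-1][-1]] - 1 < params.dis_merge:
            chains[-1].append(i)
        else:
            chains.append([i])
    for chain in chains:
        first, last = pos[chain[0]], pos[chain[-1]]
        members = [i for i in range(len(pos)) if first <= pos[i] <= last]
        span = last - first + 1
        n_cg = len(members)
        frac = sum(sig[i] for i in members) / n_cg
        if span < params.minlen or n_cg < params.min_cg or frac < params.pct_sig:
            continue
        diff = sum(mu2[i] - mu1[i] for i in members) / n_cg
        out.append((first, last + 1, n_cg, round(frac, 9), round(diff, 9)))
    return out


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_segmentation_matches_brute_force_oracle(data):
    n = data.draw(st.integers(1, 30))
    pos = sorted(data.draw(st.sets(st.integers(0, 600), min_size=n, max_size=n)))
    sig = [data.draw(st.booleans()) for _ in pos]
    rows = [("chr1", p, 0.2 + 0.01 * i, 0.9 - 0.01 * i, s)
            for i, (p, s) in enumerate(zip(pos, sig))]
    stats = pd.DataFrame(rows, columns=["chrom", "pos", "mu1", "mu2",
                                        "is_significant"])
    params = DmrParams(minlen=data.draw(st.sampled_from([20, 50])),
                       min_cg=data.draw(st.sampled_from([2, 3])),
                       dis_merge=data.draw(st.sampled_from([50, 100])))
    got = [(r.start, r.end, r.n_cg, round(r.frac_sig, 9),
            round(r.diff_methyl, 9)) for r in D.call_dmrs(stats, params).itertuples()]
    assert got == brute_force_segmentation(stats, params)


def test_swapping_group_labels_negates_diff(small_bundle):
    records = small_bundle.records
    params = DmrParams()
    fwd = D.call_dmrs(D.site_wald_test(records, params), params)
    swapped = records.copy()
    swapped["group"] = swapped.group.map({"epithelial": "fiber",
                                          "fiber": "epithelial"})
    rev = D.call_dmrs(D.site_wald_test(swapped, params), params)
    assert len(fwd) == len(rev)
    assert np.allclose(fwd.diff_methyl.to_numpy(), -rev.diff_methyl.to_numpy())
    assert (fwd.direction.to_numpy() != rev.direction.to_numpy()).all()


# ---------------------------------------------------------------------------
# methylome summary


def test_context_proportions_all_cg():
    rows = [("chr1", p, "epithelial", 0, 3, 10) for p in range(0, 100, 10)]
    out = D.methylome_summary(make_records(rows))
    assert out["context_proportions"]["epithelial"]["CG"] == 100.0


def test_context_share_with_mixed_contexts():
    df = make_records([("chr1", 10 * i, "epithelial", 0, 2, 10)
                       for i in range(10)])
    df.loc[9, "context"] = "CHH"
    out = D.methylome_summary(df)
    props = out["context_proportions"]["epithelial"]
    assert props["CG"] == pytest.approx(90.0)
    assert props["CHH"] == pytest.approx(10.0)


def test_feature_level_pooled_ratio():
    rows = [("chr1", 10, "epithelial", 0, 4, 10),
            ("chr1", 20, "epithelial", 0, 6, 10),
            ("chr1", 200, "epithelial", 0, 1, 10)]
    features = {"promoter": {"chr1": [(0, 100)]}, "body": {"chr1": [(150, 300)]}}
    out = D.methylome_summary(make_records(rows), features)
    lv = out["feature_levels"]["epithelial"]
    assert lv["promoter"] == pytest.approx(10 / 20)
    assert lv["body"] == pytest.approx(1 / 10)
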