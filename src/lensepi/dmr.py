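"""Smoothed beta-binomial two-group site tests and DMR segmentation.

The caller follows the standard DSS-style recipe for two-group WGBS
comparisons with biological replicates:

1. per-site, per-group methylation levels are smoothed by pooling reads
   over a fixed window (+- span/2) across replicates;
2. a per-site beta-binomial dispersion is estimated by the method of
   moments from replicate proportions and shrunk toward the genome-wide
   median;
3. the group difference is tested with a Wald statistic whose variance is
   the exact sampling variance of the pooled window estimator under a
   beta-binomial model, summed over every (site, replicate) read chunk
   contributing to the window;
4. significant CpGs are chained into regions (gap < dis_merge), which must
   satisfy minimum span, CpG count and significant-CpG-fraction filters.

This is a documented simplification of the DSS Bayesian machinery with
DSS's published region parameters; equivalence with DSS is not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DmrParams

log = logging.getLogger(__name__)


@dataclass
class _ChromData:
    """Per-chromosome site-by-replicate count matrices for both groups."""

    pos: np.ndarray                 # (n_sites,) sorted
    meth: tuple[np.ndarray, np.ndarray]    # each (n_sites, n_reps)
    total: tuple[np.ndarray, np.ndarray]


def _group_labels(records: pd.DataFrame) -> tuple[str, str]:
    groups = sorted(records.group.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    # epithelial/fiber sort to (epithelial, fiber) = (group1, group2);
    # any other labels are taken in sorted order as (group1, group2)
    if set(groups) == {"epithelial", "fiber"}:
        return "epithelial", "fiber"
    return groups[0], groups[1]


def _prepare(records: pd.DataFrame) -> dict[str, _ChromData]:
    """Pivot a long cytosine-record table into per-chromosome matrices.

    Missing (site, replicate) combinations get zero reads.
    """
    cg = records[records.context == "CG"]
    g1, g2 = _group_labels(records)
    out: dict[str, _ChromData] = {}
    for chrom, sub in cg.groupby("chrom", sort=True):
        pos = np.unique(sub.pos.to_numpy())
        pos_idx = {p: i for i, p in enumerate(pos.tolist())}
        mats = []
        for group in (g1, g2):
            gsub = sub[sub.group == group]
            reps = sorted(gsub.replicate.unique())
            rep_idx = {r: j for j, r in enumerate(reps)}
            meth = np.zeros((pos.size, max(1, len(reps))), dtype=np.int64)
            total = np.zeros_like(meth)
            ii = np.fromiter((pos_idx[p] for p in gsub.pos), dtype=np.int64,
                             count=len(gsub))
            jj = np.fromiter((rep_idx[r] for r in gsub.replicate),
                             dtype=np.int64, count=len(gsub))
            np.add.at(meth, (ii, jj), gsub.n_meth.to_numpy())
            np.add.at(total, (ii, jj), gsub.n_total.to_numpy())
            mats.append((meth, total))
        out[chrom] = _ChromData(pos=pos,
                                meth=(mats[0][0], mats[1][0]),
                                total=(mats[0][1], mats[1][1]))
    return out


def _window_bounds(pos: np.ndarray, span: int) -> tuple[np.ndarray, np.ndarray]:
    """Index range [lo, hi) of sites within +- span/2 of each site (inclusive)."""
    half = span / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    return lo, hi


def _window_sum(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    csum = np.concatenate([[0], np.cumsum(x)])
    return csum[hi] - csum[lo]


def smooth_methylation(records: pd.DataFrame, params: DmrParams) -> pd.DataFrame:
    """Per-site, per-group smoothed methylation proportions.

    mu_hat(site, group) = sum of methylated reads over CpGs within
    +- span/2 (pooled across replicates) / sum of total reads. Sites where
    either group has zero reads in the window are dropped (logged).
    """
    rows = []
    for chrom, data in _prepare(records).items():
        lo, hi = _window_bounds(data.pos, params.smoothing_span)
        mus, tot = [], []
        for g in (0, 1):
            m = _window_sum(data.meth[g].sum(axis=1), lo, hi)
            t = _window_sum(data.total[g].sum(axis=1), lo, hi)
            with np.errstate(invalid="ignore", divide="ignore"):
                mus.append(np.where(t > 0, m / np.maximum(t, 1), np.nan))
            tot.append(t)
        keep = (tot[0] > 0) & (tot[1] > 0)
        dropped = int((~keep).sum())
        if dropped:
            log.info("%s: dropped %d sites with zero window coverage in a group",
                     chrom, dropped)
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": data.pos[keep],
            "mu1": mus[0][keep], "mu2": mus[1][keep],
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "mu1", "mu2"])
    return pd.concat(rows, ignore_index=True)


def _raw_phi(data: _ChromData) -> np.ndarray:
    """Per-site method-of-moments dispersion from replicate proportions.

    For each group with >= 2 covered replicates: phi solves
    s^2 = mu (1 - mu) * mean_j[(1 + (N_j - 1) phi) / N_j], where s^2 is the
    ddof-1 variance of replicate proportions and mu the group's pooled
    proportion. Group estimates are averaged; sites with no informative
    group return NaN.
    """
    n_sites = data.pos.size
    est = np.full((n_sites, 2), np.nan)
    for g in (0, 1):
        meth, total = data.meth[g], data.total[g]
        covered = total > 0
        m = covered.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(covered, meth / np.maximum(total, 1), np.nan)
            mu = meth.sum(axis=1) / np.maximum(total.sum(axis=1), 1)
            mean_p = np.nanmean(np.where(covered, props, np.nan), axis=1)
            s2 = np.nansum(np.where(covered, (props - mean_p[:, None]) ** 2, 0.0),
                           axis=1) / np.maximum(m - 1, 1)
            inv_n = np.where(covered, 1.0 / np.maximum(total, 1), 0.0).sum(axis=1) \
                / np.maximum(m, 1)
            frac = np.where(covered, (total - 1) / np.maximum(total, 1), 0.0) \
                .sum(axis=1) / np.maximum(m, 1)
            v = mu * (1.0 - mu)
            phi = (s2 / np.maximum(v, 1e-12) - inv_n) / np.maximum(frac, 1e-12)
        ok = (m >= 2) & (v > 0)
        est[ok, g] = np.clip(phi[ok], 0.0, 0.99)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(est, axis=1)  # NaN only if both groups uninformative


def estimate_dispersion(records: pd.DataFrame, params: DmrParams) -> pd.DataFrame:
    """Per-site shrunk dispersion phi*.

    phi* = (k phi_bar + m phi_hat) / (k + m) with k the prior pseudo-count,
    m the number of replicates contributing at the site and phi_bar the
    genome-wide median of the raw estimates. Sites without a raw estimate
    (fewer than 2 informative replicates in both groups) receive phi_bar.
    """
    prepared = _prepare(records)
    raw_parts, m_parts, keys = [], [], []
    for chrom, data in prepared.items():
        raw = _raw_phi(data)
        m = sum((data.total[g] > 0).sum(axis=1) for g in (0, 1))
        raw_parts.append(raw)
        m_parts.append(m)
        keys.append((chrom, data.pos))
    if not raw_parts:
        return pd.DataFrame(columns=["chrom", "pos", "phi"])
    raw_all = np.concatenate(raw_parts)
    informative = raw_all[~np.isnan(raw_all)]
    if informative.size == 0:
        log.warning("no site had >= 2 covered replicates; using phi = 0 everywhere")
        phi_bar = 0.0
    else:
        phi_bar = float(np.median(informative))
    k = params.dispersion_prior_weight
    rows = []
    for (chrom, pos), raw, m in zip(keys, raw_parts, m_parts):
        phi_hat = np.where(np.isnan(raw), phi_bar, raw)
        m_eff = np.where(np.isnan(raw), 0, m)
        denom = np.maximum(k + m_eff, 1e-12)
        phi_star = (k * phi_bar + m_eff * phi_hat) / denom
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                  "phi": np.clip(phi_star, 0.0, 0.99)}))
    return pd.concat(rows, ignore_index=True)


def site_wald_test(records: pd.DataFrame, params: DmrParams) -> pd.DataFrame:
    """Site-level Wald tests of the smoothed group difference.

    For group g, Var_g = sum over window chunks (site i, replicate j) of
    N_ij^2 mu_hat (1 - mu_hat) (1 + (N_ij - 1) phi*) / N_ij, divided by
    (sum N_ij)^2 — the variance of the pooled window proportion when each
    replicate-site read chunk is beta-binomial with dispersion phi*.
    wald = (mu2 - mu1) / sqrt(Var1 + Var2); p is the two-sided normal tail.
    A site is significant iff p < p_threshold and |mu2 - mu1| >= delta.
    """
    prepared = _prepare(records)
    disp = estimate_dispersion(records, params)
    disp_map = {(c, p): phi for c, p, phi
                in zip(disp.chrom, disp.pos, disp.phi)}
    frames = []
    for chrom, data in prepared.items():
        lo, hi = _window_bounds(data.pos, params.smoothing_span)
        phi = np.array([disp_map[(chrom, p)] for p in data.pos.tolist()])
        mu, var = [], []
        for g in (0, 1):
            msum = _window_sum(data.meth[g].sum(axis=1), lo, hi)
            tsum = _window_sum(data.total[g].sum(axis=1), lo, hi)
            t2sum = _window_sum((data.total[g].astype(float) ** 2).sum(axis=1),
                                lo, hi)
            with np.errstate(invalid="ignore", divide="ignore"):
                mu_g = np.where(tsum > 0, msum / np.maximum(tsum, 1), np.nan)
                # sum N (1 + (N-1) phi) = sum N + phi (sum N^2 - sum N)
                agg = tsum + phi * (t2sum - tsum)
                var_g = mu_g * (1.0 - mu_g) * agg / np.maximum(tsum, 1) ** 2
            mu.append(mu_g)
            var.append(var_g)
        keep = ~(np.isnan(mu[0]) | np.isnan(mu[1]))
        diff = mu[1] - mu[0]
        vsum = var[0] + var[1]
        unstable = keep & (vsum == 0) & (diff != 0)
        if unstable.any():
            log.warning("%s: excluding %d unstable sites (zero variance, "
                        "unequal means)", chrom, int(unstable.sum()))
        keep &= ~unstable
        with np.errstate(invalid="ignore", divide="ignore"):
            wald = np.where(vsum > 0, diff / np.sqrt(np.maximum(vsum, 1e-300)), 0.0)
        p = 2.0 * sps.norm.sf(np.abs(wald))
        p = np.where(vsum == 0, 1.0, p)  # both mu in {0,1} and equal
        sig = (p < params.p_threshold) & (np.abs(diff) >= params.delta)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": data.pos,
            "mu1": mu[0], "mu2": mu[1], "phi": phi,
            "wald": wald, "p_value": p, "is_significant": sig,
        })[keep])
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "mu1", "mu2", "phi",
                                     "wald", "p_value", "is_significant"])
    return pd.concat(frames, ignore_index=True)


def call_dmrs(site_stats: pd.DataFrame, params: DmrParams) -> pd.DataFrame:
    """Segment significant CpGs into DMRs.

    Consecutive significant CpGs chain while the half-open gap between them
    (next position minus previous position minus 1) is < dis_merge; the
    region spans first to last chained significant CpG and absorbs every
    intervening CpG. Regions must satisfy span >= minlen (span = last - first
    + 1), n_cg >= min_cg and frac_sig >= pct_sig. diff_methyl is the mean of
    (mu2 - mu1) over all region CpGs.
    """
    cols = ["chrom", "start", "end", "n_cg", "frac_sig",
            "mean_mu1", "mean_mu2", "diff_methyl", "direction"]
    if site_stats.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, sub in site_stats.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub.pos.to_numpy()
        sig = sub.is_significant.to_numpy(dtype=bool)
        mu1 = sub.mu1.to_numpy()
        mu2 = sub.mu2.to_numpy()
        sig_pos = pos[sig]
        if sig_pos.size == 0:
            continue
        gaps = sig_pos[1:] - sig_pos[:-1] - 1
        breaks = np.nonzero(gaps >= params.dis_merge)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sig_pos.size - 1]])
        for a, b in zip(starts, ends):
            first, last = int(sig_pos[a]), int(sig_pos[b])
            span = last - first + 1
            if span < params.minlen:
                continue
            i0 = int(np.searchsorted(pos, first, side="left"))
            i1 = int(np.searchsorted(pos, last, side="right"))
            n_cg = i1 - i0
            if n_cg < params.min_cg:
                continue
            frac_sig = float(sig[i0:i1].mean())
            if frac_sig < params.pct_sig:
                continue
            m1 = float(mu1[i0:i1].mean())
            m2 = float(mu2[i0:i1].mean())
            diff = m2 - m1
            rows.append((chrom, first, last + 1, n_cg, frac_sig, m1, m2, diff,
                         "hyper" if diff > 0 else "hypo"))
    return pd.DataFrame(rows, columns=cols)


def call_dmrs_from_counts(records: pd.DataFrame,
                          params: DmrParams | None = None) -> pd.DataFrame:
    """Convenience wrapper: site tests + segmentation from a count table."""
    params = params or DmrParams()
    return call_dmrs(site_wald_test(records, params), params)


def methylome_summary(records: pd.DataFrame,
                      features: dict[str, dict[str, list[tuple[int, int]]]] | None = None,
                      meth_threshold: int = 1) -> dict:
    """Genome-wide methylation summaries.

    Per group: the proportion of methylated cytosines by context, where a
    cytosine counts as methylated if its pooled methylated reads are
    >= ``meth_threshold``. If ``features`` maps category -> chrom ->
    intervals, also reports the pooled mCG/CG level (sum of methylated CG
    reads / sum of total CG reads) per category and group; intervals within
    a category must be disjoint (overlaps would double-count reads).
    """
    out: dict = {"context_proportions": {}, "feature_levels": {}}
    for group, gsub in records.groupby("group", sort=True):
        pooled = gsub.groupby(["chrom", "pos", "context"], as_index=False).agg(
            n_meth=("n_meth", "sum"))
        methylated = pooled[pooled.n_meth >= meth_threshold]
        counts = methylated.context.value_counts()
        total = int(counts.sum())
        out["context_proportions"][group] = {
            ctx: (100.0 * int(c) / total if total else 0.0)
            for ctx, c in counts.items()
        }
        if features:
            cg = gsub[gsub.context == "CG"]
            # pooled per-position sums with prefix sums for interval queries
            pooled_cg = cg.groupby(["chrom", "pos"], as_index=False).agg(
                n_meth=("n_meth", "sum"), n_total=("n_total", "sum"))
            by_chrom_arrays = {}
            for chrom, csub in pooled_cg.groupby("chrom"):
                csub = csub.sort_values("pos")
                by_chrom_arrays[chrom] = (
                    csub.pos.to_numpy(),
                    np.concatenate([[0], np.cumsum(csub.n_meth.to_numpy())]),
                    np.concatenate([[0], np.cumsum(csub.n_total.to_numpy())]),
                )
            levels = {}
            for cat, by_chrom in features.items():
                msum = tsum = 0
                for chrom, ivs in by_chrom.items():
                    if chrom not in by_chrom_arrays or not ivs:
                        continue
                    pos, cm, ct = by_chrom_arrays[chrom]
                    arr = np.asarray(ivs)
                    lo = np.searchsorted(pos, arr[:, 0], side="left")
                    hi = np.searchsorted(pos, arr[:, 1], side="left")
                    msum += int((cm[hi] - cm[lo]).sum())
                    tsum += int((ct[hi] - ct[lo]).sum())
                levels[cat] = (msum / tsum) if tsum else float("nan")
            out["feature_levels"][group] = levels
    return out
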