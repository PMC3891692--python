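"""Candidate-region construction and differential-methylation testing.

Candidate regions (the "bump-list") are maximal runs of adjacent 50 bp bins
with nonzero summed counts, kept when they hold at least 10 reads summed over
the cohorts being compared.  Regions are tested with a negative-binomial
exact test in the style of the early DESeq releases: per-sample size factors
by median-of-ratios, a mean-dispersion trend fitted across regions and
assigned to every region ("fit-only" sharing), and a two-sided conditional
allocation test.  Benjamini-Hochberg controls the FDR over all tested
regions; significant regions are classified hyper/hypo with respect to the
older group and associated with genes within a distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coupling import MethylomeTrack
from .genome import FEATURE_CLASSES, FeatureSet

DISPERSION_FLOOR = 1e-8
_POISSON_ALPHA = 1e-7   # below this the NB pmf is numerically Poisson


# ---------------------------------------------------------------------------
# bump-list
# ---------------------------------------------------------------------------

def build_bump_list(tracks: list[MethylomeTrack], group_a: str, group_b: str,
                    min_total_reads: int = 10) -> pd.DataFrame:
    """Merge adjacent nonzero bins into regions; keep those with enough reads.

    Returns a DataFrame with columns chrom, start, end, one raw-count column
    per compared sample, and ``total``; sorted by coordinate.
    """
    use = [t for t in tracks if t.group in (group_a, group_b)]
    if not use:
        raise ValueError("no tracks in the compared groups")
    bs = {t.bin_size for t in use}
    chroms = {t.chrom_order for t in use}
    if len(bs) != 1 or len(chroms) != 1:
        raise ValueError("tracks do not share a bin grid")
    bin_size = bs.pop()
    sample_ids = [t.sample_id for t in use]

    rows = []
    for chrom in use[0].chrom_order:
        mat = np.stack([t.counts[chrom] for t in use])     # samples x bins
        total = mat.sum(axis=0)
        nz = total > 0
        if not nz.any():
            continue
        # run starts/ends over the boolean mask
        starts = np.flatnonzero(nz & ~np.concatenate(([False], nz[:-1])))
        ends = np.flatnonzero(nz & ~np.concatenate((nz[1:], [False]))) + 1
        csum = np.concatenate((np.zeros((mat.shape[0], 1), dtype=np.int64),
                               np.cumsum(mat, axis=1)), axis=1)
        for s, e in zip(starts, ends):
            per_sample = csum[:, e] - csum[:, s]
            tot = int(per_sample.sum())
            if tot < min_total_reads:
                continue
            rows.append((chrom, int(s * bin_size), int(e * bin_size),
                         *per_sample.tolist(), tot))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       *sample_ids, "total"])


def region_counts(bumps: pd.DataFrame, sample_ids: list[str]) -> np.ndarray:
    return bumps[sample_ids].to_numpy(dtype=np.int64)


def region_counts_for_track(bumps: pd.DataFrame, track: MethylomeTrack) -> np.ndarray:
    """Sum a track's bin counts over each bump region (for heatmaps etc.)."""
    out = np.zeros(len(bumps), dtype=np.int64)
    bs = track.bin_size
    for chrom, sub in bumps.groupby("chrom", sort=False):
        c = track.counts[chrom]
        csum = np.concatenate(([0], np.cumsum(c)))
        lo = sub["start"].to_numpy() // bs
        hi = sub["end"].to_numpy() // bs
        out[sub.index] = csum[hi] - csum[lo]
    return out


# ---------------------------------------------------------------------------
# size factors and dispersion
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, geometric-mean-centred (product = 1).

    ``counts`` is regions x samples.  Ratios are taken against the per-region
    geometric mean over regions where every sample is positive; when no such
    region exists, falls back to total-count ratios.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a regions x samples matrix with >=2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    pos = (counts > 0).all(axis=1)
    if pos.any():
        sub = counts[pos]
        log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_gm, axis=0))
    else:
        totals = counts.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


@dataclass
class DispersionFit:
    """Mean-dispersion trend alpha(mu) = a0 + a1 / mu, 'fit-only' sharing."""

    a0: float
    a1: float
    per_region_alpha: np.ndarray      # fitted value per region, floored

    def alpha_at(self, mu: np.ndarray) -> np.ndarray:
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
        return np.maximum(self.a0 + self.a1 / mu, DISPERSION_FLOOR)


def fit_dispersion(counts: np.ndarray, factors: np.ndarray,
                   group_labels: np.ndarray) -> DispersionFit:
    """Method-of-moments dispersion per region, then a 1/mu trend fit.

    Every region is assigned the *fitted* trend value (never the larger of
    fitted and per-region estimates), mirroring the fit-only sharing mode of
    the dispersion estimator this step reproduces.
    """
    counts = np.asarray(counts, dtype=float)
    z = counts / factors[None, :]
    base_mean = z.mean(axis=1)

    groups = np.unique(group_labels)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for g in groups:
        cols = np.flatnonzero(group_labels == g)
        if len(cols) < 2:
            continue
        zg = z[:, cols]
        qg = zg.mean(axis=1)
        vg = zg.var(axis=1, ddof=1)
        xi = qg * np.mean(1.0 / factors[cols])       # shot-noise component
        with np.errstate(divide="ignore", invalid="ignore"):
            a_raw = np.where(qg > 0, (vg - xi) / np.maximum(qg, 1e-12) ** 2, np.nan)
        w = len(cols) - 1
        ok = np.isfinite(a_raw)
        num[ok] += w * a_raw[ok]
        den[ok] += w
    with np.errstate(invalid="ignore"):
        alpha_mom = np.where(den > 0, num / np.maximum(den, 1), np.nan)

    ok = np.isfinite(alpha_mom) & (base_mean > 0)
    if ok.sum() >= 5:
        x = 1.0 / base_mean[ok]
        y = alpha_mom[ok]
        A = np.stack([np.ones(ok.sum()), x], axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0 = float(np.nanmean(alpha_mom)) if np.isfinite(alpha_mom).any() else 0.0
        a1 = 0.0
    if not np.isfinite(a0):
        a0 = 0.0
    if not np.isfinite(a1):
        a1 = 0.0
    fit = DispersionFit(a0, a1, np.empty(0))
    fit.per_region_alpha = fit.alpha_at(base_mean)
    return fit


# ---------------------------------------------------------------------------
# the exact NB allocation test
# ---------------------------------------------------------------------------

def _nb_pmf_vector(mu: float, var: float, kmax: int) -> np.ndarray:
    """pmf of the NB (or Poisson when var <= mu) with given mean/variance
    evaluated at 0..kmax."""
    k = np.arange(kmax + 1)
    if mu <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    if var <= mu * (1 + _POISSON_ALPHA):
        return stats.poisson.pmf(k, mu)
    # NB parameterised by size r and success prob p: mean r(1-p)/p
    r = mu * mu / (var - mu)
    p = mu / var
    return stats.nbinom.pmf(k, r, p)


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray,
                  factors_a: np.ndarray, factors_b: np.ndarray,
                  alpha: float, pseudocount: float = 0.5
                  ) -> tuple[float, float]:
    """Two-sided conditional NB allocation test for one region.

    Counts are modeled per group as negative binomial with mean
    ``mu_g = q0 * sum(factors_g)`` (q0 the pooled normalized mean) and
    variance ``mu_g + alpha * q0**2 * sum(factors_g**2)``.  Conditional on the
    summed count, the p-value sums the probabilities of all allocations
    between the groups no more likely than the observed one.

    Returns (p_value, log2 fold change of group b over group a), the fold
    change computed on normalized group means with a pseudocount.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    if not np.isfinite(alpha):
        raise ValueError("non-finite dispersion")
    ka, kb = int(counts_a.sum()), int(counts_b.sum())
    sa, sb = float(factors_a.sum()), float(factors_b.sum())
    ks = ka + kb
    mean_a = float(np.mean(counts_a / factors_a))
    mean_b = float(np.mean(counts_b / factors_b))
    lfc = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
    if ks == 0:
        return 1.0, lfc

    q0 = ks / (sa + sb)
    mu_a, mu_b = q0 * sa, q0 * sb
    var_a = mu_a + alpha * q0 * q0 * float(np.sum(factors_a ** 2))
    var_b = mu_b + alpha * q0 * q0 * float(np.sum(factors_b ** 2))
    pa = _nb_pmf_vector(mu_a, var_a, ks)
    pb = _nb_pmf_vector(mu_b, var_b, ks)
    joint = pa * pb[::-1]              # P(A = i, B = ks - i)
    total = joint.sum()
    if total <= 0:
        return 1.0, lfc
    obs = joint[ka]
    # tolerance keeps ties (e.g. the perfectly symmetric case) counted as ties
    p = float(joint[joint <= obs * (1 + 1e-12)].sum() / total)
    return min(p, 1.0), lfc


def run_region_tests(bumps: pd.DataFrame, sample_ids: list[str],
                 group_labels: np.ndarray, group_a: str, group_b: str,
                 factors: np.ndarray | None = None,
                 dispersion: DispersionFit | None = None
                 ) -> pd.DataFrame:
    """Run the NB exact test on every bump region (group_b vs group_a)."""
    counts = region_counts(bumps, sample_ids)
    if factors is None:
        factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = fit_dispersion(counts, factors, group_labels)
    ia = np.flatnonzero(group_labels == group_a)
    ib = np.flatnonzero(group_labels == group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("need >=1 replicate per compared group")
    pvals = np.empty(len(bumps))
    lfcs = np.empty(len(bumps))
    for i in range(len(bumps)):
        pvals[i], lfcs[i] = nb_exact_test(
            counts[i, ia], counts[i, ib], factors[ia], factors[ib],
            float(dispersion.per_region_alpha[i]))
    out = bumps[["chrom", "start", "end", "total"]].copy()
    out["mean_norm_a"] = (counts[:, ia] / factors[ia]).mean(axis=1)
    out["mean_norm_b"] = (counts[:, ib] / factors[ib]).mean(axis=1)
    out["log2_fold_change"] = lfcs
    out["p_value"] = pvals
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up), via statsmodels."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

@dataclass
class DMRResult:
    """Tested regions, called DMRs and the three-group methylation heatmap."""

    table: pd.DataFrame               # all tested regions with p, fdr
    dmrs: pd.DataFrame                # fdr < threshold, with direction
    size_factors: pd.Series
    dispersion: DispersionFit
    heatmap: pd.DataFrame | None = None


def call_dmrs(tracks: list[MethylomeTrack], group_a: str, group_b: str,
              min_total_reads: int = 10, fdr_threshold: float = 0.2,
              heatmap_tracks: list[MethylomeTrack] | None = None) -> DMRResult:
    """Build the bump-list, test every region, and call DMRs at the FDR cut.

    Direction is ``hyper`` when the older group (group_b) has the higher
    normalized mean (log2 fold change > 0), ``hypo`` otherwise.  The heatmap
    holds per-sample region-level normalized scores for all DMRs across every
    supplied track (typically all three age groups), row-scaled to [0, 1].
    """
    bumps = build_bump_list(tracks, group_a, group_b, min_total_reads)
    if bumps.empty:
        raise ValueError("empty bump-list: no region reaches the read threshold")
    use = [t for t in tracks if t.group in (group_a, group_b)]
    sample_ids = [t.sample_id for t in use]
    labels = np.array([t.group for t in use])
    counts = region_counts(bumps, sample_ids)
    factors = estimate_size_factors(counts)
    dispersion = fit_dispersion(counts, factors, labels)
    table = run_region_tests(bumps, sample_ids, labels, group_a, group_b,
                             factors, dispersion)
    table["fdr"] = benjamini_hochberg(table["p_value"].to_numpy())
    sel = np.flatnonzero(table["fdr"].to_numpy() < fdr_threshold)
    dmrs = table.iloc[sel].copy()
    dmrs["direction"] = np.where(dmrs["log2_fold_change"] > 0, "hyper", "hypo")
    dmrs = dmrs.reset_index(drop=True)

    heatmap = None
    hm_tracks = heatmap_tracks if heatmap_tracks is not None else tracks
    if len(dmrs) and hm_tracks:
        # joint size factors over every displayed track, for display only
        all_counts = np.stack([region_counts_for_track(bumps, t)
                               for t in hm_tracks], axis=1)
        hm_factors = estimate_size_factors(all_counts)
        cols = {}
        for t, f in zip(hm_tracks, hm_factors):
            rc = region_counts_for_track(bumps, t).astype(float)
            cols[t.sample_id] = rc[sel] / f
        heatmap = pd.DataFrame(cols, index=[
            f"{r.chrom}:{r.start}-{r.end}" for r in dmrs.itertuples()])
        lo = heatmap.min(axis=1)
        span = heatmap.max(axis=1) - lo
        heatmap = heatmap.sub(lo, axis=0).div(span.where(span > 0, 1.0), axis=0)

    return DMRResult(table, dmrs, pd.Series(factors, index=sample_ids),
                     dispersion, heatmap)


# ---------------------------------------------------------------------------
# feature labels and gene association
# ---------------------------------------------------------------------------

def label_features(regions: pd.DataFrame, features: FeatureSet,
                   classes: tuple[str, ...] = FEATURE_CLASSES) -> pd.DataFrame:
    """Add one boolean column per feature class: region overlaps >=1 bp."""
    out = regions.copy()
    for cls in classes:
        col = np.zeros(len(out), dtype=bool)
        for chrom, sub in out.groupby("chrom", sort=False):
            col[out.index.get_indexer(sub.index)] = features.overlaps_any(
                cls, chrom, sub["start"].to_numpy(), sub["end"].to_numpy())
        out[f"in_{cls}"] = col
    return out


def associate_genes(dmrs: pd.DataFrame, features: FeatureSet,
                    cutoff: int = 100_000) -> tuple[pd.DataFrame, float]:
    """Associate each DMR with all genes within ``cutoff`` bp (inclusive).

    Distance is 0 for overlap, otherwise the gap between the closest interval
    ends.  Qualifying genes are listed nearest first, ties broken by gene id.
    Returns the annotated table and the fraction of DMRs with >=1 gene.
    """
    genes = features.of_class("gene")
    assoc = []
    n_with = 0
    for r in dmrs.itertuples():
        sub = genes[genes["chrom"] == r.chrom]
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        gap_right = gs - r.end          # gene entirely to the right
        gap_left = r.start - ge         # gene entirely to the left
        dist = np.maximum(0, np.maximum(gap_right, gap_left))
        keep = dist <= cutoff
        pairs = sorted(zip(dist[keep], sub["name"].to_numpy()[keep]),
                       key=lambda t: (t[0], t[1]))
        if pairs:
            n_with += 1
        assoc.append(";".join(f"{g}:{int(d)}" for d, g in pairs))
    out = dmrs.copy()
    out["genes"] = assoc
    fraction = n_with / len(dmrs) if len(dmrs) else 0.0
    return out, fraction
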