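"""Bump-list construction, size factors, NB exact test (vs independent
oracles), BH correction and gene association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb, gammaln

from agemeth import (associate_genes, benjamini_hochberg, build_bump_list,
                     call_dmrs, estimate_size_factors, nb_exact_test)
from agemeth.coupling import MethylomeTrack
from agemeth.dmr import fit_dispersion
from agemeth.genome import FeatureSet


def _track(counts, sample_id, group, bin_size=50):
    counts = np.asarray(counts, dtype=np.int64)
    return MethylomeTrack(sample_id, group, bin_size, {"c": counts},
                          {"c": counts.astype(float)},
                          {"c": np.zeros(len(counts), bool)},
                          int(counts.sum()))


# ---------------------------------------------------------------------------
# bump-list
# ---------------------------------------------------------------------------

def test_bump_list_empty_for_all_zero_tracks():
    tracks = [_track([0] * 6, "Y1", "Young"), _track([0] * 6, "O1", "Old")]
    assert build_bump_list(tracks, "Young", "Old").empty


@pytest.mark.parametrize("count,expected", [(10, 1), (9, 0)])
def test_bump_list_min_reads_boundary(count, expected):
    tracks = [_track([0, count, 0], "Y1", "Young"),
              _track([0, 0, 0], "O1", "Old")]
    bumps = build_bump_list(tracks, "Young", "Old", min_total_reads=10)
    assert len(bumps) == expected


def test_bump_list_hand_enumeration():
    # summed bins (0, 3, 4, 0, 2, 0): runs [1-2] (total 7) and [4] (total 2)
    tracks = [_track([0, 3, 4, 0, 2, 0], "Y1", "Young"),
              _track([0, 0, 0, 0, 0, 0], "O1", "Old")]
    assert build_bump_list(tracks, "Young", "Old", 10).empty
    bumps = build_bump_list(tracks, "Young", "Old", min_total_reads=5)
    assert len(bumps) == 1
    r = bumps.iloc[0]
    assert (r["start"], r["end"], r["total"]) == (50, 150, 7)
    assert r["Y1"] == 7 and r["O1"] == 0


def test_bump_list_rejects_grid_mismatch():
    tracks = [_track([1, 1], "Y1", "Young"),
              _track([1, 1], "O1", "Old", bin_size=100)]
    with pytest.raises(ValueError, match="grid"):
        build_bump_list(tracks, "Young", "Old")


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_columns_are_one():
    counts = np.tile([[5], [10], [20]], (1, 3))
    np.testing.assert_allclose(estimate_size_factors(counts), [1, 1, 1])


def test_size_factors_doubling_closed_form():
    a = np.array([4, 10, 50, 7], dtype=float)
    counts = np.stack([a, 2 * a], axis=1)
    f = estimate_size_factors(counts)
    np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)])
    assert np.prod(f) == pytest.approx(1.0)


def test_size_factors_order_free():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 100, size=(30, 4)).astype(float)
    f1 = estimate_size_factors(counts)
    f2 = estimate_size_factors(counts[rng.permutation(30)])
    np.testing.assert_allclose(f1, f2)


def test_size_factors_rejects_all_zero_sample():
    with pytest.raises(ValueError):
        estimate_size_factors(np.array([[1, 0], [2, 0]], dtype=float))


# ---------------------------------------------------------------------------
# NB exact test vs oracles
# ---------------------------------------------------------------------------

def oracle_nb_p(counts_a, counts_b, factors_a, factors_b, alpha):
    """Direct enumeration of the conditional allocation distribution using
    an explicit log-pmf (independent of scipy.stats frozen distributions)."""
    ka, kb = int(np.sum(counts_a)), int(np.sum(counts_b))
    ks = ka + kb
    sa, sb = float(np.sum(factors_a)), float(np.sum(factors_b))
    q0 = ks / (sa + sb)

    def log_pmf(k, mu, var):
        if var <= mu * (1 + 1e-7):     # Poisson limit
            return k * np.log(mu) - mu - gammaln(k + 1)
        r = mu * mu / (var - mu)
        p = mu / var
        return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
                + r * np.log(p) + k * np.log1p(-p))

    k = np.arange(ks + 1)
    la = log_pmf(k, q0 * sa, q0 * sa + alpha * q0 ** 2 * np.sum(np.square(factors_a)))
    lb = log_pmf(k, q0 * sb, q0 * sb + alpha * q0 ** 2 * np.sum(np.square(factors_b)))
    lj = la + lb[::-1]
    w = np.exp(lj - lj.max())
    return float(w[w <= w[ka] * (1 + 1e-12)].sum() / w.sum())


def binomial_exact_two_sided(ka, n, p):
    pmf = comb(n, np.arange(n + 1)) * p ** np.arange(n + 1) \
        * (1 - p) ** (n - np.arange(n + 1))
    return float(pmf[pmf <= pmf[ka] * (1 + 1e-12)].sum())


def test_identical_groups_give_p_one():
    ones = np.ones(3)
    p, lfc = nb_exact_test([5, 5, 5], [5, 5, 5], ones, ones, alpha=0.01)
    assert p == 1.0
    assert lfc == 0.0


def test_poisson_limit_matches_binomial_exact_test():
    # toy region: Young = (2, 3), Old = (20, 25), all size factors 1
    ones = np.ones(2)
    p, lfc = nb_exact_test([2, 3], [20, 25], ones, ones, alpha=1e-12)
    oracle = binomial_exact_two_sided(5, 50, 0.5)
    assert p == pytest.approx(oracle, abs=1e-6)
    assert lfc > 0


@pytest.mark.parametrize("seed", range(6))
def test_nb_exact_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    ca = rng.integers(0, 10, 3)
    cb = rng.integers(0, 10, 3)
    if ca.sum() + cb.sum() == 0:
        ca[0] = 1
    fa = rng.uniform(0.7, 1.4, 3)
    fb = rng.uniform(0.7, 1.4, 3)
    alpha = rng.choice([1e-10, 0.01, 0.2])
    p, _ = nb_exact_test(ca, cb, fa, fb, alpha)
    assert ca.sum() + cb.sum() <= 60
    assert p == pytest.approx(
        oracle_nb_p(ca, cb, fa, fb, alpha), abs=1e-9)


def test_nb_exact_symmetry_under_group_swap():
    rng = np.random.default_rng(3)
    for _ in range(5):
        ca, cb = rng.integers(0, 30, 3), rng.integers(0, 30, 3)
        fa, fb = rng.uniform(0.8, 1.2, 3), rng.uniform(0.8, 1.2, 3)
        p1, l1 = nb_exact_test(ca, cb, fa, fb, 0.05)
        p2, l2 = nb_exact_test(cb, ca, fb, fa, 0.05)
        assert p1 == pytest.approx(p2, rel=1e-10)
        assert l1 == pytest.approx(-l2, rel=1e-10)
        assert 0 < p1 <= 1


def test_nb_exact_rejects_nonfinite_dispersion():
    with pytest.raises(ValueError):
        nb_exact_test([1], [2], np.ones(1), np.ones(1), float("nan"))


def test_dispersion_fit_only_assigns_trend_values():
    rng = np.random.default_rng(0)
    mu = rng.uniform(20, 200, 100)
    # NB counts with true alpha 0.1
    counts = np.stack([rng.negative_binomial(10, 10 / (10 + mu))
                       for _ in range(6)], axis=1)
    labels = np.array(["Young"] * 3 + ["Old"] * 3)
    fit = fit_dispersion(counts, np.ones(6), labels)
    assert fit.per_region_alpha.shape == (100,)
    assert (fit.per_region_alpha >= 1e-8).all()
    # the fitted trend should sit near the simulated dispersion
    assert 0.03 < np.median(fit.per_region_alpha) < 0.3


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    n = len(p)
    adj = np.empty(n)
    for i in range(n):
        vals = [p[j] * n / (np.sum(p <= p[j])) for j in range(n) if p[j] >= p[i]]
        adj[i] = min(min(vals), 1.0)
    return adj


def test_bh_hand_example():
    # step-up BH: p_i * n / rank, then a running min from the largest p;
    # cross-checked against R p.adjust(method = "BH")
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    np.testing.assert_allclose(
        benjamini_hochberg(p), [0.005, 0.025, 1 / 30, 0.625, 0.9])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                max_size=10))
def test_bh_matches_brute_force(pvals):
    p = np.array(pvals)
    np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p),
                               atol=1e-12)


# ---------------------------------------------------------------------------
# call_dmrs
# ---------------------------------------------------------------------------

def _two_group_tracks(seed=0, n_bins=400):
    rng = np.random.default_rng(seed)
    mu = np.zeros(n_bins)
    mu[::4] = rng.uniform(5, 20, n_bins // 4)
    tracks = []
    for g, scale in (("Young", 1.0), ("Old", 1.0)):
        for i in range(3):
            tracks.append(_track(rng.poisson(mu * scale), f"{g}{i}", g))
    return tracks


def test_all_p_one_yields_zero_dmrs():
    tracks = [_track([0, 7, 7, 0], "Y1", "Young"),
              _track([0, 7, 7, 0], "O1", "Old")]
    res = call_dmrs(tracks, "Young", "Old", min_total_reads=10)
    assert (res.table["p_value"] == 1.0).all()
    assert res.dmrs.empty


def test_dmr_count_monotone_in_fdr_threshold():
    tracks = _two_group_tracks(seed=5)
    counts = []
    for thr in (0.01, 0.1, 0.3, 0.8):
        res = call_dmrs(tracks, "Young", "Old", fdr_threshold=thr)
        counts.append(len(res.dmrs))
        assert (res.table["fdr"].to_numpy()
                >= res.table["p_value"].to_numpy() - 1e-15).all()
    assert counts == sorted(counts)


def test_heatmap_rows_scaled_to_unit_interval(default_analysis):
    _, _, _, result = default_analysis
    hm = result.heatmap
    assert hm is not None and len(hm) == len(result.dmrs)
    assert hm.to_numpy().min() >= 0 and hm.to_numpy().max() <= 1
    np.testing.assert_allclose(hm.max(axis=1), 1.0)
    np.testing.assert_allclose(hm.min(axis=1), 0.0)
    # heatmap spans all three groups
    assert any(c.startswith("Mid") for c in hm.columns)


def test_heatmap_shows_progressive_change(default_analysis):
    ds, _, _, result = default_analysis
    hm = result.heatmap
    groups = {g: [c for c in hm.columns if c.startswith(g)]
              for g in ("Young", "Mid", "Old")}
    mid = hm[groups["Mid"]].mean(axis=1)
    young = hm[groups["Young"]].mean(axis=1)
    old = hm[groups["Old"]].mean(axis=1)
    between = ((np.minimum(young, old) - 0.15 <= mid)
               & (mid <= np.maximum(young, old) + 0.15))
    assert between.mean() > 0.8


# ---------------------------------------------------------------------------
# gene association
# ---------------------------------------------------------------------------

def _gene_features(rows):
    return FeatureSet(pd.DataFrame(
        [(c, s, e, "gene", n) for c, s, e, n in rows],
        columns=["chrom", "start", "end", "feature_class", "name"]))


def test_gene_association_overlap_boundary_and_fraction():
    feats = _gene_features([
        ("c", 1_000, 5_000, "geneA"),
        ("c", 404_000, 410_000, "geneB"),   # exactly 100 kb from DMR2 end
        ("c", 900_000, 910_000, "geneC"),
    ])
    dmrs = pd.DataFrame({
        "chrom": ["c", "c", "c"],
        "start": [2_000, 300_000, 700_000],
        "end": [3_000, 304_000, 701_000],
    })
    out, fraction = associate_genes(dmrs, feats, cutoff=100_000)
    assert out.iloc[0]["genes"] == "geneA:0"            # inside a gene
    assert out.iloc[1]["genes"] == "geneB:100000"       # boundary inclusive
    assert out.iloc[2]["genes"] == ""                   # nothing within reach
    assert fraction == pytest.approx(2 / 3)

    # one bp further: no longer associated
    out2, _ = associate_genes(
        dmrs.assign(start=[2_000, 299_999, 700_000],
                    end=[3_000, 303_999, 701_000]), feats, cutoff=100_000)
    assert out2.iloc[1]["genes"] == ""


def test_gene_association_sorted_nearest_first_with_lexicographic_ties():
    feats = _gene_features([
        ("c", 10_000, 12_000, "gB"),
        ("c", 10_000, 12_000, "gA"),    # same interval: tie on distance
        ("c", 2_000, 2_500, "gC"),
    ])
    dmrs = pd.DataFrame({"chrom": ["c"], "start": [3_000], "end": [3_500]})
    out, _ = associate_genes(dmrs, feats, cutoff=100_000)
    assert out.iloc[0]["genes"] == "gC:500;gA:6500;gB:6500"
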