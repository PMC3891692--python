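"""Tests of the synthetic-data generator: determinism, annotation geometry,
latent-surface arithmetic and the MeDIP capture model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agemeth import (SimConfig, make_ground_truth, simulate_dataset,
                     simulate_fragments, simulate_genome, simulate_methylome)
from agemeth.genome import FeatureSet
from agemeth.qc import enrichment_score, filter_fragments

from conftest import null_cfg, small_cfg


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def test_no_cgis_means_no_shores():
    cfg = small_cfg(cgi_count=0)
    _, features = simulate_genome(cfg)
    assert len(features.of_class("cgi")) == 0
    assert len(features.of_class("shore")) == 0


def test_shore_width_is_exactly_2000_for_interior_cgis():
    cfg = small_cfg()
    _, features = simulate_genome(cfg, shore_width=2000)
    cgis = features.of_class("cgi")
    shores = features.of_class("shore")
    assert len(cgis) == cfg.cgi_count
    # interior CGIs (>=2000 bp from ends and from other CGIs by construction)
    for _, r in cgis.iterrows():
        if r["start"] < 2000 or r["end"] > cfg.chrom_length - 2000:
            continue
        left = shores[(shores["chrom"] == r["chrom"]) & (shores["end"] == r["start"])]
        right = shores[(shores["chrom"] == r["chrom"]) & (shores["start"] == r["end"])]
        assert len(left) == 1 and len(right) == 1
        assert (left.iloc[0]["end"] - left.iloc[0]["start"]) == 2000
        assert (right.iloc[0]["end"] - right.iloc[0]["start"]) == 2000


def test_realized_cpg_count_matches_binomial_expectation():
    # Recount positions independently against the analytic expectation.
    cfg = SimConfig(seed=1, n_chromosomes=1, chrom_length=1_000_000,
                    background_cpg_rate=0.01, cgi_count=0, cpg_patch_count=0,
                    genes_per_chromosome=5, true_dmr_count=0,
                    hotspot_dmr_count=0)
    genome, _ = simulate_genome(cfg)
    n = cfg.chrom_length - 1          # last base cannot start a CpG
    expected = n * cfg.background_cpg_rate
    sd = np.sqrt(n * cfg.background_cpg_rate * (1 - cfg.background_cpg_rate))
    assert abs(genome.n_cpgs - expected) < 3 * sd


def test_annotation_closure_and_bed_round_trip(tmp_path):
    cfg = small_cfg()
    genome, features = simulate_genome(cfg)
    # every base belongs to >=1 of the five classes
    for chrom, L in genome.chrom_sizes.items():
        covered = np.zeros(L, dtype=bool)
        for cls in ("cgi", "shore", "exon", "intron", "intergenic"):
            for _, r in features.of_class(cls).iterrows():
                if r["chrom"] == chrom:
                    covered[r["start"]:r["end"]] = True
        assert covered.all()
    path = tmp_path / "features.bed"
    features.to_bed(str(path))
    back = FeatureSet.from_bed(str(path))
    a = features.df.sort_values(["chrom", "start", "feature_class", "name"]).reset_index(drop=True)
    b = back.df.sort_values(["chrom", "start", "feature_class", "name"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b[a.columns])


def test_rejects_overfull_genome():
    with pytest.raises(ValueError):
        simulate_genome(small_cfg(cpg_patch_count=500))


# ---------------------------------------------------------------------------
# ground truth + latent surface
# ---------------------------------------------------------------------------

def test_ground_truth_hotspot_dmrs_share_one_window():
    cfg = small_cfg()
    genome, features = simulate_genome(cfg)
    truth = make_ground_truth(genome, features, cfg)
    hot = truth.dmrs[truth.dmrs["in_hotspot"]]
    assert len(hot) == cfg.hotspot_dmr_count
    assert (hot["direction"] == "hyper").all()
    chrom, ws = truth.hotspot_location
    assert (hot["chrom"] == chrom).all()
    assert (hot["start"] >= ws).all()
    assert (hot["end"] <= ws + cfg.hotspot_window).all()


def test_ground_truth_round_trip(tmp_path):
    cfg = small_cfg()
    genome, features = simulate_genome(cfg)
    truth = make_ground_truth(genome, features, cfg)
    path = tmp_path / "truth.tsv"
    truth.to_tsv(str(path))
    back = truth.from_tsv(str(path))
    assert back.hotspot_location == truth.hotspot_location
    assert back.global_shift_fraction == truth.global_shift_fraction
    pd.testing.assert_frame_equal(back.dmrs, truth.dmrs)


def test_null_surface_is_identical_across_groups():
    cfg = null_cfg()
    genome, features = simulate_genome(cfg)
    truth = make_ground_truth(genome, features, cfg)
    surf = simulate_methylome(genome, features, truth, cfg)
    for chrom in genome.chroms:
        np.testing.assert_array_equal(surf.levels["Young"][chrom],
                                      surf.levels["Old"][chrom])


def test_hyper_dmr_bins_gain_and_global_ratio_is_exact():
    cfg = small_cfg(global_shift_fraction=0.05)
    genome, features = simulate_genome(cfg)
    truth = make_ground_truth(genome, features, cfg)
    surf = simulate_methylome(genome, features, truth, cfg)
    hyper = truth.dmrs[truth.dmrs["direction"] == "hyper"].iloc[0]
    sl = slice(hyper["start"] // 50, hyper["end"] // 50)
    y = surf.levels["Young"][hyper["chrom"]][sl]
    o = surf.levels["Old"][hyper["chrom"]][sl]
    assert (o > y).all()

    # without DMRs the non-CGI mean ratio equals 1 - shift exactly
    cfg0 = null_cfg(global_shift_fraction=0.07)
    genome, features = simulate_genome(cfg0)
    truth0 = make_ground_truth(genome, features, cfg0)
    surf0 = simulate_methylome(genome, features, truth0, cfg0)
    for chrom, L in genome.chrom_sizes.items():
        n_bins = -(-L // 50)
        is_cgi = np.zeros(n_bins, bool)
        for _, r in features.of_class("cgi").iterrows():
            if r["chrom"] == chrom:
                is_cgi[r["start"] // 50:-(-r["end"] // 50)] = True
        ratio = (surf0.levels["Old"][chrom][~is_cgi].mean()
                 / surf0.levels["Young"][chrom][~is_cgi].mean())
        assert ratio == pytest.approx(1 - 0.07, abs=1e-6)


def test_mid_group_is_arithmetic_midpoint():
    cfg = small_cfg(groups=("Young", "Mid", "Old"))
    genome, features = simulate_genome(cfg)
    truth = make_ground_truth(genome, features, cfg)
    surf = simulate_methylome(genome, features, truth, cfg)
    for chrom in genome.chroms:
        np.testing.assert_allclose(
            surf.levels["Mid"][chrom],
            0.5 * (surf.levels["Young"][chrom] + surf.levels["Old"][chrom]))


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def test_dataset_is_deterministic_for_fixed_seed():
    a = simulate_dataset(small_cfg(seed=5))
    b = simulate_dataset(small_cfg(seed=5))
    for c in a.genome.chroms:
        np.testing.assert_array_equal(a.genome.cpg_positions[c],
                                      b.genome.cpg_positions[c])
    pd.testing.assert_frame_equal(a.truth.dmrs, b.truth.dmrs)
    for sid in a.fragments:
        pd.testing.assert_frame_equal(a.fragments[sid], b.fragments[sid])


def test_adding_a_replicate_does_not_reshuffle_existing_samples():
    a = simulate_dataset(small_cfg(seed=5, replicates_per_group=2))
    b = simulate_dataset(small_cfg(seed=5, replicates_per_group=3))
    pd.testing.assert_frame_equal(a.fragments["Young1"], b.fragments["Young1"])
    pd.testing.assert_frame_equal(a.fragments["Old2"], b.fragments["Old2"])


@pytest.mark.parametrize("mode", ["input", "flat_exponent0"])
def test_uniform_sampling_modes(mode):
    cfg = null_cfg(seed=3, fragments_per_replicate=20_000,
                   mapq_fail_fraction=0.0, improper_fraction=0.0,
                   duplicate_fraction=0.0)
    genome, features = simulate_genome(cfg)
    truth = make_ground_truth(genome, features, cfg)
    surf = simulate_methylome(genome, features, truth, cfg)
    if mode == "input":
        df = simulate_fragments(genome, None, cfg, "InputX", input_control=True)
    else:
        cfg0 = null_cfg(seed=3, fragments_per_replicate=20_000,
                        pulldown_exponent=0.0, mapq_fail_fraction=0.0,
                        improper_fraction=0.0, duplicate_fraction=0.0,
                        baseline_meth_cgi=0.5)  # flat surface
        df = simulate_fragments(genome, surf.levels["Young"], cfg0, "F1")
    mids = (df["start"] + df["end"]) // 2
    L = cfg.chrom_length
    counts, _ = np.histogram(mids, bins=10, range=(0, L))
    chi2 = ((counts - len(df) / 10) ** 2 / (len(df) / 10)).sum()
    assert stats.chi2.sf(chi2, df=9) > 0.01


def test_all_zero_surface_raises():
    cfg = null_cfg()
    genome, features = simulate_genome(cfg)
    zero = {c: np.zeros(-(-L // 50)) for c, L in genome.chrom_sizes.items()}
    with pytest.raises(ValueError, match="zero"):
        simulate_fragments(genome, zero, cfg, "Z1")


def test_medip_enrichment_exceeds_input():
    cfg = small_cfg(seed=7, input_control=True, n_input_controls=1)
    ds = simulate_dataset(cfg)
    medip, _ = filter_fragments(ds.fragments["Young1"], genome=ds.genome)
    inp, _ = filter_fragments(ds.fragments["Input1"], genome=ds.genome)
    assert enrichment_score(medip, ds.genome) > enrichment_score(inp, ds.genome)


def test_hyper_dmr_density_ratio_monotone_in_effect_size():
    ratios = []
    for effect in (0.3, 0.8):
        r_seed = []
        for seed in (11, 12, 13):
            cfg = small_cfg(seed=seed, dmr_effect_log2fc=effect,
                            global_shift_fraction=0.0)
            ds = simulate_dataset(cfg)
            hyper = ds.truth.dmrs[ds.truth.dmrs["direction"] == "hyper"]

            def density(sample):
                df = ds.fragments[sample]
                mids = (df["start"] + df["end"]) // 2
                n = 0
                for _, r in hyper.iterrows():
                    n += int(((df["chrom"] == r["chrom"]) & (mids >= r["start"])
                              & (mids < r["end"])).sum())
                return n

            old = sum(density(s) for s in ("Old1", "Old2"))
            young = sum(density(s) for s in ("Young1", "Young2"))
            r_seed.append(old / young)
        ratios.append(np.mean(r_seed))
    assert ratios[0] > 1
    assert ratios[1] > ratios[0]
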