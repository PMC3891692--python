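# agemeth

MeDIP-seq analysis of the aging methylome, rebuilt as a tested, desk-scale
Python pipeline.

Methylated-DNA immunoprecipitation sequencing (MeDIP-seq) measures DNA
methylation through read density, but that density confounds methylation with
local CpG density. This package implements the full analysis chain used in
aging-methylome studies of sorted stem-cell populations — from aligned,
filtered read pairs to CpG-coupling-normalized methylation scores,
differentially methylated regions (DMRs), a permutation test for genomic DMR
hotspots, feature enrichment, and DMR-to-gene association — together with a
synthetic-data generator that emulates the study design (three age groups in
triplicate, CpG-density-dependent pull-down, an injected DMR hotspot, and a
small global methylation loss with age), so every stage is testable end to
end with known ground truth and no external downloads.

It is written for computational biologists who want either a reusable
implementation of these methods or a controlled test bed for them.

## The methods at the core

* **Pair filtering** — a read pair is kept iff it maps as a proper pair and
  at least one read has mapping quality ≥ 10; coordinate-identical pairs are
  collapsed to one.
* **Coupling-normalized methylation score** — for 50 bp bins *b* with raw
  fragment-midpoint count *n_b*, library size *N* and coupling factor
  *C_b* = #{CpG : |CpG − center(b)| ≤ 700 bp},

  &nbsp;&nbsp;&nbsp;&nbsp;score(b) = (n_b / (N / 10⁶)) / max(C_b, 1),

  with C_b = 0 bins flagged as carrying no methylation information.
* **Group comparison** — per-group pooled score distributions on bins covered
  in all compared samples; percent change of the old-group mean relative to
  the young, and a two-sided two-sample Kolmogorov–Smirnov test.
* **DMR calling** — adjacent nonzero bins merge into candidate regions (the
  *bump-list*; regions need ≥ 10 reads summed over the compared cohorts).
  Counts are modeled as negative binomial with median-of-ratios size factors
  s_j and a mean–dispersion trend α(μ) = a₀ + a₁/μ fitted across regions and
  assigned to every region (fit-only sharing). The two-sided exact test
  conditions on the region's summed count and adds up the probabilities of
  all allocations between the groups no more likely than the observed one.
  Benjamini–Hochberg FDR is controlled over all tested regions.
* **Hotspot permutation test** — DMRs are placed into fixed 100 kb windows by
  midpoint; the max window count is compared against 1000 draws of the same
  number of regions from the bump-list without replacement;
  empirical p = (1 + #{null ≥ observed}) / 1001.
* **Feature enrichment** — one-sided Fisher exact tests of hyper-/hypo-DMRs
  vs the rest of the bump-list per feature class (CGI, shore = 2000 bp CGI
  flank, exon, intron, intergenic); genes within 100 kb are associated with
  each DMR.

## Worked example

```python
import numpy as np
from agemeth import (SimConfig, simulate_dataset, build_coupling,
                     filter_fragments, methylation_track, global_comparison,
                     call_dmrs, hotspot_permutation)

cfg = SimConfig(seed=17)                  # default study conditions
ds = simulate_dataset(cfg)                # genome, annotation, truth, samples

coupling = build_coupling(ds.genome, bin_size=50, coupling_distance=700)
tracks = []
for sample_id, frags in ds.fragments.items():
    group = cfg.group_of(sample_id)
    if group == "Input":
        continue
    kept, tallies = filter_fragments(frags, min_mapq=10, genome=ds.genome)
    tracks.append(methylation_track(kept, coupling, sample_id, group))

comp = global_comparison(tracks, "Young", "Old", ds.genome)
print(f"global change Old vs Young: {comp.percent_change:+.2f}% "
      f"(KS D={comp.ks_statistic:.3f}, p={comp.ks_pvalue:.2e})")

result = call_dmrs(tracks, "Young", "Old", min_total_reads=10, fdr_threshold=0.2)
n_hyper = (result.dmrs["direction"] == "hyper").sum()
print(f"bump-list regions: {len(result.table)}; "
      f"DMRs at FDR<0.2: {len(result.dmrs)} ({n_hyper} hyper, "
      f"{len(result.dmrs) - n_hyper} hypo)")

perm = hotspot_permutation(result.dmrs, result.table, ds.genome,
                           window_size=100_000, n_permutations=1000,
                           rng=np.random.default_rng(17))
print(f"hotspot: {perm.observed_max_count} DMRs in window "
      f"{perm.observed_window[0]}:{perm.observed_window[1]}, "
      f"empirical p = {perm.empirical_p:.6f}")
```

Output:

```
global change Old vs Young: -4.29% (KS D=0.096, p=8.88e-52)
bump-list regions: 502; DMRs at FDR<0.2: 31 (25 hyper, 6 hypo)
hotspot: 14 DMRs in window chr1:500000, empirical p = 0.000999
```

Reading the numbers: the generator injected a 5% loss of non-island
methylation in the Old group; after coupling normalization that surfaces as a
−4.3% change in the mean bin score with a decisive KS rejection. Twenty true
DMRs were injected, eight of them clustered inside a single 100 kb window;
the caller reports 31 significant regions (clustered CpG patches can split
into more than one called region), and the permutation test finds the
injected hotspot window at the smallest p-value 1000 permutations can return
(1/1001).

## Command line

The same stages are available as subcommands operating on a run directory;
every stage can be re-run standalone on the previous stage's on-disk outputs:

```sh
agemeth all --run-dir run1 --seed 17          # simulate → qc → score → dmr → hotspot → enrich
agemeth dmr --config run1/config.json --run-dir run1
```

`run1/report.json` aggregates QC, the group comparisons, DMR counts by
direction, the hotspot summary, the enrichment table and (for simulated runs)
ground-truth recovery metrics, and embeds the fully resolved configuration.

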