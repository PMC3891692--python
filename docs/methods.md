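# Methods

This note documents the models behind `agemeth`: what the synthetic data
generator emulates and deliberately omits, the statistical procedures and
their numerical details, the defaults and why they were chosen, and known
limitations.

## 1. The synthetic MeDIP experiment

### Genome and annotation

The default genome is 2 chromosomes × 1 Mb with three CpG compartments:

| compartment | count | size | CpG rate (per bp) | baseline methylation |
|---|---|---|---|---|
| CpG islands (CGI) | 40 | ~800 bp | 0.15 | 0.40 ± 0.15 |
| CpG patches | 200 | 2 × 900 bp sub-clusters, 800 bp gap | 0.02 | 0.50 ± 0.15 |
| background | — | rest | 0.001 | 0.50 ± (patch jitter n/a) |

CpG positions are sampled per-bp Bernoulli at the compartment rate. "CpG
patches" stand for the intermediate-CpG-density territory of real genomes
(orphan CpG clusters, shore-like regions): they are CpG-dense enough for
MeDIP to assay but are not islands, and they carry most of the methylated
CpG mass. Each island and patch draws its own baseline methylation level
(class mean ± uniform jitter 0.15, clipped to [0.05, 0.95]); homogeneous
regional levels would make bin scores pile up at a few values, which real
methylomes do not do. Genes (25 per chromosome, 10–30 kb, 3–7 exons) are
laid down independently of the CpG compartments; shores extend exactly
2000 bp each side of a CGI, clipped at chromosome ends and neighbouring
CGIs; intergenic space is the complement of the gene set, so every base
belongs to at least one of {CGI, shore, exon, intron, intergenic}.

### Aging signal (ground truth)

Three components, each directly controllable:

* **Global shift** — Old latent levels equal Young × (1 − 0.05) outside
  CGIs. The Mid group is the arithmetic midpoint of Young and Old: the
  observed pattern of age-related change is progressive and directional, but
  no functional form is available, so the midpoint is the minimal choice.
* **DMRs** — 20 regions with per-region effect 2^(±1.0 × U(0.8, 1.2)) applied
  to the Old level (clipped to [0, 1]). Eight form a hypermethylated cluster
  of patches inside a single 100 kb window (the hotspot); of the remaining
  twelve, 25% are hypomethylated patches and the rest are hypermethylated
  CGIs. Placing the non-hotspot gains on islands mirrors the biology the
  pipeline is meant to recover — methylation gains concentrate at CpG
  islands while the diffuse non-island compartment loses methylation — and
  at desk scale it is also what keeps the global average negative: island
  gains add capture mass that renormalizes all other bins down, while their
  own contribution to the mean score is damped by the large island coupling
  factors.
* DMRs sit on patches and islands because MeDIP can only assay regions with
  appreciable CpG density; a "DMR" in a CpG desert would be invisible to the
  assay by construction.

### Capture model

A fragment's capture weight at a 50 bp bin is

    w(b) = methylation(b) × k(b)^e,   k(b) = CpGs within ±(fragment length)/2,

with e = 2 (`pulldown_exponent`) and a hard gate w = 0 when k < 3
(`min_cpgs_per_fragment`): anti-methyl-cytosine pull-down requires several
methylated CpGs per fragment and responds super-linearly to CpG density at
low density. With e = 0 the CpG dependence (gate included) is disabled and
sampling is uniform — the input-control regime. Fragment midpoints are drawn
∝ w; lengths are Normal(700, 100) truncated to [50, 1400] (700 bp is also
the coupling distance, reflecting the fragment size the coupling concept was
designed around). Each contiguous captured segment gets a per-replicate
gamma noise factor (CV 0.15, `replicate_noise_cv`), giving genuine
extra-Poisson between-replicate variation for the NB test to absorb.
Nuisance processes: 2% of pairs get both mapping qualities < 10, 5% exactly
one, 2% are improperly paired, 1% are injected exact duplicates.

Default depth is 2 × 10⁵ fragments per replicate, 3 replicates per group,
3 groups — large enough for NB testing on every candidate region, small
enough that a full pipeline run takes well under a minute.

### Reproducibility

Each sample derives its RNG stream from (master seed, CRC32(sample id));
genome, ground truth and baselines use fixed sub-streams. Identical
configuration (including seed) therefore yields byte-identical outputs, and
adding a replicate does not reshuffle existing samples.

### What the generator does not emulate

No base-level sequence, no sequencing errors, no bisulfite chemistry, no
mappability structure, no GC amplification bias, no chromosome-scale
methylation domains. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under a faithful abstraction of MeDIP sampling —
not that the pipeline is robust to every artifact of real libraries.

## 2. Analysis pipeline

### Filtering

A pair survives iff proper AND max(mapq₁, mapq₂) ≥ 10 — only pairs where
*neither* read reaches the threshold are removed. Duplicates collapse on
(chrom, start, end, sample); strand is ignored because fragment intervals
are strand-symmetric after pairing. Filtering is idempotent and survivors
are coordinate-sorted.

### QC statistics

The enrichment score is the plain ratio (CpGs per fragment-covered bp) /
(CpGs per bp genome-wide); an input-like library scores ≈ 1. It plays the
role of the MeDIP enrichment score reported by specialised packages but is
not numerically identical to their relH/GoGe variants, whose exact formula
is not recoverable. Replicate correlation uses 500 bp windows stepped by
250 bp, counting each fragment at its midpoint once per grid pass; windows
with fewer than 5 reads summed across the pair are excluded (`each` mode is
available — the source tooling pools, so `sum` is the default).

### Coupling normalization

Coupling factor C_b counts CpGs within ±700 bp of the bin centre (inclusive
edges). Score = (count / library-in-millions) / max(C_b, 1). The floor of 1
avoids dividing by zero while leaving zero-coupling bins flagged as no-data
rather than inflated. Fragments are never extended; the midpoint of the
sequenced fragment places it in exactly one bin, so bin counts sum to the
library size. A raw-count mode is available by reading
`MethylomeTrack.counts` directly.

### Group comparisons

Comparisons run on bins covered (count ≥ 1) in *all* compared samples and
containing ≥ 1 CpG — per-CpG attribution from MeDIP is not identifiable, so
the bin is the unit. The KS test is two-sample, two-sided, asymptotic;
exact when either pool has fewer than 50 observations.

**Calibration caveat (demonstrated by the test suite):** under an exact
null the pooled KS test rejects more often than its nominal level at desk
scale. Two structural reasons: the pools share bins and are heavily tied,
so the true variability of the D statistic differs from the iid KS null;
and the per-sample library normalization applies a tiny sample-specific
multiplicative offset that coherently splits the integer-valued
(count, coupling) score ties, adding a systematic CDF offset on the order
of the largest score atom. Both effects are properties of pooled KS testing
on depth-normalized discrete scores — the implementation's KS is exactly
calibrated on iid continuous data — and both vanish as scores become
continuous at real-data scale. Consequence: the KS p-value on the default
simulation is best read as decisive-vs-not, not as a calibrated tail
probability.

### DMR testing

* Bump-list: maximal runs of adjacent bins with nonzero summed counts across
  the compared cohorts; regions kept at ≥ 10 total reads. The merged run
  (not the 50 bp bin) is the tested unit.
* Size factors: median-of-ratios against the per-region geometric mean over
  regions positive in every sample, geometric-mean-centred; total-count
  fallback when no such region exists.
* Dispersion: per-region method-of-moments estimates pooled across groups,
  then a least-squares trend α(μ) = a₀ + a₁/μ; every region is assigned the
  *fitted* value (fit-only sharing, never the max of fitted and per-region),
  floored at 10⁻⁸. Fit-only sharing is mildly anti-conservative for regions
  whose true dispersion sits above the trend; the suite verifies the null
  fraction of p < 0.05 stays below 0.075 under the default conditions.
* Exact test: groups are modeled NB with mean q₀·Σs_j and variance
  mean + α q₀² Σs_j²; conditional on the summed count, the two-sided
  p-value sums allocation probabilities ≤ the observed one (relative tie
  tolerance 10⁻¹²; the pmf switches to Poisson when variance ≤ mean(1+10⁻⁷)).
  Verified against exhaustive enumeration and, in the α → 0 limit with unit
  size factors, against the conditional binomial exact test.
* Fold change: log₂ of normalized group means with pseudocount 0.5;
  direction is hyper iff the older group is higher. FDR by
  Benjamini–Hochberg over all tested regions; the reporting threshold is
  0.2 and the strict hotspot subset uses 0.01, both configurable.
* Heatmap: per-sample region-level normalized counts for all called DMRs
  across all three groups, row-scaled to [0, 1], to expose progressive
  change.

### Hotspot permutation

Fixed non-overlapping windows anchored at position 0 (a sliding variant is
deliberately not the default: the window description reads as a tiling);
a region belongs to the window containing its midpoint (half-open). Null
draws are uniform without replacement from the bump-list — the bump-list is
a set of regions, not a weighted population. The (k+1)/(n+1) correction
makes p = 0 impossible; 0 exceedances in 1000 permutations gives 1/1001,
matching a reported "p < 0.001". Exceedance is counted as ≥ (conservative);
`strict_greater` switches to >. The empirical p is superuniform under the
null (verified), but it is a discrete statistic: the null max-count
concentrates on a few integers, so its distribution cannot be (and is not)
two-sided-uniform on [0, 1].

### Feature enrichment and genes

A region is in a feature class when it overlaps ≥ 1 bp; the background for
each direction is the bump-list minus that direction's DMRs, so each 2×2
table sums to the bump-list size. Fisher is one-sided (greater): only
enrichment is claimed. Gene association is inclusive at the 100 kb cutoff,
distance 0 on overlap, nearest first, ties by gene id.

## 3. Problem sizes used by the test suite

Unit tests run on 1 chromosome × 400 kb with 2 replicates per group and
3 × 10⁴ fragments per replicate; end-to-end checks (hotspot, global shift,
recovery) run the full default conditions (2 × 1 Mb, 3 × 3 samples + 2
inputs, 2 × 10⁵ fragments each). Null-calibration checks use 200 seeds of
the small configuration (KS), five default-scale null simulations (NB test,
≥ 2500 regions), and 200 self-calibration repeats of the permutation test.
The whole suite runs in a few minutes on one CPU; `scripts/acceptance.py`
takes ~30 s.

## 4. Known limitations

* The coupling normalization is a declared "rms-like" score (CPM / coupling
  factor); it is not claimed identical to any specific historical
  normalization whose exact formula is unpublished.
* The pooled-KS calibration caveat above: at desk scale the global-comparison
  p-value is anti-conservative under the exact null.
* Fit-only dispersion sharing ignores per-region dispersion excursions above
  the trend; with many true DMRs the trend itself can be pulled up slightly,
  costing power rather than validity.
* The gene association step reports distances to annotated gene bodies only;
  no promoter/TSS-specific logic.
* Replicate exclusion (e.g., a low-correlation replicate) is exposed as
  configuration (`excluded_samples`) and applied from the scoring stage on;
  the package takes no position on whether such samples should also leave
  the DMR comparison.
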