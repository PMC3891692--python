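"""Synthetic MeDIP-seq data generator with known ground truth.

Generates a small genome (chromosome sizes + CpG positions), a consistent
feature annotation (CpG islands, 2000 bp shores, genes with exon/intron
structure, intergenic space, and intermediate-density "CpG patches"), a latent
per-bin methylation surface for each age group, and per-sample paired-end
fragment sets whose capture probability follows CpG density and methylation —
the defining bias of methylated-DNA immunoprecipitation.

Ground truth (which regions change with age, where the hotspot sits, the
global shift) is recorded so that every downstream stage can be scored for
recovery.  One RNG stream is derived per sample from (master seed, sample id),
so adding a replicate never reshuffles the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .genome import FeatureSet, GenomeModel, complement_intervals

_STREAM_GENOME = 101
_STREAM_TRUTH = 202
_STREAM_BASELINES = 303


def _rng_for(seed: int, *keys) -> np.random.Generator:
    ints = [int(seed)]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k))
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng, length: int, sizes: list[int], margin: int,
                          occupied: list[tuple[int, int]],
                          lo: int = 0, hi: int | None = None
                          ) -> list[tuple[int, int]]:
    """Place intervals of given sizes in [lo, hi) at least ``margin`` bp away
    from every ``occupied`` interval and from each other (mutates occupied).

    Placement is exact: each interval picks a start uniformly from the free
    capacity that remains, so it only fails when the capacity is truly
    exhausted.
    """
    hi = length if hi is None else hi
    placed = []
    for size in sizes:
        if hi - lo < size:
            raise ValueError(
                "feature demands exceed chromosome capacity: could not place "
                f"an interval of {size} bp in [{lo}, {hi})")
        # a start value x is forbidden iff [x, x+size) comes within margin of
        # an occupied interval [s, e): x in [s - margin - size + 1, e + margin)
        forbidden = sorted((s - margin - size + 1, e + margin)
                           for s, e in occupied)
        segments = []                  # allowed start ranges [a, b)
        cur = lo
        last = hi - size + 1           # starts are in [lo, hi - size]
        for fs, fe in forbidden:
            if fs > cur:
                segments.append((cur, min(fs, last)))
            cur = max(cur, fe)
            if cur >= last:
                break
        if cur < last:
            segments.append((cur, last))
        segments = [(a, b) for a, b in segments if b > a]
        total = sum(b - a for a, b in segments)
        if total <= 0:
            raise ValueError(
                "feature demands exceed chromosome capacity: could not place "
                f"an interval of {size} bp in [{lo}, {hi})")
        pick = int(rng.integers(0, total))
        for a, b in segments:
            if pick < b - a:
                start = a + pick
                break
            pick -= b - a
        occupied.append((start, start + size))
        occupied.sort()
        placed.append((start, start + size))
    return placed


def simulate_genome(cfg: SimConfig, shore_width: int = 2000
                    ) -> tuple[GenomeModel, FeatureSet]:
    """Simulate chromosome sizes, CpG positions and a consistent annotation.

    CpG positions are sampled per-bp Bernoulli at ``cgi_cpg_rate`` inside CGIs,
    ``cpg_patch_cpg_rate`` inside patches and ``background_cpg_rate`` elsewhere.
    Shores extend exactly ``shore_width`` bp on each side of a CGI, clipped at
    chromosome ends and at neighbouring CGI boundaries.  One hotspot-sized
    window on the first chromosome receives ``hotspot_dmr_count`` patches so a
    DMR cluster can be injected there.
    """
    rng = _rng_for(cfg.seed, _STREAM_GENOME)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    L = cfg.chrom_length
    sizes = {c: L for c in chroms}

    margin = 2 * cfg.fragment_length_mean  # keeps capture territories separate
    patch_footprint = 2 * cfg.cpg_patch_sublength + cfg.cpg_patch_gap
    demand = (cfg.cgi_count * (cfg.cgi_mean_length + margin)
              + cfg.cpg_patch_count * (patch_footprint + margin))
    if demand > 0.7 * cfg.n_chromosomes * L:
        raise ValueError("feature demands exceed chromosome capacity")

    rows: list[tuple] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    # --- hotspot window: reserve space on chr1 and fill it with patches -----
    n_hot = min(cfg.hotspot_dmr_count, cfg.cpg_patch_count)
    hot_chrom = chroms[0]
    n_windows = L // cfg.hotspot_window
    if n_windows >= 3:
        wi = int(rng.integers(1, n_windows - 1))
    else:
        wi = 0
    hot_lo, hot_hi = wi * cfg.hotspot_window, (wi + 1) * cfg.hotspot_window
    if n_hot * (patch_footprint + margin) > (hot_hi - hot_lo):
        raise ValueError("hotspot window too small for hotspot_dmr_count patches")

    patch_id = 0

    def add_patch(chrom: str, start: int, end: int) -> None:
        nonlocal patch_id
        patch_id += 1
        name = f"patch{patch_id:04d}"
        a_end = start + cfg.cpg_patch_sublength
        b_start = a_end + cfg.cpg_patch_gap
        rows.append((chrom, start, a_end, "cpg_patch", f"{name}/a"))
        rows.append((chrom, b_start, end, "cpg_patch", f"{name}/b"))

    for s, e in _place_nonoverlapping(rng, L, [patch_footprint] * n_hot, margin,
                                      occupied[hot_chrom], lo=hot_lo, hi=hot_hi):
        add_patch(hot_chrom, s, e)

    # --- remaining patches and CGIs, spread over the genome -----------------
    # keep the reserved window exclusive to its patch cluster
    occupied[hot_chrom].append((hot_lo, hot_hi))
    occupied[hot_chrom].sort()

    n_rest = cfg.cpg_patch_count - n_hot
    per_chrom = [n_rest // cfg.n_chromosomes + (1 if i < n_rest % cfg.n_chromosomes else 0)
                 for i in range(cfg.n_chromosomes)]
    for chrom, n in zip(chroms, per_chrom):
        for s, e in _place_nonoverlapping(rng, L, [patch_footprint] * n, margin,
                                          occupied[chrom]):
            add_patch(chrom, s, e)

    n_cgi = cfg.cgi_count
    per_chrom = [n_cgi // cfg.n_chromosomes + (1 if i < n_cgi % cfg.n_chromosomes else 0)
                 for i in range(cfg.n_chromosomes)]
    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    ci = 0
    for chrom, n in zip(chroms, per_chrom):
        lens = np.maximum(200, rng.normal(cfg.cgi_mean_length,
                                          cfg.cgi_mean_length / 8, n)).astype(int)
        for s, e in _place_nonoverlapping(rng, L, list(lens),
                                          max(margin, shore_width),
                                          occupied[chrom]):
            ci += 1
            rows.append((chrom, s, e, "cgi", f"cgi{ci:04d}"))
            cgi_by_chrom[chrom].append((s, e))

    # --- shores: exactly shore_width each side, clipped ---------------------
    for chrom in chroms:
        cgis = sorted(cgi_by_chrom[chrom])
        for i, (s, e) in enumerate(cgis):
            left_lim = cgis[i - 1][1] if i > 0 else 0
            right_lim = cgis[i + 1][0] if i + 1 < len(cgis) else L
            ls, le = max(left_lim, s - shore_width, 0), s
            rs, re = e, min(right_lim, e + shore_width, L)
            name = f"cgi{0:04d}"  # placeholder, replaced below
            name = [r[4] for r in rows
                    if r[0] == chrom and r[1] == s and r[3] == "cgi"][0]
            if ls < le:
                rows.append((chrom, ls, le, "shore", f"{name}/shoreL"))
            if rs < re:
                rows.append((chrom, rs, re, "shore", f"{name}/shoreR"))

    # --- genes with exon/intron structure -----------------------------------
    gi = 0
    for chrom in chroms:
        n_genes = cfg.genes_per_chromosome
        if n_genes == 0:
            rows.append((chrom, 0, L, "intergenic", f"{chrom}_ig1"))
            continue
        glens = rng.integers(10_000, 30_000, n_genes)
        total = int(glens.sum())
        if total >= L:
            raise ValueError("feature demands exceed chromosome capacity (genes)")
        gaps = rng.multinomial(L - total, np.ones(n_genes + 1) / (n_genes + 1))
        pos = 0
        gene_iv = []
        for glen, gap in zip(glens, gaps[:-1]):
            gs = pos + int(gap)
            ge = gs + int(glen)
            gi += 1
            gname = f"gene{gi:04d}"
            rows.append((chrom, gs, ge, "gene", gname))
            gene_iv.append((gs, ge))
            # exon/intron structure
            n_ex = int(rng.integers(3, 8))
            ex_lens = rng.integers(150, 400, n_ex)
            intron_total = int(glen - ex_lens.sum())
            if intron_total <= n_ex:   # degenerate, single-exon gene
                rows.append((chrom, gs, ge, "exon", f"{gname}/ex1"))
            else:
                iv = rng.multinomial(intron_total, np.ones(n_ex - 1) / (n_ex - 1))
                p = gs
                for k, el in enumerate(ex_lens):
                    rows.append((chrom, p, p + int(el), "exon", f"{gname}/ex{k + 1}"))
                    p += int(el)
                    if k < n_ex - 1:
                        rows.append((chrom, p, p + int(iv[k]), "intron",
                                     f"{gname}/in{k + 1}"))
                        p += int(iv[k])
            pos = ge
        s_arr = np.array([s for s, _ in gene_iv])
        e_arr = np.array([e for _, e in gene_iv])
        ig_s, ig_e = complement_intervals(s_arr, e_arr, L)
        for k, (s, e) in enumerate(zip(ig_s, ig_e)):
            rows.append((chrom, int(s), int(e), "intergenic", f"{chrom}_ig{k + 1}"))

    features = FeatureSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature_class", "name"]))

    # --- CpG positions -------------------------------------------------------
    cpgs: dict[str, np.ndarray] = {}
    for chrom in chroms:
        rate = np.full(L, cfg.background_cpg_rate)
        for _, r in features.df.iterrows():
            if r["chrom"] != chrom:
                continue
            if r["feature_class"] == "cgi":
                rate[r["start"]:r["end"]] = cfg.cgi_cpg_rate
            elif r["feature_class"] == "cpg_patch":
                rate[r["start"]:r["end"]] = cfg.cpg_patch_cpg_rate
        draw = rng.random(L) < rate
        draw[L - 1] = False            # a CpG needs room for the G
        cpgs[chrom] = np.flatnonzero(draw).astype(np.int64)

    return GenomeModel(sizes, cpgs), features


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Injected aging signal: DMR intervals, hotspot location, global shift."""

    dmrs: pd.DataFrame          # chrom,start,end,direction,effect_log2fc,baseline_meth,source,in_hotspot
    hotspot_location: tuple[str, int] | None
    global_shift_fraction: float

    def __post_init__(self) -> None:
        d = self.dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in d.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping ground-truth DMRs on {chrom}")
        self.dmrs = d

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            hs = ("none" if self.hotspot_location is None
                  else f"{self.hotspot_location[0]}:{self.hotspot_location[1]}")
            fh.write(f"#hotspot={hs}\tglobal_shift_fraction={self.global_shift_fraction}\n")
            self.dmrs.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#")
            fields = dict(kv.split("=") for kv in header.split("\t"))
            dmrs = pd.read_csv(fh, sep="\t")
        hs = fields["hotspot"]
        loc = None
        if hs != "none":
            chrom, start = hs.rsplit(":", 1)
            loc = (chrom, int(start))
        return cls(dmrs, loc, float(fields["global_shift_fraction"]))


def feature_baselines(features: FeatureSet, cfg: SimConfig) -> dict[str, float]:
    """Baseline methylation level per CGI and per CpG-patch footprint.

    Levels are the class mean plus a uniform jitter (deterministic for a
    given seed), clipped to [0.05, 0.95]: regional methylation in real
    genomes varies around the class average rather than sitting at it.
    """
    rng = _rng_for(cfg.seed, _STREAM_BASELINES)
    out: dict[str, float] = {}
    j = cfg.baseline_meth_jitter
    for _, r in features.of_class("cgi").iterrows():
        out[r["name"]] = float(np.clip(
            cfg.baseline_meth_cgi + rng.uniform(-j, j), 0.05, 0.95))
    patch_names = sorted({n.split("/")[0]
                          for n in features.of_class("cpg_patch")["name"]})
    for name in patch_names:
        out[name] = float(np.clip(
            cfg.baseline_meth_background + rng.uniform(-j, j), 0.05, 0.95))
    return out


def _patch_footprints(features: FeatureSet) -> pd.DataFrame:
    sub = features.of_class("cpg_patch").copy()
    if sub.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    sub["pname"] = sub["name"].str.split("/").str[0]
    agg = sub.groupby("pname").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
    return agg.reset_index().rename(columns={"pname": "name"})


def make_ground_truth(genome: GenomeModel, features: FeatureSet, cfg: SimConfig
                      ) -> GroundTruth:
    """Select ground-truth DMR intervals from the genome's CpG-dense territory.

    MeDIP can only assay regions with appreciable CpG density, so truth DMRs
    are drawn from CGIs and CpG patches.  The hotspot is the patch-densest
    window of size ``hotspot_window`` (ties to the reserved cluster laid down
    by :func:`simulate_genome`); its DMRs are all hypermethylated.
    """
    rng = _rng_for(cfg.seed, _STREAM_TRUTH)
    patches = _patch_footprints(features)
    cgis = features.of_class("cgi")

    hotspot = None
    hot_names: list[str] = []
    if cfg.hotspot_dmr_count > 0:
        best = (-1, None, None)
        for chrom in genome.chroms:
            sub = patches[patches["chrom"] == chrom]
            for ws in range(0, genome.chrom_sizes[chrom], cfg.hotspot_window):
                inside = sub[(sub["start"] >= ws)
                             & (sub["end"] <= ws + cfg.hotspot_window)]
                if len(inside) > best[0]:
                    best = (len(inside), chrom, ws)
        count, chrom, ws = best
        if count < cfg.hotspot_dmr_count:
            raise ValueError("no window holds enough patches for the hotspot")
        hotspot = (chrom, ws)
        inside = patches[(patches["chrom"] == chrom) & (patches["start"] >= ws)
                         & (patches["end"] <= ws + cfg.hotspot_window)]
        pick = rng.choice(len(inside), cfg.hotspot_dmr_count, replace=False)
        hot_names = inside.iloc[np.sort(pick)]["name"].tolist()

    remaining = cfg.true_dmr_count - cfg.hotspot_dmr_count
    n_hypo = int(round(cfg.dmr_hypo_fraction * remaining))
    n_hyper = remaining - n_hypo
    n_cgi_hyper = min(int(round(cfg.cgi_hyper_fraction * n_hyper)), len(cgis))
    n_patch_hyper = n_hyper - n_cgi_hyper

    free = patches[~patches["name"].isin(hot_names)]
    if cfg.hotspot_dmr_count > 0 and hotspot is not None:
        ch, ws = hotspot
        in_hot = ((free["chrom"] == ch) & (free["start"] >= ws)
                  & (free["end"] <= ws + cfg.hotspot_window))
        free = free[~in_hot]
    if n_patch_hyper + n_hypo > len(free):
        raise ValueError("not enough CpG patches for the requested DMR count")
    pick = rng.choice(len(free), n_patch_hyper + n_hypo, replace=False)
    picked = free.iloc[pick]
    hyper_patches = picked.iloc[:n_patch_hyper]
    hypo_patches = picked.iloc[n_patch_hyper:]
    cgi_pick = (cgis.iloc[np.sort(rng.choice(len(cgis), n_cgi_hyper, replace=False))]
                if n_cgi_hyper else cgis.iloc[:0])

    rows = []

    baselines = feature_baselines(features, cfg)

    def emit(df, direction, source, in_hotspot=False):
        for _, r in df.iterrows():
            grade = float(rng.uniform(0.8, 1.2))
            rows.append((r["chrom"], int(r["start"]), int(r["end"]), direction,
                         cfg.dmr_effect_log2fc * grade,
                         baselines[r["name"]], source, in_hotspot))

    emit(patches[patches["name"].isin(hot_names)], "hyper", "cpg_patch", True)
    emit(cgi_pick, "hyper", "cgi")
    emit(hyper_patches, "hyper", "cpg_patch")
    emit(hypo_patches, "hypo", "cpg_patch")

    dmrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                       "effect_log2fc", "baseline_meth",
                                       "source", "in_hotspot"])
    return GroundTruth(dmrs, hotspot, cfg.global_shift_fraction)


# ---------------------------------------------------------------------------
# latent methylation surface
# ---------------------------------------------------------------------------

@dataclass
class MethylationSurface:
    """Latent per-bin methylation level in [0, 1] for each group."""

    bin_size: int
    levels: dict[str, dict[str, np.ndarray]]   # group -> chrom -> array
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.groups = tuple(self.levels)


def _bin_range(start: int, end: int, bin_size: int, n_bins: int) -> slice:
    return slice(max(0, start // bin_size),
                 min(n_bins, -(-end // bin_size)))


def simulate_methylome(genome: GenomeModel, features: FeatureSet,
                       truth: GroundTruth, cfg: SimConfig,
                       bin_size: int = 50) -> MethylationSurface:
    """Deterministic latent methylation surface per group.

    Young carries the baseline (CGIs low, elsewhere high); Old equals Young
    times (1 - global_shift_fraction) outside CGIs, with DMR intervals further
    multiplied by 2**(+-effect) and clipped to [0, 1]; Mid is the arithmetic
    midpoint of Young and Old.
    """
    for _, r in truth.dmrs.iterrows():
        if r["chrom"] not in genome.chrom_sizes or r["end"] > genome.chrom_sizes[r["chrom"]]:
            raise ValueError("ground-truth DMR outside genome bounds")

    baselines = feature_baselines(features, cfg)
    young: dict[str, np.ndarray] = {}
    old: dict[str, np.ndarray] = {}
    for chrom, L in genome.chrom_sizes.items():
        n_bins = -(-L // bin_size)
        y = np.full(n_bins, cfg.baseline_meth_background, dtype=float)
        is_cgi = np.zeros(n_bins, dtype=bool)
        for _, r in features.of_class("cpg_patch").iterrows():
            if r["chrom"] == chrom:
                sl = _bin_range(r["start"], r["end"], bin_size, n_bins)
                y[sl] = baselines[r["name"].split("/")[0]]
        for _, r in features.of_class("cgi").iterrows():
            if r["chrom"] == chrom:
                sl = _bin_range(r["start"], r["end"], bin_size, n_bins)
                y[sl] = baselines[r["name"]]
                is_cgi[sl] = True
        o = y.copy()
        o[~is_cgi] *= (1.0 - truth.global_shift_fraction)
        for _, r in truth.dmrs.iterrows():
            if r["chrom"] != chrom:
                continue
            sl = _bin_range(r["start"], r["end"], bin_size, n_bins)
            mult = 2.0 ** (r["effect_log2fc"] if r["direction"] == "hyper"
                           else -r["effect_log2fc"])
            o[sl] = np.clip(o[sl] * mult, 0.0, 1.0)
        young[chrom] = y
        old[chrom] = o

    levels: dict[str, dict[str, np.ndarray]] = {}
    groups = cfg.groups
    for g in groups:
        if g == groups[0]:
            levels[g] = young
        elif g == groups[-1]:
            levels[g] = old
        else:
            levels[g] = {c: 0.5 * (young[c] + old[c]) for c in young}
    return MethylationSurface(bin_size, levels)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "mapq1", "mapq2",
                    "proper_pair", "sample_id"]


def capture_weights(genome: GenomeModel, surface_levels: dict[str, np.ndarray],
                    cfg: SimConfig, bin_size: int = 50) -> dict[str, np.ndarray]:
    """Per-bin MeDIP capture weight: (local CpG count)**exponent x methylation.

    The local CpG count is taken in a fragment-length window centred on the
    bin; fragments with fewer than ``min_cpgs_per_fragment`` CpGs are not
    captured (antibody binding needs several methyl-CpGs).  With exponent 0
    the CpG dependence (including the minimum-CpG gate) is disabled entirely.
    """
    half = cfg.fragment_length_mean // 2
    weights = {}
    for chrom, L in genome.chrom_sizes.items():
        n_bins = -(-L // bin_size)
        centers = np.arange(n_bins) * bin_size + bin_size // 2
        k = genome.count_cpgs(chrom, centers - half, centers + half)
        meth = surface_levels[chrom]
        if cfg.pulldown_exponent == 0:
            dens = np.ones(n_bins)
        else:
            dens = np.where(k >= cfg.min_cpgs_per_fragment,
                            k.astype(float) ** cfg.pulldown_exponent, 0.0)
        weights[chrom] = dens * meth
    return weights


def _segment_noise(rng, w: np.ndarray, cv: float) -> np.ndarray:
    """Multiply each contiguous positive-weight run by a gamma(mean 1, CV cv)."""
    if cv <= 0:
        return w
    pos = w > 0
    seg_start = pos & ~np.concatenate(([False], pos[:-1]))
    seg_id = np.cumsum(seg_start)       # 0 where before first segment
    n_seg = int(seg_id.max()) if len(seg_id) else 0
    if n_seg == 0:
        return w
    shape = 1.0 / cv ** 2
    factors = rng.gamma(shape, 1.0 / shape, n_seg + 1)
    factors[0] = 1.0
    out = w.copy()
    out[pos] = w[pos] * factors[seg_id[pos]]
    return out


def simulate_fragments(genome: GenomeModel, surface_levels: dict[str, np.ndarray] | None,
                       cfg: SimConfig, sample_id: str,
                       input_control: bool = False,
                       rng: np.random.Generator | None = None,
                       bin_size: int = 50) -> pd.DataFrame:
    """Draw one sample's paired-end fragments.

    MeDIP samples draw fragment midpoints proportional to the capture weight;
    input controls draw uniformly.  Injects the configured fractions of
    low-mapq pairs, improperly-paired pairs and exact duplicates.
    """
    if rng is None:
        rng = _rng_for(cfg.seed, sample_id)

    chroms = genome.chroms
    n_bins_per = {c: -(-genome.chrom_sizes[c] // bin_size) for c in chroms}
    if input_control:
        w_all = [np.full(n_bins_per[c], 1.0) for c in chroms]
    else:
        if surface_levels is None:
            raise ValueError("surface required for MeDIP samples")
        weights = capture_weights(genome, surface_levels, cfg, bin_size)
        w_all = [_segment_noise(rng, weights[c], cfg.replicate_noise_cv)
                 for c in chroms]
    w = np.concatenate(w_all)
    total = w.sum()
    if total <= 0:
        raise ValueError("capture weight is zero everywhere; nothing to sample")

    n_total = cfg.fragments_per_replicate
    n_dup = int(round(cfg.duplicate_fraction * n_total))
    n = n_total - n_dup

    idx = rng.choice(len(w), size=n, p=w / total)
    # map flat bin index back to (chrom, bin)
    offsets = np.cumsum([0] + [n_bins_per[c] for c in chroms])
    chrom_idx = np.searchsorted(offsets, idx, side="right") - 1
    bin_idx = idx - offsets[chrom_idx]

    mids = bin_idx * bin_size + rng.integers(0, bin_size, size=n)
    lengths = np.clip(rng.normal(cfg.fragment_length_mean,
                                 cfg.fragment_length_sd, size=n),
                      50, 2 * cfg.fragment_length_mean).astype(np.int64)
    starts = mids - lengths // 2
    chrom_arr = np.array(chroms, dtype=object)[chrom_idx]
    chrom_len = np.array([genome.chrom_sizes[c] for c in chroms])[chrom_idx]
    starts = np.clip(starts, 0, np.maximum(0, chrom_len - lengths))
    ends = np.minimum(starts + lengths, chrom_len)

    u = rng.random(n)
    both_low = u < cfg.mapq_fail_fraction
    one_low = (~both_low) & (u < cfg.mapq_fail_fraction + cfg.single_low_mapq_fraction)
    mapq1 = rng.integers(10, 61, size=n)
    mapq2 = rng.integers(10, 61, size=n)
    low1 = rng.integers(0, 10, size=n)
    low2 = rng.integers(0, 10, size=n)
    mapq1 = np.where(both_low, low1, mapq1)
    mapq2 = np.where(both_low, low2, mapq2)
    swap = rng.random(n) < 0.5
    mapq1 = np.where(one_low & swap, low1, mapq1)
    mapq2 = np.where(one_low & ~swap, low2, mapq2)
    proper = rng.random(n) >= cfg.improper_fraction

    df = pd.DataFrame({
        "chrom": chrom_arr,
        "start": starts.astype(np.int64),
        "end": ends.astype(np.int64),
        "name": [f"{sample_id}:{i}" for i in range(n)],
        "mapq1": mapq1.astype(np.int64),
        "mapq2": mapq2.astype(np.int64),
        "proper_pair": proper,
        "sample_id": sample_id,
    })
    if n_dup > 0:
        src = rng.choice(n, size=n_dup)
        dup = df.iloc[src].copy()
        dup["name"] = [f"{sample_id}:{n + i}" for i in range(n_dup)]
        df = pd.concat([df, dup], ignore_index=True)
    df = df.sort_values(["chrom", "start", "end", "name"],
                        kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    cfg: SimConfig
    genome: GenomeModel
    features: FeatureSet
    truth: GroundTruth
    surface: MethylationSurface
    fragments: dict[str, pd.DataFrame]    # sample id -> fragments

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.fragments
                if self.cfg.group_of(s) == group]


def simulate_dataset(cfg: SimConfig, shore_width: int = 2000,
                     bin_size: int = 50) -> SimulatedDataset:
    """Generate genome, annotation, ground truth, surface and all samples."""
    genome, features = simulate_genome(cfg, shore_width=shore_width)
    truth = make_ground_truth(genome, features, cfg)
    surface = simulate_methylome(genome, features, truth, cfg, bin_size=bin_size)
    fragments: dict[str, pd.DataFrame] = {}
    for sid in cfg.sample_ids:
        group = cfg.group_of(sid)
        if group == "Input":
            fragments[sid] = simulate_fragments(genome, None, cfg, sid,
                                                input_control=True,
                                                bin_size=bin_size)
        else:
            fragments[sid] = simulate_fragments(genome, surface.levels[group],
                                                cfg, sid, bin_size=bin_size)
    return SimulatedDataset(cfg, genome, features, truth, surface, fragments)
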