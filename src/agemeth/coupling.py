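"""CpG coupling factors and coupling-normalized methylation scores.

MeDIP read density confounds methylation with local CpG density.  The
coupling factor of a 50 bp bin counts the CpGs within a fixed distance
(default 700 bp, the fragment length used when the vector was introduced) of
the bin centre; dividing depth-normalized bin counts by it yields a
CpG-density-corrected methylation score, the unit used for all group
comparisons here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FeatureSet, GenomeModel


@dataclass
class CouplingVector:
    """Per-bin CpG coupling factors for a genome."""

    bin_size: int
    coupling_distance: int
    factors: dict[str, np.ndarray]     # chrom -> int array, one per bin

    def n_bins(self, chrom: str) -> int:
        return len(self.factors[chrom])


def n_bins_for(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def bin_centers(length: int, bin_size: int) -> np.ndarray:
    return np.arange(n_bins_for(length, bin_size)) * bin_size + bin_size // 2


def build_coupling(genome: GenomeModel, bin_size: int = 50,
                   coupling_distance: int = 700) -> CouplingVector:
    """Count, for every bin, the CpGs within +-coupling_distance of its centre.

    The count is inclusive at both window edges: a CpG at exactly
    ``center - d`` or ``center + d`` qualifies.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if coupling_distance < 0:
        raise ValueError("coupling_distance must be >= 0")
    factors = {}
    for chrom, L in genome.chrom_sizes.items():
        centers = bin_centers(L, bin_size)
        pos = genome.cpg_positions[chrom]
        lo = np.searchsorted(pos, centers - coupling_distance, side="left")
        hi = np.searchsorted(pos, centers + coupling_distance, side="right")
        factors[chrom] = (hi - lo).astype(np.int64)
    return CouplingVector(bin_size, coupling_distance, factors)


@dataclass
class MethylomeTrack:
    """Raw bin counts and coupling-normalized methylation scores for a sample.

    The normalized score of a bin is (count / library-size-in-millions)
    divided by max(coupling factor, coupling_floor); bins whose coupling
    factor is zero are flagged ``nodata`` (no CpG within reach, so MeDIP
    carries no methylation information there).
    """

    sample_id: str
    group: str
    bin_size: int
    counts: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    nodata: dict[str, np.ndarray]
    library_size: int
    chrom_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.chrom_order = tuple(self.counts)

    def flat(self, what: str = "scores") -> np.ndarray:
        d = getattr(self, what)
        return np.concatenate([d[c] for c in self.chrom_order])


def methylation_track(df: pd.DataFrame, coupling: CouplingVector,
                      sample_id: str, group: str = "",
                      coupling_floor: float = 1.0) -> MethylomeTrack:
    """Bin a sample's fragments and compute normalized methylation scores.

    The raw count of a bin is the number of fragments whose midpoint lies in
    it; fragment intervals are used as given, without extension.
    """
    if len(df) == 0:
        raise ValueError(f"sample {sample_id!r} has no fragments")
    counts = {}
    scores = {}
    nodata = {}
    lib = len(df)
    for chrom, fac in coupling.factors.items():
        sub = df[df["chrom"] == chrom]
        n = len(fac)
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        c = np.bincount(np.minimum(mids // coupling.bin_size, n - 1),
                        minlength=n).astype(np.int64)
        counts[chrom] = c
        cpm = c / (lib / 1e6)
        scores[chrom] = cpm / np.maximum(fac, coupling_floor)
        nodata[chrom] = fac == 0
    return MethylomeTrack(sample_id, group, coupling.bin_size,
                          counts, scores, nodata, lib)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Result of a young-vs-old score comparison on commonly covered bins."""

    group_a: str                       # younger group
    group_b: str                       # older group
    n_units: int                       # bins (or CGIs) entering the comparison
    mean_a: float
    mean_b: float
    percent_change: float              # 100 * (mean_b - mean_a) / mean_a
    ks_statistic: float
    ks_pvalue: float
    summaries: dict[str, dict[str, float]]   # per group five-number summary

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a, "group_b": self.group_b,
            "n_units": self.n_units, "mean_a": self.mean_a,
            "mean_b": self.mean_b, "percent_change": self.percent_change,
            "ks_statistic": self.ks_statistic, "ks_pvalue": self.ks_pvalue,
            "summaries": self.summaries,
        }


def _five_number(x: np.ndarray) -> dict[str, float]:
    q = np.quantile(x, [0, 0.25, 0.5, 0.75, 1])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


def _ks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    method = "exact" if min(len(a), len(b)) < 50 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def common_coverage_mask(tracks: list[MethylomeTrack],
                         genome: GenomeModel | None = None,
                         min_bin_cpgs: int = 1) -> dict[str, np.ndarray]:
    """Bins covered (raw count >= 1) in every track, restricted to bins that
    contain at least one CpG when a genome is supplied."""
    chroms = tracks[0].chrom_order
    masks = {}
    for chrom in chroms:
        m = np.ones(len(tracks[0].counts[chrom]), dtype=bool)
        for t in tracks:
            m &= t.counts[chrom] >= 1
        if genome is not None and min_bin_cpgs > 0:
            n = len(m)
            bs = tracks[0].bin_size
            starts = np.arange(n) * bs
            in_bin = genome.count_cpgs(chrom, starts, starts + bs)
            m &= in_bin >= min_bin_cpgs
        masks[chrom] = m
    return masks


def global_comparison(tracks: list[MethylomeTrack], group_a: str, group_b: str,
                      genome: GenomeModel | None = None) -> GroupComparison:
    """Compare pooled bin-level score distributions between two groups.

    Uses only bins covered in all compared samples (and containing >=1 CpG
    when the genome is given); pools each group's per-sample scores on those
    bins, reports group means, the percent change of the older group relative
    to the younger, a two-sample two-sided KS test, and box-plot summaries.
    """
    ta = [t for t in tracks if t.group == group_a]
    tb = [t for t in tracks if t.group == group_b]
    if not ta or not tb:
        raise ValueError(f"need >=1 track in each of {group_a!r} and {group_b!r}")
    masks = common_coverage_mask(ta + tb, genome)
    n_units = int(sum(m.sum() for m in masks.values()))
    if n_units == 0:
        raise ValueError("no commonly covered bins between the groups")

    def pooled(ts):
        return np.concatenate([np.concatenate([t.scores[c][masks[c]]
                                               for c in t.chrom_order])
                               for t in ts])

    xa, xb = pooled(ta), pooled(tb)
    mean_a, mean_b = float(xa.mean()), float(xb.mean())
    d, p = _ks(xa, xb)
    return GroupComparison(
        group_a, group_b, n_units, mean_a, mean_b,
        percent_change=100.0 * (mean_b - mean_a) / mean_a,
        ks_statistic=d, ks_pvalue=p,
        summaries={group_a: _five_number(xa), group_b: _five_number(xb)},
    )


def cgi_comparison(tracks: list[MethylomeTrack], features: FeatureSet,
                   group_a: str, group_b: str) -> GroupComparison | None:
    """Compare CGI-level mean scores between two groups.

    The score of a CGI in a sample is the mean normalized score over the
    CGI's bins; the group comparison then mirrors :func:`global_comparison`
    restricted to CGIs.  Returns None (with a warning) when the annotation
    holds no CGIs.
    """
    cgis = features.of_class("cgi")
    if cgis.empty:
        warnings.warn("annotation contains no CpG islands; skipping CGI comparison")
        return None
    ta = [t for t in tracks if t.group == group_a]
    tb = [t for t in tracks if t.group == group_b]
    if not ta or not tb:
        raise ValueError(f"need >=1 track in each of {group_a!r} and {group_b!r}")

    def cgi_scores(t: MethylomeTrack) -> np.ndarray:
        vals = []
        bs = t.bin_size
        for _, r in cgis.iterrows():
            chrom = r["chrom"]
            if chrom not in t.scores:
                continue
            lo = r["start"] // bs
            hi = -(-r["end"] // bs)
            vals.append(t.scores[chrom][lo:hi].mean())
        return np.array(vals)

    xa = np.concatenate([cgi_scores(t) for t in ta])
    xb = np.concatenate([cgi_scores(t) for t in tb])
    mean_a, mean_b = float(xa.mean()), float(xb.mean())
    d, p = _ks(xa, xb)
    return GroupComparison(
        group_a, group_b, len(cgis), mean_a, mean_b,
        percent_change=100.0 * (mean_b - mean_a) / mean_a,
        ks_statistic=d, ks_pvalue=p,
        summaries={group_a: _five_number(xa), group_b: _five_number(xb)},
    )
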