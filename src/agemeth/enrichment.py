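"""DMR hotspot permutation test and genomic feature enrichment.

The hotspot test tiles the genome with fixed, non-overlapping windows
(default 100 kb, anchored at position 0), assigns each region to the window
containing its midpoint, and asks whether the best window's DMR count could
arise by drawing the same number of regions at random from the bump-list.
The empirical p-value uses the (k + 1) / (n + 1) correction, so p = 0 is
impossible and 0/1000 exceedances gives p = 1/1001.

Feature enrichment contrasts DMRs of one direction against the remaining
bump-list regions with a one-sided Fisher exact test per feature class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FEATURE_CLASSES, FeatureSet, GenomeModel
from .dmr import label_features


# ---------------------------------------------------------------------------
# window counts
# ---------------------------------------------------------------------------

@dataclass
class WindowCounts:
    window_size: int
    counts: pd.DataFrame            # chrom, window_start, count
    max_count: int
    max_window: tuple[str, int]
    tie: bool


def _window_index(regions: pd.DataFrame, genome: GenomeModel,
                  window_size: int) -> np.ndarray:
    """Flat window index (over the genome tiling) of each region's midpoint."""
    n_win = {c: -(-genome.chrom_sizes[c] // window_size) for c in genome.chroms}
    offsets = {}
    off = 0
    for c in genome.chroms:
        offsets[c] = off
        off += n_win[c]
    mids = (regions["start"].to_numpy() + regions["end"].to_numpy()) // 2
    idx = np.empty(len(regions), dtype=np.int64)
    for chrom, sub in regions.groupby("chrom", sort=False):
        pos = sub.index.to_numpy()
        loc = regions.index.get_indexer(pos)
        idx[loc] = offsets[chrom] + np.minimum(
            mids[loc] // window_size, n_win[chrom] - 1)
    return idx


def _window_of_flat(flat: int, genome: GenomeModel, window_size: int
                    ) -> tuple[str, int]:
    off = 0
    for c in genome.chroms:
        n = -(-genome.chrom_sizes[c] // window_size)
        if flat < off + n:
            return c, int((flat - off) * window_size)
        off += n
    raise IndexError(flat)


def window_counts(regions: pd.DataFrame, genome: GenomeModel,
                  window_size: int = 100_000) -> WindowCounts:
    """Count regions per fixed window; report the most enriched window.

    A region belongs to the window containing its midpoint (half-open:
    midpoint exactly at a boundary goes to the following window).  Ties for
    the maximum are broken by (chromosome order, window start), first wins,
    and flagged.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    total_windows = sum(-(-genome.chrom_sizes[c] // window_size)
                        for c in genome.chroms)
    if regions.empty:
        return WindowCounts(window_size, pd.DataFrame(
            columns=["chrom", "window_start", "count"]), 0,
            (genome.chroms[0], 0), False)
    flat = _window_index(regions, genome, window_size)
    counts = np.bincount(flat, minlength=total_windows)
    best = int(np.argmax(counts))
    max_count = int(counts[best])
    tie = int((counts == max_count).sum()) > 1
    nz = np.flatnonzero(counts)
    rows = [( *_window_of_flat(int(i), genome, window_size), int(counts[i]))
            for i in nz]
    return WindowCounts(window_size,
                        pd.DataFrame(rows, columns=["chrom", "window_start",
                                                    "count"]),
                        max_count, _window_of_flat(best, genome, window_size),
                        tie)


# ---------------------------------------------------------------------------
# hotspot permutation
# ---------------------------------------------------------------------------

@dataclass
class PermutationSummary:
    window_size: int
    n_permutations: int
    observed_max_count: int
    observed_window: tuple[str, int]
    null_max_counts: np.ndarray
    empirical_p: float
    strict_greater: bool = False

    def to_dict(self) -> dict:
        return {
            "window_size": self.window_size,
            "n_permutations": self.n_permutations,
            "observed_max_count": self.observed_max_count,
            "observed_window": list(self.observed_window),
            "empirical_p": self.empirical_p,
            "strict_greater": self.strict_greater,
            "null_max_counts": [int(v) for v in self.null_max_counts],
        }


def hotspot_permutation(observed: pd.DataFrame, bumps: pd.DataFrame,
                        genome: GenomeModel, window_size: int = 100_000,
                        n_permutations: int = 1000,
                        rng: np.random.Generator | int | None = None,
                        strict_greater: bool = False) -> PermutationSummary:
    """Permutation test for spatial clustering of DMRs.

    Each permutation draws ``len(observed)`` regions from the bump-list
    uniformly without replacement and records the null max window count.
    empirical_p = (1 + #{null >= observed}) / (n_permutations + 1), or with a
    strict > when ``strict_greater`` is set.
    """
    if len(bumps) < len(observed):
        raise ValueError("bump-list smaller than the observed DMR list")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs = window_counts(observed, genome, window_size)
    total_windows = sum(-(-genome.chrom_sizes[c] // window_size)
                        for c in genome.chroms)
    bump_windows = _window_index(bumps.reset_index(drop=True), genome, window_size)
    n_obs = len(observed)
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        draw = rng.choice(len(bump_windows), size=n_obs, replace=False)
        null[i] = np.bincount(bump_windows[draw], minlength=total_windows).max()
    exceed = (null > obs.max_count if strict_greater
              else null >= obs.max_count).sum()
    p = (1 + int(exceed)) / (n_permutations + 1)
    return PermutationSummary(window_size, n_permutations, obs.max_count,
                              obs.max_window, null, p, strict_greater)


# ---------------------------------------------------------------------------
# feature enrichment
# ---------------------------------------------------------------------------

def feature_enrichment(dmrs: pd.DataFrame, bumps: pd.DataFrame,
                       features: FeatureSet,
                       directions: tuple[str, ...] = ("hyper", "hypo"),
                       classes: tuple[str, ...] = FEATURE_CLASSES
                       ) -> pd.DataFrame:
    """One-sided Fisher enrichment of DMRs in feature classes vs the bump-list.

    A region is "in" a class when it overlaps >= 1 bp of it (a region may hit
    several classes).  For each direction, the background is the bump-list
    minus the DMRs of that direction, so every 2x2 table sums to the
    bump-list size.  Rows are sorted by p within direction.
    """
    labeled_bumps = label_features(bumps.reset_index(drop=True), features, classes)
    key_cols = ["chrom", "start", "end"]
    bump_keys = set(map(tuple, labeled_bumps[key_cols].to_numpy()))
    rows = []
    for direction in directions:
        sub = dmrs[dmrs.get("direction", pd.Series(dtype=str)) == direction] \
            if len(dmrs) else dmrs
        keys = set(map(tuple, sub[key_cols].to_numpy())) if len(sub) else set()
        if not keys <= bump_keys:
            raise ValueError("every DMR must be a member of the bump-list")
        is_dmr = np.array([tuple(k) in keys
                           for k in labeled_bumps[key_cols].to_numpy()])
        for cls in classes:
            in_cls = labeled_bumps[f"in_{cls}"].to_numpy()
            a = int((is_dmr & in_cls).sum())
            b = int((is_dmr & ~in_cls).sum())
            c = int((~is_dmr & in_cls).sum())
            d = int((~is_dmr & ~in_cls).sum())
            if a + b == 0:
                odds, p = 0.0, 1.0
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]],
                                             alternative="greater")
            rows.append((direction, cls, a, b, c, d, float(odds), float(p)))
    out = pd.DataFrame(rows, columns=["direction", "feature_class",
                                      "a", "b", "c", "d", "odds_ratio",
                                      "p_value"])
    return (out.sort_values(["direction", "p_value", "feature_class"])
               .reset_index(drop=True))
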