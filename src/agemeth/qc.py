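"""Fragment ingestion, filtering and library quality control.

Filtering follows the original pipeline's rules: a pair is removed when it
fails to map as a proper pair, or when neither read reaches mapping quality
10; of coordinate-identical pairs all but one are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .simulate import FRAGMENT_COLUMNS


def validate_fragments(df: pd.DataFrame, genome: GenomeModel | None = None) -> None:
    """Raise ValueError naming the first malformed record, if any."""
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        raise ValueError(f"malformed fragment record at index {bad[0]}: start >= end")
    if (df["mapq1"].to_numpy() < 0).any() or (df["mapq2"].to_numpy() < 0).any():
        bad = df.index[(df["mapq1"] < 0) | (df["mapq2"] < 0)]
        raise ValueError(f"malformed fragment record at index {bad[0]}: negative mapq")
    if genome is not None:
        known = set(genome.chrom_sizes)
        bad = df.index[~df["chrom"].isin(known)]
        if len(bad):
            raise ValueError(
                f"malformed fragment record at index {bad[0]}: unknown chromosome")


def filter_fragments(df: pd.DataFrame, min_mapq: int = 10,
                     genome: GenomeModel | None = None
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the pair filters; return survivors (coordinate-sorted) + tallies.

    Keeps a pair iff it is a proper pair AND at least one read has mapping
    quality >= ``min_mapq`` (only pairs where *neither* read reaches the
    threshold are removed).  Among pairs with identical
    (chrom, start, end, sample_id) exactly one survives.
    """
    validate_fragments(df, genome)
    n_input = len(df)
    proper = df["proper_pair"].to_numpy(dtype=bool)
    removed_improper = int((~proper).sum())
    df = df[proper]
    ok_mapq = np.maximum(df["mapq1"].to_numpy(), df["mapq2"].to_numpy()) >= min_mapq
    removed_mapq = int((~ok_mapq).sum())
    df = df[ok_mapq]
    df = df.sort_values(["sample_id", "chrom", "start", "end", "name"],
                        kind="mergesort")
    dup = df.duplicated(subset=["chrom", "start", "end", "sample_id"], keep="first")
    removed_dup = int(dup.sum())
    out = (df[~dup]
           .sort_values(["chrom", "start", "end", "sample_id"], kind="mergesort")
           .reset_index(drop=True))
    tallies = {
        "n_input_pairs": n_input,
        "removed_improper_pair": removed_improper,
        "removed_low_mapq": removed_mapq,
        "removed_duplicate": removed_dup,
        "n_after_filters": len(out),
    }
    return out, tallies


def enrichment_score(df: pd.DataFrame, genome: GenomeModel) -> float:
    """CpG enrichment of the library over the genomic background.

    (mean CpG count per fragment-covered bp) / (mean CpG count per bp
    genome-wide).  An input-like (uniform) library scores ~1; a MeDIP library
    scores above 1.  This is a plain observed/expected CpG-density ratio; it
    plays the role of the published "MeDIP enrichment score" but is not
    claimed numerically identical to it.
    """
    if len(df) == 0:
        raise ValueError("enrichment_score needs at least one fragment")
    cpg_total = 0
    bp_total = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        cpg_total += int(genome.count_cpgs(chrom, s, e).sum())
        bp_total += int((e - s).sum())
    genome_rate = genome.n_cpgs / genome.total_length
    return (cpg_total / bp_total) / genome_rate


def cpg_coverage(df: pd.DataFrame, genome: GenomeModel
                 ) -> tuple[float, dict[int, float]]:
    """Fraction of genome CpGs overlapped by >=1 fragment + fold histogram."""
    n_cpg = genome.n_cpgs
    if n_cpg == 0:
        return 0.0, {0: 1.0}
    folds = []
    for chrom in genome.chroms:
        pos = genome.cpg_positions[chrom]
        if len(pos) == 0:
            continue
        L = genome.chrom_sizes[chrom]
        depth_diff = np.zeros(L + 1, dtype=np.int64)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            np.add.at(depth_diff, sub["start"].to_numpy(), 1)
            np.add.at(depth_diff, sub["end"].to_numpy(), -1)
        depth = np.cumsum(depth_diff[:-1])
        folds.append(depth[pos])
    folds = np.concatenate(folds) if folds else np.zeros(0, dtype=np.int64)
    counts = np.bincount(folds)
    hist = {int(k): float(v) / n_cpg for k, v in enumerate(counts) if v > 0}
    fraction = float((folds >= 1).sum()) / n_cpg
    return fraction, hist


def window_read_counts(df: pd.DataFrame, genome: GenomeModel,
                       window: int = 500, step: int = 250) -> np.ndarray:
    """Fragment counts in sliding windows of ``window`` bp stepped by ``step``.

    A fragment counts in every window its midpoint falls in (one count per
    window-grid pass, avoiding fragment-length bias).  Requires window to be
    an integer multiple of step.
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    span = window // step
    out = []
    for chrom in genome.chroms:
        L = genome.chrom_sizes[chrom]
        n_cells = -(-L // step)
        sub = df[df["chrom"] == chrom]
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        cells = np.bincount(np.minimum(mids // step, n_cells - 1),
                            minlength=n_cells)
        n_win = max(0, n_cells - span + 1)
        csum = np.concatenate(([0], np.cumsum(cells)))
        out.append(csum[span:span + n_win] - csum[:n_win])
    return np.concatenate(out)


def replicate_correlation(df_a: pd.DataFrame, df_b: pd.DataFrame,
                          genome: GenomeModel, window: int = 500,
                          step: int = 250, min_reads: int = 5,
                          mode: str = "sum") -> float:
    """Pearson correlation of windowed fragment counts between two samples.

    Counts are taken in ``window`` bp windows advanced in ``step`` bp
    increments; windows below ``min_reads`` are excluded before computing r
    (``mode='sum'``: summed across the pair; ``mode='each'``: required of each
    sample).  Returns NaN when fewer than two windows survive.
    """
    a = window_read_counts(df_a, genome, window, step)
    b = window_read_counts(df_b, genome, window, step)
    if mode == "sum":
        keep = (a + b) >= min_reads
    elif mode == "each":
        keep = (a >= min_reads) & (b >= min_reads)
    else:
        raise ValueError("mode must be 'sum' or 'each'")
    a, b = a[keep], b[keep]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class QCReport:
    """Per-sample filter tallies and library QC statistics."""

    tallies: dict[str, dict[str, int]]
    enrichment_scores: dict[str, float]
    cpg_coverage_fraction: dict[str, float]
    coverage_histograms: dict[str, dict[int, float]] = field(default_factory=dict)
    pairwise_correlations: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, t in self.tallies.items():
            rows.append({
                "sample_id": sid,
                **t,
                "enrichment_score": self.enrichment_scores.get(sid, float("nan")),
                "cpg_coverage_fraction": self.cpg_coverage_fraction.get(sid, float("nan")),
            })
        return pd.DataFrame(rows)


def qc_report(fragments: dict[str, pd.DataFrame], genome: GenomeModel,
              min_mapq: int = 10, window: int = 500, step: int = 250,
              min_reads: int = 5, mode: str = "sum",
              medip_samples: list[str] | None = None
              ) -> tuple[dict[str, pd.DataFrame], QCReport]:
    """Filter every sample and assemble the QC report.

    Pairwise correlations are computed between the MeDIP samples only (input
    controls are excluded from the correlation matrix by default).
    """
    filtered: dict[str, pd.DataFrame] = {}
    tallies: dict[str, dict[str, int]] = {}
    scores: dict[str, float] = {}
    coverage: dict[str, float] = {}
    hists: dict[str, dict[int, float]] = {}
    for sid, df in fragments.items():
        filt, t = filter_fragments(df, min_mapq=min_mapq, genome=genome)
        filtered[sid] = filt
        tallies[sid] = t
        scores[sid] = enrichment_score(filt, genome) if len(filt) else float("nan")
        coverage[sid], hists[sid] = cpg_coverage(filt, genome)
    ids = medip_samples if medip_samples is not None else list(fragments)
    corr = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            r = replicate_correlation(filtered[a], filtered[b], genome,
                                      window, step, min_reads, mode)
            corr.loc[a, b] = corr.loc[b, a] = r
    return filtered, QCReport(tallies, scores, coverage, hists, corr)
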