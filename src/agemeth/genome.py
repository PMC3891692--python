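"""Genome model: chromosome sizes and CpG dinucleotide positions.

All coordinates in this package are 0-based, half-open intervals, the BED
convention.  The :class:`GenomeModel` is the coordinate frame for every
downstream computation (binning, coupling factors, coverage).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("cgi", "shore", "exon", "intron", "intergenic")


@dataclass
class GenomeModel:
    """Chromosome sizes plus sorted CpG positions per chromosome.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.  Insertion order defines
        chromosome order everywhere (window tilings, sorted output).
    cpg_positions
        Mapping chromosome name -> sorted int array of CpG start positions
        (position of the C of each CpG dinucleotide).
    """

    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
            pos = np.asarray(self.cpg_positions.get(chrom, np.empty(0, dtype=np.int64)),
                             dtype=np.int64)
            if pos.size and (pos.min() < 0 or pos.max() >= size):
                raise ValueError(f"CpG positions outside chromosome {chrom!r}")
            self.cpg_positions[chrom] = np.sort(pos)
        extra = set(self.cpg_positions) - set(self.chrom_sizes)
        if extra:
            raise ValueError(f"CpG positions for unknown chromosomes: {sorted(extra)}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))

    def count_cpgs(self, chrom: str, starts, ends) -> np.ndarray:
        """Number of CpG positions in each half-open interval [start, end)."""
        pos = self.cpg_positions[chrom]
        lo = np.searchsorted(pos, np.asarray(starts), side="left")
        hi = np.searchsorted(pos, np.asarray(ends), side="left")
        return hi - lo

    # ---- on-disk form: chrom.sizes TSV + CpG BED3 -------------------------
    def to_files(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "chrom.sizes"), "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        with open(os.path.join(directory, "cpgs.bed"), "w") as fh:
            for chrom in self.chroms:
                for p in self.cpg_positions[chrom]:
                    fh.write(f"{chrom}\t{p}\t{p + 2}\n")

    @classmethod
    def from_files(cls, directory: str) -> "GenomeModel":
        sizes: dict[str, int] = {}
        with open(os.path.join(directory, "chrom.sizes")) as fh:
            for line in fh:
                chrom, size = line.split()
                sizes[chrom] = int(size)
        cpgs: dict[str, list[int]] = {c: [] for c in sizes}
        with open(os.path.join(directory, "cpgs.bed")) as fh:
            for line in fh:
                chrom, start, _end = line.split()[:3]
                cpgs[chrom].append(int(start))
        return cls(sizes, {c: np.array(v, dtype=np.int64) for c, v in cpgs.items()})

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeModel":
        """Build the model from a FASTA file, scanning for CpG dinucleotides."""
        from pyfaidx import Fasta

        fa = Fasta(path)
        sizes: dict[str, int] = {}
        cpgs: dict[str, np.ndarray] = {}
        for name in fa.keys():
            seq = str(fa[name][:]).upper()
            sizes[name] = len(seq)
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
            cpgs[name] = np.flatnonzero(is_cg).astype(np.int64)
        return cls(sizes, cpgs)


class FeatureSet:
    """Genomic feature annotation (CGIs, shores, exons, introns, genes, ...).

    Backed by a DataFrame with columns chrom, start, end, feature_class, name.
    Intervals within one feature class are expected to be non-overlapping on a
    chromosome (true for everything this package emits).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end", "feature_class", "name"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"FeatureSet missing columns: {sorted(missing)}")
        self.df = df.sort_values(["feature_class", "chrom", "start"]).reset_index(drop=True)
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def classes(self) -> list[str]:
        return sorted(self.df["feature_class"].unique())

    def of_class(self, feature_class: str) -> pd.DataFrame:
        return self.df[self.df["feature_class"] == feature_class]

    def _chrom_index(self, feature_class: str, chrom: str):
        key = (feature_class, chrom)
        if key not in self._index:
            sub = self.df[(self.df["feature_class"] == feature_class)
                          & (self.df["chrom"] == chrom)]
            order = np.argsort(sub["start"].to_numpy())
            self._index[key] = (sub["start"].to_numpy()[order],
                                sub["end"].to_numpy()[order],
                                sub["name"].to_numpy()[order])
        return self._index[key]

    def overlaps_any(self, feature_class: str, chrom: str, starts, ends) -> np.ndarray:
        """Boolean array: does each query interval overlap >=1 bp of the class?

        Uses the non-overlapping-within-class property: a query [s, e) hits an
        interval iff some feature start < e and the preceding feature end > s.
        """
        f_start, f_end, _ = self._chrom_index(feature_class, chrom)
        starts = np.atleast_1d(np.asarray(starts))
        ends = np.atleast_1d(np.asarray(ends))
        if f_start.size == 0:
            return np.zeros(starts.shape, dtype=bool)
        # candidate: last feature with start < e
        idx = np.searchsorted(f_start, ends, side="left") - 1
        hit = np.zeros(starts.shape, dtype=bool)
        valid = idx >= 0
        hit[valid] = f_end[idx[valid]] > starts[valid]
        # also cover the case where the query spans several features: the
        # candidate above is the rightmost feature starting before e, which is
        # sufficient because intervals within a class do not overlap.
        return hit

    def to_bed(self, path: str) -> None:
        out = self.df.sort_values(["chrom", "start", "feature_class"])
        out.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "feature_class", "name"])

    @classmethod
    def from_bed(cls, path: str) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "feature_class", "name"],
                         dtype={"chrom": str, "name": str})
        return cls(df)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted-by-start intervals into disjoint ones."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def complement_intervals(starts: np.ndarray, ends: np.ndarray, length: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Complement of disjoint sorted intervals within [0, length)."""
    starts, ends = merge_intervals(np.asarray(starts), np.asarray(ends))
    bounds_s, bounds_e = [], []
    prev = 0
    for s, e in zip(starts, ends):
        if s > prev:
            bounds_s.append(prev)
            bounds_e.append(s)
        prev = max(prev, e)
    if prev < length:
        bounds_s.append(prev)
        bounds_e.append(length)
    return np.array(bounds_s, dtype=np.int64), np.array(bounds_e, dtype=np.int64)
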