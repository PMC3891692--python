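"""Plain-text readers and writers for the pipeline's on-disk formats.

Fragments travel as BED6+3 (chrom, start, end, name=sample:pairid,
score=min mapq of the pair, strand, mapq1, mapq2, proper_pair); a plain
6-column BED is also accepted on input, in which case both mapqs take the
score value and pairs are assumed proper.  Tracks and coupling vectors are
bedGraph; tables are TSV; summaries are JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .coupling import CouplingVector, MethylomeTrack
from .genome import GenomeModel


def write_fragments_bed(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["score"] = np.minimum(out["mapq1"], out["mapq2"])
    out["strand"] = "."
    out["proper_pair"] = out["proper_pair"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False,
               columns=["chrom", "start", "end", "name", "score", "strand",
                        "mapq1", "mapq2", "proper_pair"])


def read_fragments_bed(path: str, sample_id: str | None = None) -> pd.DataFrame:
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    n_cols = first.shape[1]
    if n_cols >= 9:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score",
                                "strand", "mapq1", "mapq2", "proper_pair"],
                         dtype={"chrom": str, "name": str})
        df["proper_pair"] = df["proper_pair"].astype(bool)
    elif n_cols >= 6:
        df = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                         names=["chrom", "start", "end", "name", "score",
                                "strand"],
                         dtype={"chrom": str, "name": str})
        df["mapq1"] = df["score"]
        df["mapq2"] = df["score"]
        df["proper_pair"] = True
    else:
        raise ValueError(f"{path}: expected >=6 BED columns, got {n_cols}")
    if sample_id is None:
        df["sample_id"] = df["name"].str.split(":").str[0]
    else:
        df["sample_id"] = sample_id
    return df.drop(columns=["score", "strand"], errors="ignore")


def fragments_from_bam(path: str, sample_id: str, min_len: int = 1) -> pd.DataFrame:
    """Map a coordinate-sorted paired-end BAM/SAM onto fragment records.

    Uses read1 of each pair; the fragment interval is the template span, the
    two mapping qualities come from the pair, and the proper-pair flag from
    the SAM flags.  Requires pysam.
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    rows = []
    mates: dict[str, int] = {}
    with pysam.AlignmentFile(path, mode) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_read2:
                mates[rec.query_name] = rec.mapping_quality
                continue
            tlen = abs(rec.template_length)
            if tlen < min_len:
                continue
            # the fragment spans from the leftmost mate start over |tlen| bp
            start = min(rec.reference_start, rec.next_reference_start)
            rows.append((rec.reference_name, start, start + tlen,
                         f"{sample_id}:{rec.query_name}",
                         rec.mapping_quality, rec.query_name,
                         rec.is_proper_pair))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "mapq1", "qname", "proper_pair"])
    df["mapq2"] = df["qname"].map(mates).fillna(df["mapq1"]).astype(int)
    df["sample_id"] = sample_id
    return df.drop(columns=["qname"])


def write_bedgraph(values: dict[str, np.ndarray], bin_size: int, path: str,
                   genome: GenomeModel | None = None) -> None:
    """Write per-bin values as bedGraph; zero bins are omitted (sparse form)."""
    frames = []
    for chrom, vals in values.items():
        L = genome.chrom_sizes[chrom] if genome else len(vals) * bin_size
        nz = np.flatnonzero(vals)
        starts = nz * bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + bin_size, L),
            "value": np.asarray(vals)[nz],
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["chrom", "start", "end", "value"]))
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.10g")


def write_track(track: MethylomeTrack, path: str,
                genome: GenomeModel | None = None) -> None:
    write_bedgraph(track.scores, track.bin_size, path, genome)


def write_coupling(coupling: CouplingVector, path: str,
                   genome: GenomeModel | None = None) -> None:
    write_bedgraph(coupling.factors, coupling.bin_size, path, genome)


def read_track_counts(path: str, genome: GenomeModel, bin_size: int
                      ) -> dict[str, np.ndarray]:
    """Read a bedGraph of per-bin values back into per-chromosome arrays."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    out = {}
    for chrom, L in genome.chrom_sizes.items():
        n = -(-L // bin_size)
        arr = np.zeros(n)
        sub = df[df["chrom"] == chrom]
        arr[sub["start"].to_numpy() // bin_size] = sub["value"].to_numpy()
        out[chrom] = arr
    return out


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)
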