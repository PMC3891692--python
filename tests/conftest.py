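import numpy as np
import pandas as pd
import pytest

from agemeth import (SimConfig, build_coupling, call_dmrs, filter_fragments,
                     methylation_track, simulate_dataset)
from agemeth.genome import GenomeModel


def make_fragments(rows, sample_id="S1"):
    """Build a fragment DataFrame from (chrom, start, end[, mapq1, mapq2, proper])."""
    recs = []
    for i, r in enumerate(rows):
        chrom, start, end = r[:3]
        mapq1 = r[3] if len(r) > 3 else 30
        mapq2 = r[4] if len(r) > 4 else 30
        proper = r[5] if len(r) > 5 else True
        recs.append((chrom, start, end, f"{sample_id}:{i}", mapq1, mapq2,
                     proper, sample_id))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name",
                                       "mapq1", "mapq2", "proper_pair",
                                       "sample_id"])


def small_cfg(seed=1, **kw):
    """A fast, fully functional simulation configuration for unit tests."""
    base = dict(n_chromosomes=1, chrom_length=400_000, cgi_count=6,
                cpg_patch_count=30, genes_per_chromosome=8,
                replicates_per_group=2, fragments_per_replicate=30_000,
                true_dmr_count=6, hotspot_dmr_count=3,
                groups=("Young", "Old"), input_control=False)
    base.update(kw)
    return SimConfig(seed=seed, **base)


def null_cfg(seed=1, **kw):
    kw.setdefault("true_dmr_count", 0)
    kw.setdefault("hotspot_dmr_count", 0)
    kw.setdefault("global_shift_fraction", 0.0)
    return small_cfg(seed, **kw)


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeModel(
        {"chrA": 2_000, "chrB": 1_000},
        {"chrA": np.array([100, 500, 1000]), "chrB": np.array([10, 60, 110])},
    )


def analyse(cfg, with_dmr=True):
    """Simulate and run the in-memory analysis used across the suite."""
    ds = simulate_dataset(cfg)
    coupling = build_coupling(ds.genome)
    tracks = []
    for sid, df in ds.fragments.items():
        group = cfg.group_of(sid)
        if group == "Input":
            continue
        filt, _ = filter_fragments(df, genome=ds.genome)
        tracks.append(methylation_track(filt, coupling, sid, group))
    result = call_dmrs(tracks, "Young", "Old") if with_dmr else None
    return ds, coupling, tracks, result


@pytest.fixture(scope="session")
def default_analysis():
    """One full default-condition run (seed 17), shared across tests."""
    return analyse(SimConfig(seed=17))
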