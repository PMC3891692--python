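"""Configuration objects for the simulator and the pipeline.

Configs round-trip through a flat ``key=value`` file or a JSON dialect; both
are accepted by :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic MeDIP data generator.

    The genome layout emulates a mammalian methylome at desk scale: a small
    number of CpG islands (CGIs, CpG-dense and mostly unmethylated), a larger
    set of intermediate-density "CpG patches" (orphan CpG clusters / shore-like
    regions, methylated), and a CpG-poor methylated background.  MeDIP capture
    concentrates on CpG-dense fragments, so islands and patches carry nearly
    all read mass, as in real MeDIP libraries.

    The aging signal has three components, each with its own knob: regional
    DMRs of graded effect (``true_dmr_count`` / ``dmr_effect_log2fc``), a
    spatial cluster of hypermethylated DMRs inside one ``hotspot_window``
    (``hotspot_dmr_count``), and a small genome-wide loss of non-CGI
    methylation in the oldest group (``global_shift_fraction``).  The middle
    group sits at the arithmetic midpoint of the young and old latent levels.
    """

    seed: int = 17
    # genome layout
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    cgi_count: int = 40                 # total CGIs across the genome
    cgi_mean_length: int = 800
    background_cpg_rate: float = 0.001  # CpG probability per bp outside CGIs/patches
    cgi_cpg_rate: float = 0.15
    # intermediate-CpG-density patches (methylated, non-island CpG clusters)
    cpg_patch_count: int = 200          # total patches; each is a pair of sub-clusters
    cpg_patch_sublength: int = 900
    cpg_patch_gap: int = 800
    cpg_patch_cpg_rate: float = 0.02
    genes_per_chromosome: int = 25
    # samples
    groups: tuple[str, ...] = ("Young", "Mid", "Old")
    replicates_per_group: int = 3
    fragments_per_replicate: int = 200_000
    fragment_length_mean: int = 700
    fragment_length_sd: int = 100
    # MeDIP capture model
    pulldown_exponent: float = 2.0
    min_cpgs_per_fragment: int = 3      # below this a fragment is not captured
    replicate_noise_cv: float = 0.15    # per-replicate, per-capture-segment noise
    # latent methylation; each island/patch draws its own baseline from
    # class mean +- jitter, emulating heterogeneous regional methylation
    baseline_meth_cgi: float = 0.4
    baseline_meth_background: float = 0.5
    baseline_meth_jitter: float = 0.15
    # ground truth aging signal
    true_dmr_count: int = 20
    dmr_effect_log2fc: float = 1.0
    hotspot_dmr_count: int = 8
    hotspot_window: int = 100_000
    global_shift_fraction: float = 0.05
    dmr_hypo_fraction: float = 0.25     # fraction of non-hotspot DMRs that are hypo
    cgi_hyper_fraction: float = 1.0     # fraction of non-hotspot hyper DMRs on CGIs
    # read-level nuisance parameters
    mapq_fail_fraction: float = 0.02    # pairs where neither read reaches q10
    single_low_mapq_fraction: float = 0.05  # pairs with exactly one read below q10
    improper_fraction: float = 0.02
    duplicate_fraction: float = 0.01
    input_control: bool = True
    n_input_controls: int = 2

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if self.cgi_cpg_rate <= self.background_cpg_rate:
            raise ValueError("cgi_cpg_rate must exceed background_cpg_rate")
        for name in ("chrom_length", "cgi_mean_length", "fragment_length_mean",
                     "hotspot_window", "cpg_patch_sublength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("background_cpg_rate", "cgi_cpg_rate", "cpg_patch_cpg_rate",
                     "global_shift_fraction", "mapq_fail_fraction",
                     "improper_fraction", "duplicate_fraction",
                     "baseline_meth_cgi", "baseline_meth_background",
                     "dmr_hypo_fraction", "cgi_hyper_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hotspot_dmr_count > self.true_dmr_count:
            raise ValueError("hotspot_dmr_count must be <= true_dmr_count")
        if self.n_chromosomes < 1 or self.replicates_per_group < 1:
            raise ValueError("need >=1 chromosome and >=1 replicate per group")

    @property
    def sample_ids(self) -> list[str]:
        ids = [f"{g}{i + 1}" for g in self.groups
               for i in range(self.replicates_per_group)]
        if self.input_control:
            ids += [f"Input{i + 1}" for i in range(self.n_input_controls)]
        return ids

    def group_of(self, sample_id: str) -> str:
        for g in self.groups:
            if sample_id.startswith(g):
                return g
        if sample_id.startswith("Input"):
            return "Input"
        raise KeyError(sample_id)


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run.

    Defaults are the study's printed analysis parameters: 50 bp bins, 700 bp
    coupling distance, 10-read bump threshold, 100 kb hotspot windows, 1000
    permutations, FDR 0.2, 100 kb gene-association cutoff, 2000 bp shores.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 17
    bin_size: int = 50
    coupling_distance: int = 700
    coupling_floor: float = 1.0
    min_mapq: int = 10
    corr_window: int = 500
    corr_step: int = 250
    corr_min_reads: int = 5
    corr_min_reads_mode: str = "sum"    # {"sum", "each"}
    min_total_reads: int = 10
    fdr_threshold: float = 0.2
    hotspot_fdr_threshold: float = 0.01
    window_size: int = 100_000
    n_permutations: int = 1000
    gene_cutoff: int = 100_000
    shore_width: int = 2000
    young_group: str = "Young"
    old_group: str = "Old"
    excluded_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.excluded_samples = tuple(self.excluded_samples)
        for name in ("bin_size", "min_total_reads", "window_size",
                     "n_permutations", "gene_cutoff", "shore_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.coupling_distance < 0:
            raise ValueError("coupling_distance must be >= 0")
        if self.corr_min_reads_mode not in ("sum", "each"):
            raise ValueError("corr_min_reads_mode must be 'sum' or 'each'")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def save_config(cfg, path: str) -> None:
    """Write a config as JSON (``*.json``) or flat ``key=value`` lines."""
    d = config_to_dict(cfg)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            for key, val in _flatten(d):
                fh.write(f"{key}={json.dumps(val)}\n")


def _flatten(d: dict, prefix: str = ""):
    for k, v in sorted(d.items()):
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, prefix=f"{key}.")
        else:
            yield key, v


def _unflatten(pairs) -> dict:
    root: dict = {}
    for key, val in pairs:
        node = root
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return root


def load_config(path: str, cls=RunConfig):
    """Load a RunConfig (or SimConfig) from JSON or key=value text."""
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        d = json.loads(text)
    else:
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            pairs.append((key.strip(), json.loads(val.strip())))
        d = _unflatten(pairs)
    return dict_to_config(d, cls)


def dict_to_config(d: dict, cls=RunConfig):
    d = dict(d)
    if cls is RunConfig and isinstance(d.get("sim"), dict):
        d["sim"] = SimConfig(**d["sim"])
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**d)
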