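"""End-to-end orchestration: simulate -> qc -> score -> dmr -> hotspot/enrich.

Every stage writes its outputs before the next begins and can be re-run
standalone from the previous stage's on-disk outputs; the final report embeds
the fully resolved configuration, so a run is re-executable from its report
alone.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import io as aio
from .config import RunConfig, config_to_dict, save_config
from .coupling import build_coupling, cgi_comparison, global_comparison, \
    methylation_track
from .dmr import associate_genes, call_dmrs, label_features
from .enrichment import feature_enrichment, hotspot_permutation
from .genome import FeatureSet, GenomeModel
from .qc import qc_report
from .simulate import GroundTruth, simulate_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _dir(run_dir: str, *parts: str) -> str:
    path = os.path.join(run_dir, *parts)
    os.makedirs(os.path.dirname(path) or path, exist_ok=True)
    return path


def stage_simulate(cfg: RunConfig, run_dir: str) -> None:
    """Generate the synthetic dataset and write genome, annotation, truth and
    per-sample fragment BEDs."""
    ds = simulate_dataset(cfg.sim, shore_width=cfg.shore_width,
                          bin_size=cfg.bin_size)
    os.makedirs(run_dir, exist_ok=True)
    save_config(cfg, os.path.join(run_dir, "config.json"))
    ds.genome.to_files(os.path.join(run_dir, "genome"))
    ds.features.to_bed(os.path.join(run_dir, "features.bed"))
    ds.truth.to_tsv(os.path.join(run_dir, "truth.tsv"))
    frag_dir = os.path.join(run_dir, "fragments")
    os.makedirs(frag_dir, exist_ok=True)
    for sid, df in ds.fragments.items():
        aio.write_fragments_bed(df, os.path.join(frag_dir, f"{sid}.bed"))


def _load_genome(run_dir: str) -> GenomeModel:
    return GenomeModel.from_files(os.path.join(run_dir, "genome"))


def _load_fragments(run_dir: str, subdir: str) -> dict[str, pd.DataFrame]:
    frag_dir = os.path.join(run_dir, subdir)
    out = {}
    for fn in sorted(os.listdir(frag_dir)):
        if fn.endswith(".bed"):
            sid = fn[:-4]
            out[sid] = aio.read_fragments_bed(os.path.join(frag_dir, fn), sid)
    return out


def stage_qc(cfg: RunConfig, run_dir: str) -> None:
    """Filter every sample, write filtered BEDs and the QC report."""
    genome = _load_genome(run_dir)
    fragments = _load_fragments(run_dir, "fragments")
    medip = [s for s in fragments
             if not s.startswith("Input") and s not in cfg.excluded_samples]
    filtered, report = qc_report(
        fragments, genome, min_mapq=cfg.min_mapq, window=cfg.corr_window,
        step=cfg.corr_step, min_reads=cfg.corr_min_reads,
        mode=cfg.corr_min_reads_mode, medip_samples=medip)
    out_dir = os.path.join(run_dir, "fragments_filtered")
    os.makedirs(out_dir, exist_ok=True)
    for sid, df in filtered.items():
        aio.write_fragments_bed(df, os.path.join(out_dir, f"{sid}.bed"))
    qc_dir = os.path.join(run_dir, "qc")
    os.makedirs(qc_dir, exist_ok=True)
    report.to_frame().to_csv(os.path.join(qc_dir, "qc_report.tsv"),
                             sep="\t", index=False)
    report.pairwise_correlations.to_csv(
        os.path.join(qc_dir, "correlations.tsv"), sep="\t")
    aio.write_json({
        "tallies": report.tallies,
        "enrichment_scores": report.enrichment_scores,
        "cpg_coverage_fraction": report.cpg_coverage_fraction,
        "pairwise_correlations": {
            a: dict(report.pairwise_correlations.loc[a])
            for a in report.pairwise_correlations.index},
    }, os.path.join(qc_dir, "qc_report.json"))


def _build_tracks(cfg: RunConfig, run_dir: str):
    genome = _load_genome(run_dir)
    fragments = _load_fragments(run_dir, "fragments_filtered")
    coupling = build_coupling(genome, cfg.bin_size, cfg.coupling_distance)
    tracks = []
    for sid, df in fragments.items():
        if sid.startswith("Input") or sid in cfg.excluded_samples:
            continue
        group = cfg.sim.group_of(sid)
        tracks.append(methylation_track(df, coupling, sid, group,
                                        cfg.coupling_floor))
    return genome, coupling, tracks


def stage_score(cfg: RunConfig, run_dir: str) -> None:
    """Coupling vector, per-sample score tracks and the group comparisons."""
    genome, coupling, tracks = _build_tracks(cfg, run_dir)
    features = FeatureSet.from_bed(os.path.join(run_dir, "features.bed"))
    track_dir = os.path.join(run_dir, "tracks")
    os.makedirs(track_dir, exist_ok=True)
    aio.write_coupling(coupling, os.path.join(track_dir, "coupling.bedgraph"),
                       genome)
    for t in tracks:
        aio.write_track(t, os.path.join(track_dir, f"{t.sample_id}.bedgraph"),
                        genome)
    glob = global_comparison(tracks, cfg.young_group, cfg.old_group, genome)
    cgi = cgi_comparison(tracks, features, cfg.young_group, cfg.old_group)
    aio.write_json({
        "global": glob.to_dict(),
        "cgi": None if cgi is None else cgi.to_dict(),
    }, os.path.join(run_dir, "comparison.json"))


def stage_dmr(cfg: RunConfig, run_dir: str) -> None:
    """Bump-list, NB tests, FDR, direction, features and gene association."""
    genome, coupling, tracks = _build_tracks(cfg, run_dir)
    features = FeatureSet.from_bed(os.path.join(run_dir, "features.bed"))
    result = call_dmrs(tracks, cfg.young_group, cfg.old_group,
                       cfg.min_total_reads, cfg.fdr_threshold,
                       heatmap_tracks=tracks)
    dmr_dir = os.path.join(run_dir, "dmr")
    os.makedirs(dmr_dir, exist_ok=True)
    result.table.to_csv(os.path.join(dmr_dir, "bumps.tsv"), sep="\t",
                        index=False)
    dmrs = label_features(result.dmrs, features)
    dmrs, fraction = associate_genes(dmrs, features, cfg.gene_cutoff)
    dmrs.to_csv(os.path.join(dmr_dir, "dmrs.tsv"), sep="\t", index=False)
    with open(os.path.join(dmr_dir, "dmrs.bed"), "w") as fh:
        for r in dmrs.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t"
                     f"{min(int(-10 * np.log10(max(r.fdr, 1e-100))), 1000)}\t.\n")
    if result.heatmap is not None:
        result.heatmap.to_csv(os.path.join(dmr_dir, "heatmap.tsv"), sep="\t")
    aio.write_json({"gene_association_fraction": fraction,
                    "size_factors": dict(result.size_factors),
                    "dispersion": {"a0": result.dispersion.a0,
                                   "a1": result.dispersion.a1}},
                   os.path.join(dmr_dir, "dmr_meta.json"))


def stage_hotspot(cfg: RunConfig, run_dir: str) -> None:
    """Permutation hotspot test on the called DMRs vs the bump-list null.

    Runs both the full FDR<fdr_threshold set and the stricter
    FDR<hotspot_fdr_threshold hypermethylated subset.
    """
    genome = _load_genome(run_dir)
    dmr_dir = os.path.join(run_dir, "dmr")
    bumps = pd.read_csv(os.path.join(dmr_dir, "bumps.tsv"), sep="\t")
    dmrs = pd.read_csv(os.path.join(dmr_dir, "dmrs.tsv"), sep="\t")
    rng = np.random.default_rng([cfg.seed, 777])
    out = {}
    if len(dmrs):
        summary = hotspot_permutation(dmrs, bumps, genome, cfg.window_size,
                                      cfg.n_permutations, rng)
        out["all_dmrs"] = summary.to_dict()
        strict = dmrs[(dmrs["fdr"] < cfg.hotspot_fdr_threshold)
                      & (dmrs["direction"] == "hyper")]
        if len(strict):
            out["hyper_strict"] = hotspot_permutation(
                strict, bumps, genome, cfg.window_size,
                cfg.n_permutations, rng).to_dict()
    hs_dir = os.path.join(run_dir, "hotspot")
    os.makedirs(hs_dir, exist_ok=True)
    aio.write_json(out, os.path.join(hs_dir, "summary.json"))


def stage_enrich(cfg: RunConfig, run_dir: str) -> None:
    """Fisher feature-enrichment of hyper/hypo DMRs vs the bump-list."""
    features = FeatureSet.from_bed(os.path.join(run_dir, "features.bed"))
    dmr_dir = os.path.join(run_dir, "dmr")
    bumps = pd.read_csv(os.path.join(dmr_dir, "bumps.tsv"), sep="\t")
    dmrs = pd.read_csv(os.path.join(dmr_dir, "dmrs.tsv"), sep="\t")
    table = feature_enrichment(dmrs, bumps, features)
    en_dir = os.path.join(run_dir, "enrich")
    os.makedirs(en_dir, exist_ok=True)
    table.to_csv(os.path.join(en_dir, "enrichment.tsv"), sep="\t", index=False)


def _recovery_metrics(cfg: RunConfig, run_dir: str) -> dict:
    truth = GroundTruth.from_tsv(os.path.join(run_dir, "truth.tsv"))
    dmrs = pd.read_csv(os.path.join(run_dir, "dmr", "dmrs.tsv"), sep="\t")
    hs = aio.read_json(os.path.join(run_dir, "hotspot", "summary.json"))
    comp = aio.read_json(os.path.join(run_dir, "comparison.json"))

    def overlaps(a, b) -> bool:
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    t_iv = [(r.chrom, r.start, r.end, r.direction)
            for r in truth.dmrs.itertuples()]
    d_iv = [(r.chrom, r.start, r.end) for r in dmrs.itertuples()]
    recovered = [t for t in t_iv if any(overlaps(t, d) for d in d_iv)]
    false_calls = [d for d in d_iv if not any(overlaps(t, d) for t in t_iv)]
    sensitivity = len(recovered) / len(t_iv) if t_iv else None
    fdp = len(false_calls) / len(d_iv) if d_iv else 0.0

    hotspot_detected = False
    if truth.hotspot_location is not None and "all_dmrs" in hs:
        obs = hs["all_dmrs"]["observed_window"]
        hotspot_detected = (obs[0] == truth.hotspot_location[0]
                            and obs[1] == truth.hotspot_location[1]
                            and hs["all_dmrs"]["empirical_p"] < 0.05)
    return {
        "n_true_dmrs": len(t_iv),
        "n_called_dmrs": len(d_iv),
        "sensitivity": sensitivity,
        "false_discovery_proportion": fdp,
        "hotspot_detected": hotspot_detected,
        "true_global_shift_percent": -100.0 * truth.global_shift_fraction,
        "recovered_percent_change": comp["global"]["percent_change"],
    }


STAGES = ["simulate", "qc", "score", "dmr", "hotspot", "enrich"]
_STAGE_FN = {
    "simulate": stage_simulate, "qc": stage_qc, "score": stage_score,
    "dmr": stage_dmr, "hotspot": stage_hotspot, "enrich": stage_enrich,
}


def run_stage(name: str, cfg: RunConfig, run_dir: str) -> None:
    try:
        _STAGE_FN[name](cfg, run_dir)
    except Exception as exc:           # noqa: BLE001 - named-stage reporting
        raise PipelineError(name, exc) from exc


def run_pipeline(cfg: RunConfig, run_dir: str,
                 stages: list[str] | None = None) -> dict:
    """Execute the stages in order and write the aggregated report JSON."""
    for name in stages or STAGES:
        run_stage(name, cfg, run_dir)
    report = build_report(cfg, run_dir)
    aio.write_json(report, os.path.join(run_dir, "report.json"))
    return report


def build_report(cfg: RunConfig, run_dir: str) -> dict:
    qc = aio.read_json(os.path.join(run_dir, "qc", "qc_report.json"))
    comp = aio.read_json(os.path.join(run_dir, "comparison.json"))
    dmrs = pd.read_csv(os.path.join(run_dir, "dmr", "dmrs.tsv"), sep="\t")
    hs = aio.read_json(os.path.join(run_dir, "hotspot", "summary.json"))
    enrich = pd.read_csv(os.path.join(run_dir, "enrich", "enrichment.tsv"),
                         sep="\t")
    n_hyper = int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0
    report = {
        "config": config_to_dict(cfg),
        "qc": qc,
        "comparison": comp,
        "dmr_counts": {"total": int(len(dmrs)), "hyper": n_hyper,
                       "hypo": int(len(dmrs)) - n_hyper},
        "hotspot": hs,
        "enrichment": enrich.to_dict(orient="records"),
    }
    if os.path.exists(os.path.join(run_dir, "truth.tsv")):
        report["recovery"] = _recovery_metrics(cfg, run_dir)
    return report
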