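"""End-to-end orchestration: simulate/load -> diff -> call -> controls -> report.

The pipeline runs every stage at the resolutions the analyses expect —
region calling on 100 kb maps, pileups on 10 kb maps — from one pair of
input maps: when the input is simulated at fine resolution it is coarsened
(count-conserving block sums) for the calling stage.  All outputs land in a
run directory with a JSON report listing parameters, stage results and a
checksummed file manifest; given a seed the whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .caller import call_regions, choose_threshold, evaluate_recovery, window_scores
from .contacts import coarsen_map, read_contact_tsv, write_contact_tsv
from .decay import compare_decay, decay_curve
from .diffmap import coverage_report, log2_ratio
from .enrichment import enrichment_test
from .genome import read_chrom_sizes
from .intervals import read_bed, write_bed
from .pileup import PileupConfig, pileup_regions
from .simulate import demo_config, simulate_pair

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one end-to-end run.

    Either ``simulate=True`` (the planted demo fixture at ``sim_bin_size_bp``)
    or explicit paths to two contact TSVs plus a chrom-sizes table and
    optional feature/truth BEDs.
    """

    outdir: str = "results/run"
    seed: int = 7
    simulate: bool = True
    sim_bin_size_bp: int = 10_000
    sim_overrides: dict = field(default_factory=dict)  # e.g. {"delta": 1.0}
    control_path: str | None = None
    treated_path: str | None = None
    chrom_sizes_path: str | None = None
    features_path: str | None = None
    truth_regions_path: str | None = None
    calling_bin_size_bp: int = 100_000
    window_bins: int = 10
    threshold_method: str = "mean_sd"
    threshold_param: float | None = None
    zero_policy: str = "mask"
    pseudocount: float | None = None
    min_valid_fraction: float = 0.5
    direction: str = "decrease"
    pileup: PileupConfig = field(default_factory=PileupConfig)
    enrichment_unit: str = "bin"
    enrichment_inclusive: bool = False
    decay_probes_bp: tuple[float, float] = (1e6, 1e7)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pileup" in raw:
            raw["pileup"] = PileupConfig(**raw["pileup"])
        if "decay_probes_bp" in raw:
            raw["decay_probes_bp"] = tuple(raw["decay_probes_bp"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _prepare_inputs(config: RunConfig):
    """Returns (control, treated, features, truth) at input resolution."""
    if config.simulate:
        sim = simulate_pair(
            demo_config(
                bin_size_bp=config.sim_bin_size_bp, seed=config.seed, **config.sim_overrides
            )
        )
        return sim.control, sim.treated, sim.feature_peaks, sim.truth_regions
    for name in ("control_path", "treated_path", "chrom_sizes_path"):
        if getattr(config, name) is None:
            raise ValueError(f"run config needs {name} when simulate=False")
    genome = read_chrom_sizes(config.chrom_sizes_path, config.sim_bin_size_bp)
    control = read_contact_tsv(config.control_path, genome)
    treated = read_contact_tsv(config.treated_path, genome)
    features = read_bed(config.features_path) if config.features_path else None
    truth = read_bed(config.truth_regions_path) if config.truth_regions_path else None
    return control, treated, features, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs plus a JSON report to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        control_fine, treated_fine, features, truth = _prepare_inputs(config)
        factor = config.calling_bin_size_bp // control_fine.genome.bin_size_bp
        stage = "coarsen"
        if factor > 1:
            control = coarsen_map(control_fine, factor)
            treated = coarsen_map(treated_fine, factor)
        else:
            control, treated = control_fine, treated_fine

        stage = "diff"
        diff = log2_ratio(treated, control, config.zero_policy, config.pseudocount)
        stage = "call"
        track = window_scores(diff, config.window_bins)
        threshold = choose_threshold(track, config.threshold_method, config.threshold_param)
        calls = call_regions(track, threshold, config.direction, config.min_valid_fraction)
        track.to_bedgraph(outdir / "window_scores.tsv")
        calls.to_bed(outdir / "differential_regions.bed")

        stage = "coverage"
        cov = coverage_report(control, treated, calls.regions)
        cov.regions.to_csv(outdir / "coverage_regions.tsv", sep="\t", index=False)

        stage = "decay"
        curve_c = decay_curve(control, normalize=True)
        curve_t = decay_curve(treated, normalize=True)
        contrast = compare_decay(curve_t, curve_c, config.decay_probes_bp)

        stage = "pileup"
        pcfg = config.pileup
        ri = {}
        if len(calls.regions) > 0:
            for label, cmap in (("control", control_fine), ("treated", treated_fine)):
                res = pileup_regions(cmap, calls.regions, pcfg)
                np.savetxt(outdir / f"pileup_{label}.tsv", res.grid, delimiter="\t")
                ri[label] = {
                    "relative_insulation": res.relative_insulation,
                    "quadrant_means": res.quadrant_means,
                    "n_stacked": res.n_stacked,
                    "skipped": res.skipped,
                }

        stage = "enrichment"
        enrich = None
        if features is not None and len(calls.regions) > 0:
            result = enrichment_test(
                features,
                calls.regions,
                control.genome,
                config.enrichment_unit,
                config.enrichment_inclusive,
            )
            enrich = {
                "N": result.counts.N,
                "m": result.counts.m,
                "k": result.counts.k,
                "q": result.counts.q,
                "fold": result.fold,
                "p_exclusive": result.p_exclusive,
                "p_inclusive": result.p_inclusive,
                "unit": result.unit,
            }

        stage = "recovery"
        recovery = None
        if truth is not None:
            write_bed(truth, outdir / "truth_regions.bed")
            rec = evaluate_recovery(calls.regions, truth)
            recovery = {
                "recall": rec.recall,
                "precision": rec.precision,
                "per_truth_jaccard": rec.truth_jaccard["jaccard"].tolist(),
            }

        stage = "report"
        n_calls = len(calls.regions)
        report = {
            "version": __version__,
            "seed": config.seed,
            "parameters": _config_dict(config),
            "stages": {
                "call": {
                    "n_windows": track.n_windows(),
                    "threshold": threshold,
                    "threshold_method": config.threshold_method,
                    "threshold_param": config.threshold_param,
                    "n_regions": n_calls,
                    "null_like": bool(n_calls <= 1),
                },
                "coverage": {
                    "max_abs_region_log2": (
                        float(cov.regions["mean_log2_scaled"].abs().max())
                        if len(cov.regions)
                        else None
                    ),
                    "n_flagged": int(cov.regions["flagged"].sum()) if len(cov.regions) else 0,
                },
                "decay": {"probes_log2_treated_over_control": contrast.probes},
                "pileup": ri,
                "enrichment": enrich,
                "recovery": recovery,
            },
        }
        manifest = {}
        for f in sorted(outdir.iterdir()):
            if f.is_file() and f.name != "report.json":
                manifest[f.name] = _sha256(f)
        report["manifest"] = manifest
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["decay_probes_bp"] = list(config.decay_probes_bp)
    d.pop("outdir")  # report location is self-evident; keeps reports comparable
    return d


def write_demo_inputs(outdir, bin_size_bp: int = 100_000, seed: int = 7) -> dict:
    """Materialise the demo fixture as TSV/BED files (CLI `simulate` command)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = demo_config(bin_size_bp=bin_size_bp, seed=seed)
    sim = simulate_pair(cfg)
    write_contact_tsv(sim.control, outdir / "control.tsv")
    write_contact_tsv(sim.treated, outdir / "treated.tsv")
    write_bed(sim.truth_regions, outdir / "truth_regions.bed")
    write_bed(sim.truth_tads, outdir / "truth_tads.bed")
    write_bed(sim.feature_peaks, outdir / "feature_peaks.bed")
    g = cfg.genome
    with open(outdir / "chrom.sizes", "w") as fh:
        for name, length, flag in zip(g.chrom_names, g.chrom_lengths_bp, g.autosome_flags):
            fh.write(f"{name}\t{length}\t{int(flag)}\n")
    echo = {
        "bin_size_bp": bin_size_bp,
        "seed": seed,
        "alpha": cfg.alpha,
        "beta": cfg.beta,
        "delta": cfg.delta,
        "total_contacts": cfg.total_contacts,
        "n_planted": len(cfg.planted_pairs),
    }
    (outdir / "config_echo.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    return echo
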