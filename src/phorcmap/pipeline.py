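"""End-to-end pipeline runner: simulate -> smooth -> call -> overlap -> motif -> compare.

One YAML config (plus a seed) fully determines the run; deterministic stages
produce bit-identical outputs across reruns.  The returned
:class:`RunManifest` records resolved parameters, input digests, and every
stage output path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomics_io import (
    PipelineParams,
    read_fasta,
    read_intervals,
    read_probe_table,
    write_fasta,
    write_probe_table,
    write_track,
)
from .motif_analysis import PWM, bin_and_summarize, count_core, extract_site_sequences, score_best_window
from .overlap_analysis import RankedSiteSet, overlap_curve
from .region_calling import adjust_profile, call_bound_regions, rank_by_strength, regions_to_bed
from .signal_pipeline import compute_ratio_profile, smooth_profile
from .state_comparison import compare_states
from .synthetic_data import (
    SimulationConfig,
    default_pho_pwm,
    generate_genome,
    plant_sites,
    simulate_track,
    simulate_two_states,
    truth_intervals,
    write_truth,
)

__all__ = ["RunManifest", "PipelineConfigError", "run_pipeline"]

logger = logging.getLogger("phorcmap")


class PipelineConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


@dataclass
class RunManifest:
    version: str
    seed: int
    params: dict
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PipelineConfigError(f"{config}: config must be a YAML mapping")
    return data


def run_pipeline(
    config: str | Path | dict,
    outdir: str | Path | None = None,
    seed: int | None = None,
    quiet: bool = False,
) -> RunManifest:
    """Run all configured stages in dependency order.

    ``config`` is a YAML path or dict with optional keys ``params``
    (PipelineParams overrides), ``simulate`` (SimulationConfig fields) or
    ``inputs`` (paths to probe_table / genome / reference_bed), ``motif``
    (``n_bins``), and ``two_state`` (``reduction_factors``).  CLI/keyword
    ``seed`` and ``outdir`` override the config.  Missing input files fail
    pre-flight, before any stage runs.
    """
    cfg = _load_config(config)
    if seed is None:
        seed = cfg.get("seed")
    if seed is None:
        raise PipelineConfigError("a seed is required (config key 'seed' or --seed)")
    outdir = Path(outdir or cfg.get("outdir", "phorcmap_run"))
    params = PipelineParams(**(cfg.get("params") or {}))

    level = logging.ERROR if quiet else logging.INFO
    logging.basicConfig(format="%(message)s")
    logger.setLevel(level)

    simulate_cfg = cfg.get("simulate")
    inputs = cfg.get("inputs") or {}
    if simulate_cfg is None and "probe_table" not in inputs:
        raise PipelineConfigError(
            "config must provide either a 'simulate' block or inputs.probe_table"
        )
    # pre-flight: every referenced input must exist before compute starts
    manifest = RunManifest(
        version=__version__, seed=int(seed), params=params.to_dict(), config=cfg
    )
    for key, value in inputs.items():
        p = Path(value)
        if not p.exists():
            raise PipelineConfigError(f"input {key!r} does not exist: {p}")
        manifest.input_digests[key] = _digest(p)
    if simulate_cfg is None and cfg.get("motif") is not None and "genome" not in inputs:
        raise PipelineConfigError("motif stage requires inputs.genome (FASTA)")
    if simulate_cfg is None and cfg.get("two_state") is not None:
        raise PipelineConfigError("two_state stage requires a 'simulate' block")

    outdir.mkdir(parents=True, exist_ok=True)
    pwm = (
        PWM.from_tsv(inputs["pwm"]) if "pwm" in inputs else default_pho_pwm()
    )

    def stage(name: str):
        t0 = time.perf_counter()
        logger.info("[%s] starting", name)
        return t0

    def done(name: str, t0: float, files: dict[str, Path]) -> None:
        manifest.outputs[name] = {k: str(v) for k, v in files.items()}
        manifest.stages_completed.append(name)
        logger.info("[%s] done in %.2f s", name, time.perf_counter() - t0)

    # --- simulate or load inputs ------------------------------------------
    if simulate_cfg is not None:
        t0 = stage("simulate")
        sim = SimulationConfig(seed=int(seed), **simulate_cfg)
        rng = sim.rng()
        genome = generate_genome(sim, rng)
        genome, truth = plant_sites(genome, pwm, sim, rng)
        track = simulate_track(genome, truth, sim, rng)
        files = {
            "genome": outdir / "genome.fa",
            "probe_table": outdir / "probes.tsv",
            "truth": outdir / "truth.tsv",
            "reference_bed": outdir / "planted_sites.bed",
            "sim_config": outdir / "sim_config.yaml",
        }
        write_fasta(genome, files["genome"])
        write_probe_table(track, files["probe_table"])
        write_truth(truth, files["truth"])
        reference = truth_intervals(truth)
        from .genomics_io import write_intervals

        write_intervals(reference, files["reference_bed"])
        with open(files["sim_config"], "w") as fh:
            yaml.safe_dump(sim.to_dict(), fh, sort_keys=True)
        done("simulate", t0, files)
    else:
        track = read_probe_table(inputs["probe_table"])
        genome = read_fasta(inputs["genome"]) if "genome" in inputs else None
        reference = (
            read_intervals(inputs["reference_bed"])
            if "reference_bed" in inputs
            else None
        )
        truth = None
        sim = None

    # --- smooth ------------------------------------------------------------
    t0 = stage("smooth")
    ratio = compute_ratio_profile(track)
    smoothed = smooth_profile(ratio, params)
    files = {"smoothed_bedgraph": outdir / "smoothed.bedgraph"}
    write_track(smoothed, files["smoothed_bedgraph"], "bedgraph")
    done("smooth", t0, files)

    # --- call regions ------------------------------------------------------
    t0 = stage("call-regions")
    adjusted = adjust_profile(
        smoothed, params.sd_multiplier, params.sd_ddof, cutoff_values=ratio.values
    )
    regions = call_bound_regions(adjusted, params)
    files = {
        "regions_bed": outdir / "bound_regions.bed",
        "peaks_bed": outdir / "binding_peaks.bed",
    }
    regions_to_bed(regions, files["regions_bed"], "span")
    regions_to_bed(regions, files["peaks_bed"], "peak")
    manifest.summary["n_bound_regions"] = len(regions)
    manifest.summary["background_cutoff"] = round(adjusted.background_cutoff, 6)
    done("call-regions", t0, files)

    ranked = RankedSiteSet.from_regions(regions, label="called")

    # --- overlap -----------------------------------------------------------
    if reference and regions:
        t0 = stage("overlap")
        curve = overlap_curve(ranked, reference, reference_label="reference")
        files = {"overlap_curve": outdir / "overlap_curve.tsv"}
        curve.to_tsv(files["overlap_curve"])
        manifest.summary["overlap_at_100pct"] = round(float(curve.overlap[0]), 6)
        done("overlap", t0, files)

    # --- motif -------------------------------------------------------------
    if genome is not None and regions:
        t0 = stage("motif")
        motif_cfg = cfg.get("motif") or {}
        peaks = [r.peak for r in ranked.regions]
        seqs = extract_site_sequences(genome, peaks, params.motif_flank_bp)
        hits = [score_best_window(s, pwm) for s in seqs]
        cores = [count_core(s, params.core_motif) for s in seqs]
        table = pd.DataFrame(
            {
                "site_rank": np.arange(1, len(seqs) + 1),
                "chrom": [p.chrom for p in peaks],
                "peak_center": [p.center for p in peaks],
                "strength": [r.strength for r in ranked.regions],
                "best_score": [h.score for h in hits],
                "offset": [h.offset for h in hits],
                "strand": [h.strand for h in hits],
                "core_count": cores,
            }
        )
        files = {"site_scores": outdir / "site_scores.tsv"}
        table.to_csv(files["site_scores"], sep="\t", index=False, float_format="%.6f")
        n_bins = int(motif_cfg.get("n_bins", 4))
        if len(table) >= n_bins:
            bins = bin_and_summarize(
                table["strength"],
                table["best_score"],
                table["core_count"],
                n_bins=n_bins,
                seed=int(seed),
            )
            files["motif_bins"] = outdir / "motif_bins.tsv"
            pd.DataFrame([dataclasses.asdict(b) for b in bins]).to_csv(
                files["motif_bins"], sep="\t", index=False, float_format="%.6f"
            )
        done("motif", t0, files)

    # --- two-state comparison ---------------------------------------------
    two_state = cfg.get("two_state")
    if two_state is not None and truth is not None:
        t0 = stage("compare")
        factors = two_state.get("reduction_factors")
        if factors is None:
            raise PipelineConfigError("two_state block needs reduction_factors")
        rng2 = np.random.default_rng(int(seed) + 1)
        track_r, track_a = simulate_two_states(genome, truth, factors, sim, rng2)
        prof_r = smooth_profile(compute_ratio_profile(track_r), params)
        prof_a = smooth_profile(compute_ratio_profile(track_a), params)
        pre_peaks = truth_intervals(truth, halfwidth=1, site_class="PRE")
        paired, result = compare_states(
            prof_r, prof_a, pre_peaks, window=params.state_window_bp
        )
        files = {"paired_signals": outdir / "paired_signals.tsv"}
        pd.DataFrame(
            {
                "pre_id": [p.pre_id for p in paired],
                "signal_repressed": [p.repressed for p in paired],
                "signal_active": [p.active for p in paired],
                "difference": [p.difference for p in paired],
            }
        ).to_csv(files["paired_signals"], sep="\t", index=False, float_format="%.6f")
        manifest.summary["signed_rank"] = {
            "n": result.n,
            "w_plus": result.statistic,
            "pvalue": result.pvalue,
            "alternative": result.alternative,
            "method": result.method,
        }
        done("compare", t0, files)

    manifest.to_yaml(outdir / "manifest.yaml")
    return manifest
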