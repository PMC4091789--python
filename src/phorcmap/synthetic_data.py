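"""Synthetic tiling-array ChIP-chip data with planted binding sites.

The generator emulates the structure of the real experiments: ~25-mer probes
at regular spacing along a random genome, two ChIP and two Input replicates,
localized enrichment over planted sites shaped by a fragment-size kernel,
and multiplicative lognormal noise.  Two classes of sites are planted:

* **TSS-class** sites carry an embedded instance sampled from the extended
  PHO/PHOL motif PWM, and their enrichment amplitude is log-linearly coupled
  to the quality (log-odds score) of the embedded instance — binding driven
  by sequence recognition.
* **PRE-class** sites carry 1-3 embedded GCCAT cores but their amplitude is
  drawn independently of the sequence — binding driven by interactions other
  than motif quality.

A two-state variant scales PRE-class amplitudes by per-site multipliers,
modelling the reduction of PhoRC binding when target genes become active.
All randomness flows through one seeded generator, so outputs are fully
deterministic under a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomics_io import GenomicInterval, IntensityTrack, ProbeLayout
from .motif_analysis import (
    PWM,
    _encode,
    count_core,
    reverse_complement,
    score_best_window,
)

__all__ = [
    "SimulationConfig",
    "default_pho_pwm",
    "generate_genome",
    "plant_sites",
    "simulate_track",
    "simulate_two_states",
    "write_truth",
    "read_truth",
    "truth_intervals",
]

TRUTH_COLUMNS = [
    "site_id",
    "site_class",
    "chrom",
    "center",
    "amplitude",
    "sequence",
    "pwm_score",
    "core_count",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic ChIP-chip experiment.

    Probe geometry defaults approximate the Affymetrix Drosophila tiling
    v1.0 design (25-mers every 36 bp); the enrichment kernel half-width of
    500 bp matches the estimated ChIP fragment resolution.  A seed is
    mandatory: all draws flow through one generator derived from it.
    """

    seed: int
    genome_length: int = 200_000
    gc_fraction: float = 0.42
    chrom_name: str = "simchr"
    probe_spacing: int = 36
    probe_length: int = 25
    n_chip_replicates: int = 2
    n_input_replicates: int = 2
    kernel_width_bp: float = 500.0
    kernel: str = "triangular"  # or "gaussian"
    noise_sigma: float = 0.1
    log_input_mean: float = math.log(500.0)
    n_pre_sites: int = 8
    n_tss_sites: int = 0
    tss_amp_base: float = 6.0
    motif_beta: float = 0.35  # log2-amplitude units per log-odds score unit
    amp_noise_sigma: float = 0.3
    pre_amp_range: tuple[float, float] = (2.0, 20.0)
    pre_core_range: tuple[int, int] = (1, 3)
    min_site_separation: int = 2000
    site_margin: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in (
            "genome_length",
            "probe_spacing",
            "probe_length",
            "n_chip_replicates",
            "n_input_replicates",
            "kernel_width_bp",
            "min_site_separation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.noise_sigma < 0 or self.amp_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.kernel not in ("triangular", "gaussian"):
            raise ValueError("kernel must be 'triangular' or 'gaussian'")
        if not (0 < self.pre_amp_range[0] <= self.pre_amp_range[1]):
            raise ValueError("pre_amp_range must be positive and ordered")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["pre_amp_range"] = list(self.pre_amp_range)
        d["pre_core_range"] = list(self.pre_core_range)
        return d


def default_pho_pwm() -> PWM:
    """A synthetic 14 bp extended PHO/PHOL recognition motif.

    Built from the motif's documented anatomy rather than any published
    matrix: a strongly conserved GCCAT core at positions 6-10 (1-based), a
    preferred thymidine two nucleotides downstream of the core, and weakly
    informative flanks.  Intended for simulation and as a scoring default
    when no user PWM is supplied.
    """
    width = 14
    probs = np.full((width, 4), 0.25)

    def set_pref(pos: int, base: str, p: float) -> None:
        row = np.full(4, (1.0 - p) / 3.0)
        row["ACGT".index(base)] = p
        probs[pos] = row

    for pos, base in zip(range(2, 5), "CGC"):
        set_pref(pos, base, 0.45)
    for pos, base in zip(range(5, 10), "GCCAT"):  # the conserved core
        set_pref(pos, base, 0.85)
    set_pref(11, "T", 0.60)
    return PWM(probs)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """I.i.d. random genome at the configured GC fraction."""
    rng = rng or config.rng()
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=config.genome_length, p=p).tobytes().decode("ascii")
    return {config.chrom_name: seq}


def _sample_centers(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo = config.site_margin
    hi = config.genome_length - config.site_margin
    if hi <= lo:
        raise ValueError("genome too small for the requested site margin")
    centers: list[int] = []
    attempts = 0
    max_attempts = 10_000 * max(1, n)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"genome of {config.genome_length} bp too small to place {n} sites "
                f"with {config.min_site_separation} bp separation"
            )
        c = int(rng.integers(lo, hi))
        if all(abs(c - x) >= config.min_site_separation for x in centers):
            centers.append(c)
    return np.array(sorted(centers))


def plant_sites(
    genome: dict[str, str],
    pwm: PWM,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Embed TSS-class and PRE-class binding sites into the genome.

    Returns the edited genome and a truth table (one row per site) recording
    class, center, amplitude, the embedded sequence, and the PWM score / core
    count measured on the +/-200 bp region around the center after editing.

    TSS-class amplitudes follow ``a0 * 2^(beta * (score - E[score]))`` times
    lognormal noise, where ``score`` is the log-odds of the embedded PWM
    sample — amplitude tracks motif quality.  The truth ``pwm_score`` of a
    TSS site is that embedded-instance score; for PRE sites (whose
    amplitudes are drawn log-uniformly, independent of sequence) it is the
    best-window score of the edited region, since nothing specific was
    planted beyond the cores.
    """
    rng = rng or config.rng()
    chrom = config.chrom_name
    seq = bytearray(genome[chrom], "ascii")
    n_total = config.n_tss_sites + config.n_pre_sites
    centers = _sample_centers(config, n_total, rng)
    # assign classes to placed centers at random
    classes = np.array(
        ["TSS"] * config.n_tss_sites + ["PRE"] * config.n_pre_sites, dtype=object
    )
    rng.shuffle(classes)
    rows = []
    expected = pwm.expected_score()
    for i, (center, cls) in enumerate(zip(centers, classes)):
        if cls == "TSS":
            instance = pwm.sample(rng)
            if rng.random() < 0.5:
                embedded = reverse_complement(instance)
            else:
                embedded = instance
            start = center - pwm.width // 2
            seq[start : start + pwm.width] = embedded.encode("ascii")
            idx = _encode(instance)
            inst_score = float(
                np.log2(
                    pwm.probs[np.arange(pwm.width), idx] / pwm.background[idx]
                ).sum()
            )
            amp = (
                config.tss_amp_base
                * 2.0 ** (config.motif_beta * (inst_score - expected))
                * math.exp(rng.normal(0.0, config.amp_noise_sigma))
            )
            embedded_record = embedded
            planted_score: float | None = inst_score
        else:
            k = int(rng.integers(config.pre_core_range[0], config.pre_core_range[1] + 1))
            core = "GCCAT"
            offsets = rng.choice(
                np.arange(-50, 50 - len(core), 10), size=k, replace=False
            )
            for off in offsets:
                pat = core if rng.random() < 0.5 else reverse_complement(core)
                pos = center + int(off)
                seq[pos : pos + len(core)] = pat.encode("ascii")
            lo_a, hi_a = config.pre_amp_range
            amp = float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
            embedded_record = core
            planted_score = None
        rows.append(
            (f"site_{i + 1:04d}", cls, chrom, int(center), float(amp), embedded_record, planted_score)
        )
    genome_out = {chrom: seq.decode("ascii")}
    # core counts (and PRE scores) are measured on the edited +/-200 bp region
    records = []
    for site_id, cls, chrom_, center, amp, embedded, planted_score in rows:
        region = genome_out[chrom_][max(0, center - 200) : center + 200]
        score = (
            planted_score
            if planted_score is not None
            else score_best_window(region, pwm).score
        )
        records.append(
            {
                "site_id": site_id,
                "site_class": cls,
                "chrom": chrom_,
                "center": center,
                "amplitude": amp,
                "sequence": embedded,
                "pwm_score": score,
                "core_count": count_core(region),
            }
        )
    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)
    return genome_out, truth


def _probe_layout(config: SimulationConfig) -> ProbeLayout:
    starts = np.arange(
        0, config.genome_length - config.probe_length + 1, config.probe_spacing
    )
    return ProbeLayout(
        [config.chrom_name] * len(starts),
        starts,
        np.full(len(starts), config.probe_length),
    )


def _enrichment(
    mids: np.ndarray,
    truth: pd.DataFrame,
    config: SimulationConfig,
    amplitude_multipliers: np.ndarray | None,
) -> np.ndarray:
    enrich = np.ones(len(mids))
    w = config.kernel_width_bp
    amps = truth["amplitude"].to_numpy(dtype=float)
    if amplitude_multipliers is not None:
        amps = amps * amplitude_multipliers
    for center, amp in zip(truth["center"].to_numpy(dtype=float), amps):
        x = np.abs(mids - center) / w
        if config.kernel == "triangular":
            k = np.clip(1.0 - x, 0.0, None)
        else:  # gaussian, sd = half the kernel width
            k = np.exp(-0.5 * (2.0 * x) ** 2)
        enrich += amp * k
    return enrich


def simulate_track(
    genome: dict[str, str],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    amplitude_multipliers: np.ndarray | None = None,
) -> IntensityTrack:
    """Replicate probe intensities: lognormal input, kernel-shaped enrichment.

    Input replicate values are ``exp(mu0 + sigma * Z)``; ChIP replicates are
    the same baseline times ``1 + sum_s a_s * K(|mid - c_s| / w)`` with an
    independent lognormal noise draw, so at ``sigma = 0`` the ChIP/Input
    ratio at a probe equals its enrichment factor exactly.
    """
    rng = rng or config.rng()
    layout = _probe_layout(config)
    mids = layout.midpoints
    enrich = _enrichment(mids, truth, config, amplitude_multipliers)
    n = len(layout)
    inp = np.exp(
        config.log_input_mean
        + config.noise_sigma * rng.standard_normal((n, config.n_input_replicates))
    )
    chip = (
        np.exp(
            config.log_input_mean
            + config.noise_sigma * rng.standard_normal((n, config.n_chip_replicates))
        )
        * enrich[:, None]
    )
    return IntensityTrack(layout, chip, inp)


def simulate_two_states(
    genome: dict[str, str],
    truth: pd.DataFrame,
    reduction_factors: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTrack, IntensityTrack]:
    """Simulate repressed- and active-state tracks over the same planted sites.

    ``reduction_factors`` gives one multiplier in (0, 1] per PRE-class site
    (in truth-table order); active-state PRE amplitudes are scaled by it
    while TSS-class sites are unchanged.  Noise draws are independent
    between the two states.
    """
    rng = rng or config.rng()
    factors = np.asarray(reduction_factors, dtype=float)
    pre_mask = (truth["site_class"] == "PRE").to_numpy()
    if len(factors) != int(pre_mask.sum()):
        raise ValueError(
            f"need one reduction factor per PRE site "
            f"({int(pre_mask.sum())}), got {len(factors)}"
        )
    if np.any((factors <= 0) | (factors > 1)):
        raise ValueError("reduction factors must lie in (0, 1]")
    multipliers = np.ones(len(truth))
    multipliers[pre_mask] = factors
    track_r = simulate_track(genome, truth, config, rng)
    track_a = simulate_track(genome, truth, config, rng, amplitude_multipliers=multipliers)
    return track_r, track_a


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def truth_intervals(
    truth: pd.DataFrame, halfwidth: int = 250, site_class: str | None = None
) -> list[GenomicInterval]:
    """Reference intervals around planted site centers (optionally one class)."""
    sub = truth if site_class is None else truth[truth["site_class"] == site_class]
    return [
        GenomicInterval(
            str(row.chrom),
            max(0, int(row.center) - halfwidth),
            int(row.center) + halfwidth,
            name=str(row.site_id),
        )
        for row in sub.itertuples(index=False)
    ]
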