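"""Bound-region calling from smoothed ChIP/Input profiles.

The caller follows the tiling-array procedure: the genome-wide mean and
standard deviation of the (smoothed) ratio profile define a background
cutoff of ``mean + sd_multiplier * SD``; the cutoff is subtracted from every
value and negatives are set to zero.  Bound regions are maximal clusters of
probes with positive adjusted values whose neighbor gaps (midpoint to
midpoint) do not exceed ``max_gap_bp``; clusters whose genomic span (first
probe start to last probe end) is shorter than ``min_region_bp`` — the
estimated ChIP resolution — are dropped.  Within each region the window of
``peak_features`` consecutive probes with the highest average ratio defines
the binding peak, and that average is the region's binding strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomics_io import GenomicInterval, PipelineParams, ProbeLayout, write_intervals
from .signal_pipeline import SmoothedProfile

__all__ = [
    "AdjustedProfile",
    "BoundRegion",
    "adjust_profile",
    "call_bound_regions",
    "define_peak",
    "rank_by_strength",
    "regions_to_bed",
]


@dataclass
class AdjustedProfile:
    """Background-adjusted profile: ``max(0, value - cutoff)`` per probe.

    Undefined probes carry an adjusted value of 0 (they never support a
    region).  ``background_cutoff`` is the genome-wide mean + k*SD that was
    subtracted.
    """

    layout: ProbeLayout | None
    values: np.ndarray
    background_cutoff: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("adjusted values must be >= 0")


@dataclass(frozen=True)
class BoundRegion:
    """A called binding site with its peak window and binding strength."""

    span: GenomicInterval
    peak: GenomicInterval
    strength: float
    n_features: int

    def __post_init__(self) -> None:
        if not self.span.contains(self.peak):
            raise ValueError("peak must lie within the region span")
        if self.strength <= 0:
            raise ValueError("strength must be > 0")
        if self.n_features < 1:
            raise ValueError("region needs >= 1 supporting feature")


def background_cutoff(
    values: Sequence[float] | np.ndarray, sd_multiplier: float = 3.0, ddof: int = 1
) -> float:
    """``mean + sd_multiplier * SD`` over all defined (finite) values."""
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined values to estimate background")
    return float(values[defined].mean() + sd_multiplier * values[defined].std(ddof=ddof))


def adjust_profile(
    profile: SmoothedProfile | Sequence[float] | np.ndarray,
    sd_multiplier: float = 3.0,
    ddof: int = 1,
    cutoff_values: Sequence[float] | np.ndarray | None = None,
) -> AdjustedProfile:
    """Subtract the genome-wide ``mean + sd_multiplier * SD`` cutoff, clip at 0.

    ``profile`` may be a :class:`SmoothedProfile` or a plain value array
    (NaN = undefined).  By default the cutoff statistics are taken over the
    profile's own defined values; ``cutoff_values`` substitutes a different
    value set for the statistics — the pipeline passes the per-feature
    (unsmoothed) ChIP/Input ratios here, reading "the mean and SD of all
    ChIP/Input hybridization ratios" as referring to the feature-level
    ratios while the thresholded values are the smoothed profile.  The
    default SD is the sample (n-1) standard deviation.
    """
    if isinstance(profile, SmoothedProfile):
        layout: ProbeLayout | None = profile.layout
        values = profile.values
    else:
        layout = None
        values = np.asarray(profile, dtype=float)
    defined = np.isfinite(values)
    cutoff = background_cutoff(
        values if cutoff_values is None else cutoff_values, sd_multiplier, ddof
    )
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined profile values to adjust")
    adjusted = np.where(defined, np.clip(values - cutoff, 0.0, None), 0.0)
    return AdjustedProfile(layout, adjusted, cutoff)


def define_peak(
    starts: Sequence[int],
    lengths: Sequence[int],
    ratios: Sequence[float],
    chrom: str = "chr",
    k: int = 6,
) -> tuple[GenomicInterval, float]:
    """Best window of ``k`` consecutive supporting probes by mean ratio.

    Returns the peak interval (first probe start to last probe end of the
    winning window) and its mean ratio (the binding strength).  Regions with
    fewer than ``k`` probes use the whole region.  Ties go to the leftmost
    window.
    """
    starts = np.asarray(starts, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    ratios = np.asarray(ratios, dtype=float)
    n = len(starts)
    if n == 0:
        raise ValueError("region must contain >= 1 probe")
    if n <= k:
        i, j = 0, n
    else:
        csum = np.concatenate(([0.0], np.cumsum(ratios)))
        window_means = (csum[k:] - csum[:-k]) / k
        i = int(np.argmax(window_means))  # first index on ties -> leftmost
        j = i + k
    strength = float(ratios[i:j].mean())
    peak = GenomicInterval(chrom, int(starts[i]), int(starts[j - 1] + lengths[j - 1]))
    return peak, strength


def call_bound_regions(
    adjusted: AdjustedProfile,
    params: PipelineParams | None = None,
    **overrides,
) -> list[BoundRegion]:
    """Call bound regions from a background-adjusted profile.

    Supporting probes are those with adjusted value > 0.  Consecutive
    supporting probes belong to the same cluster while their midpoint gap is
    <= ``max_gap_bp``; clusters spanning < ``min_region_bp`` are discarded.
    Peak windows and strengths are computed on the un-adjusted ratios
    (adjusted value + cutoff), so a single profile drives both detection and
    strength ranking.
    """
    params = (params or PipelineParams()).replace(**overrides)
    if adjusted.layout is None:
        raise ValueError("adjusted profile must carry a probe layout to call regions")
    layout = adjusted.layout
    ratios_full = adjusted.values + adjusted.background_cutoff
    regions: list[BoundRegion] = []
    for chrom in layout.chromosomes:
        sl = layout.chrom_slice(chrom)
        adj = adjusted.values[sl]
        sup = np.flatnonzero(adj > 0)
        if len(sup) == 0:
            continue
        mids = layout.midpoints[sl][sup]
        breaks = np.flatnonzero(np.diff(mids) > params.max_gap_bp) + 1
        for run in np.split(sup, breaks):
            first, last = run[0], run[-1]
            span_start = int(layout.starts[sl][first])
            span_end = int(layout.starts[sl][last] + layout.lengths[sl][last])
            if span_end - span_start < params.min_region_bp:
                continue
            peak, strength = define_peak(
                layout.starts[sl][run],
                layout.lengths[sl][run],
                ratios_full[sl][run],
                chrom=chrom,
                k=params.peak_features,
            )
            regions.append(
                BoundRegion(
                    span=GenomicInterval(chrom, span_start, span_end),
                    peak=peak,
                    strength=strength,
                    n_features=len(run),
                )
            )
    regions.sort(key=lambda r: (r.span.chrom, r.span.start))
    return regions


def rank_by_strength(regions: Sequence[BoundRegion]) -> list[BoundRegion]:
    """Regions ordered by descending binding strength; ties keep genomic order."""
    genomic = sorted(regions, key=lambda r: (r.span.chrom, r.span.start, r.span.end))
    return sorted(genomic, key=lambda r: -r.strength)  # stable sort preserves ties


def regions_to_bed(
    regions: Sequence[BoundRegion], path: str | Path, what: str = "span"
) -> None:
    """Write region spans (or peaks) as BED6; score = strength scaled to [0, 1000]."""
    if what not in ("span", "peak"):
        raise ValueError("what must be 'span' or 'peak'")
    max_strength = max((r.strength for r in regions), default=1.0)
    intervals = []
    for i, r in enumerate(regions, start=1):
        iv = r.span if what == "span" else r.peak
        intervals.append(
            GenomicInterval(
                iv.chrom,
                iv.start,
                iv.end,
                name=f"region_{i:05d}",
                score=round(1000.0 * r.strength / max_strength, 3),
            )
        )
    write_intervals(intervals, path)
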