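"""Probe-level ratio profiles and sliding-window trimmed-mean smoothing.

The binding profile for a protein is the per-probe ratio of the average ChIP
intensity to the average Input intensity (ratio of replicate means, not mean
of ratios), smoothed by a trimmed mean over a sliding window centered on each
probe's midpoint.  Windows holding fewer than a minimum number of features
yield an undefined (NaN) value; undefined values propagate downstream rather
than being imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genomics_io import IntensityTrack, PipelineParams, ProbeLayout

__all__ = ["RatioProfile", "SmoothedProfile", "compute_ratio_profile", "smooth_profile"]


@dataclass
class RatioProfile:
    """Per-probe average-ChIP / average-Input ratios (NaN where input mean is 0)."""

    layout: ProbeLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.layout),):
            raise ValueError("one ratio value per probe required")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SmoothedProfile:
    """Trimmed-mean smoothed ratio profile; NaN marks excluded windows."""

    layout: ProbeLayout
    values: np.ndarray
    window_bp: float
    min_features: int
    trim_fraction: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.layout),):
            raise ValueError("one smoothed value per probe required")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def compute_ratio_profile(track: IntensityTrack) -> RatioProfile:
    """Ratio of replicate means, chip over input, per probe.

    Probes whose input replicate mean is zero get an undefined (NaN) ratio.
    """
    if track.chip.shape[1] == 0 or track.input.shape[1] == 0:
        raise ValueError("each channel needs >= 1 replicate")
    chip_mean = track.chip.mean(axis=1)
    input_mean = track.input.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = chip_mean / input_mean
    values[input_mean == 0] = np.nan
    return RatioProfile(track.layout, values)


def _trimmed_mean(sorted_rows: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Trimmed mean of each pre-sorted row, dropping floor(trim*n) per tail."""
    n = sorted_rows.shape[1]
    k = math.floor(trim_fraction * n)
    return sorted_rows[:, k : n - k].mean(axis=1)


def smooth_profile(
    ratio: RatioProfile, params: PipelineParams | None = None, **overrides
) -> SmoothedProfile:
    """Smooth a ratio profile with a sliding trimmed-mean window.

    For each probe, the ratios of all probes whose midpoints lie within
    +/- ``smooth_window_bp / 2`` of its midpoint (window closed on both ends,
    same chromosome) are collected; undefined ratios do not count.  If fewer
    than ``min_features_per_window`` features fall in the window the smoothed
    value is undefined; otherwise it is the trimmed mean after dropping
    ``floor(trim_fraction * n)`` lowest and highest values.
    """
    params = (params or PipelineParams()).replace(**overrides)
    halfwidth = params.smooth_window_bp / 2.0
    out = np.full(len(ratio.layout), np.nan)
    for chrom in ratio.layout.chromosomes:
        sl = ratio.layout.chrom_slice(chrom)
        mids = ratio.layout.midpoints[sl]
        vals = ratio.values[sl]
        defined = np.isfinite(vals)
        dmids = mids[defined]
        dvals = vals[defined]
        if len(dvals) == 0:
            continue
        lo = np.searchsorted(dmids, mids - halfwidth, side="left")
        hi = np.searchsorted(dmids, mids + halfwidth, side="right")
        counts = hi - lo
        res = np.full(len(mids), np.nan)
        for c in np.unique(counts):
            if c < params.min_features_per_window:
                continue
            idx = np.flatnonzero(counts == c)
            windows = dvals[lo[idx][:, None] + np.arange(c)[None, :]]
            windows.sort(axis=1)
            res[idx] = _trimmed_mean(windows, params.trim_fraction)
        out[sl] = res
    return SmoothedProfile(
        ratio.layout,
        out,
        window_bp=params.smooth_window_bp,
        min_features=params.min_features_per_window,
        trim_fraction=params.trim_fraction,
    )
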