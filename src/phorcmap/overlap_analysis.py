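"""Overlap statistics between ranked binding-site sets and reference intervals.

Covers the overlap-vs-strength curves (the fraction of binding sites that
intersect a reference set, re-evaluated as the weakest sites are
progressively removed), the coverage intersection across several site sets
("co-occupied" sites detected by every antibody), and the fraction of target
domains that contain at least one such co-occupied site.

Overlap is counted per site: a site overlaps the reference when its span
shares at least ``min_overlap`` base pairs (default 1) with any reference
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genomics_io import GenomicInterval
from .region_calling import BoundRegion, rank_by_strength

__all__ = [
    "RankedSiteSet",
    "OverlapCurve",
    "overlap_fraction",
    "overlap_curve",
    "intersect_site_sets",
    "target_coverage",
    "merge_intervals",
]


def _span(site: BoundRegion | GenomicInterval) -> GenomicInterval:
    return site.span if isinstance(site, BoundRegion) else site


def _build_trees(reference: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _hits(span: GenomicInterval, trees: dict[str, IntervalTree], min_overlap: int) -> bool:
    tree = trees.get(span.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(span.start, span.end):
        if min(span.end, hit.end) - max(span.start, hit.begin) >= min_overlap:
            return True
    return False


@dataclass
class RankedSiteSet:
    """Bound regions ordered by descending strength (ties in genomic order)."""

    regions: list[BoundRegion]
    label: str = ""

    @classmethod
    def from_regions(cls, regions: Sequence[BoundRegion], label: str = "") -> "RankedSiteSet":
        return cls(rank_by_strength(regions), label)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class OverlapCurve:
    """Overlap fraction as a function of the retained top fraction of sites."""

    retained_fraction: np.ndarray  # strictly decreasing grid, e.g. 1.0 .. 0.05
    overlap: np.ndarray  # per grid point, in [0, 1]
    site_label: str = ""
    reference_label: str = ""

    def __post_init__(self) -> None:
        self.retained_fraction = np.asarray(self.retained_fraction, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if np.any(np.diff(self.retained_fraction) >= 0):
            raise ValueError("retained_fraction grid must be strictly decreasing")
        if np.any((self.overlap < 0) | (self.overlap > 1)):
            raise ValueError("overlap fractions must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("retained_fraction\toverlap_fraction\n")
            for f, v in zip(self.retained_fraction, self.overlap):
                fh.write(f"{f:.4f}\t{v:.6f}\n")


def overlap_fraction(
    sites: Sequence[BoundRegion | GenomicInterval],
    reference: Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> float:
    """Fraction of sites whose span intersects >= 1 reference interval.

    An empty site set is an error (it signals an upstream failure), not 0.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("overlap_fraction of an empty site set is undefined")
    trees = _build_trees(reference)
    n_hit = sum(_hits(_span(s), trees, min_overlap) for s in sites)
    return n_hit / len(sites)


def overlap_curve(
    ranked: RankedSiteSet,
    reference: Iterable[GenomicInterval],
    step_fraction: float = 0.05,
    min_overlap: int = 1,
    reference_label: str = "",
) -> OverlapCurve:
    """Overlap fraction of the top ``ceil(f * N)`` sites for each grid fraction f.

    The grid runs from 100% retained down in ``step_fraction`` steps (default
    5%), emulating the progressive removal of the weakest binding sites.
    """
    if not (0 < step_fraction <= 1):
        raise ValueError("step_fraction must lie in (0, 1]")
    if len(ranked) == 0:
        raise ValueError("cannot build an overlap curve from an empty site set")
    trees = _build_trees(reference)
    flags = np.array(
        [_hits(_span(s), trees, min_overlap) for s in ranked.regions], dtype=float
    )
    cum_hits = np.cumsum(flags)
    n = len(ranked)
    grid = []
    f = 1.0
    while f > 1e-9:
        grid.append(round(f, 10))
        f -= step_fraction
    fractions = []
    for f in grid:
        k = max(1, math.ceil(f * n))
        fractions.append(cum_hits[k - 1] / k)
    return OverlapCurve(
        np.array(grid), np.array(fractions), ranked.label, reference_label
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent-by-overlap intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def _intersect_two(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two merged, sorted coverage sets (sweep per chromosome)."""
    out: list[GenomicInterval] = []
    a_by: dict[str, list[GenomicInterval]] = {}
    for iv in a:
        a_by.setdefault(iv.chrom, []).append(iv)
    b_by: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        b_by.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(set(a_by) & set(b_by)):
        ia = ib = 0
        xs, ys = a_by[chrom], b_by[chrom]
        while ia < len(xs) and ib < len(ys):
            lo = max(xs[ia].start, ys[ib].start)
            hi = min(xs[ia].end, ys[ib].end)
            if hi > lo:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[ia].end <= ys[ib].end:
                ia += 1
            else:
                ib += 1
    return out


def intersect_site_sets(
    sets: Sequence[RankedSiteSet | Sequence[BoundRegion | GenomicInterval]],
) -> list[GenomicInterval]:
    """Genomic intervals covered by at least one site from *every* input set.

    This is the coverage intersection used to define sites co-occupied by all
    proteins (or detected by all antibodies); the result is merged and sorted.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 site sets to intersect")
    coverages = []
    for s in sets:
        regions = s.regions if isinstance(s, RankedSiteSet) else list(s)
        if not regions:
            return []
        coverages.append(merge_intervals(_span(r) for r in regions))
    result = coverages[0]
    for cov in coverages[1:]:
        result = _intersect_two(result, cov)
        if not result:
            break
    return result


def target_coverage(
    domains: Sequence[GenomicInterval],
    co_occupied_sites: Iterable[GenomicInterval | BoundRegion],
    min_overlap: int = 1,
) -> float:
    """Fraction of target domains intersecting >= 1 co-occupied site."""
    domains = list(domains)
    if not domains:
        raise ValueError("domains must be non-empty")
    trees = _build_trees(_span(s) for s in co_occupied_sites)
    n_hit = sum(_hits(d, trees, min_overlap) for d in domains)
    return n_hit / len(domains)
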