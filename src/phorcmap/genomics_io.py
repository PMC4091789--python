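"""Data model, coordinate conventions, and file I/O for tiling-array ChIP analysis.

All genomic coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  Conversion to/from BED is the identity on coordinates; 1-based
inputs (GFF-style) must be converted by the caller on read.

The module houses the central :class:`PipelineParams` record that collects
every numeric constant used by the downstream analysis stages, the probe-level
containers (:class:`ProbeLayout`, :class:`IntensityTrack`), and readers/writers
for the plain-text formats the pipeline consumes and emits (TSV probe tables,
BED intervals, bedGraph/WIG tracks, FASTA genomes).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "ProbeLayout",
    "IntensityTrack",
    "PipelineParams",
    "GeneExpressionRecord",
    "read_probe_table",
    "write_probe_table",
    "read_intervals",
    "write_intervals",
    "tss_windows",
    "classify_active",
    "rpkm",
    "write_track",
    "read_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
]

_VALID_STRANDS = (None, "+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint or other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class ProbeLayout:
    """Ordered microarray probe coordinates.

    Probes are stored sorted by (chromosome, start).  A probe's *position* for
    all windowing operations is its midpoint ``start + length / 2``.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        lengths: Sequence[int],
    ) -> None:
        chroms_arr = np.asarray(chroms, dtype=str)
        starts_arr = np.asarray(starts, dtype=np.int64)
        lengths_arr = np.asarray(lengths, dtype=np.int64)
        if not (len(chroms_arr) == len(starts_arr) == len(lengths_arr)):
            raise ValueError("chroms, starts, lengths must have equal length")
        if np.any(lengths_arr <= 0):
            raise ValueError("probe lengths must be > 0")
        if np.any(starts_arr < 0):
            raise ValueError("probe starts must be >= 0")
        order = np.lexsort((starts_arr, chroms_arr))
        self._was_sorted = bool(np.array_equal(order, np.arange(len(order))))
        self.chroms = chroms_arr[order]
        self.starts = starts_arr[order]
        self.lengths = lengths_arr[order]
        self.order = order
        # duplicate (chrom, start) detection on the sorted arrays
        if len(self.starts) > 1:
            dup = (self.chroms[1:] == self.chroms[:-1]) & (
                self.starts[1:] == self.starts[:-1]
            )
            if np.any(dup):
                i = int(np.argmax(dup))
                raise ValueError(
                    f"duplicate probe at {self.chroms[i + 1]}:{self.starts[i + 1]}"
                )
        self._slices: dict[str, slice] = {}
        if len(self.chroms):
            boundaries = np.flatnonzero(self.chroms[1:] != self.chroms[:-1]) + 1
            edges = np.concatenate(([0], boundaries, [len(self.chroms)]))
            for lo, hi in zip(edges[:-1], edges[1:]):
                self._slices[str(self.chroms[lo])] = slice(int(lo), int(hi))

    def __len__(self) -> int:
        return len(self.starts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeLayout):
            return NotImplemented
        return (
            np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.lengths, other.lengths)
        )

    @property
    def midpoints(self) -> np.ndarray:
        """Probe midpoints (``start + length/2``), as floats."""
        return self.starts + self.lengths / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.lengths

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)


@dataclass
class IntensityTrack:
    """Per-probe replicate intensities for one ChIP experiment.

    ``chip`` and ``input`` are probes x replicates matrices of nonnegative
    reals, row-aligned with ``layout``.
    """

    layout: ProbeLayout
    chip: np.ndarray
    input: np.ndarray

    def __post_init__(self) -> None:
        self.chip = np.atleast_2d(np.asarray(self.chip, dtype=float))
        self.input = np.atleast_2d(np.asarray(self.input, dtype=float))
        n = len(self.layout)
        for name, mat in (("chip", self.chip), ("input", self.input)):
            if mat.shape[0] != n:
                raise ValueError(
                    f"{name} matrix has {mat.shape[0]} rows for {n} probes"
                )
            if mat.shape[1] < 1:
                raise ValueError(f"{name} channel needs >= 1 replicate")
            if not np.all(np.isfinite(mat)) or np.any(mat < 0):
                raise ValueError(f"{name} intensities must be finite and >= 0")

    @property
    def n_probes(self) -> int:
        return len(self.layout)


@dataclass(frozen=True)
class PipelineParams:
    """Every numeric constant used by the analysis stages.

    Defaults follow the published tiling-array procedure: ratio profiles are
    smoothed with a trimmed mean over a sliding 675 bp window requiring at
    least 10 features; the background cutoff is mean + 3*SD of the profile;
    bound regions tolerate probe gaps up to 500 bp and must span at least
    360 bp (the estimated ChIP resolution); the binding peak is the best
    window of 6 consecutive features; motifs are scored with a 14 bp PWM over
    +/-200 bp around peaks; paired state comparisons average the profile over
    500 bp windows; TSS windows are +/-300 bp (fly) or +/-700 bp (human);
    expression activity thresholds are 300 RPKM (fly RNA-seq) and RMA > 6
    (human arrays); the conserved core motif is GCCAT.
    """

    smooth_window_bp: float = 675.0
    min_features_per_window: int = 10
    trim_fraction: float = 0.1
    sd_multiplier: float = 3.0
    max_gap_bp: float = 500.0
    min_region_bp: float = 360.0
    peak_features: int = 6
    motif_window_bp: int = 14
    motif_flank_bp: int = 200
    state_window_bp: float = 500.0
    tss_halfwidth_fly_bp: int = 300
    tss_halfwidth_human_bp: int = 700
    rpkm_threshold: float = 300.0
    rma_threshold: float = 6.0
    core_motif: str = "GCCAT"
    pwm_pseudocount: float = 0.5
    sd_ddof: int = 1  # sample SD by default

    def __post_init__(self) -> None:
        positive = (
            "smooth_window_bp",
            "min_features_per_window",
            "max_gap_bp",
            "min_region_bp",
            "peak_features",
            "motif_window_bp",
            "motif_flank_bp",
            "state_window_bp",
            "tss_halfwidth_fly_bp",
            "tss_halfwidth_human_bp",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.pwm_pseudocount < 0:
            raise ValueError("pwm_pseudocount must be >= 0")
        if set(self.core_motif) - set("ACGT") or not self.core_motif:
            raise ValueError("core_motif must be a non-empty ACGT string")

    def replace(self, **overrides) -> "PipelineParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class GeneExpressionRecord:
    """Gene expression value with the 1 bp TSS it annotates.

    ``scale`` tags the unit: ``"RPKM"`` (sequencing) or ``"RMA"``
    (log2-scale expression arrays).
    """

    gene_id: str
    value: float
    scale: str
    tss: GenomicInterval

    def __post_init__(self) -> None:
        if self.scale not in ("RPKM", "RMA"):
            raise ValueError(f"scale must be RPKM or RMA, got {self.scale!r}")
        if self.scale == "RPKM" and self.value < 0:
            raise ValueError("RPKM expression must be >= 0")
        if self.tss.width != 1:
            raise ValueError("tss interval must have width 1")


# ---------------------------------------------------------------------------
# probe tables


def read_probe_table(path: str | Path) -> IntensityTrack:
    """Read a tab-delimited probe intensity table.

    The header must name ``chrom``, ``start``, ``length`` plus one or more
    ``chip_*`` and ``input_*`` replicate columns.  Unsorted probes are sorted
    with a warning; negative intensities raise; malformed numeric fields
    raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    chip_cols = sorted(
        (c for c in df.columns if c.startswith("chip_")),
        key=lambda c: (len(c), c),
    )
    input_cols = sorted(
        (c for c in df.columns if c.startswith("input_")),
        key=lambda c: (len(c), c),
    )
    if not chip_cols or not input_cols:
        raise ValueError(f"{path}: need >= 1 chip_* and >= 1 input_* column")
    for col in ["start", "length", *chip_cols, *input_cols]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # + header line
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        if converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = converted
    chip = df[chip_cols].to_numpy(dtype=float)
    inp = df[input_cols].to_numpy(dtype=float)
    if np.any(chip < 0) or np.any(inp < 0):
        raise ValueError(f"{path}: negative intensity values")
    layout = ProbeLayout(df["chrom"].astype(str), df["start"], df["length"])
    if not layout._was_sorted:
        warnings.warn(f"{path}: probes were not sorted; sorting", stacklevel=2)
    return IntensityTrack(layout, chip[layout.order], inp[layout.order])


def write_probe_table(track: IntensityTrack, path: str | Path) -> None:
    """Write an :class:`IntensityTrack` in the TSV dialect of ``read_probe_table``."""
    cols = {
        "chrom": track.layout.chroms,
        "start": track.layout.starts,
        "length": track.layout.lengths,
    }
    for j in range(track.chip.shape[1]):
        cols[f"chip_{j + 1}"] = track.chip[:, j]
    for j in range(track.input.shape[1]):
        cols[f"input_{j + 1}"] = track.input[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# intervals


def read_intervals(path: str | Path, fmt: str = "bed") -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, returned 0-based half-open and sorted."""
    if fmt.lower() != "bed":
        raise ValueError(f"unsupported interval format {fmt!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            out.append(GenomicInterval(fields[0], start, end, name, strand, score))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (BED3 fields always present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            score_str = f"{score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score_str}\t{iv.strand or '.'}\n"
            )


def tss_windows(
    records: Iterable[GeneExpressionRecord], halfwidth: int
) -> list[GenomicInterval]:
    """Fixed-width windows centered on each TSS, clipped at position 0.

    A halfwidth of 300 yields the 600 bp windows used for fly TSS overlap
    comparisons; 700 yields the 1400 bp windows used for the human analysis.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    out = []
    for rec in records:
        pos = rec.tss.start
        out.append(
            GenomicInterval(
                rec.tss.chrom,
                max(0, pos - halfwidth),
                pos + halfwidth,
                name=rec.gene_id,
                strand=rec.tss.strand,
            )
        )
    return out


def classify_active(
    records: Iterable[GeneExpressionRecord], threshold: float, scale: str
) -> set[str]:
    """Gene ids classified as transcriptionally active.

    RPKM activity uses ``value >= threshold`` (a "threshold of 300");
    RMA activity uses the strict ``value > threshold`` ("more than 6").
    """
    if scale not in ("RPKM", "RMA"):
        raise ValueError(f"scale must be RPKM or RMA, got {scale!r}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    active: set[str] = set()
    for rec in records:
        if rec.scale != scale:
            raise ValueError(
                f"mixed expression scales: record {rec.gene_id} is {rec.scale}, "
                f"call requested {scale}"
            )
        hit = rec.value >= threshold if scale == "RPKM" else rec.value > threshold
        if hit:
            active.add(rec.gene_id)
    return active


def rpkm(read_count: float, exon_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon_length_bp must be > 0")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    return read_count / (exon_length_bp / 1000.0) / (total_mapped_reads / 1e6)


# ---------------------------------------------------------------------------
# tracks


def write_track(profile, path: str | Path, fmt: str = "bedgraph") -> None:
    """Write a per-probe profile as bedGraph or WIG (variableStep).

    ``profile`` is any object with ``layout`` and ``values`` attributes
    (ratio, smoothed, or adjusted profiles).  Probes with undefined (NaN)
    values are omitted.  Values are rendered with 6 decimal digits.
    """
    layout = profile.layout
    values = np.asarray(profile.values, dtype=float)
    defined = np.isfinite(values)
    fmt = fmt.lower()
    with open(path, "w") as fh:
        if fmt == "bedgraph":
            for i in np.flatnonzero(defined):
                fh.write(
                    f"{layout.chroms[i]}\t{layout.starts[i]}\t"
                    f"{layout.starts[i] + layout.lengths[i]}\t{values[i]:.6f}\n"
                )
        elif fmt == "wig":
            cur = (None, None)  # (chrom, span)
            for i in np.flatnonzero(defined):
                key = (str(layout.chroms[i]), int(layout.lengths[i]))
                if key != cur:
                    fh.write(f"variableStep chrom={key[0]} span={key[1]}\n")
                    cur = key
                fh.write(f"{layout.starts[i] + 1}\t{values[i]:.6f}\n")
        else:
            raise ValueError(f"unsupported track format {fmt!r}")


def read_bedgraph(path: str | Path) -> tuple[ProbeLayout, np.ndarray]:
    """Read a bedGraph written by :func:`write_track` back into a layout + values."""
    chroms: list[str] = []
    starts: list[int] = []
    lengths: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")
            chroms.append(c)
            starts.append(int(s))
            lengths.append(int(e) - int(s))
            vals.append(float(v))
    layout = ProbeLayout(chroms, starts, lengths)
    return layout, np.asarray(vals, dtype=float)[layout.order]


# ---------------------------------------------------------------------------
# sequences and expression tables


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercase sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression_table(path: str | Path) -> list[GeneExpressionRecord]:
    """Read a TSV with columns gene_id, chrom, tss, strand, value, scale."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand", "value", "scale"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else None
        tss = GenomicInterval(str(row.chrom), int(row.tss), int(row.tss) + 1, strand=strand)
        out.append(GeneExpressionRecord(str(row.gene_id), float(row.value), str(row.scale), tss))
    return out
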