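"""PWM scoring of binding sites, GCCAT core counting, and strength-trend tests.

A binding site's motif score is obtained by sliding a fixed-width window
(default 14 bp) one nucleotide at a time across the sequence around its peak
and over the reverse complement; each window is scored as a sum of log2-odds
against a background distribution, and the single best window defines the
site's score.  Conserved GCCAT cores are counted as perfect matches on
either strand.  Sites are binned by binding strength to test whether motif
quality tracks strength (the signature of sequence-driven binding at
TSS-proximal sites, absent at PREs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "BinSummary",
    "build_pwm",
    "reverse_complement",
    "extract_site_sequences",
    "score_best_window",
    "count_core",
    "bin_and_summarize",
    "rank_trend_test",
    "spearman_correlation",
]

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> column index in the PWM; unknown/ambiguous bases -> 4 (zero log-odds)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position probability matrix with a background distribution.

    ``probs`` has shape (width, 4) over A, C, G, T; each row sums to 1.
    Scores are log2(p / background) summed over positions.
    """

    probs: np.ndarray
    background: np.ndarray | None = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a (width, 4) matrix with width >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not math.isclose(
            self.background.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background must be a length-4 distribution")
        if np.any(self.probs < 0):
            raise ValueError("PWM probabilities must be >= 0")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 5) log2-odds matrix; 5th column scores ambiguous bases as 0.

        Zero probabilities (possible without a pseudocount) map to -inf.
        """
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[None, :])
        return np.hstack([lo, np.zeros((self.width, 1))])

    def expected_score(self) -> float:
        """Mean log2-odds score of a window sampled from the PWM itself."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[None, :])
        return float((self.probs * np.where(self.probs > 0, lo, 0.0)).sum())

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one motif instance from the per-position probabilities."""
        idx = [rng.choice(4, p=row) for row in self.probs]
        return "".join(ALPHABET[i] for i in idx)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.probs, columns=list(ALPHABET))
        df.index.name = "position"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PWM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df[list(ALPHABET)].to_numpy())

    def to_meme(self, path: str | Path, name: str = "motif_1") -> None:
        """Write a minimal MEME-format probability-matrix block."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            bg = " ".join(f"{b} {p:.4f}" for b, p in zip(ALPHABET, self.background))
            fh.write(f"Background letter frequencies\n{bg}\n\n")
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.width}\n")
            for row in self.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")

    @classmethod
    def from_meme(cls, path: str | Path) -> "PWM":
        rows: list[list[float]] = []
        width = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("letter-probability matrix"):
                    for token in line.split():
                        if token.isdigit() and width is None and "w=" in line:
                            pass
                    width = int(line.split("w=")[1].split()[0])
                    continue
                if width is not None and len(rows) < width:
                    parts = line.split()
                    if len(parts) == 4:
                        rows.append([float(x) for x in parts])
        if width is None or len(rows) != width:
            raise ValueError(f"{path}: no complete letter-probability matrix found")
        return cls(np.asarray(rows))


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring PWM window within one binding site."""

    score: float
    offset: int  # left edge of the window on the given (forward) sequence
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class BinSummary:
    """Per-strength-bin motif statistics (bin 0 = strongest sites)."""

    bin_index: int
    n: int
    mean_score: float
    mean_core: float
    ci_score: float  # 95% CI half-width (percentile bootstrap)
    ci_core: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("bin must contain >= 1 site")
        if self.ci_score < 0 or self.ci_core < 0:
            raise ValueError("CI half-widths must be >= 0")


def build_pwm(
    aligned_occurrences: Sequence[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> PWM:
    """Estimate a PWM from user-supplied aligned motif occurrences.

    Position probabilities are ``(count + pseudocount) / (n + 4*pseudocount)``.
    """
    occs = [s.upper() for s in aligned_occurrences]
    if not occs:
        raise ValueError("need >= 1 occurrence")
    width = len(occs[0])
    if width < 1:
        raise ValueError("occurrences must be non-empty")
    if any(len(s) != width for s in occs):
        raise ValueError("occurrences must all have the same length")
    counts = np.zeros((width, 4))
    for s in occs:
        idx = _encode(s)
        if np.any(idx == 4):
            raise ValueError(f"non-ACGT character in occurrence {s!r}")
        counts[np.arange(width), idx] += 1
    probs = (counts + pseudocount) / (len(occs) + 4 * pseudocount)
    return PWM(probs, background=background, pseudocount=pseudocount)


def extract_site_sequences(
    genome: Mapping[str, str],
    peaks: Sequence[GenomicInterval],
    flank: int = 200,
) -> list[str]:
    """Uppercased sequences ``[peak_center - flank, peak_center + flank)``.

    Windows extending past chromosome ends are clipped with a warning.
    """
    import warnings

    out = []
    for peak in peaks:
        if peak.chrom not in genome:
            raise KeyError(f"chromosome {peak.chrom!r} not in genome")
        chrom_seq = genome[peak.chrom]
        center = peak.center
        lo, hi = center - flank, center + flank
        if lo < 0 or hi > len(chrom_seq):
            warnings.warn(
                f"window [{lo}, {hi}) around {peak.chrom}:{center} clipped to "
                f"chromosome bounds",
                stacklevel=2,
            )
            lo, hi = max(0, lo), min(len(chrom_seq), hi)
        out.append(str(chrom_seq[lo:hi]).upper())
    return out


def _window_scores(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every offset of a (width, 5) log-odds matrix along encoded seq."""
    width = log_odds.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(idx, width)
    return log_odds[np.arange(width)[None, :], windows].sum(axis=1)


def score_best_window(seq: str, pwm: PWM) -> MotifHit:
    """Best log2-odds window over all offsets on both strands.

    Ambiguous bases (e.g. N) contribute the background term (0).  Ties prefer
    the forward strand, then the smallest offset.
    """
    if len(seq) < pwm.width:
        raise ValueError(
            f"sequence length {len(seq)} shorter than motif width {pwm.width}"
        )
    idx = _encode(seq)
    lo = pwm.log_odds
    # minus strand: score of the reverse complement window at each forward
    # offset == score under the position- and base-reversed matrix
    lo_rc = np.hstack([lo[::-1, [3, 2, 1, 0]], np.zeros((pwm.width, 1))])
    fwd = _window_scores(idx, lo)
    rev = _window_scores(idx, lo_rc)
    best_f, best_r = fwd.max(), rev.max()
    if best_f >= best_r:
        return MotifHit(float(best_f), int(np.argmax(fwd)), "+")
    return MotifHit(float(best_r), int(np.argmax(rev)), "-")


def count_core(seq: str, core: str = "GCCAT", both_strands: bool = True) -> int:
    """Count perfect matches to the core motif, overlaps allowed.

    With ``both_strands`` (default) occurrences of the reverse complement are
    added; each offset is counted once per pattern.
    """
    if not core or set(core.upper()) - set(ALPHABET):
        raise ValueError("core must be a non-empty ACGT string")
    seq = seq.upper()
    core = core.upper()
    patterns = [core]
    rc = reverse_complement(core)
    if both_strands and rc != core:
        patterns.append(rc)
    total = 0
    for pat in patterns:
        start = seq.find(pat)
        while start != -1:
            total += 1
            start = seq.find(pat, start + 1)
    return total


def bin_and_summarize(
    strength: Sequence[float],
    score: Sequence[float],
    core_count: Sequence[float],
    n_bins: int,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[BinSummary]:
    """Split sites into equal-count strength bins and summarize motif statistics.

    Sites are ranked by descending strength and divided into ``n_bins``
    equal-count bins (any remainder goes to the strongest bins).  Each bin
    reports mean PWM score and mean core count with 95% percentile-bootstrap
    confidence half-widths (``n_bootstrap`` resamples, seeded).
    """
    strength = np.asarray(strength, dtype=float)
    score = np.asarray(score, dtype=float)
    core_count = np.asarray(core_count, dtype=float)
    n = len(strength)
    if not (len(score) == len(core_count) == n):
        raise ValueError("strength, score, core_count must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(f"cannot split {n} sites into {n_bins} bins")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    order = np.argsort(-strength, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    out = []
    pos = 0
    for b, size in enumerate(sizes):
        idx = order[pos : pos + size]
        pos += size
        summaries = {}
        for label, vals in (("score", score[idx]), ("core", core_count[idx])):
            mean = float(vals.mean())
            resample = rng.integers(0, size, size=(n_bootstrap, size))
            boot_means = vals[resample].mean(axis=1)
            lo_q, hi_q = np.percentile(boot_means, [2.5, 97.5])
            summaries[label] = (mean, float((hi_q - lo_q) / 2.0))
        out.append(
            BinSummary(
                bin_index=b,
                n=size,
                mean_score=summaries["score"][0],
                mean_core=summaries["core"][0],
                ci_score=summaries["score"][1],
                ci_core=summaries["core"][1],
            )
        )
    return out


def rank_trend_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max_n: int = 12,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value between two groups.

    Exact by enumeration of all rank assignments when the pooled sample size
    is <= ``exact_max_n`` (mid-ranks handle ties); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need >= 1 value")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    if n_a + n_b <= exact_max_n:
        ranks = stats.rankdata(pooled)
        observed = ranks[:n_a].sum()
        expected = n_a * (n_a + n_b + 1) / 2.0
        dev = abs(observed - expected)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - expected) >= dev - 1e-9:
                extreme += 1
        return extreme / total
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(result.pvalue)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("rank correlation undefined for constant input")
    return float(np.corrcoef(rx, ry)[0, 1])
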