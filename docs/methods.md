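# Methods

This note documents the models, conventions, and numerical choices behind
`phorcmap`, and what the synthetic-data experiments do and do not show.

## Coordinates and probe geometry

All intervals are 0-based, half-open (`[start, end)`, BED-native);
conversion to and from BED is the identity on coordinates.  A probe's
position for every windowing operation is its midpoint `start + length/2`.
The published procedure never states whether features are located by start
or midpoint; the midpoint is symmetric under strand and tiling direction,
which keeps smoothing translation-equivariant.  TSS windows are clipped at
position 0 (chromosome starts); widths are `2 × halfwidth` elsewhere.

Expression activity uses `value ≥ 300` on the RPKM scale and the strict
`value > 6` on the RMA scale, mirroring the asymmetry between "a threshold
of 300" and "more than 6" in the source procedures.

## Ratio profiles and smoothing

The binding profile is the ratio of replicate means — `mean(ChIP) /
mean(Input)` per probe — not the mean of per-replicate ratios.  Probes with
zero Input mean are undefined and stay undefined: downstream stages skip
them rather than imputing.

Smoothing is a trimmed mean over a sliding window of `smooth_window_bp`
(default 675 bp, closed on both ends, same chromosome), centered on each
probe midpoint.  Windows with fewer than `min_features_per_window`
(default 10) defined features are undefined.  The trim fraction is not
stated in the published procedure; the default drops `floor(0.1·n)` values
from each tail — the conventional 10% trimmed mean — and is configurable
because results must be reproducible under any stated value.  Undefined
ratios do not count toward the feature minimum: the minimum exists to
guarantee a stable trimmed mean, which only defined values provide.

## Bound-region calling

The background cutoff is `mean + sd_multiplier·SD` (default multiplier 3,
sample SD with `ddof=1`; both configurable).  The statistics are computed
over the per-feature (unsmoothed) ChIP/Input ratios, and the cutoff is then
subtracted from the smoothed profile, negatives clipped to zero.  Reading
"the mean and SD of all ChIP/Input hybridization ratios" as the
feature-level ratios matters: if instead the statistics are taken over the
smoothed profile itself, the exceedance rate of a pure-noise profile
becomes scale-free — the cutoff and the profile fluctuations shrink
together — and the caller emits ~1.5 spurious regions per Mb at any noise
level.  With feature-level statistics the cutoff sits √n-window-fold above
the smoothed noise floor and the measured null rate is 0 calls per Mb
(20 seeds, 1 Mb each).  `adjust_profile` retains the generic contract
(cutoff from the values it is given) with `cutoff_values` as the override
the pipeline uses.

Supporting probes (adjusted value > 0) cluster while consecutive midpoint
gaps are ≤ `max_gap_bp` (500); clusters whose genomic footprint — first
probe start to last probe end — is shorter than `min_region_bp` (360, the
estimated ChIP resolution) are dropped.  The footprint reading of the
length filter (rather than probe-span sums) is the most inclusive
self-consistent option.  The peak is the best window of `peak_features`
(6) consecutive supporting probes by mean ratio; regions with fewer probes
use the whole region (the minimum-length filter makes this rare).  Peak
ties break to the leftmost window so output is deterministic.  Strength
ranking is stable: ties keep genomic order.

## Overlap statistics

Overlap is counted per site: a site hits a reference set when its span
shares ≥ 1 bp with any reference interval (a minimum-overlap option is
provided but 1 bp is the default, as the published curves never quantify
the predicate).  Overlap-vs-strength curves evaluate the top `⌈f·N⌉` sites
on a retained-fraction grid from 100% down in 5% steps.  Co-occupancy is a
coverage intersection: base pairs covered by at least one site from every
input set, merged; target coverage is the fraction of domains intersecting
at least one such co-occupied interval.

## Motif scoring

PWMs are estimated from user-supplied aligned occurrences with probability
`(count + pseudocount)/(n + 4·pseudocount)` (default pseudocount 0.5).
Scores are summed log₂-odds against a configurable background (default
uniform); the functional form is not stated in the source procedure and
log₂-odds against uniform is the field convention.  Scanning slides the
window one nucleotide at a time over the sequence and its reverse
complement; the single best window defines the site score, with ties
resolved to the forward strand and then the smallest offset.  Ambiguous
bases (N) contribute the background term (0) rather than −∞ so
repeat-masked sequence remains scoreable.  GCCAT core counting includes
both strands (GCCAT and ATGGC; PHO binds double-stranded DNA), overlaps
allowed, each offset counted once per pattern; a forward-only mode exists.

Strength bins are equal-count (remainder to the strongest bins) because
the source procedure bins "according to the strength" without defining
edges; 95% CIs are seeded percentile bootstraps with 1000 resamples.  The
rank-sum trend test is exact by enumeration of all `C(n, n_a)` rank
assignments when the pooled size is ≤ 12 (mid-ranks handle ties) and a
tie- and continuity-corrected normal approximation otherwise.  Spearman
correlation is the Pearson correlation of mid-ranks.

The default 14 bp PWM (`default_pho_pwm`) is synthetic: it encodes the
documented anatomy of the extended PHO/PHOL/YY1 recognition motif — a
strongly conserved GCCAT core at positions 6–10, a preferred T two
positions downstream, weakly informative flanks — not any published
matrix.  A degenerate variant for PRE-style scanning can be supplied as a
second PWM file.

## State comparison

The adjusted average binding signal at a PRE is the mean of defined
smoothed values within `state_window_bp` (500) centered on the PHO peak,
minus the genome-wide mean of the same profile (computed once and cached);
it is therefore invariant under constant profile shifts and may be
negative.  The Wilcoxon signed-rank test drops zero differences and
mid-ranks ties; exact p-values enumerate all 2ⁿ sign assignments via a
subset-sum recursion over doubled ranks (identical to literal enumeration,
O(n·Σranks) instead of O(2ⁿ)) for n ≤ 20, with a tie- and
continuity-corrected normal approximation beyond.  The default alternative
is one-sided "less" (active < repressed): the two printed reference values
0.004 (= 1/256, eight concordant pairs) and 0.008 (= 2/256, seven
concordant plus a smallest-magnitude discordant pair) are only mutually
consistent with one-sided exact tests, so sidedness is an inference, made
explicit here.

## Synthetic data

The generator emulates the structure of the real experiments: an i.i.d.
random genome at a configurable GC fraction (default 0.42, fly-like),
25-mer probes every 36 bp (approximating the Affymetrix *Drosophila*
tiling v1.0 design), two ChIP and two Input replicates, localized
enrichment over planted sites, and multiplicative lognormal noise
(default σ = 0.1 per replicate measurement).  Enrichment is shaped by a
triangular kernel of half-width 500 bp — the fragment-size/ChIP-resolution
scale — so a probe at a site center with amplitude *a* has expected ratio
`1 + a`; a Gaussian kernel is available by configuration.

Two site classes encode the empirical contrast the analysis is built to
detect.  TSS-class sites embed a PWM sample whose amplitude is
`a₀·2^(β·(s − E[s]))` times lognormal noise, with *s* the embedded
instance's log-odds score (defaults a₀ = 6, β = 0.35, amplitude noise
σ = 0.3): strength tracks motif quality, log-linearly — the simplest
monotone coupling.  PRE-class sites embed 1–3 GCCAT cores and draw
amplitude log-uniformly on [2, 20] (the observed ~10-fold strength range),
independent of sequence.  The truth table records the embedded instance's
own score for TSS sites (the quantity the amplitude is coupled to); for
PRE sites, where nothing beyond cores is planted, it records the measured
best-window score of the edited ±200 bp region.  Note the measured score
of any region is floored by its best background window (a stray GCCAT
scores ≈ 8 bits), which compresses score differences among weak sites;
the binned trend remains clearly detectable.

All randomness flows through one `numpy` generator derived from the
mandatory seed, so outputs are bit-reproducible.  The generator does not
model probe-sequence hybridization bias, cross-hybridization,
copy-number variation, or mappability; passing tests demonstrate the
pipeline's correctness under the stated noise model, not robustness to
array artifacts that upstream normalization is assumed to have removed.

## Test problem sizes

The deep end-to-end checks use: 2 Mb genomes with 20 planted sites (and a
site-free null) for recovery calibration; 700 kb genomes with 200 sites
per class for the motif-coupling contrast; 150 kb genomes with 8 PREs,
repeated 200 times, for two-state type-I calibration; and 200+ random
small profiles/sequences for brute-force oracle equivalence.  These sizes
give stable statistics (binomial standard errors well inside the asserted
margins) while keeping the default suite fast.

## Known limitations

* Upstream array processing (CEL parsing, RMA/quantile normalization,
  dye bias) is out of scope; the entry format is the probe-level ratio
  table such processing emits.
* De-novo motif discovery is out of scope; PWMs are estimated from
  aligned occurrences or supplied as matrices.
* No FDR or permutation significance for region calls or overlaps — the
  procedures reproduced here rank by strength and use exact paired tests
  instead.
* The two printed reference p-values are properties of the sign/rank
  pattern, not of signal magnitudes; matching them validates the test
  implementation, not the ChIP model.
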