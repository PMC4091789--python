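# phorcmap

Analysis of genome-wide PhoRC binding from tiling-array ChIP-chip data.

PhoRC is the *Drosophila* Pho Repressive Complex, a heterodimer of the
sequence-specific zinc-finger protein PHO (or its paralog PHOL) and SFMBT.
PHO/PHOL recognize an extended 14 bp motif with a conserved GCCAT core — the
same specificity as their human ortholog YY1.  Mapping where PhoRC binds, and
how strongly, distinguishes two classes of sites with different recruitment
logic: sites near transcriptionally active promoters, where binding strength
tracks the quality of the recognition sequence, and Polycomb Response
Elements (PREs), where it does not and binding instead depends on
combinatorial interactions with other Polycomb proteins.  A measurable
corollary is that PhoRC binding at a PRE drops when its target gene switches
from the Polycomb-repressed to the active state.

`phorcmap` implements the computational side of this analysis as a tested,
reusable pipeline for probe-level tiling-array data, plus a synthetic-data
generator that emulates the array experiments so every stage can be
exercised end to end without any external download.

## The pipeline

Given per-probe ChIP and Input replicate intensities:

1. **Ratio profile** — per probe, mean(ChIP replicates) / mean(Input
   replicates).
2. **Smoothing** — trimmed mean over a sliding 675 bp window centered on
   each probe midpoint; windows with fewer than 10 features are undefined.
3. **Bound regions** — a background cutoff `mean + 3·SD` of the ratio
   profile is subtracted and negatives set to zero; maximal clusters of
   positive probes with neighbor gaps ≤ 500 bp and genomic span ≥ 360 bp
   (the estimated ChIP resolution) are the bound regions.  Within each
   region, the window of 6 consecutive features with the highest average
   ratio is the **binding peak**, and that average is the region's
   **binding strength**.
4. **Overlap curves** — the fraction of binding sites intersecting a
   reference set (PREs, windows of ±300 bp or ±700 bp around active TSSs),
   re-evaluated as the weakest sites are progressively removed; plus
   coverage intersection across site sets ("co-occupied" sites) and the
   fraction of Polycomb domains containing one.
5. **Motif scoring** — sequences ±200 bp around peaks are scanned with a
   14 bp position weight matrix on both strands; each window scores
   `Σᵢ log₂(pᵢ(b)/q(b))` and the single best window defines the site's
   score.  Perfect GCCAT matches on either strand are counted.  Sites are
   split into equal-count strength bins (means with 95% bootstrap CIs,
   Wilcoxon rank-sum trend test, Spearman correlations).
6. **State comparison** — per PRE, the adjusted average binding signal is
   the mean smoothed ratio in a 500 bp window around the peak minus the
   genome-wide average; the paired repressed-vs-active difference across
   PREs is tested with an exact one-sided Wilcoxon signed-rank test
   (all 2ⁿ sign assignments enumerated; mid-ranks for ties, zeros dropped).
   With eight concordant reductions the exact p is 1/256 ≈ 0.004; with
   seven concordant and the discordant pair moving least, 2/256 ≈ 0.008.

The synthetic generator plants two site classes into a random genome —
TSS-class sites whose enrichment amplitude is log-linearly coupled to the
quality of an embedded PWM instance, and PRE-class sites carrying 1–3 GCCAT
cores with sequence-independent amplitudes — and simulates replicate probe
intensities with a triangular fragment-size kernel and multiplicative
lognormal noise.

## Worked example

Run the whole pipeline on a simulated experiment (8 PRE-class and 12
TSS-class sites in 500 kb, two ChIP + two Input replicates), then compare
two chromatin states in which all eight PRE amplitudes are halved:

```python
import phorcmap as pm

config = {
    "seed": 7,
    "simulate": {
        "genome_length": 500_000,
        "n_pre_sites": 8,
        "n_tss_sites": 12,
        "min_site_separation": 5000,
        "pre_amp_range": [4.0, 16.0],
    },
    "motif": {"n_bins": 4},
    "two_state": {"reduction_factors": [0.5] * 8},
}
manifest = pm.run_pipeline(config, outdir="example_run", quiet=True)
print(manifest.summary)
```

prints

```
{'n_bound_regions': 9, 'background_cutoff': 4.435126,
 'overlap_at_100pct': 1.0,
 'signed_rank': {'n': 8, 'w_plus': 0.0, 'pvalue': 0.00390625,
                 'alternative': 'less', 'method': 'exact'}}
```

Nine bound regions pass the cutoff of 4.44 (mean + 3·SD of the ratio
profile, inflated here by the planted sites themselves); every called site
overlaps a planted site (`overlap_at_100pct = 1.0`).  In the two-state
comparison all eight PREs lose signal in the active state
(`paired_signals.tsv` lists differences from −1.53 to −4.13), so the
exact one-sided signed-rank statistic is W⁺ = 0 and p = 1/256 ≈ 0.004 —
the most extreme value eight pairs allow.  Per-site motif scores land in
`site_scores.tsv`:

```
site_rank  chrom   peak_center  strength   best_score  offset  strand  core_count
1          simchr  173406       14.412881  9.169318    210     -       2
2          simchr  8562         11.120516  10.043787   184     +       2
...
```

The same stages are available from the shell:

```bash
phorcmap run-all --config config.yaml --outdir example_run
phorcmap call-regions --probe-table probes.tsv --regions-out regions.bed
phorcmap compare --probe-table-repressed r.tsv --probe-table-active a.tsv \
    --pre-peaks pres.bed --out paired.tsv
```

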