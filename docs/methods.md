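# Methods

## The depth model and what the simulator emulates

The package works on a single scalar per fixed-width genomic bin: the
number of reads overlapping the bin (default bin size 500 bp). The
synthetic cohort generator emulates the study conditions the pipeline is
designed for: two populations of resequenced individuals at ~6.7× mean
coverage over a multi-scaffold genome. With 100-bp reads, 6.7× coverage
corresponds to ~33.5 expected reads per 500-bp bin, which is the
`mean_depth` default.

Per-bin depth for sample *s* is Poisson with rate

    mean_depth · (CN_s(bin)/2) · gc_bias(GC_bin) · width_fraction

where CN comes from the planted truth (background 2), and `gc_bias` is a
quadratic bump peaking at GC 0.45 with floor 0.6 — the qualitative shape of
the Illumina coverage–GC response that motivates GC correction. The GC
track itself is a moving-average-smoothed Gaussian process (mean 0.42,
sd 0.07, ~50-bin correlation length), clipped to [0, 1]: spatially
autocorrelated like isochore structure without modelling sequence.

Truth events are planted on the bin grid, pairwise disjoint with a ≥4-bin
guard gap, with lengths uniform in 6–40 bins (3–20 kb) by default. Carrier
status is Bernoulli per sample at a population-specific frequency; carrier
copy number is uniform on {0, 1} for losses and {3, 4, 5, 6} for gains —
the CN range distinguishable from diploid at ~6.7×. Designated repeat
regions get an elevated multi-mapping fraction (q0 ≈ 0.8 vs background
≈ 0.02), emulating regions where read placement is ambiguous.

What the simulator deliberately does **not** model: read-level error and
mapping (no FASTQ/BAM synthesis), mappability structure beyond the q0
flag, overdispersion beyond Poisson, inter-sample batch effects, and
breakpoints off the bin grid. Passing the recovery tests therefore
demonstrates the statistical machinery under the stated depth model, not
robustness to alignment artefacts of real data.

All randomness flows from one seed through CRC32-keyed
`numpy.random.SeedSequence` children (`cnvpop.simulate.child_rng`), so any
stage or sample can be regenerated standalone, byte-identically.

## GC correction

`corrected[b] = raw[b] · global_mean / class_mean(GC%[b])`, with integer
GC-percent classes. Classes with fewer than 100 bins (or zero mean) are
left uncorrected: their class mean is too noisy to be a denominator. When
no fallback triggers the genome-wide mean is preserved exactly (the
correction is a reweighting within classes). The uncorrectable tail —
rare extreme-GC bins whose true bias stays in the depth — is one of the
residual false-positive sources the CN-deviation gate (below) absorbs.

## Segmentation

Mean-shift with a Gaussian positional kernel (bandwidths 2, 4, 8, 16, 32
bins, smallest first) and a Gaussian signal kernel whose width follows the
Poisson variance of the local depth (s²ᵢ = max(rdᵢ, 1)). Each bin gets the
sign of the kernel-weighted gradient; a candidate boundary lies between a
left-pointing bin and a right-pointing one.

At each bandwidth the candidate partition is first coalesced bottom-up:
adjacent pieces whose bin-depth distributions a pooled two-sample t-test
cannot distinguish (p ≥ 0.01) are merged, most-similar pair first. This
dissolves the spurious fragmentation of homogeneous stretches while
keeping genuine level shifts. A coalesced segment is then **frozen** when
it differs from both neighbours at `0.01 / n_bins` — a Bonferroni-style
threshold reflecting that every bin is a potential boundary; without it,
selection bias (mean-shift proposes exactly the locally extreme runs)
floods the partition with noise segments. Frozen bins are masked to the
background mean before the next, coarser bandwidth so established events
stop attracting their surroundings. The final tiling is the frozen
boundaries plus one last p ≥ 0.01 re-merge pass.

Numerical behaviour worth knowing: a constant signal yields exactly one
segment (no strict sign change); a noiseless step is recovered at the
exact breakpoints; 1,000 bins of pure Poisson(7) noise end as a single
segment in ≥95% of seeded replicates; and the procedure is deterministic
for fixed input and bandwidths.

## Calling and filters

CN = 2·segment mean / effective depth, where effective depth is the mean
corrected depth over autosomal bins (configured sex scaffolds are excluded
— hemizygosity would bias the diploid baseline). A segment becomes a call
iff all of:

- one-sample t-test of its bin depths against the genome mean,
  Benjamini–Hochberg adjusted across all segments of the sample,
  p < 0.05 (degenerate zero-variance segments get p = 0 or 1 by mean
  comparison);
- length ≥ 1,500 bp (three bins — the scale below which read-depth
  evidence at this coverage is unreliable);
- mean q0 over the call's bins ≤ 0.5 (multi-mapping guard);
- |CN − 2| ≥ 0.5, i.e. the classic 0.75×/1.25× mean-depth cutoffs for
  deletion/duplication. This gate is load-bearing: a long diploid segment
  has a tiny standard error, so a 2% baseline drift (GC residue, events
  elsewhere shifting the genome mean) is statistically significant while
  biologically meaningless. Significance controls noise; the deviation
  gate controls relevance.

Boundaries are reported on bin edges — the resolution of the signal.

## CNVR definition and the CN matrix

CNVRs are connected components of the ≥1-bp-overlap graph over all
samples' calls, computed by a sorted sweep (components of interval overlap
are contiguous in start order). Coordinates are half-open throughout, so
abutting calls do not merge. Support counts distinct samples, not calls;
regions with support < 4 are dropped (the default guards against artefacts
private to a few genomes and is configurable). Region type is gain, loss,
or both, from the kinds of the contributing calls.

The CNVR × sample matrix takes every value from depth —
2·(mean corrected depth over the region)/(effective depth) — including for
samples that contributed no call. Imputing non-callers as exactly 2 would
delete the within-population variance that V_ST needs.

## Population differentiation

V_ST = (V_T − V_S)/V_T with **population** variances (denominator n);
V_S = (n_a·var_a + n_b·var_b)/(n_a + n_b). The sample-variance variant is
available (`ddof=1`). V_T = 0 leaves the statistic undefined: reported as
0, flagged, never selected. Selection takes the top 5% of *defined* V_ST
values (quantile by linear interpolation, ties at the threshold included)
intersected with a two-sided pooled-variance Student's t-test p < 0.05 on
the CN vectors (Welch available via flag; zero-pooled-variance loci get
p = 0/1 by mean comparison, so fixed differences are never lost to an
undefined test). No multiple-testing correction is applied to the t-test:
the V_ST rank criterion is the primary filter and the dual criterion is
deliberately conservative.

## Gene content and enrichment

A gene belongs to the CNVR gene set when strictly more than 50% of its
length lies in the union of all CNVRs — the union, because a gene may be
covered by several adjacent regions, and the rule is about the gene.
GFF3 input is converted from 1-based inclusive to half-open on read.
Enrichment per term is the upper-tail hypergeometric p, P(X ≥ k), against
the full annotated gene background, BH-adjusted across tested terms with
significance at FDR 0.05. Terms absent from the background are skipped
rather than reported undefined.

## Segmental-duplication association

The direct statistic: the fraction of CNVRs longer than 15 kb whose
interval — optionally extended by a flank (5 Mb for the flanked variant),
clipped to scaffold bounds — intersects ≥ 1 SD interval. The null re-places
every such CNVR uniformly at random on its own scaffold, lengths
preserved, placements independent, mutual overlap allowed: per-scaffold
placement preserves the scaffold length composition, the main confounder
at this scale. Empirical p = (1 + #{null ≥ obs})/(n_perm + 1), so p is
never 0; one-sided enrichment by default, depletion via flag.

The fraction statistic is discrete (counts over a few dozen regions), so
its permutation p is conservative under heavy ties — calibration checks
measure the fraction of p < 0.05 at ~0.02–0.03 rather than 0.05. A total
shared-base-pairs statistic (`statistic="bp"`) is provided; being
near-continuous it calibrates at the nominal level and is what the
calibration tests use.

## Validation math

ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator;
CN = 2·2^(−ΔΔCt). The calibrator convention is a designated known-diploid
control sample measured with the same primer pair, which makes the
control's CN exactly 2 by construction. The cv between two CN estimates
uses the sample (n−1) standard deviation of the pair, |a − b|/√2, over the
mean (population variant via `ddof=0`); the acceptance gate is cv < 0.25.
A call is "supported" by a second call set when some overlapping (≥ 1 bp)
call passes the cv gate; requiring overlap is the default and can be
relaxed.

## Read QC

Rules run in a fixed order per read: N-fraction ≥ 10% → discard; > 65% of
bases at Phred ≤ 7 → discard (strict >, the boundary being otherwise
ambiguous); adapter hit → discard, where a hit is any ungapped alignment
offset with ≥ 11 overlapping bases and ≤ 2 mismatches in the overlap; trim
at the first run of 3 consecutive bases at Phred ≤ 13, keeping the 5′
prefix (3′ quality decay is the standard failure mode); post-trim length
< 45 → discard. Discard checks precede trimming so trim statistics only
reflect surviving reads. Pairs live or die together; duplicates are exact
(mate-1, mate-2) sequence pairs, first occurrence kept — the only notion
of duplicate available before alignment.

## Problem sizes and defaults

The bundled demo runs 10 samples over 6 Mb with 30 events; the
reproduction script (`scripts/acceptance.py`) runs 30 samples over 10 Mb
with 50 events, a 30× re-call of 6 samples, a 200+10-locus
differentiation scan, and a 999-permutation SD test — sizes at which the
whole analysis completes in well under a minute on one CPU while every
stage still operates in its intended regime (dozens of segments per
sample, support-4 CNVRs, a meaningful 95th percentile).

## Known limitations

- Breakpoints are bin-quantised; sub-bin precision is out of scope.
- The caller is tuned for the 6.7× regime: at much lower coverage the
  freeze test loses power for single-copy gains; at much higher coverage
  the CN-deviation gate dominates.
- The q0 model is binary (repeat vs background); graded mappability is
  not modelled.
- The permutation null preserves lengths and scaffolds but not GC or gap
  structure; matched-placement schemes are out of scope.
- V_ST assumes exactly two groups; multi-group contrasts are not
  implemented.
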