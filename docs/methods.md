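# Methods

## Coordinate and association conventions

All intervals are 0-based half-open (BED convention); GFF3 input (1-based
inclusive) is converted on read. The distance between two intervals is the
edge-to-edge gap in bp: overlapping or touching intervals are at distance
0, intervals on different chromosomes infinitely far apart. "Within *w*
bp" means gap ≤ *w*, matching `bedtools window -w` semantics. A feature
associated with several peaks counts once — the association statistic is
the number of associated features, which is what a per-class "fraction
with a peak" table reports. Pair counting (number of feature–peak pairs
within the window) is available via `associate_features(...,
count_pairs=True)` for sensitivity analyses.

Two association windows are used, both configurable in `AnalysisConfig`:
300 bp for protein-occupancy peaks (the shearing size of ChIP DNA, so a
peak within 300 bp is indistinguishable from direct overlap) and 5000 bp
for the γ-H2A damage mark, which spreads over kilobase-scale domains
around a break rather than sitting on it.

## The GC-matched permutation null

Observed association counts are compared against peak sets relocated
uniformly at random subject to three constraints per peak: same
chromosome, same length, and GC content within `gc_tolerance` (default
0.02 absolute) of the original. GC is computed from per-chromosome prefix
sums, N bases excluded from numerator and denominator; all-N candidate
windows are never accepted, and an all-N peak is an error. Matching uses
rejection sampling in batches of 1000 candidate starts; if a batch yields
no qualifying position the tolerance doubles, at most 5 times, after which
the offending peak is named in the error. The doubling schedule exists
because exact GC preservation is frequently infeasible on real genomes;
the relaxed tolerance bounds the worst-case mismatch at
`gc_tolerance · 2⁵`.

Shuffled peaks may overlap one another and the original location:
excluding either would bias the null, and nothing in the procedure's
definition forbids it. One shared set of `n_permutations` shuffles
(default 1000) scores every feature class, which makes a whole association
table reproducible from a single seed and is statistically equivalent to
independent shuffles per class (each class's null marginal is unchanged;
only the irrelevant cross-class correlation differs).

The empirical p-value is `#{permuted ≥ observed}/N`. When the count is
zero the true p is merely below the scheme's resolution, so it is reported
as the bound "<1/N" — never as 0 — while the numeric field used for
threshold comparisons is `max(count, 1)/N`. Bonferroni control uses
α/n_classes; with α = 0.05 and 16 classes the threshold is 0.003125. For
comparing hit rates between a gene subset and its parent population (are
the most highly expressed genes hit more often than genes generally?) an
upper-tail hypergeometric test is provided.

## Cross-condition peak dynamics

Peaks from two conditions are merged (`merge_union`) into maximal disjoint
regions; each region becomes one paired observation whose per-condition
strength is the **maximum** strength among that condition's peaks
overlapping the region, or 0 when the condition has no peak there. Max
rather than sum was chosen because a merged region usually contains one
peak per condition, and max is insensitive to a caller fragmenting one
binding event into two peaks. Strengths are −10·log₁₀ of the peak-calling
p-value (MACS convention); tables lacking strengths are refused rather
than imputed.

"Fraction stronger" is the fraction of matched regions with strictly
greater strength in the second condition — ties stay in the denominator
only, and a region present only in the second condition counts as
stronger. This is a descriptive per-region quantity, not a per-region
significance call: no per-peak test is defined for it, so printed
percentages from studies that used an unspecified per-peak criterion are
reproducible only up to that choice. The accompanying hypothesis test is
the two-sided Wilcoxon signed-rank on the paired strengths, zero
differences dropped, exact null distribution for ≤ 25 nonzero differences
and the normal approximation with continuity correction above; p-values
below 10⁻⁵⁰ are flagged and printed "~0". Venn-style overlap counts
default to direct overlap (window 0) and report both directions separately
because merging/splitting across conditions makes the two shared counts
differ in general.

## Signal tracks

Per-base signal is log₂((IP + c)/(input + c)) with pseudocount c = 1
added to both counts, so zero-coverage positions are exactly 0 rather
than undefined. Smoothing convolves with a Hanning window of length
`hanning_bp + 1`, forced odd so the output is phase-aligned with the
input, weights normalised to unit sum; near track ends the truncated
kernel is renormalised, which keeps constants exactly constant out to the
edges and avoids padding dips in 10 kb gene plots. Consequences asserted
by tests: constants are preserved to 1e−12, the smoothed maximum
magnitude never exceeds the raw one, and an impulse reproduces the kernel
profile. Whether input counts are read starts or fragment coverage is up
to the caller; both work, since the ratio and the smoother are agnostic.

## IP-MS scoring

SAINT scores are inputs (the scoring algorithm itself is external); the
filter keeps score ≥ threshold, inclusive, default 0.80. NSAF divides
each protein's spectral counts by its amino-acid length and normalises
over the retained set, so values sum to 1; counts are **summed** across
the two replicates before normalising — for equal-depth replicates
averaging gives identical NSAF, and summing is robust to a zero-count
replicate. NSAF is invariant to uniform count scaling, and NSAF/PAX
ordering is invariant to uniform PAX rescaling (PAX units are arbitrary;
only relative enrichment is meaningful). Proteins without a positive PAX
value are excluded from ratios and flagged, never imputed. Phase
dependence compares summed bait counts between S and G2 purifications of
the same bait with no statistical test — S-limited (G2 = 0 < S),
S-enriched (0 < G2 < S), unchanged, G2-enriched — mirroring the
descriptive comparison this analysis style uses.

## The synthetic-data generator

The generator emulates a fission-yeast-scale ChIP-seq/IP-MS study so that
every stage runs, and is itself first-class tested code.

* **Genome**: 3 × 200 kb by default (desk scale, chosen to keep a
  1000-permutation run under ten seconds), i.i.d. bases within 10 kb
  blocks whose GC targets are uniform on [0.30, 0.55], giving the
  spatially varying GC the matched shuffle must cope with.
* **Features**: eight annotation classes placed uniformly, with densities
  proportioned to fission-yeast annotations at the reduced genome size.
* **Peaks**: placement density at a position equals the largest enrichment
  weight of any feature class within 300 bp (1 elsewhere), implemented by
  inverse-CDF sampling on a per-base weight array — weight-1 classes
  therefore leave placement exactly uniform, and a weight-w class attracts
  w-fold peak density. Default planted truth: 20× at tRNA-like and
  5S-like classes, 5× at highly expressed genes, 3× at NDRs, 1 elsewhere.
  Peak strengths are −10·log₁₀ of a one-sided binomial-test p on simulated
  IP/input Poisson counts, so they live on the same scale as real peak
  calls. Condition sizes default to the study scale emulated (helicase
  120; polymerase 100/105; damage mark 40/115 at desk scale;
  `full_study_spec()` provides the full 621 / 485 / 517 / 179 / 582 sizes
  on a 6 Mb genome). WT/depleted pairs share a configurable fraction of
  locations (default 0.80, the observed overlap rate); 71% of damage-mark
  peaks are placed just outside a depleted-condition polymerase peak
  (damage accumulates where forks slow); depleted strengths get a +10
  shift plus Gaussian noise (SD = shift/5). All peaks are mutually
  non-overlapping with ≥ 50 bp separation, so planted sharing equals
  observable overlap exactly — convenient for exact recovery tests,
  though real peak sets do fragment and merge across conditions, which is
  precisely why `venn_counts` reports both shared counts.
* **Coverage**: input ~ Poisson(depth), IP ~ Poisson(depth·fold) inside
  peaks (fold 4), per base.
* **Spectral counts**: 100 proteins, 20% planted interactors with bait
  counts ~ Poisson(30) per replicate vs Poisson(2) controls; surrogate
  confidence scores ~ Beta(50, 2) for interactors and Beta(2, 50)
  otherwise, so a 0.80 cutoff recovers essentially all planted
  interactors with few false positives; G2 bait counts of interactors are
  binomially thinned by the depletion factor (0.4 default; 0 makes every
  interactor S-limited). A `deterministic_scores` mode removes all noise
  for exact-recovery tests.

Everything is deterministic given the seed; `simulate_study` derives one
substream per generator from a single `SeedSequence`, and the pipeline
does the same per stage, so stages can be rerun independently.

**What passing on synthetic data does not show.** The generator plants
clean structure: disjoint peaks, Poisson coverage, independent features,
noise-free sharing. Real data add peak fragmentation, copy-number and
mappability artifacts, correlated annotations (NDRs overlap promoters and
highly expressed genes), and peak strengths whose WT/depleted relationship
is not a simple shift — so recovered percentages (e.g. the
stronger-in-depleted fractions) characterise the planted conditions, not
any particular organism. What the tests do establish is that the
machinery is correct: counts, overlaps and matched fractions equal
brute-force recounts, the permutation null is unbiased under uniform
placement (verified against the analytic expectation), and planted
enrichment/shift/interactor structure is recovered at the configured
effect sizes.

## Numerical choices and degenerate inputs

* Empty feature sets are an error in association (the fraction is
  undefined); empty peak lists give count 0.
* `empirical_pvalue` requires at least one permutation; with N = 1 the
  p-value is 0 (flagged "<1") or 1.
* The Wilcoxon test refuses all-zero difference vectors.
* NSAF refuses a zero total count; `saint_filter` thresholds are clamped
  to [0, 1] by validation.
* Strength-bearing stages refuse tables with missing strengths.
* TSV output rounds floats to 6 significant digits; coordinate round
  trips are exact.

## Known limitations

* Strand is ignored throughout (association is strand-agnostic by
  design); nested annotation hierarchies are not modelled.
* The shuffle preserves GC only within tolerance, not exactly, and the
  relaxation schedule means a pathological peak can be matched at up to
  32× the nominal tolerance (logged in the error path only when even that
  fails).
* No FDR across strata in the dynamics stage; strata are descriptive.
* No BAM/bigWig input: coverage arrives as arrays or wiggle-like TSV.
* Network edges come only from a user-supplied known-interaction table;
  no online lookup is performed.
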