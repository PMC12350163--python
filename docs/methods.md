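# Methods

This note documents the models, conventions and design choices behind
`markbins`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) throughout; FASTA,
chrom.sizes and BED are read and written natively. Printed compartment
coordinates (e.g. `chr2R: 1-6460000` heterochromatin, `chr2R:
6460000-25286936` euchromatin) are treated as *breakpoints shared between
adjacent compartments*: a printed start of 1 maps to position 0, any other
printed start is itself the 0-based boundary (it equals the printed end of
its neighbour). This keeps euchromatin and heterochromatin disjoint — under
a strict 1-based-inclusive reading the shared base would belong to both —
and gives a total heterochromatin span of 17,093,939 bp over the four
printed intervals. Bins are assigned a compartment by midpoint, which
avoids double-labelling at boundaries; no overlap rule is canonical here,
and the midpoint rule is the least ambiguous.

## Binning and mappability

Tiling keeps the trailing short bin of every sequence; sliding windows
start at multiples of the step and are truncated at the sequence end, and
the *raw* window count is reported before sub-minimum windows are removed
(the removal is an explicit, separate filter step). Bin ids are
`seq:start-end` strings.

Mappability uses an exact-match surrogate for unique short-read alignment:
a k-mer of read length *n* is unique iff its sequence occurs exactly once
in the genome considering both strands; a k-mer equal to its own reverse
complement counts its two strand readings as one placement, and any k-mer
containing a non-ACGT symbol is non-unique. The per-position value is
(number of unique k-mers overlapping the position)/*n* with denominator *n*
everywhere — positions within *n*−1 bp of a sequence end are overlapped by
fewer than *n* k-mers and are therefore slightly penalized; this matches
the verbatim definition rather than renormalizing at the ends. The per-bin
value is the number of unique k-mer *starts* in the bin divided by the bin
length. For *n* ≤ 31 k-mers are packed into 64-bit integers and counted
with vectorized uniqueness; longer read lengths fall back to a dictionary
of canonical strings. Bins with mappability below 0.2 are removed
(strictly-less rule: exactly 0.2 is retained), as are mitochondrial bins
and sub-minimum-size windows, with per-criterion removal tallies so that
input = retained + removed at every stage.

## Signal quantification

A fragment is counted into a bin iff the overlap is at least
`min_overlap_fraction` (default 0.5) of the *fragment's* length, ties
included — a fragment split exactly in half contributes to both bins,
matching the semantics of standard interval-intersection counting tools.
Window-grid counting for background subtraction uses any-overlap (≥ 1 bp)
semantics instead, as coverage tools do on fine grids.

Background (IgG/input) subtraction works on a 50 bp window grid: windows
are ordered by signal, the lowest-signal fraction (default 50%) defines the
signal-extraction scale s = Σsignal/Σbackground over that subset (capped to
[1e-3, 1e3]; an all-zero background yields s = 1 with a warning), and the
per-window enrichment is max(signal − s·background, 0). The per-bin value
is the arithmetic mean over windows fully inside the bin. The external tool
that inspired this contract has sampling parameters that are not
recoverable; only the contract — match background where enrichment is
absent, subtract, clamp — is reproduced here.

FPKM is computed on the mappable effective length, count × 10⁹ /
(library × length × mappability), so a half-mappable bin gets twice the
per-count signal; cpm is count × 10⁶ / library. Size factors follow the
median-of-ratios construction (geometric-mean reference over rows without
zeros). Display transforms: log2((t + pc)/(c + pc)) with pc = 0.01 on
normalized values; log10(min(v, cap) + 1) with caps 300 (1 kb bins) and 200
(10 kb bins); and the minimum of the two strand signals, which suppresses
unistrand loci and focuses dual-strand production.

## Classification and enrichment

ROC curves rank bins by score descending and emit one operating point per
*distinct* score value (cumulative TP/FP over tie blocks), so tied scores
traverse the diagonal of the tie block instead of taking the optimistic
per-item path; AUC is the trapezoid over (FPR, TPR) including the (0,0)
origin. This equals the tie-corrected Mann–Whitney statistic
U/(n₊·n₋), which the tests verify on hundreds of random instances. Marks
are combined as the element-wise mean of the same per-bin enrichment values
used for the single-mark curves (the scale on which the original analysis
averaged is not stated; using identical inputs for single and combined
predictors makes the comparison internally consistent).

Consensus peaks union-merge overlapping intervals across replicates
(touching intervals stay separate) and keep merged intervals supported by
at least two distinct replicates; a single-replicate set is kept as is. Bin
presence is ≥ 1 bp overlap under half-open semantics. Odds ratios are the
sample estimate a·d/(b·c) with a Haldane correction of 0.5 on all cells
when any cell is zero — not the conditional maximum-likelihood estimate
some statistics environments report, which differs slightly for extreme
tables; p values are the standard two-sided Fisher exact probability
(scipy), which the tests check against an exhaustive hypergeometric
enumeration to 1e-12. The stratified mode builds one 2×2 per mark
combination (both / K9-only / K27-only / neither): binding versus
membership in that stratum against all other bins.

Level grouping builds one group for zero-signal bins, sorts the remaining
levels ascending, takes `n_breakpoints` (default 15) equidistant *rank*
breakpoints including the extremes, and forms half-open intervals from
consecutive distinct breakpoint values (the last interval is closed at the
top, so the maximum is always assigned). Ties collapse breakpoints, so at
most 14 interval groups result and none is empty. Because the top interval
is closed, the two highest distinct levels can share the top group even
when every level is distinct; a partition of *m* distinct values into
*m* − 1 rank intervals cannot be one-to-one.

## Dependency classification

Fold loss is control/depleted on cpm, computed per replicate pair with the
pseudocount applied before the ratio, then averaged — mean of ratios, with
a ratio-of-means mode available (the source analysis does not disambiguate;
mean-of-ratios is the default and both are exposed). A bin is
Rhino-dependent when the mean fold loss across depletion strategies is
strictly greater than 2; Rhino-dependent bins are E(z)-dependent,
Kipferl-dependent, both, or neither at ≥ 4-fold mean loss per perturbation.
The thresholds are recorded in the result tables.

Peak dependency: per-replicate control peaks with fold enrichment ≥ 3 are
union-merged into a high-confidence set; peaks on unplaced contigs
(configurable name pattern, default names containing `Scaffold`, `rand`,
or lacking a `chr` prefix — assembly naming varies) or overlapping any peak
retained in the Rhino knockdown (≥ 1 bp) are excluded with a recorded
reason; the rest are Kipferl-independent iff they overlap a peak in the
Kipferl knockdown.

The delta-group analysis ranks bins by the change in H3K27me3 after E(z)
loss (ties broken deterministically by bin id), cuts them into six
equal-size groups (remainder assigned to the lowest-rank groups — an
equal-size rank partition, since the grouping is described as equally
sized rather than by fixed thresholds), and reports the mean change of each
responder track per group. The optional restriction keeps bins whose
H3K9me3 signal is at or above the 90th percentile of euchromatic bins,
which requires compartment labels.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
real sequencing data. Defaults (the study conditions): five 600 kb
chromosomes plus a 15 kb mitochondrion-like sequence (for exclusion
testing) and a 10 kb unplaced scaffold (for peak-exclusion testing); 1 kb
bins; per-bin mark states drawn with P(K9-only) = 0.13, P(K27-only) = 0.12,
P(both) = 0.05; dual-strand clusters placed preferentially in dual-marked
bins (60% of dual-marked bins host one, versus 6% of K9-only bins) and
unistrand clusters in unmarked chromatin (1.5%); reader-protein occupancy
with P(bound) = 0.9 / 0.5 / 0.05 / 0.02 for both / K9-only / K27-only /
unmarked bins. Fragment counts are negative binomial with variance
μ + αμ² and α = 0.1 (a standard overdispersion level for sequencing
counts; no value is stated by the source), mark background mean 20
fragments per bin, 6-fold enrichment in marked bins, two replicates, and
300 bp fragments placed uniformly *within* bins — fragments never straddle
bin boundaries, so re-counting with the half-overlap rule recovers the
drawn counts exactly and generator correctness is separable from
counting-rule semantics.

piRNA reads (26 nt, stranded) are emitted at 80 reads per strand in
expressing cluster bins. Knockdown rules: under EzKD, E(z)-dependent and
both-dependent bins are divided by the knockdown fold (8) and the
anticorrelated class is multiplied by the gain fold (2); under kipfKD,
Kipferl-dependent and both-dependent bins are divided; under doubleKD both
rules apply cumulatively (a both-dependent bin loses 64-fold); under rhiKD
every dual-strand bin is divided. Unistrand bins emit one strand only and
ignore all conditions. Non-cluster bins emit a stable background of 15
reads per strand — this emulates the non-piRNA small-RNA content that
dominates real libraries and keeps cpm denominators comparable across
conditions; without it, the knockdown itself would shift all cpm values
through library composition alone. Effect-size distributions for the real
knockdowns are unknown; these defaults are free parameters of the toy
model, not estimates.

Peak files are noise-free by construction (intervals of truly
marked/occupied bins, identical across replicates, fold enrichment equal to
the configured fold), so the peak-level dependency split is expected to
match truth exactly; bin-level piRNA classification faces genuine sampling
noise. A small fraction (3%) of occupied non-cluster bins are flagged as
artifacts whose peaks persist in the Rhino knockdown, exercising the
exclusion rule.

Every random draw comes from a named substream of the master seed (one per
track, condition, replicate and output), so fixtures are byte-identical
across runs and adding a track cannot perturb existing ones. What passing
tests show: the estimators implement their definitions exactly (oracle
equivalence), and under the assumed generative model the pipeline recovers
the planted structure (≥ 95% of dependency labels; combined-mark AUC above
either single mark; odds ratios ordered both > K9-only > 1 > K27-only).
What they do not show: robustness to alignment artifacts, fragment-length
structure, GC or accessibility biases, replicate batch effects, or
cluster-boundary ambiguity in real chromatin data — none of which the
generator models.

## Problem sizes and numerics

The bundled cohort sizes (3 Mb genome, ~3,000 bins, ~10⁵ fragments per
track) were chosen so a full simulate-analyze-score cycle completes in
under a minute on one core while leaving every class populous enough for
stable recovery statistics. The fixture mappability read length is 25
(short reads on a toy genome; at this scale a random genome has essentially
no repeated 25-mers, so only the planted duplications reduce mappability).
SES scale factors are capped to [1e-3, 1e3]; degenerate inputs (all-zero
background, no nonzero levels, sequences shorter than the read length)
produce defined results with warnings rather than failures. Deterministic
tie-breaks: stable sorts everywhere, bin-id order for rank ties.

## Known limitations

The exact-match uniqueness definition is a surrogate for aligner-based
mappability (no mismatches, no quality). The dictionary fallback for read
lengths above 31 is memory-hungry on large genomes. Fisher p values are
exact but the odds ratio is the sample estimate, which is undefined without
correction for empty cells (hence Haldane). The delta-group responder means
are noisy in near-zero-change groups at fixture depth; only the planted
monotone relationship between strong H3K27me3 loss and reader loss is a
stable signal.
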