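# Methods

## The re-annotation model

The package models one linear chromosome and treats transcript predictions
as stranded closed intervals `[start, end]` (1-based, GFF3 convention;
BED-style inputs are converted at the I/O boundary). Strand is mandatory:
every rule in the cascade is strand-conditional, and a strandless record
has no meaning here.

The cascade assumes the upstream predictor errs in three specific,
direction-known ways: (i) boundary disagreement of a few nucleotides
between runs on different timepoints, (ii) fragmentation of long UTRs and
long ncRNAs into adjacent records separated by small gaps, and (iii) false
antisense calls inside duplicated regions, where a multi-mapping read must
be placed on one copy. Each cascade stage inverts one error mode:

1. **Overlap merge** (per list, per strand) — records sharing ≥ 1 position
   are unioned. Fixes (i). Abutting records (gap 0) are deliberately left
   to the gap rule so the two thresholds remain independent.
2. **UTR-priority pooling** — where an ncRNA call overlaps a same-strand
   UTR-extended gene span, the gene span wins: contained calls are dropped,
   partial overlaps trimmed to the remainder (one record per remaining
   contiguous segment). Trimming rather than wholesale deletion preserves
   genuinely distal ncRNA signal; gene records are never altered.
3. **Gap merge, ≤ 15 nt** — same-strand neighbours with
   `gap = start₂ − end₁ − 1 ≤ 15` are unioned to fixpoint. The gap is the
   count of intervening nucleotides, so "15 or fewer nucleotides apart" is
   read literally and abutting records (gap 0) merge. The merged record
   type is the common constituent type; a UTR constituent wins over mixed
   types (if both UTR kinds occur, the earliest constituent's kind is
   kept — the case does not arise from the supported predictors).
4. **Coverage collapse, ≤ 500 nt** — same-strand *ncRNA* neighbours with
   gap ≤ 500 are unioned iff every intervening position has strand-matched
   depth ≥ `min_depth` (default 1) in the per-base coverage track, applied
   to fixpoint. "Continuous signal" is formalized as a per-position floor
   because that is the weakest reading consistent with visual track
   inspection; the floor is configurable for noisier libraries. Only
   ncRNA-type records collapse — gene records grow only through the merge
   rules — and a non-ncRNA record sitting between two ncRNAs blocks their
   collapse rather than being swallowed.
5. **Repeat exclusion** — an ncRNA whose overlap with the union of
   supplied repeat intervals covers ≥ 50% of its length (configurable) is
   moved to an excluded partition, which is returned rather than discarded
   so the exclusions stay auditable. Repeats are supplied, not detected:
   identifying duplicated regions is a genome-structure problem outside
   this package.
6. **TU assembly** — cleaned spans must be disjoint per strand (violations
   raise, as they indicate a cascade bug). Each span owns the original
   annotated genes it fully contains on its own strand; member order is
   5′→3′; UTR lengths are the span's overhangs beyond the outermost member
   genes; gene-free spans become the candidate set for antisense
   classification. Genes contained in no span are reported as orphans. A
   TU with more than 25 genes triggers a warning (not an error) as a
   runaway-merge tripwire; observed operons sit well below that.

Cross-timepoint pooling order: each timepoint's two lists are
overlap-merged individually, the per-list tables are concatenated across
timepoints and overlap-merged again, and stages 2–6 run once on the pooled
result. The alternative (running the full cascade per timepoint, then
reconciling) is not order-deterministic; a single pooled cascade is.

All merge-family operations are idempotent and invariant to input
permutation; the test suite checks both over hundreds of random instances,
and checks every interval operation against per-position brute-force
oracles.

## Antisense classification

A candidate (gene-free transcript) is **asRNA I** iff it overlaps ≥ 1
annotated feature on the opposite strand, else **sRNA**. For asRNA I the
record carries each target with its overlap length, the containment
fraction (candidate positions covered by any target / candidate length,
computed on position sets), and target types: CDS where the overlap hits a
member gene's extent, UTR where it hits a unit's terminal overhangs,
within_operon for intercistronic positions, plus tRNA / pseudogene / ncRNA
targets; "mixed" is added when more than one kind is hit. An asRNA covering
< 90% of its length on its targets is flagged (a report flag, not a
filter; threshold configurable). A 1 nt overlap counts: no minimum is
biologically defensible without a read-level error model, so the smallest
literal reading is used and the threshold left configurable.

Class II/III detection operates on gene-bearing TU pairs of opposite
strand: the pair is divergent (II) when the span intersection contains both
5′ termini, convergent (III, the cutoRNA configuration) when it contains
both 3′ termini. A unit fully contained in an opposite-strand unit has both
of its termini in the intersection and is emitted as neither — containment
is class-I geometry, handled by the candidate classifier. Classes I and
II/III cannot overlap by construction: I applies to gene-free candidates,
II/III are relations between gene-bearing units. When three units mutually
overlap, every qualifying unordered pair is reported; no de-duplication
heuristic is applied.

## Expression analysis

Two size-factor rules, both scale-equivariant:

- **total-count**: `factor_s = mapped_total_s / min_s mapped_total_s`;
  dividing by the factor scales every sample to the least-covered one. Used
  for cross-strain ncRNA contrasts; mapped totals default to matrix column
  sums when chromosome-wide totals are not supplied.
- **median-of-ratios**: per-sample median of `count_fs / geomean_f` over
  features positive in every sample — the standard whole-transcriptome
  batch estimator. One test cross-checks it against an independent
  implementation.

Fold changes are `log2(μ_alt + pc) − log2(μ_ref + pc)` on normalized group
means with pseudocount 1 (configurable). The difference-of-logs form makes
group-swap antisymmetry exact in floating point. Group means over
biological duplicates, no outlier handling: with n = 2 there is no basis
for any. Regulation calls are explicitly threshold calls
(|log2FC| ≥ 1, optionally gated on externally computed adjusted p-values
≤ 0.05); negative-binomial testing with dispersion shrinkage is the job of
dedicated tools and is consumed, never reimplemented, so the package cannot
silently misrepresent a test it does not perform. Growth-course mode
contrasts each later timepoint against the 48 h reference and flags
features called up in at least one later timepoint.

## COG counting and codon usage

Enrichment counting is per-incidence: each (target, letter) occurrence adds
one count, so a dual-class target contributes twice and a class II/III pair
contributes both members' letters — two overlapping transcripts, counted
twice, even when the letters coincide. Unclassified targets are excluded.
Multi-letter assignment strings are split into the 26 standard single-letter
categories; unknown letters are a validation error. No significance test is
attached to the ratios — the proportions are the report; a two-proportion
z-test exists as a clearly labelled optional extension.

Codon usage counts frame-0 codons over CDS sets (length divisible by 3,
ACGT alphabet; ambiguous bases configurable skip-or-error), reporting
per-1000 frequencies and each codon's fraction within its synonymous
family under the bacterial code — the quantity on which rare-codon
regulation arguments rest.

## The synthetic-data generator

`generate_truth` lays out non-overlapping blocks along the chromosome, each
realizing one structure exactly: operons (mono/polycistronic TUs with UTR
overhangs), standalone sRNAs, asRNA-I blocks (a single-gene TU with an
opposite-strand ncRNA fully or partially inside, partial cases drawn to
straddle the 90% containment flag), divergent and convergent TU pairs
built directly from the terminal-overlap geometry, and repeat blocks (a TU
wrapped in a duplicated-region interval). Requested class counts are
realized exactly or generation fails with a packing error. The default
scenario — 200 kb, 40 operons of 1–4 genes (150–600 nt each), 10 sRNA, 15
asRNA I, 8 divergent and 25 convergent pairs, 4 repeats, intergenic gaps
100–600 nt — keeps convergent pairs the most numerous antisense class, the
signature of weak termination in GC-rich genomes, at a scale where the
whole pipeline runs in well under a second; the suite runs it across ten
seeds.

`fragment_predictions` applies the three error modes with defaults chosen
to exercise every cascade rule: each UTR and each ncRNA is split with
probability 0.3 (gaps 1–15 nt, drawn inside the true span so split gaps are
always covered positions), every repeat region spawns a false antisense
call per timepoint, and boundary jitter (default off) is truncated so
records never invert or leave the chromosome. Intergenic gaps are forced
above the 15 nt merge threshold — otherwise distinct elements would be
glued by design rather than by error. `emit_coverage` floors expressed
spans at depth 1 on their own strand (Poisson noise around the requested
depth) with strictly zero background, so coverage continuity holds exactly
inside true transcripts and fails exactly outside them. `emit_counts` draws
NegativeBinomial(mean = baseline × fold-change × library factor) with
variance = μ + αμ² (α = dispersion; α = 0 degenerates to Poisson) —
stated explicitly because "dispersion" is overloaded across tools.

What the generator does **not** emulate: boundary jitter in the default
scenario (the recovery property is exactness, which jitter precludes by
construction), read-level artifacts (no FASTQ, no mapping), sequence
content (no GC model — only interval structure), overlapping block
structures such as nested operons, expression-dependent prediction dropout,
and count outliers. Passing the recovery tests therefore shows the cascade
inverts the modelled error modes exactly; it does not bound performance on
real libraries, where boundary noise makes recovery approximate and the
thresholds trade precision against fragmentation.

## Numerical and degenerate-input choices

- Gap of overlapping records is negative; distance reporting clamps at 0.
- A feature alone on its strand has undefined nearest-neighbour distance
  (`None`), never infinity.
- Empty classes summarize as count 0 with `None` medians.
- Genome fraction counts positions transcribed on either strand once.
- Median-of-ratios refuses matrices with no feature positive everywhere
  and points to the total-count rule.
- All-zero samples are accepted with a logged warning (a failed library is
  data, not a crash).
- Every random draw flows from an explicit integer seed through numpy
  `SeedSequence`; identical seeds give byte-identical outputs.

## Problem sizes

Tests and the acceptance script use the 200 kb / ~125-TU scenario (ten
seeds), 100-instance oracle sweeps with ≤ 60 features per instance, and
1000-feature count matrices for fold-change recovery; the full suite runs
in a few seconds on one core. The cascade is O(n log n) in feature count
with O(L) coverage arrays, so megabase chromosomes with thousands of
features remain interactive.
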