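# Methods

This note documents the models, parameter choices and numerical decisions
behind `hornetdiet`, and what the validation on synthetic data does and does
not demonstrate about real gut-content sequencing runs.

## The analysis model

A larval gut sample is treated as a mixture of COI amplicons from unknown
prey taxa, observed through a noisy single-molecule sequencer. The pipeline
estimates, per sample, the set of prey taxa and their read counts; per nest,
it aggregates samples into the summary tables a diet study reports. No
statistical model is fitted — the chain is deterministic filtering,
alignment, voting and tabulation, which keeps every step auditable and
exactly reproducible for a given config and seed.

### Read QC

Primers are located by edit distance (substitutions + indels), each within a
window of 1.5× primer length at its read end, tolerating up to a 0.1 edit
fraction of the primer length — the tolerance a standard trimming tool
defaults to. Both orientations are tried; reverse-strand reads are flipped
into amplicon orientation. Reads in which only one primer is found are
rejected rather than one-side-trimmed: the amplicon design implies both
ends, and a read missing a primer at the tolerated edit distance most often
carries an error-dense end whose bases would degrade classification anyway.
At a 6.9% per-base error rate this rejects roughly 40% of reads; the loss
is composition-neutral because errors are independent of the source taxon.

Length bounds (550–750 nt) are applied to the trimmed insert and are
inclusive: only strict violations are removed. Applying the window after
trimming (rather than before) was an open choice; after-trimming is used
because the window describes the expected amplicon, not the
adapter/barcode-bearing raw read.

Per-read quality is −10·log₁₀(mean per-base error probability), not the
mean of Phred values. The two coincide only for uniform-quality reads; on
real Nanopore data the error-probability mean is the convention of platform
summary tooling, and it is what the Q10/Q7 platform thresholds are applied
to.

### Reference search

The aligner is an exact affine-gap Smith–Waterman (Gotoh recurrences). A
gap of length L costs open + L·extend (5 + 2L); transitions between the two
gap states are allowed, so any gap arrangement is priced consistently.
Scoring is blastn-like (+2/−3); raw scores map to bitscores through
(λS − ln K)/ln 2 with λ = 0.625, K = 0.41. Since every downstream filter
uses identity, coverage, or *relative* bitscore, any positive (λ, K) gives
identical classifications; the constants matter only for the absolute
numbers printed in hit tables. E-values are emitted for format
completeness from a fixed configurable effective search space; nothing
consumes them.

Two production shortcuts keep the search at desk scale, both with
correctness arguments:

* **Candidate prescreen.** A read is aligned against a reference only if
  they share an 11-mer and their infix edit distance is below 0.25 of the
  read length, and within 0.12 of the best reference's distance. Hits
  outside these bounds cannot pass the 85% identity filter (at near-full
  query coverage, which amplicon reads satisfy) or land near the top of
  the bitscore range.
* **Banding and the emit window.** The full-stats alignment runs in a band
  of half-width (edit distance + 32) around the diagonal located by the
  prescreen — wide enough that the optimal path cannot leave it in
  practice (verified against the full-matrix kernel on randomized pairs).
  A cheap score-only pass runs first for all candidates; full stats are
  computed and a hit emitted only when the raw score is within 10% of the
  read's best. The downstream bitscore window keeps only hits within 3%
  of the best *identity-passing* hit, so a 10% emit window leaves three
  -fold slack; hit tables therefore list the hits near the top of the
  score range rather than every positive-scoring alignment, as any
  practical search tool's output does.

The public `align_local` stays full-matrix exact and is the function the
DP-oracle validation exercises; the banded path is additionally checked
against the full kernel in the test suite.

### LCA assignment

Per read: identity ≥ 85%, alignment length ≥ 80% *of the trimmed read
length* (the reference varies in length; query coverage is the standard
guard against short spurious matches), then the inclusive 3% bitscore
window anchored on the best surviving hit, with one hit (the best) per
reference so multi-HSP references cannot vote twice. The vote ascends
species → genus → family → order → class → phylum → kingdom and stops at
the first rank where one label holds ≥ 75% of the filtered hits. Counting
hits (not distinct taxa) weights the vote by database representation,
which is the behaviour of standard metabarcoding LCA tools. Hits whose
lineage lacks the current rank abstain but remain in the denominator:
missing annotation must not manufacture agreement. The ascent does not
fall back to the root — a root label carries no dietary information, so
such reads are reported Unresolved. The 75% comparison uses an absolute
tolerance of 1e−9 so that exact fractions like 3/4 pass.

Host (*Vespa velutina*) reads are classified and reported like any other
taxon, flagged downstream; an option excludes the host from the
most-abundant-taxon call. Discarding host reads silently would hide a
quality signal (host contamination varies strongly between samples).

### Diet profiling

Thresholding: per sample, taxa with counts ≥ 1% of the sample's maximum
taxon count survive (inclusive at the boundary; the maximum itself always
survives, so a non-empty sample never empties). Unresolved reads are
excluded from the maximum — they are a noise tally, not a taxon.

Consolidation runs after thresholding, per sample by default (a nest-level
mode exists for sensitivity analysis): ascending the rank order, a taxon
whose surviving strict descendants in that sample comprise exactly one
taxon is merged into that descendant. Ascending order makes chains
(species ← genus ← family) collapse in one deterministic, order-independent
pass, and the operation is idempotent and count-conserving — both are
asserted in tests. With zero or ≥ 2 surviving descendants the higher rank
is kept as its own entry (e.g. a family split across two genera).

Relabelling moves counts from known database errors into named buckets
("uncultured bacterium"); totals are conserved and an unknown source taxid
is a configuration error rather than a silent no-op.

Nest summaries report *both* percentage conventions that appear in diet
tables — the mean of per-sample percentages and the pooled-read
percentage — because they answer different questions (typical gut
composition vs. nest-level read share) and legitimately differ; neither is
privileged.

## The simulator

The generator emulates: a tiered COI reference set (pairwise divergence
~3% within genera, ~10% within families, ~15% between families — typical
COI barcode-gap structure), realized by substitution along the generated
taxonomy with branch fractions of half the pairwise targets; per-larva
compositions from a symmetric Dirichlet (concentration 0.3, giving the
strong skew towards one or two dominant prey taxa that real nests show);
multinomial read counts at platform depth presets (5,827 reads/larva
Flongle-like, 18,000 MinION-like); and per-read errors as i.i.d.
substitutions/insertions/deletions summing to 6.9% by default (the MinION
regime; a Flongle-like run sits nearer 9.5%), split 4.1/1.4/1.4 among the
three classes. Quality strings are drawn per base from a Gamma
distribution (shape 4) around each read's realized error fraction, then
discretized to integer Phred — so mean-quality filtering averages over
genuine variation instead of seeing uniform strings. Reads are emitted on
a random strand.

Not emulated: homopolymer-conditioned errors (real Nanopore error is
context-dependent), chimeras, barcode cross-talk, reference sequences with
indel variation, multiple accessions per species, and taxonomically
mislabelled references. Consequently, passing the recovery study shows the
*analysis chain* is correct and well-calibrated under aggregate error
rates; it does not certify performance against context-dependent artefacts
or a curated-database's labelling errors, which the relabel step exists to
patch case by case.

## Problem sizes and numerics

The end-to-end validation study uses 1 nest × 10 larvae × 5,000 reads over
a 20-species reference at 6.9% error — large enough that every larva's
major prey (≥5%) should be recovered and small enough to run in minutes on
one CPU. Oracle sweeps use 1,000 random hit sets (classification) and 500
random pairs ≤ 60 nt (alignment), where exhaustive plain-Python dynamic
programming is affordable. Integer scores are exact; the only floating
comparisons (75% agreement, 1% threshold, 3% window) carry 1e−9 absolute
tolerances on the inclusive side. All randomness flows from a single seed
through numpy's seed-sequence spawning, so every artefact — FASTQ bytes
included — replays exactly.

## Known limitations

* The 85%/80%/3%/75%/1% constants are the analysis defaults, not fitted
  quantities; the config exposes them all.
* Hit tables list top-of-range hits (see the emit window above), not every
  positive-scoring alignment; a user widening the downstream bitscore
  window beyond ~10% should also widen `emit_window`.
* The candidate prescreen assumes near-full-length query alignments; for
  degraded references that only match a read fragment, raise
  `max_candidate_div` (up to 1.0 disables the bound).
* Unresolved reads are reported but never rescued; no probabilistic
  reassignment is attempted.
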