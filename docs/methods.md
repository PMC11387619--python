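# Methods

## Calling model

`strainvar` operates in a marker-gene frame: reads have already been binned
to one species and aligned against a database of known alleles of a set of
conserved single-copy genes (rMLST-style: tens of genes, length-conserved
alleles, headers encoding `gene_allele`). The pipeline is:

1. **Read filter.** Whole reads are kept when the arithmetic mean of their
   Phred scores is ≥ `min_q` (default 14). The mean is taken over the Phred
   integers, not in error-probability space — the simplest defensible reading
   of an "average read Q-score" — and no further trimming is applied beyond
   what the aligner soft-clipped.
2. **Top allele.** Per gene, the allele with the largest total aligned base
   count (match + mismatch columns over all its alignments) becomes the
   template; ties break to the lexicographically smallest allele id so runs
   are reproducible. Alignments to other alleles of the gene are projected
   onto the template positionally when the alleles have equal length and are
   dropped with a warning otherwise. This replaces a realignment step;
   marker-gene alleles are typically length-conserved, and the projection
   avoids embedding an aligner.
3. **Variant map.** Per template column, counts of A/C/G/T and of deletions.
   Positional depth is the sum of the four nucleotide counts only: deletions
   and N bases never count toward depth, and insertions are ignored.
   Deletion evidence is recorded but never emitted as a call — in conserved
   marker genes indels are overwhelmingly alignment-corrected sequencing
   errors, and the dominant long-read error mode (deletions at roughly twice
   the mismatch rate) would otherwise flood the call set.
4. **Candidates.** Every non-consensus base with count ≥ `min_count`
   (default 3) and abundance ≥ the entry gate. The gate is the literal
   product `MAF × cor` (configurable to the alternative reading
   `MAF − MAF × cor`; the two coincide at cor = 0.5). The count floor applies
   at extraction only; the loop afterwards works purely on abundances.
   The recorded reference base is the column consensus, which equals the
   template base except in the rare case where the majority strain itself
   differs from its database allele; this keeps the alt ≠ ref invariant and
   keeps call keys aligned with the truth frame.
5. **Evidence and convergence.** Candidates are annotated (novelty against
   same-length database alleles, proximity within 5 bp, density within 15 bp,
   read-level co-occurrence above MAF/2) and passed through the threshold
   loop described in the README. After each iteration the working values are
   escalated cumulatively by `cor ← cor + ii·cor₀` and `dp ← dp + ii·dp₀`
   (`cor₀`, `dp₀` the original values); the loop stops when
   two consecutive iterations retain the same count (an empty candidate set
   returns after one iteration), with a `max_iter = 100` safety valve that
   flags the result as unconverged instead of looping forever.

### Numerical and structural choices

* **Abundance space.** All thresholds are computed and compared as
  fractions of positional depth. The adjustment terms are all MAF-scaled, so
  keeping every quantity in relative-abundance space is the only
  dimensionally coherent arrangement; count-space thresholds would mix units.
* **Adjustment order.** Novelty, proximity, density, co-occurrence — fixed,
  because the proximity term is multiplicative and order therefore matters.
* **Monotone retention.** Dropped candidates never re-enter. Proximity,
  density and co-occurrence are recomputed over survivors each iteration
  (configurable to the initial-set variant), so removed noise stops
  penalizing nearby true variants. Retained counts are consequently
  non-increasing, which, bounded below by zero, guarantees termination.
* **Novelty is computed once** — database membership cannot change between
  iterations.
* **Co-occurrence** is restricted to candidate pairs within one gene (reads
  do not span genes in this frame) and normalized by the number of reads
  covering both positions; normalization by single-position depth is
  available as an option. Pairs with no shared coverage have frequency 0.
* **Thresholds are floored at 0** so an extreme reward cannot produce a
  negative threshold.
* **Parameter splines.** Each bundled model stores five knots per parameter
  (MAF 0.01–0.05). An interpolating cubic spline (smoothing 0) guarantees the
  stored knot values are served exactly. The spline is densified and refit —
  mirroring a store/reload cycle — over a grid of 500 evenly spaced points
  *with the knot MAFs retained in the grid*: on a plain even grid the refit
  interpolant misses the knot values by ~6e-9, while keeping the knots in the
  grid preserves them to machine precision and keeps the round-trip error
  below 1e-6 everywhere on the range. MAF outside the trained range is
  clipped to the nearest bound with a warning, never extrapolated (cubic
  extrapolation from five knots is wild); served values are floored at 0.

## Synthetic data

The simulator generates what the caller consumes, with known truth:

* **Database.** `make_synthetic_db` emits equal-length random genes
  (defaults: 53 genes × 900 bp × 4 alleles, mirroring the size and shape of a
  ribosomal marker scheme) with alleles derived by substituting
  `ceil(divergence × length)` positions (default divergence 1%, i.e. a few
  SNPs per allele pair — typical for conserved marker genes).
* **Mixtures.** Dual mixes draw the minority uniformly from 1–10% (majority
  90–99%); triple mixes draw both minorities from 1–10% (majority 80–98%).
  Default target depth is 220×, with 120× and 170× as the other standard
  design points.
* **Reads.** Each read covers a contiguous fragment of one gene, length
  uniform in [0.7, 1.0] × gene length; per-gene read count is
  `depth / 0.85` (the mean fraction), split across strains by a multinomial
  draw on the abundances. Alignments are emitted by construction with the
  true template and coordinates.
* **Errors.** Defaults: mismatch 1%, insertion 1%, deletion 2% per base —
  deletions at twice the mismatch/insertion rate, the characteristic
  long-read balance at a mean read accuracy around 96%. Optional
  `cluster_fraction` places that share of mismatch errors within 15 bp of a
  previously injected error on the same gene (a fresh burst seeds its own
  companion, so clustered errors always have a neighbour); optional
  `systematic_pairs` inject two co-occurring errors on the same reads at a
  joint rate, emulating contaminated-style data. Per-read mean quality is
  drawn at Q 18 ± 4 (per-base jitter ± 3, clipped to [2, 41]) so the default
  Q ≥ 14 filter removes a realistic tail; qualities are independent of the
  injected errors.
* **Truth.** The set of (gene, position, alt) where a minority strain's gene
  consensus differs from the majority strain's, in the majority frame; a
  triple mix takes the union of the two pairwise diffs.
  `TruthSet.restrict_to_map` gives the *recoverable* subset — truth variants
  whose realized pileup abundance and count clear the calling gates — which
  is the exact identity target for noise-free end-to-end checks: with
  multinomial read sampling, a 5% minority leaves every truth column a small
  binomial chance of falling under any fixed abundance gate, so exact recall
  of the full truth set is not a deterministic property at finite depth.

What the simulator does **not** model: signal-level or homopolymer error
structure, base-caller-specific error profiles, reference bias from a real
aligner, inter-gene read structure, or unequal-length alleles. Passing tests
therefore demonstrate the scoring logic and its implementation, not
performance on real nanopore data.

## Benchmarking and profiling

Calls are scored against truth on exact (gene, position, alt) identity —
near misses are a plain FP + FN, no partial credit. Precision, recall and F1
follow the standard definitions; zero-denominator cases are reported as 0
with an explicit `*_defined = False` flag rather than NaN so that averaging
over many samples is total. Profile percentages are rounded half-up to two
decimals (`decimal.Decimal`, not banker's rounding), and a call can
contribute to several categories at once.

## Trainer

Parameters are fitted per MAF by exhaustive grid search maximizing mean F1
over training mixes (ties: higher mean precision, then the lexicographically
smallest (np, pp, dp, ii, cor) combination), followed by four refinement
stages bracketing the running best at ±20%, ±15%, ±10% and ±5% (three points
per parameter; the bracket density is configurable). Because the previous
winner is always a member of the refined space, stage-best mean F1 is
non-decreasing by construction. Each per-sample candidate pool, co-occurrence
index and truth set is precomputed once with a zero entry gate (a superset of
every combination's candidates), so a combination evaluation is a cheap
filter-plus-convergence. Stages checkpoint to JSON and resume. Training uses
a single depth (220× by default).

The test and demonstration runs use reduced problem sizes — around a dozen
genes of 300–900 bp, two to three values per parameter, a handful of mixes —
chosen so the full suite completes in minutes on one core; the search logic
is identical at any scale.

## Known limitations

* Unequal-length alleles of a gene are dropped rather than realigned; a gene
  whose true template differs in length from every database allele will be
  mis-served.
* Deletions are never called, by design; a strain distinguished only by an
  indel is invisible.
* Co-occurrence requires overlapping reads; variants farther apart than a
  read length can never reward each other even when truly linked.
* The bundled parameter models were trained on nanopore-era error profiles;
  as base-calling improves the penalties are likely over-strong and should be
  refit with the trainer.
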