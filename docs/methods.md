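# Methods

## Marker design

A trigger fragment (uppercase A/C/G/T only; 1-based inclusive coordinates,
signed promoter coordinates with no position 0) is marked by substituting
every `spacing`-th base starting at `offset`. The base maps are fixed and
involutive — transitions A↔G, C↔T (`transition_guw`) or transversions A↔T,
G↔C (`transversion`) — so re-applying a design to its own output restores the
input, which the property tests exploit. `offset` must not exceed `spacing`
(otherwise the first interval would be unmarked) and defaults to
`spacing / 2` for even spacings, `spacing` for odd ones, placing the first
marker mid-interval where possible; both conventions used for spacing-20
designs (offset 10 or 20) remain expressible.

The mismatch guarantee is checked by brute-force enumeration of every
fully-internal window of each read length (fragments are locus-scale, so
O(n·L) enumeration is instantaneous and leaves no room for an off-by-one in
a closed form). For spacing *s* and read length *L* the count is at least
⌊*L*/*s*⌋ − 1, and at least 1 whenever *s* ≤ *L*.

Wobble annotation enumerates both pairings of a substitution: a sense sRNA
carries the substituted base (as RNA) against the complement of the
reference base; an antisense sRNA carries the complement of the substituted
base against the reference base. Whichever pair equals {G, U} is the wobble
polarity. Every transition has exactly one; transversions none.

Projection of the markers onto a full locus requires the fragment to occur
exactly once (either strand); multiple occurrences raise an error rather
than silently picking one, since a mis-projected variant reference corrupts
all downstream classification.

## Read tracing

Reads are compared in DNA space (U is normalised to T; reads with other
symbols are dropped and counted). The 3' adapter is removed at the leftmost
exact match of an adapter prefix of at least `min_overlap` (default 8) bases;
size selection keeps 21–24 nt, the DCL product range. Mapping is exhaustive
exact matching of the read and its reverse complement against locus-scale
references — every occurrence is reported, with minus-strand hits given the
plus-strand coordinate of their leftmost base. No mismatch-tolerant or
gapped alignment: a single mismatch is exactly what separates primary from
secondary reads, so only perfect matches are informative.

Classification follows from hits against the wild-type and variant
references (same length, differing only at marker positions): variant-only →
primary, wild-type-only → secondary, both → ambiguous (the read covers no
marker position), neither → unmapped. Reads with multiple hits contribute
1/n_hits per hit to counts and profiles so totals are conserved; unmapped
reads are tallied under strand ".". Profiles store non-negative per-strand
start and coverage counts; rendering minus-strand counts as negative values
is left to presentation.

Transitivity — the spread of target-derived amplification beyond the
targeted region — is the fraction of aligned bases of mapped non-primary
reads (secondary **and** ambiguous) lying outside the trigger window. The
ambiguous class is included deliberately: outside the window the two
references are identical, so any read there matches both and can never be
labelled "secondary", yet the trigger spans only the window and nothing
outside it can be trigger-derived. Restricting the score to strictly
secondary reads would force it to zero by construction.

## Methylation calling

Bisulfite converts unmethylated C to T while 5mC stays C, so each Sanger
clone of the converted amplicon reads out one molecule's methylation
pattern on the assayed strand (bisulfite PCR is strand-specific; the assayed
strand is an input, default +). Clones are globally aligned to the reference
with an asymmetric substitution matrix in which reference-C/clone-T scores
as a full match (expected chemistry, not an error), affine gaps (open −6,
extend −1) and free terminal gaps; clone orientation is auto-detected by
aligning both the clone and its reverse complement and keeping the higher
score. Clones whose bisulfite-aware matches cover less than 80% of the
reference (identity × coverage) are rejected and reported. Note that gap
placement next to runs involving T is inherently ambiguous under bisulfite
scoring; calls at such positions depend on the aligner's tie-break.

Contexts are assigned from the assayed strand with priority CG > CHG > CHH
(H ∈ {A, C, T}); terminal cytosines lacking two downstream bases are
excluded unless flanking sequence is supplied. Per-site calls are C →
methylated, T → unmethylated, anything else (including gaps) → missing.
Summaries report m, n (missing excluded), the proportion and its Wilson 95%
score interval per context and in total; a context with no informative calls
is reported as absent (NaN), never as 0. An optional conversion-efficiency
filter (reject clones with more than N unconverted CHH calls) is available
but off by default. Sample comparisons use an equal-variance two-sample
t-test on replicate-level proportions (at least two biological replicates
per group).

The Wilson interval is computed in closed form with the normal quantile
taken from scipy (so any confidence level works); at m = 0 and m = n the
boundary endpoints are returned exactly. The test suite checks the bounds
against an independently coded formula and against statsmodels to 1e-9.

## Synthetic data

The generators are pure functions of (seed, config) via
`numpy.random.default_rng`, with byte-identical output across runs and
ground-truth labels embedded in read and clone identifiers.

* **Locus fixture**: uniform-composition random sequence with designated
  promoter and CDS windows of 120 nt (the trigger size used throughout);
  defaults of 800 nt promoter + 720 nt CDS give a locus-scale reference with
  room on both sides of each window for transitive reads. Real sequences may
  be substituted via FASTA at any entry point.
* **Primary reads**: exact substrings of the marked trigger embedded in its
  carrier, drawn from within the trigger window — the trigger is the only
  marker-bearing source. Lengths follow a 21/22-nt-heavy distribution over
  21–24 nt (weights 0.4/0.3/0.1/0.2) as in DCL4/DCL2-dominated viral sRNA
  populations; strands are Bernoulli (default 0.5); start positions follow a
  lumpy mixture-of-peaks profile over a uniform floor, emulating the uneven
  positional abundance of viral sRNAs. An adapter can be appended to
  exercise trimming.
* **Secondary reads**: exact substrings of the wild-type locus; a fraction
  `transitivity_fraction` is drawn entirely outside the trigger window
  (regions chosen proportional to their length), the rest entirely inside,
  so base-level and read-level transitivity coincide by construction.
* **Bisulfite clones**: per clone, each contexted C is methylated with its
  context probability (defaults 0.8/0.6/0.3 for CG/CHG/CHH — a
  symmetric-heavy pattern typical of RdDM-silenced promoters) and stays C;
  unmethylated Cs convert to T except with probability
  `conversion_failure_rate` (default 0.01). Incomplete conversion therefore
  inflates apparent methylation by ≈ f(1 − p), which the tests assert; the
  generator has no sequencing-error or chimera model.

What passing tests show — and do not. The simulations contain no sequencing
errors, no multi-locus backgrounds beyond the single carrier/locus pair, and
no biological variation in sRNA processing; perfect classification accuracy
on them demonstrates the correctness of the classification logic under the
marker guarantee, not expected accuracy on real libraries, where sequencing
errors convert a small fraction of reads between classes or to unmapped.
Likewise the Wilson-coverage calibration treats every clone as independent;
real clone sets can contain PCR duplicates, which narrow apparent intervals.

## Problem sizes

The shipped tests and the acceptance script use 10 000 reads for tracing and
transitivity runs and 100 replicates of 50 clones on a 240-nt amplicon for
methylation calibration — sizes at which binomial error is well below the
asserted tolerances (±0.05 on transitivity; ≥90% Wilson coverage) while a
full run stays interactive.

## Known limitations

* Exact matching only: no quality-aware or mismatch-tolerant rescue of reads
  with sequencing errors; error-bearing primary reads become unmapped (or,
  rarely, flip class).
* References are locus-scale; there is no genome-scale index.
* The bisulfite aligner's gap placement near T-runs is tie-broken by the
  underlying dynamic program, not by biological priors.
* The marker base maps are a fixed convention; published designs built with
  other per-position choices are accepted as input but not reconstructed.
* Phenotype support tallies user-provided labels or leaf counts; there is no
  image-based scoring.
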