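# Methods

This note records what the package computes, the choices made where the
underlying conventions are loose, and what the synthetic world does and
does not establish.

## Sequence identity, one definition everywhere

Nucleotide identity is matches / compared_sites from a global alignment
with free terminal gaps (match +5, mismatch −4, gap open −10, extend
−0.5), where compared_sites counts only columns ungapped and unambiguous
(A/C/G/T) on both sides. Tools in this space ship several identity
dialects (alignment-length identity, shorter-sequence identity, BLAST
identity); one definition is declared and used for 16S identity, ANI
fragments, and clustering alike so thresholds mean the same thing in
every module. Ambiguous bases are excluded from the comparison rather
than counted as mismatches, so sequencing ambiguity is not penalized.

Protein comparisons use local Smith–Waterman alignment (BLOSUM62,
−11/−1) with BLAST-style approximate E-values from the Karlin–Altschul
parameters for gapped BLOSUM62 (λ = 0.267, K = 0.041, E = K·m·n·e^(−λS)).
Protein identity is matches / alignment length with gap columns counted
in the length.

## Kimura 2-parameter distance

d = −½·ln((1 − 2P − Q)·√(1 − 2Q)) with P and Q the transition and
transversion fractions over compared sites. Gap and ambiguous columns
are dropped pairwise (pairwise deletion); the external programs usually
used for this step do not document their deletion mode, so the choice is
made explicit here. Saturation (log argument ≤ 0) raises a dedicated
error; callers that need a "very distant" semantic (cross-collection
overlap) catch it and treat the pair as unambiguously beyond threshold,
with a warning.

## Fragment-based ANI and the dDDH estimate

Both genomes are cut into consecutive, non-overlapping 1,020-bp windows
per contig (trailing remainder discarded). Fragments are matched across
genomes by 13-mer seeding: shared seeds vote for a (fragment, diagonal)
pair; when ≥ 80% of a candidate's seeds agree on one diagonal the pair
is scored by ungapped comparison on that diagonal, otherwise (indels) a
full gapped alignment is used. Only reciprocal best pairs with alignment
coverage ≥ 70% of the fragment are retained; ANI is the mean identity
over retained pairs, and an empty retained set is an undefined result,
not an ANI of 0. Ties between equal-identity candidates resolve to the
lowest subject coordinate. The seed word size bounds the method's
validity: at 80% identity about 5% of 13-mers survive (~35 seeds per
fragment), which is why the generator refuses targets at or below 50%.

The dDDH estimate pools all retained fragment alignments into a single
distance d = 1 − Σmatches/Σaligned_sites and maps it through
ddh = 100/(1 + exp(a + b·d)). The default coefficients (a = −7,
b = 137) are a calibration, not a published regression: they place the
70% dDDH species boundary at d ≈ 0.045, i.e. alongside the 95–96% ANI
species boundary, give ~99.9% for identical genomes, and decay to ~0 by
d = 0.1. The value is an estimate for ranking and thresholding on
well-separated pairs; it is not numerically interchangeable with GGDC
output, and tests assert only monotonicity, symmetry and separation
around 70%.

## POCP

A protein is conserved when some protein of the other proteome hits it
with E < 1e-5, identity > 40%, and an alignable region > 50% of the
query length — the standard hit criteria of the conserved-proteins
method; POCP = 100·(C1+C2)/(T1+T2). The hit criteria live in keyword
arguments, not constants, because published analyses occasionally vary
them.

## MinHash (Mash) distance

Sketches keep the s = 1,000 smallest 64-bit hashes (BLAKE2b, 8-byte
digest) of canonical 21-mers — defaults of the reference tool. The
Jaccard index is estimated over the merged bottom sketch and
d = −(1/k)·ln(2j/(1+j)); j = 0 returns the sentinel 1.0. Reference
matching reports all references at d < 0.05 (strict), ascending; an
empty result is meaningful (a candidate taxon "dark" to the reference
set).

## Rank delineation

All comparisons are strict as printed (<, >), and the ANI phenotype
window is closed on both ends ([95, 96]). Two deliberate decisions:

* The 98.7% boundary is contradictory in the source conventions (the
  assignment rule says ≤ 98.7% is a novelty candidate; the species
  clause says < 98.7%). A record at exactly 0.987 that satisfies no
  rank is returned as `ambiguous` rather than silently resolved either
  way.
* The numbered species clauses must hold simultaneously for every
  novelty rank, including the ANI-window exception path — the exception
  replaces only the ANI clause, never the dDDH or 16S clauses.

Phenotype distinctness and clade topology are boolean inputs; the
package does not compute them (BIOLOG/microscopy/tree building are out
of scope), which keeps the rule engine total, auditable and testable.
Missing evidence raises, never defaults.

## Prevalence statistics

Per study: FO = 100 × (samples with RA > floor)/n, with the presence
floor defaulting to 0 (any nonzero abundance counts as detection — the
source conventions state no floor); mean RA includes absent samples in
the denominator, because FO and RA are reported as separate statistics.
Equally-weighted averages are unweighted means of per-study means, so a
600-sample study counts exactly as much as a 60-sample one; a regression
test pins the fact that duplicating samples within a study changes
nothing while merging studies does. Dominant means ew RA > 0.1% and
common means ew FO > 30%, both strict. QC drops samples with < 10,000
reads (a sample with exactly 10,000 stays). Accumulation curves average
cumulative union richness over seeded random study orderings; the
endpoint equals union richness for every permutation by construction.

## Collection overlap

Within-collection dereplication keeps sequences ≥ 1 kb and clusters at
98.7%. Across collections, representatives are joined when their K2P
distance is < 0.013 (strict), and taxa are the connected components of
that graph — single linkage. The source conventions do not say how
non-transitive triples (a–b and b–c close, a–c not) were resolved;
single linkage is declared and a test encodes the resulting chain
behavior explicitly.

## Gene catalogs

Catalog building is greedy incremental clustering in decreasing length
order: a sequence joins the first representative at ≥ 95% identity with
the alignment covering ≥ 90% of the shorter sequence. The word-index
heuristics of the usual clustering tool are not replicated; the declared
greedy semantics are the contract and are validated against brute-force
all-pairs alignment on small fixtures. Coverage of a subject catalog
counts subject entries hit at ≥ the identity cutoff with the alignment
spanning ≥ 70% of the query; whether published coverage denominators
count ortholog groups or gene entries is ambiguous in the conventions
this follows, so the module computes over subject entries (annotation
grouping can be layered on via `partition_by_annotation`).

## The synthetic world

Generators state divergence exactly: substitutions are sampled without
replacement, so a 100-kb pair at target ANI 0.95 has exactly 5,000
substituted sites and parameter-recovery tests can use tight tolerances
(±1 ANI point; ±2 when indels are enabled, since indels break the
no-gap assumption of the fast diagonal path). 16S pairs work the same
way at gene scale. Proteome pairs plant an exact number of conserved
homologs above the POCP hit criteria (designs at ≤ 40% conserved
identity are rejected because their truth value would be undefined).
OTU tables draw per-sample presence from per-study Bernoulli
probabilities and lognormal abundances (μ = 0, σ = 1.5) normalized per
sample — a generic heavy-tailed stand-in, not a claim about any real
survey's abundance law. A sample in which no pooled taxon was drawn
stays all-zero (its reads belong outside the pool), so row sums are 1
or 0; per-study expected FO equals the design's presence probability.

What a green test establishes: the metrics recover designed divergence,
the rules fire at their printed boundaries, and the statistics match
closed forms. What it does not: realistic gene content, codon usage,
rRNA secondary structure, compositional bias, chimeras or sequencing
error — none are modeled, so performance on real assemblies should be
validated against the usual reference tools before production use.

## Numerical and degenerate-input choices

* Identity/K2P on zero comparable sites raises rather than returning 0.
* `orthoani` on genomes shorter than two fragments raises; no
  reciprocal pairs raises an undefined-result error distinct from 0.
* Greedy clustering pins processing order (length desc, then input
  order) to make centroid choice deterministic; an empty input yields
  an empty cluster set.
* All stochastic routines take explicit integer seeds and are
  bit-reproducible; permutation curves report ddof = 0 standard
  deviations.
* G+C is reported rounded to 2 decimals (the convention in protologs);
  all other metrics are returned at full precision.

## Known limitations

* The fragment aligner is seed-based: pairs below ~55% identity fall
  outside its validity (and outside the generator's allowed range).
* The dDDH logistic is a calibrated estimate (see above).
* E-values use Karlin–Altschul parameters without edge-effect or
  composition corrections; fine at the 1e-5 cutoff on designed
  homologs, not a BLAST replacement for borderline hits.
* POCP and catalog coverage are all-pairs scans, sized for desk-scale
  proteomes (hundreds of sequences), not for hundred-thousand-entry
  catalogs.
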