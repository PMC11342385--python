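# Methods

## The evaluation

The question the pipeline answers is operational: *if a query sequence were
compared against this reference library, which species could it be assigned
to unambiguously?* Two signals are combined, mirroring standard practice in
barcode-gap audits of reference libraries.

**Tree placement.** A neighbour-joining tree is built over all sequences
(identical sequences are kept as separate leaves, joined by zero-length
branches). For each species with at least two sequences we count its *pure
clusters*: the maximal clades — either side of any edge, so the count is
independent of rooting — containing only that species' leaves. Because
pure sides containing a given leaf are nested, the maximal pure clades
always partition the species' leaves; the count `k` is well defined. Two
refinements make the published category definitions deterministic rather
than a matter of visual OTU judgement:

* leaves within `identity_epsilon` (default 0, i.e. identical haplotypes)
  of one another count as one cluster even when tie-breaking scattered them
  in the tree;
* *sharing* is defined on the distance matrix: a species shares a cluster
  with another iff some heterospecific sequence lies within
  `identity_epsilon` of one of its sequences.

The four categories follow: Match (`k = 1`, not shared), Split (`k ≥ 2`,
not shared), Merge (`k = 1`, shared), Mixture (`k ≥ 2`, shared). Split,
Merge and Mixture are failures — a query could not be assigned uniquely.

**Distance thresholding.** Tree placement says nothing about a species
represented by a single sequence. Such species fail only when another
species carries an identical sequence (the single-specimen equivalent of
Merge). Otherwise they — and every non-failing species — are judged by the
minimum distance from any of their sequences to any heterospecific
sequence: strictly greater than the caution threshold (default 0.01
substitutions/site, uncorrected p) is a success; anything in (0, 0.01]
(inclusive at the boundary) is a *caution*: diagnosable in the present
library, but too close to its nearest relative for confident
identification. The 0.01 default reflects the empirical upper bound of
within-species variation in densely sampled fish 12S libraries, where most
multi-sequence species show maximum conspecific distances below 0.01.

## Distances

Distances are computed per pair from a global affine-gap alignment
(Needleman–Wunsch via Bio.Align.PairwiseAligner; match +2, mismatch −1, gap
open 5, gap extend 2, end gaps penalised). Columns containing a gap or a
non-ACGT symbol are excluded pair by pair (pairwise deletion — the common
default for these estimators); base frequencies for the TN93 correction are
pooled over both sequences' included sites. Raw integer mismatch counts are
carried alongside the proportions and are authoritative whenever a result
is reported "in bp". The TN93 distance is flagged undefined (NaN) when a
logarithm argument is non-positive (saturation); matrix consumers must
either reject such entries (tree building refuses non-finite input) or fall
back to the p-distance, which the pipeline does with a logged warning. A
zero pooled base frequency is treated as an error rather than a sentinel —
it indicates an input too short or too degenerate for the correction.

For inputs that are already positionally homologous (a multiple alignment,
or simulated sequences without indels) a vectorised counting path computes
the same quantities without per-pair alignment; the two paths are checked
against each other in the tests.

A small progressive multiple aligner (p-distance NJ guide tree,
profile–profile alignment under the same affine scheme, deterministic
tie-breaking) exists solely to give bootstrap resampling a column structure
when the input is unaligned. It is quadratic-time per merge and intended
for the ~200 nt subregion; it is not a general-purpose MSA tool.

## Neighbour joining and bootstrap

Classic Saitou–Nei agglomeration on the full distance matrix. Ties in the
Q-criterion are broken by the lexicographically smallest label pair
(carrying each cluster's smallest member label), making runs reproducible
regardless of input order; the Q matrix is computed with grouped arithmetic
so it is exactly symmetric in floating point. Negative branch lengths —
finite-sample artifacts — are clamped to zero with the deficit moved to the
sibling branch, preserving the path length through the joined node (the
classification logic consumes clades, not signed lengths). Bootstrap
support resamples alignment columns with replacement under a seeded
generator, rebuilds the tree per replicate, and annotates each internal
edge of the (unresampled) reference tree with the percentage of replicates
containing the same bipartition; replicates whose resampled matrix is
undefined are dropped, and more than 10% dropped aborts the run.

## Region excision

The hypervariable window is excised by locating the forward primer and the
reverse-complemented reverse primer on the sense strand with an ungapped
IUPAC-aware scan (degenerate symbols match any base in their set; default
budget 3 mismatches per ~20-mer, never more than a quarter of the primer
length). The primers themselves are excluded from the insert, consistent
with reported insert lengths for the fish 12S metabarcoding window
(166–199 nt, mean ≈ 172). When a deposited fragment lacks the primer
sites, an alignment-anchored fallback trims to the extent of a trusted
insert exemplar (semi-global alignment, ≥ 80% identity-coverage of the
anchor required).

## The simulator

The generator produces libraries with the statistical structure the
evaluation assumes, plus per-species ground truth:

* **Species tree.** Pure-birth (Yule), made ultrametric, rescaled so the
  mean leaf-pair path equals twice `interspecific_depth` (default 0.05
  substitutions/site). By default split times have no floor, so
  near-identical species pairs occur — exactly the situation in recently
  radiated reef fishes, where congeneric p-distances range from 0 to ~0.25.
  Scenarios that assume all species are diagnosable set
  `min_species_depth`, which pushes the most recent splits back so every
  pair is separated by at least twice that value. Species names are
  generated binomials assigned in genus blocks along the leaf order, so
  per-genus summaries are exercised.
* **Sequences.** The root sequence (default 750 nt) carries a planted
  hypervariable core (length drawn 166–199 nt) flanked by exact primer
  sequences. Evolution along each branch is TN93 with frequencies
  (A, C, G, T) = (0.32, 0.26, 0.19, 0.23), purine/pyrimidine transition
  factors 4 and 8 and transversion factor 1, normalised to one substitution
  per site per unit branch length; the core evolves 3× faster and the
  primer sites 10× slower (conserved flanks). These rate classes mean the
  realised mean rate across the sequence is ≈ 1.5× the nominal branch
  length; all regime statements below are about realised distances.
* **Individuals.** Each species receives a uniform 1–5 individuals, each
  hanging off the species tip by *half* of `intraspecific_depth` — so
  `intraspecific_depth` (default 0.002) is the expected pairwise divergence
  between conspecifics, which puts the conspecific mean at ~2–3
  substitutions per 750 nt and keeps the maximum conspecific distance below
  0.01 for well over 80% of multi-sequence species, the regime observed in
  real 12S libraries. A star genealogy per species is deliberate: the
  evaluation consumes distances and clades, not within-species coalescent
  shape.
* **Indels** occur at `indel_rate` events per site per unit branch length
  (default 0.01, i.e. roughly one indel per hundred substitutions), lengths
  1–6, never inside the primer sites, and the true core interval is tracked
  through every event. Simulated length variation (a few nt) is narrower
  than in real deposits, whose boundaries also differ for non-biological
  reasons.
* **Planted events.** *Full introgression* copies one donor haplotype
  verbatim over every sequence of the recipient — the recipient then
  carries only donor mtDNA and is expected Merge; *partial* introgression
  copies it over a subset (expected Mixture). An *identical injection*
  copies one haplotype across a species pair. Copies are verbatim because
  the Merge/Mixture definitions hinge on shared identity at
  `identity_epsilon = 0`; re-evolved donor draws at realistic sequence
  lengths would essentially never be exactly identical, and recent
  mitochondrial sweeps do leave shared haplotypes. Donors and injection
  partners are expected failures; the exact Merge/Mixture label of a donor
  depends on tree arrangement and is left open in the truth table.

All randomness flows from a single seed through one generator; identical
configurations give byte-identical FASTA, metadata, truth tables and trees.

## What the synthetic tests do and do not show

Passing the recovery tests shows the pipeline correctly measures distances
under the model the TN93 estimator assumes, reconstructs additive trees
exactly, and reproduces planted discriminability structure (including
introgression signatures) with high reliability. It does not certify
behaviour on real libraries, where alignment ambiguity in rRNA loops,
sequencing and labelling errors, pseudogene contamination and non-TN93 rate
variation all add noise; the curation screen (which flags sequences whose
nearest conspecific is suspiciously far, default > 0.05, or whose nearest
neighbour is another genus) exists precisely because real deposits need
human review before the evaluation is trusted. Exclusion is always a
curator's decision; the screen never removes sequences.

## Numerical and design choices

* Pairwise vs complete deletion: pairwise throughout (per-pair exclusion);
  this follows the common default and keeps single-pair operations
  independent of the rest of the library.
* Boundary at the threshold: success requires nearest-heterospecific
  distance strictly greater than the threshold; exactly 0.01 is a caution.
* Percentages are reported to one decimal.
* The alignment scoring (2/−1/5/2) favours substitution over gapping at
  these divergences; the exhaustive-search oracle in the tests pins the
  implementation to the declared scheme.
* Problem sizes: the shipped analysis uses a 60-species library (~190
  sequences), 100 bootstrap replicates on the subregion, 200 replicates per
  divergence for estimator bias, and 20 seeds for category recovery —
  sizes chosen so the full analysis reruns in minutes on one core while
  keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* No coalescent within species, no rate autocorrelation, no selection.
* The progressive aligner is not profile-HMM quality; distance computation
  deliberately does not depend on it.
* TN93 without gamma rate heterogeneity (by design — the evaluation it
  reimplements uses the plain distance).
* The inner metabarcoding primer sequences are configuration: the package
  plants synthetic primers in simulations and accepts user-supplied pairs
  for real data (the outer 12S amplicon primers L709/H1552 are provided as
  constants).
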