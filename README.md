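# barcode-eval

Can a ~170 bp hypervariable window of the mitochondrial 12S rRNA gene — the
short amplicon used for fish eDNA metabarcoding — discriminate species as
reliably as the ~750 bp first half of the gene it sits in? This package
implements the reference-library evaluation that answers that question for a
given collection of 12S sequences, and ships a sequence simulator so the
entire analysis runs, and is tested, without any downloads.

It is aimed at people curating DNA-barcoding reference libraries for
recently radiated fish groups (where interspecific divergence can be tiny
and mitochondrial introgression is a live concern), and at anyone who wants
a transparent, scriptable reimplementation of the classic tree-plus-distance
barcoding audit.

## What it computes

For a library of sequences with species labels:

* **Distances.** Pairwise global alignments (Needleman–Wunsch, affine gaps)
  feed site-pattern counts under pairwise deletion; from these the
  uncorrected p-distance `p = P1 + P2 + Q` and the Tamura–Nei (TN93)
  distance

  `d = −k1 ln(1 − P1/k1 − Q/2gR) − k2 ln(1 − P2/k2 − Q/2gY) − c3 ln(1 − Q/2gRgY)`

  with `k1 = 2gAgG/gR`, `k2 = 2gTgC/gY`, `c3 = 2(gRgY − gAgGgY/gR − gTgCgR/gY)`,
  where `P1`, `P2`, `Q` are the purine-transition, pyrimidine-transition and
  transversion proportions and `gA..gT` base frequencies pooled over the
  compared sites.
* **Trees.** Saitou–Nei neighbour-joining with deterministic tie-breaking,
  plus nonparametric bootstrap over alignment columns (support = percentage
  of replicates containing each bipartition of the reference tree).
* **Species categories.** Every species with ≥ 2 sequences is scored
  **Match** (one exclusive cluster — barcoding works), **Split** (several
  exclusive clusters), **Merge** (one cluster shared with another species)
  or **Mixture** (several clusters, at least one shared); Split, Merge and
  Mixture are failures. A single-sequence species fails only when another
  species carries an identical sequence, and is otherwise judged by its
  nearest-heterospecific distance with a **0.01 substitutions/site caution
  threshold** (≤ 0.01 ⇒ "caution"). The headline number is the percentage
  of species with unique (diagnosable) sequences.
* **Region excision.** Degenerate-primer matching cuts the hypervariable
  window out of longer sequences in silico (with an alignment-anchored
  fallback), so the same specimens can be evaluated at both lengths and the
  two runs diffed species by species.
* **Simulation.** A pure-birth species tree, TN93 sequence evolution with a
  rate-multiplied hypervariable window and conserved primer flanks, per-species
  individual sampling, indels, and planted events (full/partial mitochondrial
  introgression, cross-species identical haplotypes) with per-species ground
  truth.

## Worked example

```
$ barcode-eval simulate --n-species 12 --seed 4 --indel-rate 0 --out demo/lib
wrote 33 sequences for 12 species to demo/lib

$ barcode-eval run --fasta demo/lib/library.fasta --aligned --out demo/run
{
  "n_seqs": 33,
  "n_species": 12,
  "species_with_multiple": 9,
  "category_counts": {"Match": 9, "Split": 0, "Merge": 0, "Mixture": 0, "NA_single": 3},
  "n_single_merge": 0,
  "n_caution": 0,
  "n_failures": 0,
  "pct_unique": 100.0,
  "conspecific_mean_subst": 2.29,
  ...
}
```

Reading: all 9 multi-sequence species form exclusive clusters (Match), none
of the 3 singletons shares a haplotype or sits within 0.01 of another
species, so 100% of species are diagnosable; conspecific sequences differ by
2.3 substitutions on average. `demo/run/` also receives the distance matrix
(PHYLIP + long TSV), the NJ tree (newick), per-species assessments (TSV) and
a grouped caution report.

The `analysis/` directory holds the numbered drivers for the full study on a
regime-faithful 60-species library (simulate → excise subregion → distances
and trees → classify → compare regions); each writes its tables under
`results/` and prints what it found. On that library the longer region
leaves 85.0% of species uniquely identifiable against 76.7% for the
subregion alone — the same direction and magnitude of loss the evaluation is
designed to expose — while a handful of near-threshold species actually
*gain* diagnosability in the subregion because divergence concentrates in
the hypervariable window.

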