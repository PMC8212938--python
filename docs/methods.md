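# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `familymap`.  It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Domain model

A family member is defined structurally: a WRKY domain is an occurrence of an
allowed heptapeptide followed, within `max_zf_gap` residues, by a zinc-finger
motif.

* **Allowed heptapeptides.** Default `{WRKYGQK, WRKYGKK, WRKYGEK}`; a strict
  mode restricts to the canonical WRKYGQK.  The two variants are widespread
  in real plant families and would otherwise be silently dropped; the
  synthetic generator plants WRKYGQK only, so both modes behave identically
  on generated data.
* **Zinc-finger patterns.** C2H2 is matched as `C-x(4,5)-C-x(22,23)-H-x-H`
  and C2HC as `C-x(7)-C-x(23)-H-x-C`.  The spacer ranges are fixed here
  because the common structural descriptions leave them implicit.  When both
  patterns match downstream of a heptapeptide, the one whose first cysteine
  is nearer wins; exact ties go to C2H2.
* **`max_zf_gap` = 60 residues** between heptapeptide end and the first
  cysteine, matching the canonical ~60-residue domain span.
* The scanner is a deterministic surrogate for profile-HMM searching: it
  trades sensitivity to degenerate domains for exact reproducibility.  It
  performs no E-value computation.

Classification follows the standard structural rule: ≥2 domains ⇒ group I;
one domain with C2H2 ⇒ group II; one domain with C2HC ⇒ group III.  When
domains disagree on finger type the C-terminal domain decides (group I
proteins are classified by their C-terminal domain).  A single domain with
no detectable finger stays in the family as group II with the missing finger
flagged, rather than being dropped: the scan already admitted the protein.
Subgroups IIa–IIe are assigned by minimum patristic distance to labelled
reference leaves, a deterministic, testable stand-in for visual clade
assignment; ties break alphabetically.

## Alignment and distances

* **Pairwise alignment** is global Needleman–Wunsch with affine gaps (Gotoh
  recurrences).  A gap run of length L costs `gap_open + (L−1)·gap_extend`;
  adjacent runs in opposite sequences each pay their own opening.  Defaults
  BLOSUM62, −10/−1 — conventional protein-alignment settings, exposed in the
  config.  Traceback tie-breaks prefer diagonal, then up, then left, so
  alignments are unique and reproducible.
* **Multiple alignment** is progressive: a UPGMA guide tree on 3-mer cosine
  distances, then profile–profile alignment scored by mean-of-pairs (column
  frequency vectors through the substitution matrix; gap symbols carry zero
  mass).  Column count never falls below the longest input; degapping any
  row returns its input sequence exactly.
* **Distances.** Default p-distance (mismatches over compared columns,
  pairwise deletion of gapped columns); Poisson correction `−ln(1−p)` by
  config.  A sequence pair with no comparable columns is an error naming the
  pair, not a silent zero.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration on the Q criterion.  Numerical choices:

* Ties in Q (within a relative tolerance of 1e-9, which also absorbs
  float-ordering noise between vectorized and scalar evaluation) are broken
  by the smallest (i, j) index pair in the current matrix; the merged node
  is appended at the end.  The per-step choice is verified in the tests
  against an exhaustive-scan oracle.
* Negative branch-length estimates are clamped to zero with the deficit
  transferred to the sister branch, preserving the pair's summed length; the
  final trifurcation lengths are clamped at zero.
* The result carries a trifurcating root (the tree is unrooted).
* Bootstrap supports resample alignment columns with replacement; the
  support of an internal edge is the percentage of replicate trees containing
  the same leaf bipartition (canonicalized on the side excluding the
  alphabetically first leaf).  One integer seed drives all replicates.
  Default 100 replicates at desk scale; 1000 mirrors common practice and is
  a config switch.  The full pipeline runs with bootstrap off by default
  (supports do not affect grouping).

## Homeolog grouping and nomenclature

A clade qualifies as a gene iff all its leaves share one non-null chromosome
complement and no subgenome repeats — hence at most three leaves, one per
subgenome.  Because the NJ tree is unrooted, candidate clades are taken as
*edge sides*: each subtree leaf set and its complement.  This matters in
practice: the arbitrary trifurcating root occasionally lands inside a triad,
which a purely rooted traversal would wrongly split.  Maximal qualifying
clades are claimed greedily (larger first, deterministic tie order); every
remaining leaf becomes a singleton.  Copies without a complement (unplaced
scaffolds) are kept in the catalog as singletons but excluded from the
naming order — the annotation source does not dictate a placement, so none
is invented.

Cross-complement clades are always split.  The nomenclature is
complement-based, so a translocated copy would make a gene's name ambiguous;
keeping groups within one complement keeps naming well-defined.

Naming: serials run 1..G across complements 1→7.  Within a complement the
reference subgenome is the one carrying the most family copies (ties
A > B > D); groups with a copy on it are ordered by that copy's start
coordinate, the rest follow ordered by (highest-priority subgenome, start).
This is one consistent reading of the
"physical location and number of copies" convention for wheat gene families;
type-level statistics are invariant to the within-complement order,
individual serials are not.  Unplaced groups are numbered last by gene id.

Percentages round half-up to two decimals (so 75/124 → 60.48); copy-ratio
comparisons against other species' family sizes round likewise.

## Expression utilities

`2^(−ΔΔCt)` with ΔCt = Ct(target) − Ct(reference) and ΔΔCt relative to the
control condition.  Biological replicate Ct values are averaged
arithmetically before ΔCt, the common practice for the Livak method when
replicate pairing is not recorded.  TPM display uses log2(TPM + pseudocount),
default pseudocount 1.  The multi-stress filter classes a gene as
`multi_stress` when detected (TPM ≥ threshold) under at least two of cold,
drought, heat, and PEG, else `non_responsive`; the detection threshold
defaults to TPM ≥ 0.5, a conventional low-expression cutoff, since public
expression browsers do not publish theirs.  Raising the threshold can only
demote genes (monotonicity is property-tested).

## Synthetic proteome generator

The generator emulates the features of an allohexaploid proteome that the
pipeline actually exercises; its defaults are the catalogued wheat family
architecture:

| parameter | default | meaning |
|---|---|---|
| `type_counts` | 75 / 1 / 12 / 7 / 10 / 4 / 15 | genes per homeolog type (A:B:D … D) = 124 genes, 294 copies |
| `per_complement_counts` | 24, 19, 19, 19, 19, 5, 19 | genes per chromosome complement 1–7; only complements 1 (24) and 6 (5) are externally fixed, the remainder is spread evenly |
| `group_plan` | I 52, III 94, IIa 8, IIb 16, IIc 60, IId 24, IIe 40 | structural-group copies; the II subgroup split is not externally fixed and was chosen once |
| `n_multi_isoform` / `extra_isoforms_total` | 47 / 59 | candidate loci with ≥2 isoforms and total extra isoform records (294 + 59 = 353) |
| `n_background` | 500 | motif-free proteins |
| `within_triad_divergence` | 0.08 subs/site | copy-vs-ancestor divergence inside a gene; homeologs in hexaploid wheat are highly similar, well under 10% |
| `between_gene_divergence` | 0.25 subs/site | backbone divergence between chain-adjacent genes (paralog scale) |
| `protein_length_range` | 130–210 | clan backbone lengths; comfortably holds one or two ~45-residue cassettes |

Construction: genes are organised into *clans* of up to seven genes, one per
chromosome complement, balanced in size.  Within a clan, gene backbones form
a mutation chain (each derived from the previous gene's backbone at
`between_gene_divergence`); different clans have independent random roots.
Motif cassettes — heptapeptide, 5-residue linker, zinc finger — are drawn
once per zinc-finger type and shared family-wide, planted at
length-proportional positions (two for group I, one central otherwise), and
protected from mutation.  Copies then diverge at `within_triad_divergence`
over non-cassette positions only (substitutions, no indels, so alignments
stay trivially verifiable).  Extra isoforms duplicate the copy's sequence
with an incremented suffix.  Backgrounds are uniform 20-letter proteins with
heptapeptide-containing draws rejected.

Two generator choices are deliberate safeguards rather than biology:

* Family backbones and substitutions avoid W, C, and H, so planted
  heptapeptides and zinc-finger C/H skeletons are the only motif matches —
  scanner recall *and* precision are 1 by construction.  This is a statement
  about the generator, not about real proteomes.
* The clan-chain topology ensures every gene's nearest relatives lie on
  *different* chromosome complements.  Tree-adjacent gene pairs are therefore
  never complement-compatible, so the maximal-clade grouping rule cannot
  merge two distinct genes, and singleton genes are anchored near chain
  neighbours instead of drifting to the tree periphery (where the NJ Q
  criterion would otherwise pair distant, row-sum-inflated leaves — the
  long-branch-attraction failure observed with star-shaped clans during
  development).  Shared cassette content and proportional cassette placement
  keep all family members colinear in the progressive alignment; without
  positional anchoring, pairwise-deletion distances between unrelated genes
  collapse towards zero because only the conserved cassette columns remain
  comparable.

What the generator does **not** emulate: real length and composition
distributions, indels (an explicit non-goal at the defaults), degenerate or
partial domains, pseudogenes, translocations, tandem duplications, and
expression counts.  Passing the recovery tests therefore shows the pipeline
is correct on clean, well-separated family structure — it does not establish
sensitivity on diverged real domains, which is bounded by the motif scanner
by design.

## Pipeline and reproducibility

`run_all` executes load/simulate → scan → collapse → align → tree → group →
name → classify → stats, aborting with the stage name on error.  One integer
seed drives generation and bootstrap; reruns with the same config are
byte-identical.  The manifest records the package version, the full
config with all filled defaults, and a hash of it.  At the default problem
size (853 proteins, 294 aligned copies) the full pipeline completes in a few
seconds on one CPU; the acceptance script runs one such pipeline.

## Known limitations

* The motif scanner cannot find WRKY domains with non-canonical
  heptapeptides outside the allowed set or unusual zinc-finger spacing.
* Progressive alignment has no iterative refinement; deep-divergence
  alignments (p ≳ 0.7) are noisy, which is why the generator keeps related
  backbones colinear.
* Grouping is purely topological; it uses no branch-length or synteny
  evidence, and its correctness on real data depends on homeologs being
  each other's nearest neighbours in the tree.
* The within-complement serial order is one defensible convention; catalogs
  built with a different reading of the convention will agree on statistics
  but not on every individual serial.
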