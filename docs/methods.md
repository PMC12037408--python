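# Methods

This note documents the models, scores, numerical choices and known
limitations behind `trnachimera`, in the order the pipeline runs.

## Database model and cleaning

A database row is one aligned tRNA gene: metadata (gene id, organism,
isoacceptor, anticodon) plus the nine canonical parts as aligned strings
over {A, C, G, T, −}, two-region parts serialized with `_` between
regions.  The internal alphabet is DNA; conversion to RNA happens only at
the folding boundary.

Cleaning normalizes every record or rejects it with a reason code
(`missing-field`, `ambiguous-base`, `dloop-unalignable`, `part-size`);
the cleaned set and the reject log always partition the input, and
cleaning is idempotent.  Normalizations: U→T; positions 74–76 forced to
CCA; the anticodon set to a configurable default (CTA, the amber
suppressor — all designs share the target anticodon anyway).  D-loops are
variable in length, so they are aligned on the conserved GG motif into
eight slots (GG at aligned slots 5–6, canonical 18–19): a curated
dictionary is consulted first; otherwise 6-mers get `--` after the 2nd
base and 7-mers get `-` after the 3rd, falling back to the 5′-most gap
placement that still puts GG at slots 5–6.  Loops longer than eight are
kept only if GG already sits at the canonical slots.  Anticodon
replacement happens after D-loop alignment; the two operations commute.

Variable loops occupy canonical slots 44–48 but may carry up to seven
nucleotides; positions beyond slot 48 are not addressable by canonical
numbering and no shipped identity element lives there.

## Identity scoring

Two scores quantify similarity to host (E. coli) synthetase recognition
sets; both weight every element position equally, since the relative
importance of identity elements is not well quantified.

* **Part identity score** ∈ [0, 1]: over the part's element positions,
  the mean fraction of the per-position host base multiset matched by
  the query.  Within one isoacceptor, duplicate bases at a position
  count once; different isoacceptors contribute separately.  A part with
  no element positions is flagged and ranked as 0.
* **Sequence identity score** ∈ [−1, 1] per isoacceptor: per host gene,
  +1/−1 per element match/mismatch, divided by the number of scored
  elements, averaged over the isoacceptor's genes.  The maximum entry
  over isoacceptors drives filtering.  Elements inside the run's fixed
  identity parts are excluded (they are the target's own elements), as
  are anticodon positions 34–36 by default (every design carries the
  same user-chosen anticodon, so they carry no signal); both exclusions
  are configurable.  Positions 74–76 never appear in element tables
  (universal CCA).

The shipped element table is deliberately partial: element *positions*
and isoacceptor attributions follow the standard host identity-element
literature (Trp 1, 2, 3, 70–73; Ala 2, 3, 4, 20, 69–71, 73; D/T-loop
elements 14, 15, 16, 20, 59, 60 for Leu/Cys/Pro/Ala/Arg/Phe, with the
position-20 multiset {G, A, T}); a complete table is expected as user
input in the same four-column TSV schema.

## Part filtering, exemplars and generation

Default part rules: bases only (no ambiguity codes); paired parts must be
strict Watson–Crick duplexes (no G·U wobble — folding, below, does allow
wobble; the stricter rule at the part level buys unambiguous stems);
variable loops < 8 nt; at least one T in unpaired 8–9; D-loops open with
A.  All failures are counted per rule, never silent.

The lowest-scoring `cluster_parts` sequences per part (default 200, ties
at the boundary broken lexicographically) are clustered by affinity
propagation on similarity = −Levenshtein distance with the median
preference, damping 0.9 and a fixed seed; pools with fewer than
`min_cluster_size` (15) unique sequences are used unclustered.
Non-convergence falls back to the `min_cluster_size` lowest scorers
(logged).  Chimera generation streams the Cartesian product of all part
choices with constant memory per design; iterated runs exclude all
previously used exemplars before re-clustering and pool results,
deduplicated on the assembled sequence.

The length filter keeps designs strictly shorter than 79 nt.  The
stringency filter keeps designs with max sequence identity score ≤ t,
lowering t from 0.5 in steps of 0.05 while more than the target number
(default 2.5 × 10⁶) survive, and stops at the floor (0) even if the pool
is still larger — matching a run that retains slightly more than its
target at the floor.

## Folding and the cloverleaf grammar

Folding uses the ViennaRNA library at default parameters (37 °C) with
the partition function enabled.  Reported per sequence: the MFE
structure and energy, the **frequency** (the MFE structure's share of
the Boltzmann ensemble, exp((G_ensemble − E_MFE)/RT), in percent — the
implementation uses the engine's structure probability, and the tests
assert the thermodynamic identity to within 0.1 %) and the **ensemble
diversity** (mean base-pair distance, Δbp).  The engine name and version
are stamped into every result; numerical values can shift slightly
between engine versions.

The cloverleaf verdict matches the MFE dot-bracket against a structural
grammar compiled to a regular expression.  Default ranges: acceptor stem
6–7 bp; 8–9 linker 1–3 nt; D-stem 3–4 bp with a 3–12 nt loop; base 26
spacer 0–2 nt; anticodon stem 4–6 bp with a 7–9 nt loop (the anticodon
triplet therefore always unpaired); variable loop 1–9 nt; T-stem 4–6 bp
with a 6–9 nt loop; 1–6 unpaired 3′ bases.  Because RNAfold structures
are well nested, a regex match pins the helix topology.  Two tolerances
(each switchable) admit deviations seen in functional tRNAs: a small
self-contained hairpin inside the variable loop, and partial internal
pairing of the D-loop — the latter accepted only when the sequence keeps
a U in the 8–9 linker and an A opening the D-loop.  The grammar is this
package's own reconstruction of the usual cloverleaf acceptance
criteria; it is configurable precisely because reasonable practitioners
draw the line differently.

Survival is inclusive: cloverleaf ∧ frequency ≥ threshold ∧ diversity ≤
threshold (defaults 30 % and 10 Δbp; the worked Trp-style run uses 40 %
and 9 Δbp).  The anticodon sweep refolds each survivor with every
further anticodon in order, applies the same per-anticodon rule, then
drops designs whose unweighted mean frequency/diversity across all
anticodons miss the stricter final thresholds (defaults 50 % and 8 Δbp).

## Output selection

"Mismatches to the parent" are implemented as Levenshtein distances
(designs differ in length).  In automatic mode the pool is trimmed
toward 200 sequences by removing whole tie-groups at the current maximum
distance to the parent, stopping before a step that would drop below
half the cap; a hard user threshold (e.g. ≤ 14 edits) is supported
instead.  Candidates are clustered by affinity propagation
(non-convergence falls back to k-medoids with k = ⌈√n⌉, logged) and the
final group of `num_trnas` maximizes the minimum pairwise distance —
exhaustive whenever C(n, k) ≤ 10⁶ (which covers e.g. 33-choose-4), else
farthest-point greedy with single-swap hill climbing; the mode is
recorded in the result, and the heuristic never returns less than the
greedy baseline by construction.

## Synthetase identification

For a chosen isoacceptor class, each tRNA's identity parts (default:
acceptor stem and discriminator + CCA) are concatenated and
deduplicated with organism provenance.  Candidates with more than
`max_mismatch` (default 1) mismatches at identity-element positions
relative to the closest reference are discarded; full-sequence
mismatches are reported but never filtered on.  Pairwise dissimilarity
is 1 − fractional identity of a global alignment (matches divided by the
longer length; 0 identical, 1 no homology), computed internally via
Biopython's pairwise aligner — a precomputed matrix file is accepted so
any external distance tool can be substituted bit-exactly.  The UMAP
embedding (precomputed metric, neighborhood capped at half the pool so
tight duplicate groups stay separable) and HDBSCAN labels are visual
aids only; the filtered report never depends on them, and runs with
fewer than five survivors skip clustering.

## Synthetic data

The generator emulates the shape of a large aligned tRNA gene database
at toy scale.  Records derive from a consensus backbone found by
constrained search to fold into a high-frequency (≈86 %), low-diversity
cloverleaf; stem mutations are always compensatory (so every uncorrupted
record passes the Watson–Crick part rule by construction), loop
mutations avoid the D-loop's opening A and GG motif, the 8–9 uracil and
the anticodon.  Identity-part groups are planted: group 0 matches the
synthetic host table at every element position (sequence identity score
exactly +1), foreign groups differ at the acceptor 1–3/70–72 signature,
the discriminator and five D/T-loop elements (score ≤ 0).  Corruption
injects missing fields, ambiguity codes and GG-less D-loops; benign 6–7
nt D-loops (foreign groups only, since the re-inserted gap occupies
element position 16) must re-align.  The manifest records every planted
truth per gene, so rejects and scores are asserted exactly.

Deliberately not emulated: phylogenetic covariance between organisms,
post-transcriptional modification signals, type-II long variable arms,
and realistic base composition.  Passing tests on synthetic data
therefore demonstrate the pipeline's mechanics and bookkeeping, not
performance on real databases — on real data the variable-part pools are
orders of magnitude larger and survival rates through the structure
filter are far lower.

## Problem sizes and determinism

Default test and demonstration scales: ~100 organisms per isoacceptor
(the end-to-end check uses 105 organisms × 20 classes ≈ 2,100 records),
`cluster_parts` 30, stringency target 1,500 — sizes chosen so a full run
completes in well under a minute on one CPU while exercising every
stage, including affinity-propagation clustering on both ends of the
pipeline.  All randomness (generator, clustering, embedding) flows from
explicit seeds recorded in the run manifest; reruns with the same seed
and inputs are bit-identical, and the manifest asserts that stage counts
never increase after generation.

## Known limitations

* The cloverleaf grammar is a reconstruction; sequences near its range
  boundaries (e.g. 5-bp acceptor stems) are rejected even though a human
  inspector might accept them.
* The shipped identity table is partial; production runs need a complete
  host table (documented TSV schema).
* Identity scoring addresses canonical positions only; insertions
  relative to the canonical alignment (Sprinzl 17a/20a-style positions,
  long type-II variable arms) are out of scope.
* Folding ignores post-transcriptional modifications, which stabilize
  real tRNAs; predicted misfolding of a natural sequence does not imply
  non-function in its native host.
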