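# trnachimera

Automated design of **chimeric orthogonal tRNAs** and identification of
candidate aminoacyl-tRNA synthetases to pair with them.

Genetic code expansion needs tRNAs that are transcribed and folded in the
host (typically *E. coli*) but are **not** aminoacylated by any host
synthetase — orthogonal tRNAs — while still being charged by a co-expressed
cognate synthetase.  `trnachimera` searches for such sequences by
recombination at the level of tRNA structural parts:

1. **Segmentation.**  Every aligned tRNA gene is split into nine parts
   chosen so base-pairing and tertiary contacts stay within a part:
   acceptor stem {1–7 + 66–72}, unpaired bases 8–9, D-arm {10–13 + 22–25},
   D/T-loops {14–21 + 54–60}, base 26 + variable loop {26 + 44–48},
   anticodon stem {27–31 + 39–43}, anticodon loop {32–38}, T-arm
   {49–53 + 61–65}, and discriminator + CCA {73–76}.
2. **Fix identity, vary the rest.**  The parts of a target tRNA carrying
   the identity elements of its cognate synthetase are fixed; all other
   parts are harvested from the same isoacceptor class, filtered
   (Watson–Crick stems, short variable loops, a U at 8–9, an A opening the
   D-loop) and ranked by the **part identity score**

   *PartIdentityScore* = (1/k) · Σ_{i∈j} |{m ∈ M_i : m = n_i}| / |M_i|

   where *j* (|j| = k) are the part's positions that are identity elements
   for at least one host isoacceptor, M_i is the multiset of host bases at
   position *i* (unique bases per isoacceptor counted once) and n_i is the
   query base.  The lowest-scoring parts are collapsed to affinity-
   propagation exemplars on pairwise Levenshtein distances.
3. **Combinatorial assembly and pruning.**  The Cartesian product of all
   exemplars is streamed, filtered by length (< 79 nt), then by the
   **sequence identity score** (per host isoacceptor: ±1 per matching /
   mismatching element position, normalized and averaged over that
   isoacceptor's genes; the maximum entry is thresholded, and the
   threshold is walked down until the pool fits a target size).
4. **Structure filtering.**  Survivors are folded (ViennaRNA, default
   parameters); a chimera survives only if its MFE structure matches a
   cloverleaf grammar with frequency ≥ and ensemble diversity ≤ the
   configured cutoffs — repeated for every requested anticodon, plus a
   stricter cut on the ensemble means, so designs are robust to anticodon
   reassignment.
5. **Diverse output group.**  Remaining sequences are clustered by
   affinity propagation and the final group of *k* tRNAs maximizes the
   minimum pairwise Levenshtein distance (exact for the scales that
   matter).

A companion scan (`rsid`) finds organisms whose tRNAs carry the same (or
nearly the same) concatenated identity parts as the design's reference
tRNA — their genomes are where to look for synthetases that may acylate
the designed chimeras.  Scheme-based chimera generation (`crtm`) supports
the complementary strategy of replacing defined regions of one tRNA with
the corresponding regions of donor isoacceptors.

## Worked example

Everything below runs on a synthetic, tRNADB-CE-shaped database so it
works offline; swap in a real cleaned table for production use.

```bash
trnachimera synthdb --organisms 105 --isoacceptors Trp --corruption 0.05 \
    --seed 11 --out synth.tsv --manifest truth.json
trnachimera clean --in synth.tsv --out clean.tsv --rejects rejects.csv
trnachimera run --db clean.tsv --target Trp_0001 --isoacceptor Trp \
    --anticodons CTA,TGA --cluster-parts 30 \
    --stringency-filt 0.5 0 1500 0.05 --frequency 0.4 --diversity 9 \
    --final-frequency 0.5 --final-diversity 8 --num-trnas 4 --seed 3 \
    --identity-table identity.tsv --out-prefix trp_demo
```

prints the audited stage chain (written to `trp_demo.manifest.json`):

```
input         100     # cleaned Trp genes (5 of 105 rows were malformed)
generated     1536    # Cartesian product of part exemplars
length        1536    # all designs < 79 nt
identity      1536    # max sequence identity score <= 0.5
cloverleaf@CTA 152    # MFE cloverleaf, freq >= 40%, diversity <= 9 dbp
cloverleaf@TGA 151    # refolded with the second anticodon
ensemble      104     # anticodon-ensemble mean freq >= 50%, div <= 8
prefilter     104
exemplars     13      # affinity-propagation cluster exemplars
final         4
selected 4 designs, min pairwise distance 7 (exhaustive)
```

The four FASTA records in `trp_demo.fasta` are the designs to synthesize;
`min pairwise distance 7` is the (provably maximal) smallest edit distance
between any two of them.  Candidate synthetase sources come from:

```bash
trnachimera rsid --db clean.tsv --isoacceptor Trp --ref Trp_0000 \
    --max-mismatch 1 --seed 2 --identity-table identity.tsv --out rsid.csv
# 33 surviving tRNAs across 33 organisms
```

i.e. the 33 organisms whose tRNAs carry the reference's identity parts to
within one element mismatch.  `trnachimera profile` folds any FASTA into
a per-sequence frequency/diversity/cloverleaf table, and
`trnachimera enrich --counts a,b,c,d` runs the two-sided Fisher exact
test on a 2×2 group table (e.g. cloverleaf × orthogonal-active):

```
trnachimera enrich --counts 33,8,56,146
p = 3.55354e-10
```

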