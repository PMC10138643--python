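# Methods

This note records how `cuticula` operationalises cuticular-protein (CP)
family annotation: the rules, the numeric choices behind them, what the
synthetic generators do and do not emulate, and the known limitations.

## Motif engine

Family diagnostics are degenerate patterns over the 20-letter amino-acid
alphabet plus X (unknown). A pattern parses into fixed residues,
alternative sets (`[AVL]`, `Y/F`), and bounded wildcard runs (`x`,
`x(14-16)`, `X_5_`). Matching is anchored per window: fixed/alternative
positions may be substituted up to a per-motif mismatch budget
(default 0), wildcards and gaps are free, and an X in the protein never
satisfies a fixed or alternative position. `scan` reports *every*
matching window (overlaps included) via a budget-pruned forward dynamic
program; an independent per-window matcher (`match_window`) exists so the
two routes can be cross-checked exhaustively in tests.

Numeric choices:

* **ChtBD2 mismatch budget = 1.** The CPAP1/CPAP3 cysteine-spacing
  patterns contain 6 fixed cysteines per domain; with a budget of 0 a
  single point substitution erases a domain, which is too brittle for
  predicted proteomes. One substituted cysteine per domain instance is
  tolerated.
* **Repeat counting** is greedy left-to-right, and consecutive counted
  occurrences may share exactly one residue: tandem cysteine-anchored
  repeats (`C-x5-C-x5-C`) chain on the shared cysteine and count as two.
* **Dipeptide counting** (PV/PY for CPLCP) allows overlaps — it is plain
  substring counting.
* **Consensus scoring** slides the R&R consensus (gaps at minimal width)
  along the protein and reports the best fraction of fixed/alternative
  positions matched; ties resolve to the smallest offset. This replaces
  profile-HMM detection of the chitin_bind_4 domain with a transparent,
  dependency-free score against the printed extended consensus strings;
  the acceptance threshold (0.5 of fixed positions) is configuration,
  since no published numeric threshold exists for the manual equivalent.

## Classification cascade

One verdict per protein, first matching rule wins:

1. **CPAP** — ≥3 non-overlapping CPAP3 spacings → CPAP3; else ≥1 CPAP1
   spacing → CPAP1. CPAP precedes CPR deliberately: a ChtBD2-bearing
   protein belongs to the peritrophin-analogous superfamily even when it
   also shows weak R&R-like signal.
2. **CPR** — scored against the RR-1 and RR-2 extended consensus; the
   larger score wins the subfamily when it clears the threshold (0.5) and
   beats the other by the tie margin (0.05); near-ties become RR-NC
   ("CPR not classified", an explicit verdict, not an error state).
   Identity ≥0.50 to a reference RR-3 exemplar that exceeds the consensus
   evidence yields RR-3. The 0.50 floor is a package choice — no
   published cutoff exists — kept deliberately high so RR-3 calls stay
   conservative.
3. **CPT** — at least 3 of the 4 Tweedle blocks, hit in order
   I < II < III < IV. Requiring 3-of-4 keeps single-block losses from a
   point substitution from erasing the family.
4. **Low-complexity rules**, in order: CPCFC (≥2 C-x(5)-C repeats);
   CPF/CPFL/18aa/CPLCA by best reference identity ≥0.40; CPLCP
   (PV+PY ≥10 and proline fraction ≥0.10); CPG (glycine fraction ≥0.20
   and ≥2 GGxGG repeats); CPH (identity ≥0.36 to a CPG/CPH reference —
   the weakest identity reported for this family class in the
   literature — or ≥3 AAP[AVL] repeats).
5. Everything else is **not-CP**.

All thresholds live in `RunConfig`, are serialized into every output
directory and echoed in report headers. Manual curation (e.g. a synteny
based reassignment of a single gene) is applied only through an explicit
override TSV, logged and flagged per call.

The measured false-positive rate of the cascade on uniform-random
100-residue proteins is ~3%, essentially all from chance C-x(5)-C pairs
satisfying the CPCFC rule; this rate is a property of the family's
definition, and the test suite measures it over a 300-protein aggregate
because per-100 draws fluctuate by several counts.

## Homology and naming

Identity is computed from an optimal global (Needleman–Wunsch) alignment
with affine gaps (BLOSUM62, open 10, extend 1, all configurable);
matches / aligned columns with terminal gap columns excluded — the least
length-punitive convention for full-length proteins of unequal length.
The input pair is canonically ordered before alignment so identity is
exactly symmetric. Orthology is reciprocal-best-hit: unique mutual best
hits at ≥ the identity floor are 1:1; remaining best-hit edges are
grouped into connected components and reported as co-ortholog groups
(the signature of lineage-specific expansion). Proteins with a 1:1
partner inherit the reference name stem under the species prefix
(`RefCPF` → `ApCPF`); the rest are numbered per family in genomic
annotation order. Exact identity values from heuristic local aligners
are not reproduced and are treated as external checks only.

## Phylogeny and logos

Distances are Poisson-corrected, d = −ln(1 − p), with pairwise deletion:
for each pair, only columns where both rows are ungapped and not X
contribute. p = 1 gives an infinite distance; the full-data tree refuses
it (the pair must be excluded), while bootstrap replicates truncate p at
1 − 1e−6 so a resampled replicate cannot abort a run. Trees are built by
canonical neighbor joining (Saitou–Nei Q-criterion). Two conventions the
reference desktop tools leave implicit are fixed here: Q ties break
toward the lexicographically smallest label pair (internal nodes carry
the smallest leaf label beneath them), and negative branch-length
estimates are clamped to zero and logged. Bootstrap support is the
percentage of replicate trees (columns resampled with replacement,
seeded) containing each internal bipartition of the full-data tree.

Logo matrices report per-column residue frequencies over non-gap,
non-X residues and information R = log2(20) − H bits (no small-sample
correction by default). Subfamily trees for RR-1 and RR-2 are built
separately on the consensus region — the best-scoring consensus window
±10 residues of flank (configurable) — extracted per protein. Where no
externally built alignment is supplied, a center-star progressive
aligner over the global-alignment engine produces the MSA; it is
approximate and logged as such, which is adequate at desk scale.

## Genome layout

A tandem array is a maximal chain of same-family (same-subfamily, for
CPR) genes on one chromosome in which consecutive members are ≤100 kb
apart start-to-start and separated by ≤1 non-family gene. Both knobs are
configuration and echoed in output headers: the literature describes CP
tandem arrays without defining them numerically, so transparency is
preferred over false precision. Distances are start-to-start on a
strand-agnostic axis. Singletons are not arrays. By construction RR-1
and RR-2 never share an array; the per-chromosome report carries the
(always-false) mixed-array flag as an output-level check of that
invariant.

## Expression

FPKM values are binned into six left-closed decade categories
([0,1), [1,10), [10,100), [100,1000), [1000,10000), [10000,∞)); a
boundary value falls in the upper bin — the published ranges ("1–10",
"10–100") are ambiguous at their endpoints, so one convention is fixed
and stated. A gene is "expressed" when FPKM ≥ 1, i.e. anything above the
lowest ("no or extremely low") category; whether the original counts
used >0 or ≥1 cannot be determined from the published text, so the
threshold is configuration and printed in every report header.
Family-by-tissue tables append a totals row and per-row percentages
(expressed / genome count, rounded half away from zero to 1 decimal).
Heat-map matrices are log10(FPKM + 1); the pseudocount handles zeros,
which the published transform leaves unspecified. Rows are ordered by
average-linkage hierarchical clustering of transformed profiles
(Euclidean), or by genomic order. Tissue specificity is the dominance
ratio max/sum, flagged at ≥0.8.

While validating the bundled published counts we found three printed
percentages inconsistent with their own printed counts (e.g. 18/22
printed as "80%"); the reporting code computes percentages from counts,
so those cells re-derive to 81.8%, 65.2% and 36.6% respectively.

## Synthetic data

`make_proteome` plants each family's diagnostic into random uniform
flanks (wildcard positions randomized per instance), derives
homology-family members as mutated copies of synthetic reference
entries, then applies uniform per-site substitution at the requested
rate. Every planted protein is verified to classify as its planted group
*before* mutation (resampled otherwise) and every decoy is
rejection-sampled until the classifier calls it not-CP — so measured
recovery reflects the effect of mutation, and measured false positives
reflect the classifier, not generator leakage. The default fixture is 60
planted genes (5 × 12 family groups) at 2% per-site mutation plus 10
decoys; the demo fixture is shaped like a lepidopteran catalog (CPR
dominating, split RR-1/RR-2) at ~60 genes with planted arrays of
5/7 (RR-1) and 6/12 (RR-2) genes. `make_layout` places requested arrays
at fixed spacings with decoy genes elsewhere; `make_expression` draws
FPKM log-uniformly inside per-gene per-tissue target bins (the lowest
bin samples [0.01, 1) since log 0 is undefined; the top bin is capped at
1e5), so binning the output reproduces the targets exactly;
`make_clade_msa` mutates a root at the between-clade rate to get clade
ancestors and at the within-clade rate to get leaves (no indels, so the
output is already aligned). All generators are byte-reproducible given
(spec, seed).

What the generators do **not** emulate: real amino-acid composition
biases (backgrounds are uniform unless the glycine-bias option is used),
signal peptides, isoform structure, alignment gaps from indels, read
level noise in FPKM, or the curation judgment behind real catalog
rosters. Passing the recovery suites therefore demonstrates the
correctness and robustness of the rules, not their sensitivity or
specificity on real proteomes.

## Problem sizes

The bundled suites run at desk scale by design: ~60–70 protein fixtures,
trees of ≤20 leaves with 100 bootstrap replicates, exhaustive oracles at
≤8 taxa / ≤50-residue windows / ≤6-residue alignment enumerations. These
sizes exercise every code path; the algorithms themselves are O(n²)
alignment and O(n³) NJ and handle catalog-scale inputs (hundreds of
proteins) in minutes.

## Limitations

* One protein per gene is assumed; isoforms should be collapsed upstream
  (the annotation pipeline documents, rather than resolves, this).
* Consensus scoring is not a profile HMM: position-specific residue
  preferences inside the R&R consensus are flattened to match/mismatch.
* The CPAP spacing patterns match anywhere in the sequence; whether the
  canonical patterns anchor at the first cysteine of the mature protein
  is left open, and hit offsets are recorded for inspection.
* Exact reproduction of published genome-wide rosters (217/236) is out
  of scope: it depends on genome downloads, pHMM searches and manual
  curation. The published per-family counts are used as arithmetic
  inputs instead.
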