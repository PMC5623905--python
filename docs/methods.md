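# Methods

This note documents the models, rules and numerical choices implemented in
`varstruct`, in enough detail to reproduce or audit any stage.

## Variant model and data sets

A variant is one amino-acid substitution in a gene, identified by
`(gene, 1-based protein position, ref, alt)` and tagged with a data-set
label (disease-associated sets vs neutral sets such as common or benign
variants). Gene records carry both the protein sequence and a consistent
coding sequence (`3·|protein| + 3` nucleotides including the stop codon;
codon *k* spans CDS nucleotides `3k−2..3k`). Loading validates every row
against the gene sequence and rejects, with row-numbered diagnostics rather
than aborting: unknown genes, out-of-range positions, reference mismatches
and identity substitutions. Duplicate rows collapse to one variant with a
multiplicity count.

Disease sets are cleaned by removing exact `(gene, position, ref, alt)`
matches present in any neutral set; the removed count is reported.

### Randomized controls

Each variant set has a randomized twin: per gene, the same number of
substitutions is drawn by picking a coding-sequence nucleotide uniformly at
random, a different base uniformly at random, and rejection-resampling until
the codon change is missense (synonymous and stop-gain draws are discarded
and redrawn; the output must remain a missense set). Draws are with
replacement across sites, so recurrent positions can occur, as in real
mutation data, and randomized variants may coincide with original variant
sites. The induced null over positions is uniform over *(site, alternative
base)* pairs that produce a missense change, i.e. a site's probability is
proportional to its number of missense-producing alternatives; the test
suite checks a 10 000-draw experiment against exactly this
enumeration-derived expectation (chi-square, α = 0.01).

## Template recognition

Structure chains are admitted as templates for a gene by a global pairwise
alignment (Biopython `PairwiseAligner`, BLOSUM62, gap open 10, gap extend
0.5, free end gaps — the EMBOSS `needle` convention) under three filters:

- sequence identity > 0.35, computed as identical columns divided by
  aligned (non-double-gap) columns;
- alignment coverage > 50% of the shorter sequence, **or** aligned span
  > 50 residues (the reported `cov` field is relative to the target);
- e-value < 1e−5 — applied only when a pluggable external search backend
  supplies e-values; the internal alignment search has none.

Variant positions travel through alignment columns; a position aligned to a
gap in the template row marks that template unusable for that variant.
Hits are sorted by identity descending, ties broken by
`(structure_id, chain_id)` for reproducibility.

Template quality is the equally weighted (configurable) mean of four
normalised attributes: sequence identity, target coverage,
`res = 1/(1+exp(1.5·resolution − 4))` (0.5 at 8/3 Å, → 1 for perfect
resolution) and `r = 1 − R-value`. Missing resolution or R-value (models,
non-crystallographic entries) contributes a neutral 0.5. The mean form is a
declared reconstruction: it is monotone in each attribute, bounded in
[0, 1], and reproduces all qualitative dependencies expected of a template
score; the exact published combination is not available in closed form.

## Structural annotation

PDB-format files are parsed with gemmi: first model only, alternate
location A only, insertion codes preserved. Chains are typed
protein/DNA/RNA by residue alphabet; modified residues inside polymer
chains stay polymer. HETATM groups become ligands after removing a packaged
list of common crystallographic buffers (HOH, GOL, EDO, PEG, SO4, PO4, ACT,
DMS, MPD, TRS, FMT, NO3, …); metal and halide ions are kept because
mutations at ion-binding sites are functionally relevant. Het codes on a
user-supplied drug list are kept but flagged, enabling the drug-exclusion
re-analysis. Resolution is read from the standard header; the R-value from
the refinement remark.

Per residue and template we compute minimum inter-atomic (non-hydrogen)
Euclidean distances to: any ligand (SLD), the nearest other protein chain
(the residue's own chain excluded), and the nearest DNA chain; SCD is the
minimum over macromolecular categories (DNA included). Absent partners are
"infinite" and encoded as missing.

RSA uses a Shrake–Rupley accessible surface (biotite implementation; probe
1.4 Å, 960 sphere points, single-atom van der Waals radii C 1.70 / N 1.55 /
O 1.52 / P 1.80 / S 1.80) computed once per structure with **all** atoms of
the entry — ligands and partner chains included — occluding, i.e.
whole-complex accessibility (chain-only accessibility is a configuration
away). Residue areas are divided by a packaged theoretical Gly-X-Gly
maximum-ASA scale and expressed in percent; extended conformations can
exceed 100%. The SASA engine is cross-checked in the tests against the
closed-form spherical-cap area of a two-sphere system (2% tolerance) and
against an independent Shrake–Rupley implementation inside the acceptance
checks.

## Classification and candidate scores

Aggregating over all templates of a variant (per-category minima), the
exclusive class is:

1. if any partner category has a minimum distance strictly below 5 Å, the
   class of the smallest such distance; exact ties break by the fixed,
   configurable priority DNA > Ligand > Protein (rarest class wins, so ties
   never mask scarce signal);
2. otherwise Core if RSA is strictly below 16%;
3. otherwise Surface.

The RSA used in step 2 comes from the template providing the overall
minimum distance, or from the best-scoring template when no partner was
observed anywhere. A variant with no mapped template is Unmapped and
excluded from class fractions (counted separately). The non-exclusive view
(every category within 5 Å in any template) is kept alongside as the
contact multiset.

Logistic contact weights `lig_cont = 1/(1+exp(SLD−10))` and
`chain_cont = 1/(1+exp(SCD−10))` vanish for absent partners; the
interaction score is their maximum, and the per-template candidate score is
`template_score × IS` (both combinations pluggable). The drug-exclusion
re-analysis removes distances to excluded het codes, re-runs the rule, and
logs every class flip.

## Statistics

- **Class fractions** are over mapped variants; bootstrap SDs resample the
  annotated set with replacement (size *n*, B = 1000 by default, seeded).
- **Rank-sum test**: two-sided Wilcoxon/Mann-Whitney. For combined sample
  sizes ≤ 25 the p-value is exact — the null distribution of the rank sum
  (mid-ranks doubled to integers, so ties are handled) is computed by
  dynamic programming, equivalent to enumerating all group assignments; the
  tests verify equality with brute-force enumeration for every split with
  n ≤ 10. Larger samples use the tie-corrected normal approximation
  (scipy). Two fully tied samples give p = 1.
- **Template-count-matched sampling** draws, without replacement, neutral
  variants whose proteins have the same number of templates as the target
  set, bin-for-bin over exact integer counts; empty bins fall back to ±1
  then ±2 neighbours, then to sampling with replacement, each fallback
  counted and reported.
- **Pair proximity**: the statistic is the mean pairwise distance between
  representative atoms (Cβ, Cα for glycine) of the mutated residues of one
  complex; the null redraws residue sets of the same per-chain sizes
  uniformly without replacement; `p = (1 + #{null ≤ obs})/(n_perm + 1)`
  (add-one smoothing keeps p > 0; n_perm = 10 000 by default). The
  statistic and null are the package's own design — the simplest
  exchangeable null preserving per-chain counts.

## Enrichment

Per protein: for each template take the mean candidate score of the
protein's variants mapped in it; the combined score is the maximum of these
means — a few high-scoring candidate substitutions beat many low-scoring
ones (this realisation of the normalisation is a declared design choice and
pluggable). Per pathway/GO term: sum of member-protein scores divided by
the number of members represented in the data set; unrepresented terms are
omitted; duplicate membership rows are ignored. Terms shared by the
disease-side and neutral-side maps are ranked by the score difference
(antisymmetric by construction, ties broken by term id). A 10 000-gene
randomized control draws genes from the universe, gives each a count
sampled i.i.d. from the empirical per-gene count distribution, and places
variants via the randomizer above. GO terms and pathways share one code
path keyed by an annotation namespace column.

## Complex networks

Genes carrying at least one mapped variant are nodes; an edge connects two
genes mapping (each with sequence identity strictly above 0.90 on its own
alignment) onto different chains of at least one common structure, with the
supporting structure ids as an edge attribute; a gene on two or more chains
of one structure gets a self-loop (homooligomer). Stoichiometry is ignored.
Components with ≥ 2 nodes or a self-loop are the reported multi-mutated
complexes, sorted by size then lexicographically.

## Synthetic data: what it emulates, and what it does not

Toy complexes are geometrically exact but physically naive: protein chains
are extended strands (N, CA, C, O plus one pseudo side-chain atom per
residue) with 8 Å between consecutive residues; DNA duplexes are two
complementary strands of P/C1'/N1 atom subsets; ligands are 3-atom
molecules. Partners are placed along the side-chain direction and solved by
bisection to a target minimum inter-atomic distance with a small seeded
jitter (±0.1 Å, within the documented ±0.2 Å tolerance). The 8 Å spacing
guarantees that a partner planted at < 8 Å from its designated residue
stays ≥ 8 Å from every other residue, so planted classes are unambiguous;
the generator verifies this clearance and all inter-partner separations
post hoc and fails loudly, naming the clash, on infeasible specs. Buried
("Core") residues are realised by a same-chain occlusion cage (60 carbon
atoms on a 4.6 Å sphere, a single extra `UNK` residue), which must sit
≥ 2 sequence positions from any partner placement. Generators are pure
functions of (spec, seed): identical inputs give byte-identical files.

Consequences for interpretation: absolute RSA values of 5-atom toy residues
are inflated relative to real residues (the maximum-ASA scale assumes full
side chains), so the synthetic tests exercise the *rules* (thresholds,
minima, tie-breaks, aggregation) and the geometry engines at exact,
planted values — they do not certify calibration on real crystallographic
material, where coordinate error, alternate conformations, assembly choices
and real side-chain packing matter. Distances, by contrast, are exact in
both worlds. The demo study plants contact variants only on the genes of
one enriched pathway, giving the enrichment stage a known top-ranked
answer, and includes a heterodimer and a homodimer structure so the network
stage has planted edges.

## Numerical choices and degenerate inputs

- "Closer than 5 Å" and "below 16%" are strict inequalities.
- Distances use all non-hydrogen atoms (crystal structures rarely resolve
  hydrogens); the representative-atom convention (Cβ/Cα) applies only to
  the proximity statistic, with a full-atom option.
- Bootstrap requires n ≥ 2; class fractions require ≥ 1 mapped variant;
  the proximity test requires ≥ 2 mutated residues; empty rank-sum samples
  are rejected.
- Residues with fewer than 4 atoms are annotated but flagged low
  confidence.
- A gene admitting no missense change (degenerate coding sequence) makes
  the randomizer fail naming the gene, rather than looping forever.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  public sampler takes an explicit seed.

## Problem sizes used in the shipped checks

The test-suite and acceptance script run at desk scale, chosen so the whole
suite completes in well under a minute of compute: 50 randomized complexes
for classifier-oracle agreement (~700 residues), 100 genes / 500 planted
variants for class recovery, 10 000 draws for randomization uniformity,
B = 1000 bootstraps, 10 000 permutations for proximity tests, and 100
seeded replicates for planted-pathway recovery. Fraction-level results from
full-scale variant databases are not reproducible at this scale and are not
asserted anywhere.

## Known limitations

- mmCIF input, biological-assembly generation, RNA contact analysis,
  secondary-structure and disorder annotation are out of scope.
- The internal template search is alignment-only; BLAST-scale e-values
  enter only through the pluggable external-search interface.
- The template-score and candidate-score combinations are reconstructions
  (means / products of the documented components); both are configurable.
- The five-factor descriptor table is the published Atchley et al. (2005)
  solution, standing in for equivalent factor sets derived from large
  property compilations; it is replaceable via an argument.
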