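# varstruct

**Where do missense variants fall in protein 3D structures?**

`varstruct` is a Python library for structural annotation of amino-acid
substitutions (nsSNVs). Given protein/coding sequences, variant tables and a
library of PDB-format structures, it:

1. finds homologous structure chains ("templates") for each gene with an
   EMBOSS-style global alignment (BLOSUM62, gap open 10 / extend 0.5) and the
   admission filters *sequence identity > 35%* and *(coverage > 50% of the
   shorter sequence or aligned span > 50 residues)*; an e-value < 1e−5 gate
   applies when an external search supplies e-values;
2. maps each variant position through the alignment (positions falling on a
   gap discard that template) and measures, per template, the shortest
   inter-atomic distances to ligands (SLD), to other protein chains, and to
   DNA, plus the relative solvent accessibility (RSA) from a Shrake–Rupley
   surface (probe 1.4 Å, 960 points) normalised by a theoretical
   maximum-ASA scale;
3. assigns each variant to one of five exclusive spatial classes —
   **DNA contact / Ligand contact / Protein contact** (nearest partner
   < 5 Å wins), else **Core** (RSA < 16%), else **Surface** — aggregating
   per-category minima over all templates;
4. scores candidates as `template_score × IS`, where
   `template_score = mean(seq_id, cov, res, 1 − R)` with
   `res = 1/(1+exp(1.5·resolution − 4))`, and the interaction score
   `IS = max(lig_cont, chain_cont)` with
   `lig_cont = 1/(1+exp(SLD − 10))`, `chain_cont = 1/(1+exp(SCD − 10))`;
5. compares variant sets statistically: per-class bootstrap SDs (B = 1000),
   two-sided Wilcoxon rank-sum distance tests (exact for small samples),
   randomized control sets (same genes, same per-gene counts, random
   missense positions), template-count-matched sampling, and a spatial
   pair-proximity permutation test;
6. ranks pathways / GO terms by differential score: per-protein combined
   scores (max over templates of the mean candidate score) are summed per
   term, normalised by member count, and the disease-side minus
   neutral-side difference is ranked;
7. builds networks of complexes with mutated subunits: genes mapping at
   > 90% identity onto different chains of one structure are linked;
   homooligomers get self-loops.

Because public variant/structure snapshots are large and churn constantly,
the package ships a first-class synthetic-data module: toy multi-chain
complexes with partners planted at controlled distances, gene sets with
consistent coding sequences, planted variant classes and planted pathway
enrichments — so every stage is testable end-to-end with exact ground truth
and zero downloads.

## Worked example

```sh
python examples/02_classify_variants.py
```

prints, for a six-gene synthetic study (disease variants planted on
interfaces of the enriched genes, neutral variants on core/surface
residues):

```
disease set: 14 mapped variants
  Core             28.6%  (bootstrap SD 0.124)
  DNA contact      14.3%  (bootstrap SD 0.092)
  Ligand contact   14.3%  (bootstrap SD 0.094)
  Protein contact  14.3%  (bootstrap SD 0.094)
  Surface          28.6%  (bootstrap SD 0.116)
common set: 12 mapped variants
  Core             50.0%  (bootstrap SD 0.140)
  Surface          50.0%  (bootstrap SD 0.140)
```

The disease set shows the interface excess the classifier is built to
detect; the bootstrap SDs quantify the resampling noise of each fraction.
`examples/04_pathway_enrichment.py` then ranks the planted pathway first
(differential score +0.886 over a zero background), and
`examples/05_complex_network.py` recovers the planted heterodimer edge
`G0001—G0002` and the `G0003` homodimer self-loop. The remaining examples
cover toy-complex geometry (01) and randomized controls with rank-sum
distance tests (03).

A thin CLI wraps the same stages:

```sh
varstruct generate --n-genes 6 --seed 0 --outdir demo/
varstruct randomize --variants demo/variants.tsv --genes demo/genes.fasta --seed 1 --out demo/random.tsv
varstruct all --n-genes 6 --seed 0 --outdir demo/out/
```

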