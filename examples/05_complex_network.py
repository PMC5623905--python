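"""Network of complexes whose subunits carry mapped variants.

Two genes are linked when they map (at > 90% sequence identity) onto
different chains of at least one common template structure; a gene mapping
onto two chains of one structure is a homooligomer and gets a self-loop.
The demo study contains a heterodimer of the first two genes and a
homodimer of the third.
"""

from varstruct.network import build_network, edges_frame, multi_mutated_complexes
from varstruct.pipeline import RunConfig, annotate_variants, generate_study

study = generate_study(n_genes=6, seed=3)
genes = study.gene_map()
hits_by_gene, annotated = annotate_variants(
    study.disease_variants + study.neutral_variants, genes, study.entries,
    RunConfig(seed=3))
hits = [h for hs in hits_by_gene.values() for h in hs]

graph = build_network(hits, annotated, identity_threshold=0.90)
print("edges (gene pairs co-resolved in one structure):")
print(edges_frame(graph).to_string(index=False))
print("\ncomplexes with multiple mutated subunits (or homooligomers):")
for comp in multi_mutated_complexes(graph):
    print(" ", comp)
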