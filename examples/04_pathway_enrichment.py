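"""Differential pathway scoring with a planted enriched pathway.

Per-protein combined scores (max over templates of the mean per-variant
candidate score) are summed per pathway, normalised by the number of member
proteins, and the disease-side minus neutral-side difference ranks pathways.
The study plants one pathway whose member genes carry interface variants;
it should come out on top.
"""

from varstruct.enrichment import differential_ranking, pathway_scores
from varstruct.pipeline import generate_study, protein_scores_from_annotation

study = generate_study(n_genes=6, seed=2)
genes = study.gene_map()

disease_scores = protein_scores_from_annotation(
    study.disease_variants, genes, study.entries)
neutral_scores = protein_scores_from_annotation(
    study.neutral_variants, genes, study.entries)

print("combined protein scores (disease side):")
for gid, s in sorted(disease_scores.items()):
    print(f"  {gid}: {s:.3f}")

pw_d = pathway_scores(disease_scores, study.annotations)
pw_n = pathway_scores(neutral_scores, study.annotations)
print(f"\nplanted enriched pathway: {study.planted_terms[0]}")
print("top differential scores (disease - neutral):")
for r in differential_ranking(pw_d, pw_n, k=5):
    marker = "  <-- planted" if r.term_id in study.planted_terms else ""
    print(f"  {r.term_id}: {r.differential:+.3f}{marker}")
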