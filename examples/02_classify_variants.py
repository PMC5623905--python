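"""Annotate planted variant sets and show their spatial class distributions.

A synthetic study plants disease variants on interaction interfaces of the
enriched genes and neutral ("common") variants on core/surface residues.
After homology template search and per-template annotation, each variant is
assigned one of five exclusive classes; bootstrap SDs quantify the sampling
noise of the class fractions.
"""

from varstruct.pipeline import RunConfig, annotate_variants, generate_study
from varstruct.stats import bootstrap_sd, class_fractions

study = generate_study(n_genes=6, seed=0)
config = RunConfig(bootstrap_B=1000, seed=0)
genes = study.gene_map()

for label, variants in (("disease", study.disease_variants),
                        ("common", study.neutral_variants)):
    _, annotated = annotate_variants(variants, genes, study.entries, config)
    dist = class_fractions(annotated)
    sd = bootstrap_sd(annotated, B=config.bootstrap_B, seed=config.seed)
    print(f"{label} set: {dist.n_mapped} mapped variants")
    for cls, frac in sorted(dist.fractions.items()):
        if frac:
            print(f"  {cls:<16s} {frac:5.1%}  (bootstrap SD {sd[cls]:.3f})")
print("\nDisease variants concentrate at ligand/DNA/protein interfaces;")
print("neutral variants stay on the surface or in the core.")
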