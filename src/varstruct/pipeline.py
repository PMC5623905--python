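"""End-to-end orchestration: from genes, variants and a structure library to
annotated variants, statistics, enrichment rankings and complex networks.

Also provides the synthetic demo study generator used by the examples, the
command-line ``generate`` stage and the test-suite fixtures: a set of genes,
one toy complex per gene with designated residues of all five structural
classes, planted variant sets and a pathway annotation table with one
planted enriched pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import synthetic
from .enrichment import (differential_ranking, pathway_scores,
                         protein_combined_score)
from .scoring import (AnnotatedVariant, aggregate_over_templates,
                      candidate_score, DEFAULT_CONTACT_THRESHOLD,
                      DEFAULT_CORE_RSA)
from .stats import bootstrap_sd, class_fractions, ranksum_test
from .structure import StructureEntry, parse_structure, residue_context
from .synthetic import ComplexSpec, Placement, PlantedTruth
from .templates import (ChainSeq, library_from_entries, map_positions,
                        search_templates, TemplateHit,
                        DEFAULT_IDENTITY_THRESHOLD)
from .variants import GeneRecord, Variant, randomize_dataset
from .network import build_network, edges_frame, multi_mutated_complexes


@dataclass
class RunConfig:
    """Thresholds and sizes of one pipeline run (documented defaults)."""

    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    coverage_threshold: float = 0.5
    min_aligned_length: int = 50
    contact_threshold_A: float = DEFAULT_CONTACT_THRESHOLD
    core_rsa_percent: float = DEFAULT_CORE_RSA
    network_identity: float = 0.90
    bootstrap_B: int = 1000
    n_perm: int = 10_000
    seed: int = 0
    excluded_ligands: tuple[str, ...] = ()


@dataclass
class Study:
    """A fully specified synthetic data set with ground truth."""

    genes: list[GeneRecord]
    entries: list[StructureEntry]
    pdb_texts: list[str]
    truths: list[PlantedTruth]
    disease_variants: list[Variant]
    neutral_variants: list[Variant]
    annotations: pd.DataFrame
    planted_terms: list[str]

    def gene_map(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}

    def library(self) -> list[ChainSeq]:
        return library_from_entries(self.entries)


# designated positions within each toy chain (all >= 2 apart, so core cages
# never encroach on partner placements)
_POS_LIGAND, _POS_DNA, _POS_PROTEIN, _POS_CORE, _POS_SURFACE = 3, 8, 13, 18, 23
_STUDY_CHAIN_LEN = 26


def generate_study(n_genes: int = 6, seed: int = 0,
                   contact_distance: float = 3.5,
                   n_pathways: int = 8,
                   enriched_fraction: float = 0.34,
                   drug_every: int | None = None) -> Study:
    """One toy complex per gene with a planted residue of every class.

    Each chain of length 26 carries a ligand contact at position 3 (het code
    ``DRG`` for every ``drug_every``-th gene when requested, ``LIG``
    otherwise), a DNA contact at 8, a protein-chain contact at 13, a caged
    core residue at 18 and a free surface residue at 23.  Disease variants
    sit on contact residues, neutral variants on core/surface residues, and
    the first ``enriched_fraction`` of genes form one planted pathway.
    """
    genes = synthetic.make_gene_set(
        n_genes, length_range=(_STUDY_CHAIN_LEN, _STUDY_CHAIN_LEN), seed=seed)
    entries, texts, truths = [], [], []
    for i, gene in enumerate(genes):
        het = "DRG" if drug_every and (i % drug_every == 0) else "LIG"
        spec = ComplexSpec(
            n_protein_chains=1,
            chain_lengths=(len(gene.protein_seq),),
            chain_sequences=(gene.protein_seq,),
            chain_gene_ids=(gene.gene_id,),
            ligand_placements=(Placement("A", _POS_LIGAND, contact_distance,
                                         het_code=het),),
            dna_placements=(Placement("A", _POS_DNA, contact_distance),),
            partner_chain_placements=(Placement("A", _POS_PROTEIN,
                                                contact_distance),),
            core_residues=(("A", _POS_CORE),),
            surface_residues=(("A", _POS_SURFACE),),
            structure_id=f"T{i + 1:03d}",
            seed=seed + 1000 + i,
        )
        text, truth = synthetic.make_toy_complex(spec)
        entries.append(parse_structure(text, structure_id=spec.structure_id))
        texts.append(text)
        truths.append(truth)
    # co-complex structures so the network stage has something to build:
    # a heterodimer of the first two genes and a homodimer of the third
    if n_genes >= 2:
        for sid, seqs, gids in _shared_complexes(genes):
            spec = ComplexSpec(
                n_protein_chains=len(seqs), chain_lengths=tuple(map(len, seqs)),
                chain_sequences=tuple(seqs), chain_gene_ids=tuple(gids),
                structure_id=sid, seed=seed + 5000)
            text, truth = synthetic.make_toy_complex(spec)
            entries.append(parse_structure(text, structure_id=sid))
            texts.append(text)

    # pathway signal: only the enriched genes carry contact variants, so
    # their combined protein scores dominate the planted pathway
    n_enriched = max(1, round(enriched_fraction * n_genes))
    enriched, background = genes[:n_enriched], genes[n_enriched:]
    disease = synthetic.plant_variants(
        enriched, truths,
        {synthetic.CLASS_LIGAND: n_enriched, synthetic.CLASS_DNA: n_enriched,
         synthetic.CLASS_PROTEIN: n_enriched},
        seed=seed + 1, dataset_label="disease")
    if background:
        disease += synthetic.plant_variants(
            background, truths,
            {synthetic.CLASS_CORE: len(background),
             synthetic.CLASS_SURFACE: len(background)},
            seed=seed + 4, dataset_label="disease")
    neutral = synthetic.plant_variants(
        genes, truths,
        {synthetic.CLASS_CORE: n_genes, synthetic.CLASS_SURFACE: n_genes},
        seed=seed + 2, dataset_label="common")
    annotations, planted = synthetic.make_annotation_db(
        n_pathways, [g.gene_id for g in genes],
        planted_enriched=[g.gene_id for g in enriched],
        seed=seed + 3, pathway_size=max(2, n_enriched))
    return Study(genes=genes, entries=entries, pdb_texts=texts, truths=truths,
                 disease_variants=disease, neutral_variants=neutral,
                 annotations=annotations, planted_terms=planted)


def _shared_complexes(genes):
    out = [("CPLX1", (genes[0].protein_seq, genes[1].protein_seq),
            (genes[0].gene_id, genes[1].gene_id))]
    if len(genes) >= 3:
        out.append(("CPLX2", (genes[2].protein_seq, genes[2].protein_seq),
                    (genes[2].gene_id, genes[2].gene_id)))
    return out


def annotate_variants(variants: Sequence[Variant],
                      genes: Mapping[str, GeneRecord],
                      entries: Sequence[StructureEntry],
                      config: RunConfig = RunConfig(),
                      library: Sequence[ChainSeq] | None = None,
                      ) -> tuple[dict[str, list[TemplateHit]],
                                 list[AnnotatedVariant]]:
    """Template search + position mapping + per-template annotation +
    aggregation for a whole variant set."""
    if library is None:
        library = library_from_entries(entries)
    entry_by_id = {e.structure_id: e for e in entries}
    hits_by_gene: dict[str, list[TemplateHit]] = {}
    for gid in sorted({v.gene_id for v in variants}):
        gene = genes[gid]
        hits_by_gene[gid] = search_templates(
            gene, library, identity_threshold=config.identity_threshold,
            coverage_threshold=config.coverage_threshold,
            min_aligned_length=config.min_aligned_length)
    annotated: list[AnnotatedVariant] = []
    for v in variants:
        contexts = []
        for hit in hits_by_gene.get(v.gene_id, []):
            mp = map_positions(hit, [v.position])[0]
            if not mp.mapped:
                continue
            entry = entry_by_id[hit.structure_id]
            ctx = residue_context(entry, hit.chain_id, mp.template_index,
                                  exclude_het_codes=frozenset(
                                      config.excluded_ligands))
            contexts.append((hit, ctx))
        annotated.append(aggregate_over_templates(
            v, contexts, contact_threshold=config.contact_threshold_A,
            core_rsa_percent=config.core_rsa_percent))
    return hits_by_gene, annotated


def protein_scores_from_annotation(
        variants: Sequence[Variant], genes: Mapping[str, GeneRecord],
        entries: Sequence[StructureEntry], config: RunConfig = RunConfig(),
        library: Sequence[ChainSeq] | None = None) -> dict[str, float]:
    """Combined per-protein scores (max over templates of the mean candidate
    score of the protein's variants mapped in that template)."""
    if library is None:
        library = library_from_entries(entries)
    entry_by_id = {e.structure_id: e for e in entries}
    scores: dict[str, float] = {}
    for gid in sorted({v.gene_id for v in variants}):
        gene = genes[gid]
        gene_variants = [v for v in variants if v.gene_id == gid]
        hits = search_templates(
            gene, library, identity_threshold=config.identity_threshold,
            coverage_threshold=config.coverage_threshold,
            min_aligned_length=config.min_aligned_length)
        per_template: dict[tuple[str, str], list[float]] = {}
        for hit in hits:
            key = (hit.structure_id, hit.chain_id)
            for v in gene_variants:
                mp = map_positions(hit, [v.position])[0]
                if not mp.mapped:
                    continue
                ctx = residue_context(entry_by_id[hit.structure_id],
                                      hit.chain_id, mp.template_index)
                per_template.setdefault(key, []).append(
                    candidate_score(hit, ctx).score)
        scores[gid] = protein_combined_score(gid, per_template).score
    return scores


def annotated_frame(annotated: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        v = a.variant
        rows.append((v.gene_id, v.position, v.ref_aa, v.alt_aa,
                     v.dataset_label, a.structural_class, a.min_sld,
                     a.min_d_protein, a.min_d_dna, a.rsa, a.best_score,
                     a.n_templates, ";".join(a.contact_multiset)))
    return pd.DataFrame(rows, columns=[
        "gene_id", "position_1based", "ref_aa", "alt_aa", "dataset_label",
        "structural_class", "min_SLD", "min_D_protein", "min_D_DNA", "RSA",
        "candidate_score", "n_templates", "contacts"])


def run_all(study: Study, config: RunConfig = RunConfig(),
            outdir: str | Path | None = None) -> dict:
    """Full pipeline on a study; returns (and optionally writes) the report
    bundle with a machine-readable manifest of counts at every stage."""
    genes = study.gene_map()
    entries = study.entries
    library = study.library()

    all_variants = list(study.disease_variants) + list(study.neutral_variants)
    randomized = randomize_dataset(study.disease_variants, genes,
                                   seed=config.seed)
    hits, annotated = annotate_variants(all_variants + randomized, genes,
                                        entries, config, library)
    n_input = len(all_variants) + len(randomized)
    by_label: dict[str, list[AnnotatedVariant]] = {}
    for a in annotated:
        by_label.setdefault(a.variant.dataset_label, []).append(a)

    distributions = {}
    for label, group in by_label.items():
        dist = class_fractions(group)
        dist.sd = bootstrap_sd(group, B=config.bootstrap_B, seed=config.seed)
        distributions[label] = dist

    def _dists(group, attr):
        return [getattr(a, attr) for a in group
                if getattr(a, attr) is not None]

    labels = sorted(by_label)
    tests = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for attr in ("min_sld", "min_d_protein", "min_d_dna"):
                da, db = _dists(by_label[la], attr), _dists(by_label[lb], attr)
                if da and db:
                    tests.append((la, lb, attr, ranksum_test(da, db)))

    disease_scores = protein_scores_from_annotation(
        study.disease_variants, genes, entries, config, library)
    neutral_scores = protein_scores_from_annotation(
        study.neutral_variants, genes, entries, config, library)
    pw_d = pathway_scores(disease_scores, study.annotations)
    pw_n = pathway_scores(neutral_scores, study.annotations)
    ranking = differential_ranking(pw_d, pw_n, k=20)

    all_hits = [h for hs in hits.values() for h in hs]
    graph = build_network(all_hits, annotated,
                          identity_threshold=config.network_identity)
    complexes = multi_mutated_complexes(graph)

    manifest = {
        "config": asdict(config),
        "n_genes": len(study.genes),
        "n_structures": len(entries),
        "n_variants_input": n_input,
        "n_variants_mapped": sum(1 for a in annotated if a.mapped),
        "n_templates_total": len(all_hits),
        "datasets": {label: len(group) for label, group in by_label.items()},
        "n_network_edges": graph.number_of_edges(),
        "n_multi_mutated_complexes": len(complexes),
    }
    bundle = {
        "annotated": annotated,
        "distributions": distributions,
        "distance_tests": tests,
        "pathway_ranking": ranking,
        "network": graph,
        "complexes": complexes,
        "manifest": manifest,
    }
    if outdir is not None:
        _write_bundle(bundle, by_label, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, by_label: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    annotated_frame(bundle["annotated"]).to_csv(
        outdir / "annotated_variants.tsv", sep="\t", index=False)
    rows = []
    for label, dist in bundle["distributions"].items():
        for cls, fr in sorted(dist.fractions.items()):
            rows.append((label, cls, fr, dist.sd.get(cls, float("nan")),
                         dist.n_mapped, dist.n_unmapped))
    pd.DataFrame(rows, columns=["dataset", "class", "fraction",
                                "bootstrap_sd", "n_mapped", "n_unmapped"]
                 ).to_csv(outdir / "class_distributions.tsv", sep="\t",
                          index=False)
    pd.DataFrame(bundle["distance_tests"],
                 columns=["dataset_a", "dataset_b", "distance", "p_value"]
                 ).to_csv(outdir / "distance_tests.tsv", sep="\t", index=False)
    pd.DataFrame([(r.term_id, r.disease_score, r.neutral_score,
                   r.differential) for r in bundle["pathway_ranking"]],
                 columns=["term_id", "disease_score", "neutral_score",
                          "differential"]
                 ).to_csv(outdir / "pathway_ranking.tsv", sep="\t", index=False)
    edges_frame(bundle["network"]).to_csv(outdir / "network_edges.tsv",
                                          sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
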