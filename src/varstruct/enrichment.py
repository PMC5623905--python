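"""Protein-level combined scores and differential pathway / GO-term scoring.

Per protein, candidate scores of its variants are averaged within each
template and the maximum over templates is the combined score, so a protein
with a few high-scoring candidate substitutions outranks one with many
low-scoring ones.  Pathway (or GO-term) scores are the sum of member-protein
scores normalised by the number of represented members; pathways shared
between a disease-side and a neutral-side score map are ranked by the
difference of the two normalised scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import Variant, per_gene_counts, randomize_dataset


@dataclass(frozen=True)
class ProteinCombinedScore:
    gene_id: str
    score: float
    n_variants: int
    best_template: tuple[str, str] | None  # (structure_id, chain_id)


@dataclass(frozen=True)
class DifferentialScore:
    term_id: str
    disease_score: float
    neutral_score: float

    @property
    def differential(self) -> float:
        return self.disease_score - self.neutral_score


def protein_combined_score(
        gene_id: str,
        per_template_scores: Mapping[tuple[str, str], Sequence[float]],
        ) -> ProteinCombinedScore:
    """Max over templates of the mean candidate score of the gene's variants
    mapped in that template; 0 when nothing maps anywhere."""
    best, best_t = 0.0, None
    n = max((len(v) for v in per_template_scores.values()), default=0)
    for tmpl, scores in sorted(per_template_scores.items()):
        if not scores:
            continue
        m = float(np.mean(scores))
        if m > best:
            best, best_t = m, tmpl
    return ProteinCombinedScore(gene_id=gene_id, score=best, n_variants=n,
                                best_template=best_t)


def pathway_scores(protein_scores: Mapping[str, float],
                   annotations: pd.DataFrame,
                   namespace: str | None = None) -> dict[str, float]:
    """Per-term normalised score: sum of member scores / number of members
    represented in the data set.  Terms with no represented member are
    omitted.  Duplicate membership rows are ignored."""
    df = annotations
    if namespace is not None:
        df = df[df["namespace"] == namespace]
    df = df.drop_duplicates(subset=["gene_id", "term_id"])
    out: dict[str, float] = {}
    for term, members in df.groupby("term_id")["gene_id"]:
        present = [g for g in members if g in protein_scores]
        if not present:
            continue
        out[term] = float(sum(protein_scores[g] for g in present) / len(present))
    return out


def differential_ranking(disease: Mapping[str, float],
                         neutral: Mapping[str, float],
                         k: int = 20) -> list[DifferentialScore]:
    """Top-k terms shared by both sides, ranked by (disease - neutral)
    descending, ties broken by term id."""
    shared = sorted(set(disease) & set(neutral))
    if not shared:
        raise ValueError("no shared terms between the two score maps")
    rows = [DifferentialScore(t, disease[t], neutral[t]) for t in shared]
    rows.sort(key=lambda r: (-r.differential, r.term_id))
    return rows[:k]


def random_gene_control(gene_universe: Sequence, variants: Sequence[Variant],
                        n_genes: int = 10_000, seed: int = 0,
                        label: str = "random_control") -> list[Variant]:
    """Randomized comparison set: draw ``n_genes`` genes (with replacement
    when the universe is smaller), give each a variant count sampled i.i.d.
    from the empirical per-gene count distribution of ``variants``, and place
    the substitutions at random missense-producing nucleotide positions."""
    rng = np.random.default_rng(seed)
    counts = list(per_gene_counts(variants).values())
    if not counts:
        return []
    genes = list(gene_universe)
    replace = n_genes > len(genes)
    chosen_idx = rng.choice(len(genes), size=n_genes, replace=replace)
    seeds = rng.integers(0, 2**31 - 1, size=n_genes)
    out: list[Variant] = []
    for i, gi in enumerate(chosen_idx):
        gene = genes[int(gi)]
        c = int(counts[int(rng.integers(len(counts)))])
        if c == 0:
            continue
        pseudo = [Variant(gene.gene_id, 1, gene.protein_seq[0],
                          "A" if gene.protein_seq[0] != "A" else "G", label)
                  ] * c
        out.extend(randomize_dataset(pseudo, {gene.gene_id: gene},
                                     seed=int(seeds[i])))
    return out
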