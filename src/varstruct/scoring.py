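"""Candidate scores and the five-class spatial classification.

A mapped variant is placed into exactly one of five structural classes:
within 5 A of a DNA chain, a low-molecular-weight ligand, or another protein
chain (the closest partner wins, with a fixed DNA > Ligand > Protein priority
on exact ties), otherwise Core when the relative solvent accessibility is
below 16%, otherwise Surface.  Aggregation over templates takes per-category
minimum distances so a variant receives its fullest possible annotation.

The candidate score combines template quality with logistic contact weights
lig_cont = 1/(1+exp(SLD-10)) and chain_cont = 1/(1+exp(SCD-10)); the
interaction score IS is their maximum and candidate = template_score * IS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .structure import ResidueContext
from .templates import TemplateHit, template_score
from .variants import Variant

CLASS_SURFACE = "Surface"
CLASS_CORE = "Core"
CLASS_DNA = "DNA contact"
CLASS_LIGAND = "Ligand contact"
CLASS_PROTEIN = "Protein contact"
CLASS_UNMAPPED = "Unmapped"

CONTACT_CLASSES = (CLASS_DNA, CLASS_LIGAND, CLASS_PROTEIN)
ALL_CLASSES = (CLASS_SURFACE, CLASS_CORE, CLASS_DNA, CLASS_LIGAND, CLASS_PROTEIN)

DEFAULT_CONTACT_THRESHOLD = 5.0   # A, strict
DEFAULT_CORE_RSA = 16.0           # %, strict
# fixed priority on exactly equal minimum distances: rarest class wins
DEFAULT_TIE_PRIORITY = (CLASS_DNA, CLASS_LIGAND, CLASS_PROTEIN)


def _sigmoid_weight(distance: float | None, midpoint: float = 10.0) -> float:
    if distance is None:
        return 0.0
    return 1.0 / (1.0 + math.exp(distance - midpoint))


def interaction_weights(sld: float | None, scd: float | None,
                        ) -> tuple[float, float, float]:
    """(lig_cont, chain_cont, IS); absent distances weigh 0."""
    lig = _sigmoid_weight(sld)
    chain = _sigmoid_weight(scd)
    return lig, chain, max(lig, chain)


@dataclass(frozen=True)
class CandidateScore:
    seq_id: float
    cov: float
    res: float
    r: float
    lig_cont: float
    chain_cont: float
    interaction: float
    score: float


def candidate_score(hit: TemplateHit, ctx: ResidueContext) -> CandidateScore:
    """Per-template candidate score of one mapped variant position."""
    lig, chain, inter = interaction_weights(ctx.sld, ctx.scd)
    ts = template_score(hit)
    res = 1.0 / (1.0 + math.exp(1.5 * hit.resolution - 4.0)) \
        if hit.resolution is not None else 0.5
    r = 1.0 - hit.r_value if hit.r_value is not None else 0.5
    return CandidateScore(seq_id=hit.seq_id, cov=hit.cov, res=res, r=r,
                          lig_cont=lig, chain_cont=chain, interaction=inter,
                          score=ts * inter)


def classify_exclusive(min_sld: float | None, min_d_protein: float | None,
                       min_d_dna: float | None, rsa: float | None,
                       contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
                       core_rsa_percent: float = DEFAULT_CORE_RSA,
                       tie_priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
                       ) -> str:
    """The exclusive five-class rule applied to aggregated minima."""
    contacts = []
    for label, d in ((CLASS_DNA, min_d_dna), (CLASS_LIGAND, min_sld),
                     (CLASS_PROTEIN, min_d_protein)):
        if d is not None and d < contact_threshold:
            contacts.append((d, tie_priority.index(label), label))
    if contacts:
        return min(contacts)[2]
    if rsa is not None and rsa < core_rsa_percent:
        return CLASS_CORE
    return CLASS_SURFACE


@dataclass
class AnnotatedVariant:
    variant: Variant
    structural_class: str
    min_sld: float | None = None
    min_d_protein: float | None = None
    min_d_dna: float | None = None
    rsa: float | None = None
    best_score: float = 0.0
    n_templates: int = 0
    contact_multiset: tuple[str, ...] = ()
    ligand_distances: dict[str, float] = field(default_factory=dict)
    class_template: tuple[str, str] | None = None  # (structure, chain)

    @property
    def mapped(self) -> bool:
        return self.structural_class != CLASS_UNMAPPED


def aggregate_over_templates(variant: Variant,
                             contexts: Sequence[tuple[TemplateHit, ResidueContext]],
                             contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
                             core_rsa_percent: float = DEFAULT_CORE_RSA,
                             tie_priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
                             ) -> AnnotatedVariant:
    """Fold all per-template contexts of one variant into one annotation.

    Per-category minima are taken across templates; the RSA used for the
    Core/Surface decision comes from the template providing the overall
    minimum distance, or from the best-scoring template when no partner was
    seen anywhere.  The contact multiset lists every category with a sub-
    threshold distance in any template (the non-exclusive view).
    """
    if not contexts:
        return AnnotatedVariant(variant=variant,
                                structural_class=CLASS_UNMAPPED)
    min_sld = min_prot = min_dna = None
    lig_dists: dict[str, float] = {}
    best_score = 0.0
    contact_set: set[str] = set()
    source_by_dist: list[tuple[float, TemplateHit, ResidueContext]] = []
    best_ts: tuple[float, TemplateHit, ResidueContext] | None = None
    for hit, ctx in contexts:
        cs = candidate_score(hit, ctx)
        best_score = max(best_score, cs.score)
        ts = template_score(hit)
        if best_ts is None or ts > best_ts[0]:
            best_ts = (ts, hit, ctx)
        for d, which in ((ctx.sld, "sld"), (ctx.d_protein, "prot"),
                         (ctx.d_dna, "dna")):
            if d is None:
                continue
            source_by_dist.append((d, hit, ctx))
        if ctx.sld is not None:
            min_sld = ctx.sld if min_sld is None else min(min_sld, ctx.sld)
            if ctx.sld < contact_threshold:
                contact_set.add(CLASS_LIGAND)
        if ctx.d_protein is not None:
            min_prot = ctx.d_protein if min_prot is None else min(min_prot, ctx.d_protein)
            if ctx.d_protein < contact_threshold:
                contact_set.add(CLASS_PROTEIN)
        if ctx.d_dna is not None:
            min_dna = ctx.d_dna if min_dna is None else min(min_dna, ctx.d_dna)
            if ctx.d_dna < contact_threshold:
                contact_set.add(CLASS_DNA)
        for key, d in ctx.ligand_distances.items():
            lig_dists[key] = min(d, lig_dists.get(key, math.inf))
    if source_by_dist:
        _, hit, ctx = min(source_by_dist, key=lambda t: t[0])
    else:
        _, hit, ctx = best_ts
    rsa = ctx.rsa
    label = classify_exclusive(min_sld, min_prot, min_dna, rsa,
                               contact_threshold, core_rsa_percent,
                               tie_priority)
    return AnnotatedVariant(
        variant=variant, structural_class=label, min_sld=min_sld,
        min_d_protein=min_prot, min_d_dna=min_dna, rsa=rsa,
        best_score=best_score, n_templates=len(contexts),
        contact_multiset=tuple(sorted(contact_set)),
        ligand_distances=dict(lig_dists),
        class_template=(ctx.structure_id, ctx.chain_id))


def reclassify_excluding_ligands(annotated: Sequence[AnnotatedVariant],
                                 excluded_het_codes: Iterable[str],
                                 contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
                                 core_rsa_percent: float = DEFAULT_CORE_RSA,
                                 ) -> tuple[list[AnnotatedVariant],
                                            list[tuple[Variant, str, str]]]:
    """Re-run classification with distances to the named ligand codes
    removed (the drug-exclusion re-analysis).  Returns the new annotations
    and a change log of (variant, old class, new class) for every flip."""
    excluded = set(excluded_het_codes)
    out, changes = [], []
    for av in annotated:
        if not av.mapped:
            out.append(av)
            continue
        kept = {k: d for k, d in av.ligand_distances.items()
                if k.split(":", 1)[0] not in excluded}
        new_sld = min(kept.values()) if kept else None
        label = classify_exclusive(new_sld, av.min_d_protein, av.min_d_dna,
                                   av.rsa, contact_threshold, core_rsa_percent)
        multiset = set()
        for cls, d in ((CLASS_LIGAND, new_sld),
                       (CLASS_PROTEIN, av.min_d_protein),
                       (CLASS_DNA, av.min_d_dna)):
            if d is not None and d < contact_threshold:
                multiset.add(cls)
        new = AnnotatedVariant(
            variant=av.variant, structural_class=label, min_sld=new_sld,
            min_d_protein=av.min_d_protein, min_d_dna=av.min_d_dna,
            rsa=av.rsa, best_score=av.best_score, n_templates=av.n_templates,
            contact_multiset=tuple(sorted(multiset)), ligand_distances=kept,
            class_template=av.class_template)
        out.append(new)
        if label != av.structural_class:
            changes.append((av.variant, av.structural_class, label))
    return out, changes
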