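"""Homology template search, position mapping and template quality scores.

Each gene's protein sequence is aligned against every protein chain of the
structure library with an EMBOSS-style global alignment (BLOSUM62, gap open
10, gap extend 0.5, free end gaps).  A chain qualifies as a template when
sequence identity exceeds 35% and the alignment covers more than half of the
shorter sequence or spans more than 50 residues; when a pluggable external
search supplies e-values, hits at e-value >= 1e-5 are dropped.  Variant
positions are carried through the alignment columns; a position aligned to a
gap discards that template for that variant.

Template quality combines four normalised attributes - sequence identity,
target coverage, a resolution sigmoid res = 1/(1+exp(1.5*resolution-4)) and
r = 1 - R-value - as their (configurable, by default equally weighted) mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import StructureEntry

DEFAULT_IDENTITY_THRESHOLD = 0.35
DEFAULT_COVERAGE_THRESHOLD = 0.5
DEFAULT_MIN_ALIGNED_LENGTH = 50
DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class ChainSeq:
    """One structure chain available as a potential template."""

    structure_id: str
    chain_id: str
    sequence: str
    resolution: float | None = None
    r_value: float | None = None


@dataclass(frozen=True)
class TemplateHit:
    gene_id: str
    structure_id: str
    chain_id: str
    seq_id: float            # identical / aligned (non-double-gap) columns
    cov: float               # aligned target residues / target length
    aligned_length: int      # columns with a residue on both rows
    alignment: tuple[str, str]  # gapped (target, template) strings
    resolution: float | None = None
    r_value: float | None = None
    evalue: float | None = None


@dataclass(frozen=True)
class MappedPosition:
    gene_id: str
    position: int
    structure_id: str
    chain_id: str
    template_index: int | None  # 1-based residue index in the chain
    mapped: bool


def library_from_entries(entries: Iterable[StructureEntry]) -> list[ChainSeq]:
    """Chain sequences of the protein chains of parsed structures."""
    lib = []
    for e in entries:
        for ch in e.protein_chains():
            lib.append(ChainSeq(e.structure_id, ch.chain_id, ch.sequence(),
                                e.resolution, e.r_value))
    return lib


@lru_cache(maxsize=1)
def _aligner(open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -open_gap
    al.extend_gap_score = -extend_gap
    # EMBOSS needle convention: end gaps are free
    al.end_gap_score = 0.0
    return al


def align_global(target: str, template: str, open_gap: float = 10.0,
                 extend_gap: float = 0.5) -> tuple[str, str]:
    """Gapped (target, template) strings of the optimal global alignment."""
    aln = _aligner(open_gap, extend_gap).align(target, template)[0]
    return str(aln[0]), str(aln[1])


def alignment_stats(gapped_target: str, gapped_template: str,
                    ) -> tuple[float, float, int]:
    """(seq_id, target coverage, aligned length) of a gapped pair."""
    ident = aligned = covered = 0
    target_len = sum(1 for c in gapped_target if c != "-")
    for a, b in zip(gapped_target, gapped_template):
        if a == "-" and b == "-":
            continue
        aligned += 1
        if a != "-" and b != "-":
            covered += 1
            if a == b:
                ident += 1
    seq_id = ident / aligned if aligned else 0.0
    cov = covered / target_len if target_len else 0.0
    return seq_id, cov, covered


def passes_filters(seq_id: float, aligned_length: int, target_len: int,
                   template_len: int, evalue: float | None = None,
                   identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                   coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                   min_aligned_length: int = DEFAULT_MIN_ALIGNED_LENGTH,
                   evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> bool:
    """Template admission rule: identity > 35% and (coverage > 50% of the
    shorter sequence or aligned span > 50 residues); e-value < 1e-5 when an
    external search provides one."""
    if evalue is not None and evalue >= evalue_cutoff:
        return False
    if seq_id <= identity_threshold:
        return False
    shorter = min(target_len, template_len)
    cov_shorter = aligned_length / shorter if shorter else 0.0
    return cov_shorter > coverage_threshold or aligned_length > min_aligned_length


def search_templates(gene, library: Sequence[ChainSeq],
                     evalues: Mapping[tuple[str, str], float] | None = None,
                     identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                     coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                     min_aligned_length: int = DEFAULT_MIN_ALIGNED_LENGTH,
                     open_gap: float = 10.0, extend_gap: float = 0.5,
                     ) -> list[TemplateHit]:
    """All library chains admissible as templates for one gene, sorted by
    sequence identity descending (ties by structure and chain id)."""
    hits = []
    for cs in library:
        if not cs.sequence:
            continue
        gt, gq = align_global(gene.protein_seq, cs.sequence, open_gap, extend_gap)
        seq_id, cov, alen = alignment_stats(gt, gq)
        ev = None if evalues is None else evalues.get(
            (cs.structure_id, cs.chain_id))
        if not passes_filters(seq_id, alen, len(gene.protein_seq),
                              len(cs.sequence), ev, identity_threshold,
                              coverage_threshold, min_aligned_length):
            continue
        hits.append(TemplateHit(
            gene_id=gene.gene_id, structure_id=cs.structure_id,
            chain_id=cs.chain_id, seq_id=seq_id, cov=cov, aligned_length=alen,
            alignment=(gt, gq), resolution=cs.resolution, r_value=cs.r_value,
            evalue=ev))
    hits.sort(key=lambda h: (-h.seq_id, h.structure_id, h.chain_id))
    return hits


def map_positions(hit: TemplateHit, positions: Iterable[int],
                  ) -> list[MappedPosition]:
    """Translate 1-based gene positions through the alignment columns.

    A position aligned to a gap in the template row comes back with
    ``mapped=False`` (that template is discarded for that variant).
    """
    gt, gq = hit.alignment
    lookup: dict[int, int | None] = {}
    ti = qi = 0
    for a, b in zip(gt, gq):
        if a != "-":
            ti += 1
        if b != "-":
            qi += 1
        if a != "-":
            lookup[ti] = qi if b != "-" else None
    out = []
    for pos in positions:
        idx = lookup.get(pos)
        out.append(MappedPosition(hit.gene_id, pos, hit.structure_id,
                                  hit.chain_id, idx, idx is not None))
    return out


def resolution_weight(resolution: float | None) -> float:
    """Sigmoid quality weight of crystallographic resolution; 0.5 at 8/3 A,
    approaching 1 for very high resolution.  Missing resolution -> 0.5."""
    if resolution is None:
        return 0.5
    return 1.0 / (1.0 + math.exp(1.5 * resolution - 4.0))


def template_score(hit: TemplateHit,
                   weights: tuple[float, float, float, float] = (1, 1, 1, 1),
                   ) -> float:
    """Weighted mean of (seq_id, cov, res, 1 - R-value) in [0, 1].

    Missing resolution or R-value contributes a neutral 0.5.
    """
    res = resolution_weight(hit.resolution)
    r = 1.0 - hit.r_value if hit.r_value is not None else 0.5
    comps = (hit.seq_id, hit.cov, res, r)
    wsum = sum(weights)
    return sum(w * c for w, c in zip(weights, comps)) / wsum
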