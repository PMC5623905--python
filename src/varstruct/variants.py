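"""Variant data sets: loading, deduplication, overlap removal, randomization.

A variant here is one amino-acid substitution caused by a single-nucleotide
change in a coding sequence, tagged with the data set it belongs to (e.g.
cancer germline/somatic, non-cancer disease, common, benign).  Disease sets
are cleaned against neutral sets by removing exact matches, and each data set
has a randomized control twin: the same genes, the same per-gene variant
counts, but substitutions placed at random nucleotide positions (resampled
until the codon change is missense).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from ._aa import CODON_TABLE, NUCLEOTIDES, translate_cds

VARIANT_COLUMNS = ["gene_id", "position_1based", "ref_aa", "alt_aa", "dataset_label"]


@dataclass(frozen=True)
class GeneRecord:
    """A gene: protein sequence plus the consistent coding sequence.

    The coding sequence includes the terminal stop codon, so
    ``len(cds) == 3 * len(protein_seq) + 3``.
    """

    gene_id: str
    protein_seq: str
    cds: str
    isoform_tag: str | None = None

    def __post_init__(self) -> None:
        if translate_cds(self.cds) != self.protein_seq:
            raise ValueError(
                f"{self.gene_id}: coding sequence does not translate to the "
                f"protein sequence")

    def codon(self, position: int) -> str:
        """Codon for 1-based protein position (CDS nt 3k-2..3k)."""
        return self.cds[3 * (position - 1):3 * position]


@dataclass(frozen=True)
class Variant:
    gene_id: str
    position: int           # 1-based protein coordinate
    ref_aa: str
    alt_aa: str
    dataset_label: str
    multiplicity: int = 1   # collapsed duplicate rows

    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class Rejection:
    row: int
    gene_id: str
    reason: str


def variants_to_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.gene_id, v.position, v.ref_aa, v.alt_aa, v.dataset_label)
         for v in variants], columns=VARIANT_COLUMNS)


def write_variants(variants: Iterable[Variant], path_or_buf) -> None:
    variants_to_frame(variants).to_csv(path_or_buf, sep="\t", index=False)


def load_variants(source: str | TextIO, genes: Mapping[str, GeneRecord],
                  ) -> tuple[list[Variant], list[Rejection]]:
    """Read a variant TSV, validating every row against the gene sequences.

    Rows that violate an invariant (unknown gene, position out of range, ref
    mismatch, silent substitution) are rejected with a row-numbered
    diagnostic instead of aborting the load.  Duplicate
    (gene, position, ref, alt) rows within one dataset label are collapsed to
    a single variant whose ``multiplicity`` records the row count.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    accepted: dict[tuple, Variant] = {}
    rejections: list[Rejection] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        gid = row.gene_id
        gene = genes.get(gid)
        if gene is None:
            rejections.append(Rejection(i, gid, "unknown gene"))
            continue
        try:
            pos = int(row.position_1based)
        except (TypeError, ValueError):
            rejections.append(Rejection(i, gid, "non-integer position"))
            continue
        if not 1 <= pos <= len(gene.protein_seq):
            rejections.append(Rejection(i, gid, "position out of range"))
            continue
        if gene.protein_seq[pos - 1] != row.ref_aa:
            rejections.append(Rejection(i, gid, "ref mismatch"))
            continue
        if row.ref_aa == row.alt_aa:
            rejections.append(Rejection(i, gid, "not a substitution"))
            continue
        key = (gid, pos, row.ref_aa, row.alt_aa, row.dataset_label)
        if key in accepted:
            v = accepted[key]
            accepted[key] = replace(v, multiplicity=v.multiplicity + 1)
        else:
            accepted[key] = Variant(gid, pos, row.ref_aa, row.alt_aa,
                                    row.dataset_label)
    return list(accepted.values()), rejections


def write_rejections(rejections: Iterable[Rejection], path_or_buf) -> None:
    pd.DataFrame([(r.row, r.gene_id, r.reason) for r in rejections],
                 columns=["row", "gene_id", "reason"]).to_csv(
        path_or_buf, sep="\t", index=False)


def remove_neutral_overlap(disease: Sequence[Variant],
                           neutral: Sequence[Variant],
                           ) -> tuple[list[Variant], int]:
    """Drop from the disease set every exact (gene, position, ref, alt) match
    present in a neutral set; returns (cleaned set, number removed)."""
    neutral_keys = {v.key() for v in neutral}
    kept = [v for v in disease if v.key() not in neutral_keys]
    return kept, len(disease) - len(kept)


def per_gene_counts(variants: Sequence[Variant]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.gene_id] = counts.get(v.gene_id, 0) + 1
    return counts


def missense_site_weights(gene: GeneRecord) -> np.ndarray:
    """Per-nucleotide count of alternative bases producing a missense change
    (length 3·|protein|; the stop codon is not mutated)."""
    n = 3 * len(gene.protein_seq)
    weights = np.zeros(n, dtype=int)
    for k in range(len(gene.protein_seq)):
        codon = gene.codon(k + 1)
        ref_aa = CODON_TABLE[codon]
        for off in range(3):
            for base in NUCLEOTIDES:
                if base == codon[off]:
                    continue
                aa = CODON_TABLE[codon[:off] + base + codon[off + 1:]]
                if aa != ref_aa and aa != "*":
                    weights[3 * k + off] += 1
    return weights


def randomize_dataset(variants: Sequence[Variant],
                      genes: Mapping[str, GeneRecord], seed: int = 0,
                      max_attempts: int = 10_000) -> list[Variant]:
    """Randomized control twin of a variant set.

    For each gene the same number of substitutions is introduced at uniformly
    drawn nucleotide positions of the coding sequence with a uniformly drawn
    alternative base; synonymous and stop-gain draws are rejection-resampled
    so the output is a pure missense set.  Draws are with replacement across
    sites, so recurrent positions can occur, as in real data.  Labels become
    ``randomized:<parent label>``.
    """
    rng = np.random.default_rng(seed)
    counts = per_gene_counts(variants)
    label_of = {v.gene_id: v.dataset_label for v in variants}
    out: list[Variant] = []
    for gid in sorted(counts):
        gene = genes.get(gid)
        if gene is None:
            raise KeyError(f"no gene record for {gid}")
        n_sites = 3 * len(gene.protein_seq)
        if missense_site_weights(gene).sum() == 0:
            raise ValueError(f"gene {gid} admits no missense change")
        label = f"randomized:{label_of[gid]}"
        for _ in range(counts[gid]):
            for _attempt in range(max_attempts):
                nt = int(rng.integers(n_sites))
                codon_idx, off = divmod(nt, 3)
                codon = gene.codon(codon_idx + 1)
                base = NUCLEOTIDES[int(rng.integers(4))]
                if base == codon[off]:
                    continue
                new_codon = codon[:off] + base + codon[off + 1:]
                new_aa = CODON_TABLE[new_codon]
                ref_aa = CODON_TABLE[codon]
                if new_aa == ref_aa or new_aa == "*":
                    continue
                out.append(Variant(gid, codon_idx + 1, ref_aa, new_aa, label))
                break
            else:  # pragma: no cover - max_attempts is generous
                raise RuntimeError(f"resampling stalled for gene {gid}")
    return out
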