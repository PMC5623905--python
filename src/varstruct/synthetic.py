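"""Synthetic structures, genes, variant sets and annotation tables.

Every downstream stage of the pipeline (template search, distance and
accessibility annotation, spatial classification, enrichment) is exercised on
data produced here, with full ground truth: each designated residue of a toy
complex carries a planted structural class and a planted partner distance.

Toy complexes are deliberately unphysical but geometrically exact.  Protein
chains are laid out as extended strands with one pseudo side-chain atom per
residue and a residue spacing of 8 A, which guarantees that an interaction
partner planted at < 8 A from a designated residue stays >= 8 A away from
every other residue of the chain.  Partners (small-molecule ligands, DNA
duplexes, extra protein chains) are placed along the side-chain direction at a
controlled minimum inter-atomic distance; buried ("Core") residues are
realised by enclosing them in a same-chain occlusion cage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._aa import (
    AA1,
    AA1_TO_3,
    CODONS_FOR_AA,
    NUCLEOTIDES,
    STOP_CODONS,
    translate_cds,
)
from .variants import GeneRecord, Variant

RESIDUE_SPACING = 8.0     # A between consecutive residues along the chain axis
CHAIN_SPACING = 60.0      # A between stacked protein chains of one complex
CONTACT_THRESHOLD = 5.0   # A; planted labels follow the same rule as the classifier
CAGE_RADIUS = 4.6         # A; occlusion shell radius for planted Core residues
CAGE_POINTS = 60

# local residue geometry: CA at origin, chain axis +x, side chain +y
_RESIDUE_TEMPLATE = (
    ("N", "N", (-1.2, -0.7, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, -0.7, 0.0)),
    ("O", "O", (1.2, -1.9, 0.0)),
    ("CB", "C", (0.0, 1.5, 0.0)),
)

_DNA_COMPLEMENT = {"DA": "DT", "DT": "DA", "DC": "DG", "DG": "DC"}

CLASS_LIGAND = "Ligand contact"
CLASS_DNA = "DNA contact"
CLASS_PROTEIN = "Protein contact"
CLASS_CORE = "Core"
CLASS_SURFACE = "Surface"


class GeometryError(ValueError):
    """Raised when a complex specification demands clashing placements."""


@dataclass(frozen=True)
class Placement:
    """One partner planted at a controlled distance from a designated residue.

    ``distance`` is the target minimum inter-atomic distance in Angstrom
    between the designated residue and the nearest partner atom.
    """

    chain: str
    residue: int          # 1-based index within the chain
    distance: float
    het_code: str = "LIG"  # only meaningful for ligand placements


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for one toy multi-chain complex.

    Chains are named ``A``, ``B``, ... in order.  ``chain_sequences``
    overrides ``chain_lengths`` and lets chains carry real gene sequences so
    that template search maps variants onto them; ``chain_gene_ids`` records
    which gene each chain stands for (used in the planted truth table).
    """

    n_protein_chains: int = 1
    chain_lengths: Sequence[int] = (30,)
    chain_sequences: Sequence[str] | None = None
    chain_gene_ids: Sequence[str] | None = None
    ligand_placements: Sequence[Placement] = ()
    dna_placements: Sequence[Placement] = ()
    partner_chain_placements: Sequence[Placement] = ()
    core_residues: Sequence[tuple[str, int]] = ()
    surface_residues: Sequence[tuple[str, int]] = ()
    structure_id: str = "TOY1"
    resolution: float = 1.8
    r_value: float = 0.2
    seed: int = 0

    def lengths(self) -> list[int]:
        if self.chain_sequences is not None:
            return [len(s) for s in self.chain_sequences]
        return list(self.chain_lengths)

    def chain_ids(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_protein_chains)]


@dataclass(frozen=True)
class PlantedResidue:
    chain_id: str
    residue: int
    gene_id: str | None
    intended_class: str
    intended_distance: float | None  # min over this residue's placements, A


@dataclass
class PlantedTruth:
    """Ground truth for the designated residues of one toy complex."""

    structure_id: str
    residues: list[PlantedResidue] = field(default_factory=list)

    def by_class(self, label: str) -> list[PlantedResidue]:
        return [r for r in self.residues if r.intended_class == label]

    def lookup(self, chain_id: str, residue: int) -> PlantedResidue | None:
        for r in self.residues:
            if r.chain_id == chain_id and r.residue == residue:
                return r
        return None


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class _Builder:
    """Collects atoms and renders fixed-width PDB records."""

    def __init__(self) -> None:
        self.rows: list[tuple] = []  # (het, name, elem, resname, chain, resnum, xyz)

    def add(self, het: bool, name: str, element: str, res_name: str,
            chain_id: str, res_num: int, xyz: Sequence[float]) -> None:
        self.rows.append((het, name, element, res_name, chain_id, res_num,
                          (float(xyz[0]), float(xyz[1]), float(xyz[2]))))

    def atoms_of_residue(self, chain_id: str, res_num: int) -> np.ndarray:
        pts = [r[6] for r in self.rows
               if r[4] == chain_id and r[5] == res_num and not r[0]]
        return np.asarray(pts)

    def render(self, structure_id: str, resolution: float, r_value: float) -> str:
        lines = [
            f"HEADER    SYNTHETIC COMPLEX                       01-JAN-00   {structure_id:<4s}",
            "REMARK   2",
            f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.",
            "REMARK   3",
            f"REMARK   3   R VALUE            (WORKING SET) : {r_value:.3f}",
        ]
        serial = 0
        prev_chain = None
        prev_polymer_row = None
        for het, name, elem, res_name, chain_id, res_num, (x, y, z) in self.rows:
            if prev_chain is not None and chain_id != prev_chain and prev_polymer_row:
                lines.append(self._ter(serial + 1, prev_polymer_row))
                serial += 1
            serial += 1
            record = "HETATM" if het else "ATOM  "
            aname = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"{record}{serial:>5d} {aname}{'':1s}{res_name:>3s} {chain_id}"
                f"{res_num:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {elem:>2s}"
            )
            prev_chain = chain_id
            prev_polymer_row = None if het else (res_name, chain_id, res_num)
        if prev_polymer_row:
            serial += 1
            lines.append(self._ter(serial, prev_polymer_row))
        lines.append("END")
        return "\n".join(lines) + "\n"

    @staticmethod
    def _ter(serial: int, row: tuple) -> str:
        res_name, chain_id, res_num = row
        return f"TER   {serial:>5d}      {res_name:>3s} {chain_id}{res_num:>4d}"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA1), size=length))


def _solve_offset(partner_local: np.ndarray, residue_atoms: np.ndarray,
                  anchor: np.ndarray, target: float) -> np.ndarray:
    """Translate a rigid partner along +y above ``anchor`` so that its minimum
    inter-atomic distance to ``residue_atoms`` equals ``target`` (bisection;
    the distance is monotone in the shift once the partner is above the
    residue)."""

    def min_dist(t: float) -> float:
        pts = partner_local + anchor + np.array([0.0, t, 0.0])
        d = np.linalg.norm(residue_atoms[:, None, :] - pts[None, :, :], axis=-1)
        return float(d.min())

    lo, hi = 0.0, target + 30.0
    if min_dist(lo) > target:
        lo = -10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return anchor + np.array([0.0, 0.5 * (lo + hi), 0.0])


def make_toy_complex(spec: ComplexSpec, path: str | Path | None = None,
                     ) -> tuple[str, PlantedTruth]:
    """Build one toy complex; returns the PDB text and its planted truth.

    Raises :class:`GeometryError` when two placements demand overlapping atoms
    or a placement would violate the >= 8 A clearance of non-designated
    residues.  Output is a pure function of the spec (byte-identical across
    runs for the same spec and seed).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = spec.lengths()
    if spec.n_protein_chains != len(lengths):
        raise ValueError("chain_lengths/chain_sequences must match n_protein_chains")
    chain_ids = spec.chain_ids()
    sequences = (list(spec.chain_sequences) if spec.chain_sequences is not None
                 else [_random_protein(rng, n) for n in lengths])
    gene_ids = (list(spec.chain_gene_ids) if spec.chain_gene_ids is not None
                else [None] * len(chain_ids))

    _validate_spec(spec, chain_ids, lengths)

    b = _Builder()
    chain_z = {cid: CHAIN_SPACING * i for i, cid in enumerate(chain_ids)}
    for cid, seq in zip(chain_ids, sequences):
        z = chain_z[cid]
        for j, aa in enumerate(seq, start=1):
            x0 = RESIDUE_SPACING * (j - 1)
            for name, elem, (lx, ly, lz) in _RESIDUE_TEMPLATE:
                b.add(False, name, elem, AA1_TO_3[aa], cid, j, (x0 + lx, ly, z + lz))

    next_chain_ord = ord("A") + len(chain_ids)
    placed_partner_atoms: list[np.ndarray] = []
    group_of_chain: dict[str, int] = {}
    group_counter = [0]
    truth = PlantedTruth(structure_id=spec.structure_id)
    planted: dict[tuple[str, int], list[tuple[str, float]]] = {}

    def anchor_of(p: Placement) -> np.ndarray:
        x0 = RESIDUE_SPACING * (p.residue - 1)
        return np.array([x0, 1.5, chain_z[p.chain]])

    def register(p: Placement, kind: str, realized: float,
                 atoms: np.ndarray) -> None:
        planted.setdefault((p.chain, p.residue), []).append((kind, realized))
        placed_partner_atoms.append(atoms)

    for p in spec.ligand_placements:
        jitter = float(rng.uniform(-0.1, 0.1))
        target = p.distance + jitter
        local = np.array([[0.0, 0.0, 0.0], [0.3, 1.5, 0.3], [0.0, 3.0, 0.0]])
        res_atoms = b.atoms_of_residue(p.chain, p.residue)
        origin = _solve_offset(local, res_atoms, anchor_of(p), target)
        pts = local + origin
        cid = chr(next_chain_ord)
        next_chain_ord += 1
        group_of_chain[cid] = group_counter[0]
        group_counter[0] += 1
        for k, (name, elem) in enumerate([("C1", "C"), ("C2", "C"), ("O1", "O")]):
            b.add(True, name, elem, p.het_code, cid, 1, pts[k])
        register(p, CLASS_LIGAND, target, pts)

    for p in spec.dna_placements:
        jitter = float(rng.uniform(-0.1, 0.1))
        target = p.distance + jitter
        local_rows = []
        res_names_1 = [rng.choice(["DA", "DC", "DG", "DT"]) for _ in range(4)]
        atoms1, atoms2 = [], []
        for n, zoff in enumerate((-3.4, 0.0, 3.4, 6.8)):
            base = np.array([0.0, 0.0, zoff])
            atoms1.append(("N1", "N", base))
            atoms1.append(("C1'", "C", base + [0.4, 1.5, 0.4]))
            atoms1.append(("P", "P", base + [0.0, 3.0, 0.0]))
            atoms2.append(("N1", "N", base + [0.0, 5.0, 0.0]))
            atoms2.append(("C1'", "C", base + [0.4, 6.5, 0.4]))
            atoms2.append(("P", "P", base + [0.0, 8.0, 0.0]))
        local = np.array([a[2] for a in atoms1 + atoms2], dtype=float)
        res_atoms = b.atoms_of_residue(p.chain, p.residue)
        origin = _solve_offset(local, res_atoms, anchor_of(p), target)
        pts = local + origin
        cid1, cid2 = chr(next_chain_ord), chr(next_chain_ord + 1)
        next_chain_ord += 2
        group_of_chain[cid1] = group_of_chain[cid2] = group_counter[0]
        group_counter[0] += 1
        for n in range(4):
            for k in range(3):
                name, elem, _ = atoms1[3 * n + k]
                b.add(False, name, elem, res_names_1[n], cid1, n + 1, pts[3 * n + k])
        for n in range(4):
            for k in range(3):
                name, elem, _ = atoms2[3 * n + k]
                b.add(False, name, elem, _DNA_COMPLEMENT[res_names_1[n]], cid2,
                      n + 1, pts[12 + 3 * n + k])
        register(p, CLASS_DNA, target, pts)

    for p in spec.partner_chain_placements:
        jitter = float(rng.uniform(-0.1, 0.1))
        target = p.distance + jitter
        seq = _random_protein(rng, 4)
        local_rows = []
        for k, zoff in enumerate((-8.0, 0.0, 8.0, 16.0)):
            # side chain points down toward the designated residue
            local_rows += [
                ("N", "N", (0.0, 2.2, zoff - 1.2)),
                ("CA", "C", (0.0, 1.5, zoff)),
                ("C", "C", (0.0, 2.2, zoff + 1.2)),
                ("O", "O", (0.0, 3.4, zoff + 1.2)),
                ("CB", "C", (0.0, 0.0, zoff)),
            ]
        local = np.array([r[2] for r in local_rows], dtype=float)
        res_atoms = b.atoms_of_residue(p.chain, p.residue)
        origin = _solve_offset(local, res_atoms, anchor_of(p), target)
        pts = local + origin
        cid = chr(next_chain_ord)
        next_chain_ord += 1
        group_of_chain[cid] = group_counter[0]
        group_counter[0] += 1
        for k in range(4):
            for a in range(5):
                name, elem, _ = local_rows[5 * k + a]
                b.add(False, name, elem, AA1_TO_3[seq[k]], cid, k + 1,
                      pts[5 * k + a])
        register(p, CLASS_PROTEIN, target, pts)

    # occlusion cages for planted Core residues: one extra same-chain residue
    # whose atoms tile a sphere around the designated residue
    cage_counter: dict[str, int] = {}
    for cid, j in spec.core_residues:
        length = lengths[chain_ids.index(cid)]
        center = np.array([RESIDUE_SPACING * (j - 1), 0.5, chain_z[cid]])
        shell = center + CAGE_RADIUS * _fibonacci_sphere(CAGE_POINTS)
        cage_counter[cid] = cage_counter.get(cid, 0) + 1
        res_num = length + cage_counter[cid]
        for k, xyz in enumerate(shell):
            b.add(False, f"C{k:02d}", "C", "UNK", cid, res_num, xyz)

    _check_clearance(b, spec, chain_ids, lengths, planted, group_of_chain)

    for (cid, j), kinds in sorted(planted.items()):
        gid = gene_ids[chain_ids.index(cid)]
        contacts = [(k, d) for k, d in kinds if d < CONTACT_THRESHOLD]
        dmin = min(d for _, d in kinds)
        if contacts:
            label = min(contacts, key=lambda kd: kd[1])[0]
        else:
            label = CLASS_SURFACE
        truth.residues.append(PlantedResidue(cid, j, gid, label, dmin))
    for cid, j in spec.core_residues:
        gid = gene_ids[chain_ids.index(cid)]
        truth.residues.append(PlantedResidue(cid, j, gid, CLASS_CORE, None))
    for cid, j in spec.surface_residues:
        gid = gene_ids[chain_ids.index(cid)]
        truth.residues.append(PlantedResidue(cid, j, gid, CLASS_SURFACE, None))
    truth.residues.sort(key=lambda r: (r.chain_id, r.residue))

    text = b.render(spec.structure_id, spec.resolution, spec.r_value)
    if path is not None:
        Path(path).write_text(text)
    return text, truth


def _validate_spec(spec: ComplexSpec, chain_ids: list[str],
                   lengths: list[int]) -> None:
    length_of = dict(zip(chain_ids, lengths))
    all_placements = (list(spec.ligand_placements) + list(spec.dna_placements)
                      + list(spec.partner_chain_placements))
    for p in all_placements:
        if p.chain not in length_of:
            raise ValueError(f"placement on unknown chain {p.chain!r}")
        if not 1 <= p.residue <= length_of[p.chain]:
            raise ValueError(
                f"placement residue {p.residue} outside chain {p.chain} "
                f"(length {length_of[p.chain]})")
        if p.distance <= 0:
            raise ValueError("target distance must be > 0")
        if p.distance >= RESIDUE_SPACING:
            raise GeometryError(
                f"target distance {p.distance} A on {p.chain}{p.residue} "
                f"exceeds the {RESIDUE_SPACING} A clearance budget")
    seen: dict[tuple[str, int], int] = {}
    for p in all_placements:
        seen[(p.chain, p.residue)] = seen.get((p.chain, p.residue), 0) + 1
    if any(n > 1 for n in seen.values()):
        # multiple partners stacked over one residue would overlap
        clash = [k for k, n in seen.items() if n > 1][0]
        raise GeometryError(
            f"multiple partner placements on residue {clash[0]}{clash[1]} "
            f"would clash")
    designated = set(seen)
    for cid, j in list(spec.core_residues) + list(spec.surface_residues):
        if cid not in length_of or not 1 <= j <= length_of[cid]:
            raise ValueError(f"designated residue {cid}{j} out of range")
    for cid, j in spec.core_residues:
        if (cid, j) in designated:
            raise GeometryError(
                f"core cage on {cid}{j} clashes with a partner placement there")
        for pcid, pj in designated:
            if pcid == cid and abs(pj - j) < 2:
                raise GeometryError(
                    f"core cage on {cid}{j} too close to partner placement on "
                    f"{pcid}{pj}")


def _check_clearance(b: _Builder, spec: ComplexSpec, chain_ids: list[str],
                     lengths: list[int],
                     planted: Mapping[tuple[str, int], list],
                     group_of_chain: Mapping[str, int]) -> None:
    """Post-hoc verification: partners keep >= 8 A from non-designated
    residues and partner groups do not clash with each other."""
    partner_rows = [(i, r) for i, r in enumerate(b.rows)
                    if r[4] not in chain_ids or r[0]]
    if not partner_rows:
        return
    partner_xyz = np.array([r[6] for _, r in partner_rows])
    partner_chain = [r[4] for _, r in partner_rows]
    for cid, length in zip(chain_ids, lengths):
        for j in range(1, length + 1):
            if (cid, j) in planted:
                continue
            atoms = b.atoms_of_residue(cid, j)
            d = np.linalg.norm(atoms[:, None, :] - partner_xyz[None, :, :],
                               axis=-1)
            if d.min() < RESIDUE_SPACING - 1e-6:
                k = int(np.unravel_index(d.argmin(), d.shape)[1])
                raise GeometryError(
                    f"partner group in chain {partner_chain[k]} comes within "
                    f"{d.min():.2f} A of non-designated residue {cid}{j}")
    groups: dict[int, list[np.ndarray]] = {}
    for (_, r), xyz in zip(partner_rows, partner_xyz):
        groups.setdefault(group_of_chain[r[4]], []).append(xyz)
    names = sorted(groups)
    for i, gi in enumerate(names):
        a = np.asarray(groups[gi])
        for gj in names[i + 1:]:
            bb = np.asarray(groups[gj])
            d = np.linalg.norm(a[:, None, :] - bb[None, :, :], axis=-1).min()
            if d < 2.0:
                raise GeometryError(
                    f"partner placements {gi} and {gj} clash ({d:.2f} A)")


def make_gene_set(n_genes: int, length_range: tuple[int, int] = (30, 60),
                  seed: int = 0, prefix: str = "G") -> list[GeneRecord]:
    """Random genes: a protein sequence plus a consistent coding sequence
    (codon drawn uniformly per residue, one terminal stop)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = []
    lo, hi = length_range
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        protein = _random_protein(rng, length)
        cds = "".join(rng.choice(CODONS_FOR_AA[aa]) for aa in protein)
        cds += str(rng.choice(STOP_CODONS))
        rec = GeneRecord(gene_id=f"{prefix}{i + 1:04d}", protein_seq=protein,
                         cds=cds)
        assert translate_cds(rec.cds) == rec.protein_seq
        genes.append(rec)
    return genes


def gene_for_sequence(gene_id: str, protein: str, seed: int = 0) -> GeneRecord:
    """A GeneRecord with a random coding sequence for a given protein."""
    rng = np.random.default_rng(seed)
    cds = "".join(rng.choice(CODONS_FOR_AA[aa]) for aa in protein)
    cds += str(rng.choice(STOP_CODONS))
    return GeneRecord(gene_id=gene_id, protein_seq=protein, cds=cds)


def missense_neighbors(codon: str) -> list[tuple[int, str, str]]:
    """All (offset, new_base, new_aa) single-nucleotide missense changes."""
    from ._aa import CODON_TABLE
    ref_aa = CODON_TABLE[codon]
    out = []
    for off in range(3):
        for base in NUCLEOTIDES:
            if base == codon[off]:
                continue
            new = codon[:off] + base + codon[off + 1:]
            aa = CODON_TABLE[new]
            if aa != ref_aa and aa != "*":
                out.append((off, base, aa))
    return out


def plant_variants(genes: Sequence[GeneRecord],
                   truths: Iterable[PlantedTruth] | PlantedTruth,
                   n_per_class: Mapping[str, int], seed: int = 0,
                   dataset_label: str = "disease") -> list[Variant]:
    """Emit variants whose positions carry a requested planted class.

    Residues are drawn without replacement within each class; the alternative
    residue is reachable from the underlying codon by exactly one nucleotide
    substitution.  Raises ``ValueError`` naming the class when it does not
    have enough designated residues.
    """
    if isinstance(truths, PlantedTruth):
        truths = [truths]
    rng = np.random.default_rng(seed)
    by_gene = {g.gene_id: g for g in genes}
    pool: dict[str, list[PlantedResidue]] = {}
    for t in truths:
        for r in t.residues:
            if r.gene_id is not None and r.gene_id in by_gene:
                pool.setdefault(r.intended_class, []).append(r)
    out: list[Variant] = []
    for label, n in n_per_class.items():
        avail = pool.get(label, [])
        if len(avail) < n:
            raise ValueError(
                f"class {label!r} exhausted: {len(avail)} designated residues "
                f"available, {n} requested")
        picks = rng.choice(len(avail), size=n, replace=False)
        for idx in sorted(int(i) for i in picks):
            r = avail[idx]
            gene = by_gene[r.gene_id]
            pos = r.residue
            codon = gene.cds[3 * (pos - 1):3 * pos]
            choices = missense_neighbors(codon)
            _, _, alt = choices[int(rng.integers(len(choices)))]
            out.append(Variant(gene_id=gene.gene_id, position=pos,
                               ref_aa=gene.protein_seq[pos - 1], alt_aa=alt,
                               dataset_label=dataset_label))
    return out


def make_annotation_db(n_pathways: int, proteins: Sequence[str],
                       planted_enriched: Sequence[str] = (), seed: int = 0,
                       pathway_size: int = 6, namespace: str = "pathway",
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Protein -> pathway annotation table with optional planted enrichment.

    When ``planted_enriched`` is non-empty, the first pathway's membership is
    exactly that protein subset; remaining pathways draw members uniformly
    from the other proteins.  Returns (table, planted term ids); the table
    has columns gene_id, term_id, namespace and round-trips through TSV.
    """
    rng = np.random.default_rng(seed)
    rows = []
    planted_ids: list[str] = []
    background = [p for p in proteins if p not in set(planted_enriched)]
    start = 0
    if planted_enriched:
        term = "PW0000"
        planted_ids.append(term)
        for p in planted_enriched:
            rows.append((p, term, namespace))
        start = 1
    for i in range(start, n_pathways):
        term = f"PW{i:04d}"
        size = min(pathway_size, len(background))
        members = rng.choice(background, size=size, replace=False)
        for p in members:
            rows.append((p, term, namespace))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace"]), planted_ids
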