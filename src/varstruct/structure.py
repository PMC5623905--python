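"""Structure parsing, residue-partner distances, and solvent accessibility.

Structures are read from PDB-format files (via gemmi).  Chains are typed as
protein / DNA / RNA by their residue alphabet; HETATM groups become ligands
after stripping common crystallographic buffers, with metal and halide ions
retained because mutations at ion-binding sites are functionally relevant.
Per-residue annotation yields SLD (shortest inter-atomic distance to any
ligand), per-category chain distances (protein / DNA / RNA; SCD is their
minimum), and relative solvent accessibility from a Shrake-Rupley surface
(probe 1.4 A, 960 sphere points) normalised by a theoretical per-residue
maximum-ASA scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
import biotite.structure as bst

from ._aa import AA3_TO_1, DEFAULT_BUFFER_CODES, DNA_RES_NAMES, MAX_ASA, RNA_RES_NAMES

PROBE_RADIUS = 1.4
SASA_POINTS = 960


@dataclass
class Residue:
    """One polymer residue with its heavy-atom coordinates."""

    seq_num: int
    icode: str
    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)

    @property
    def label(self) -> str:
        return f"{self.seq_num}{self.icode.strip()}"


@dataclass
class Chain:
    chain_id: str
    polymer_type: str  # "protein" | "DNA" | "RNA"
    residues: list[Residue]

    def residue_by_index(self, index: int) -> Residue:
        """1-based position along the chain (alignment coordinate)."""
        return self.residues[index - 1]

    def sequence(self) -> str:
        """One-letter sequence; unknown residues map to X (protein chains)."""
        if self.polymer_type != "protein":
            return "".join(r.name[-1] if r.name else "N" for r in self.residues)
        return "".join(AA3_TO_1.get(r.name, "X") for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])


@dataclass
class Ligand:
    het_code: str
    chain_id: str
    seq_num: int
    elements: list[str]
    coords: np.ndarray
    is_metal: bool = False
    drug_like: bool = False


@dataclass
class StructureEntry:
    structure_id: str
    chains: list[Chain]
    ligands: list[Ligand]
    resolution: float | None = None
    r_value: float | None = None
    warnings: list[str] = field(default_factory=list)
    _atom_sasa: dict | None = None

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in {self.structure_id}")

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type == "protein"]


@dataclass
class ResidueContext:
    """Distances and accessibility of one residue within one structure.

    Absent partners are encoded as ``None`` (the paper's "infinite
    distance"); ``scd`` is the minimum over macromolecular categories.
    """

    structure_id: str
    chain_id: str
    residue_index: int
    sld: float | None
    d_protein: float | None
    d_dna: float | None
    d_rna: float | None
    rsa: float
    ligand_distances: dict[str, float] = field(default_factory=dict)
    low_confidence: bool = False

    @property
    def scd(self) -> float | None:
        ds = [d for d in (self.d_protein, self.d_dna, self.d_rna) if d is not None]
        return min(ds) if ds else None


_RVALUE_RE = re.compile(r"R VALUE\s*\(WORKING SET\)\s*:\s*([0-9.]+)")
_RVALUE_RE2 = re.compile(r"R VALUE\s*:\s*([0-9.]+)")


def _polymer_type(res_names: Iterable[str]) -> str:
    names = set(res_names)
    if names & DNA_RES_NAMES:
        return "DNA"
    if names <= RNA_RES_NAMES and names:
        return "RNA"
    return "protein"


def parse_structure(path_or_text: str | Path,
                    buffer_codes: frozenset[str] = DEFAULT_BUFFER_CODES,
                    drug_codes: frozenset[str] = frozenset(),
                    structure_id: str | None = None) -> StructureEntry:
    """Read a PDB-format file (or raw text) into a StructureEntry.

    First model only; alternate location A only.  HETATM groups whose code is
    in ``buffer_codes`` are dropped; codes in ``drug_codes`` are kept but
    flagged drug-like so the ligand-exclusion re-analysis can remove them.
    Modified residues inside polymer chains stay part of the chain.
    """
    text = None
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        text = path_or_text
    if text is None:
        text = Path(path_or_text).read_text()
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError("no ATOM records in structure")

    r_value = None
    for remark in st.raw_remarks:
        m = _RVALUE_RE.search(remark) or _RVALUE_RE2.search(remark)
        if m:
            r_value = float(m.group(1))
            break
    resolution = float(st.resolution) if st.resolution else None

    warnings: list[str] = []
    chains: list[Chain] = []
    ligands: list[Ligand] = []
    model = st[0]
    if len(st) > 1:
        warnings.append(f"multi-model file: using first of {len(st)} models")

    known = set(AA3_TO_1) | DNA_RES_NAMES | RNA_RES_NAMES | {"UNK"}
    residues_by_name: dict[str, list[Residue]] = {}
    for ch in model:
        poly_residues = residues_by_name.setdefault(ch.name, [])
        for res in ch:
            het = res.het_flag == "H"
            atoms = [a for a in res if a.altloc in ("\0", "", "A")]
            if not atoms:
                continue
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            elements = [a.element.name for a in atoms]
            if het:
                code = res.name
                if code in buffer_codes:
                    continue
                is_metal = all(a.element.is_metal for a in atoms) or (
                    len(atoms) == 1 and atoms[0].element.name in
                    ("Cl", "Br", "I", "F"))
                ligands.append(Ligand(
                    het_code=code, chain_id=ch.name, seq_num=res.seqid.num,
                    elements=elements, coords=coords, is_metal=is_metal,
                    drug_like=code in drug_codes))
            else:
                if res.name not in known:
                    warnings.append(f"unknown residue code {res.name} in "
                                    f"chain {ch.name}: kept")
                poly_residues.append(Residue(
                    seq_num=res.seqid.num, icode=res.seqid.icode or " ",
                    name=res.name,
                    atom_names=[a.name for a in atoms], elements=elements,
                    coords=coords))
    for name, poly_residues in residues_by_name.items():
        if poly_residues:
            chains.append(Chain(chain_id=name,
                                polymer_type=_polymer_type(
                                    r.name for r in poly_residues),
                                residues=poly_residues))
    if not chains:
        raise ValueError("no ATOM records in structure")
    sid = structure_id or (st.name.strip() if st.name.strip() else "UNNAMED")
    return StructureEntry(structure_id=sid, chains=chains, ligands=ligands,
                          resolution=resolution, r_value=r_value,
                          warnings=warnings)


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def residue_distances(entry: StructureEntry, chain_id: str, residue_index: int,
                      exclude_het_codes: frozenset[str] = frozenset(),
                      ) -> tuple[float | None, float | None, float | None,
                                 float | None, dict[str, float]]:
    """Minimum inter-atomic distances from one residue to each partner class.

    Returns (sld, d_protein, d_dna, d_rna, per-ligand distances); the
    residue's own chain is excluded from the protein category.  Distances use
    all non-hydrogen atoms.
    """
    res = entry.chain(chain_id).residue_by_index(residue_index)
    heavy = np.array([e != "H" for e in res.elements])
    xyz = res.coords[heavy] if heavy.any() else res.coords

    per_ligand: dict[str, float] = {}
    for lig in entry.ligands:
        if lig.het_code in exclude_het_codes:
            continue
        d = _min_dist(xyz, lig.coords)
        key = f"{lig.het_code}:{lig.chain_id}{lig.seq_num}"
        per_ligand[key] = d
    sld = min(per_ligand.values()) if per_ligand else None

    cat: dict[str, float] = {}
    for ch in entry.chains:
        if ch.polymer_type == "protein" and ch.chain_id == chain_id:
            continue
        d = _min_dist(xyz, ch.coords())
        key = ch.polymer_type
        cat[key] = min(d, cat.get(key, math.inf))
    return (sld, cat.get("protein"), cat.get("DNA"), cat.get("RNA"), per_ligand)


def _compute_all_sasa(entry: StructureEntry) -> dict[tuple[str, int], float]:
    """Shrake-Rupley accessible area per polymer residue, all atoms of the
    entry (ligands and partner chains included) occluding."""
    coords, elements, owner = [], [], []
    for ch in entry.chains:
        for i, res in enumerate(ch.residues, start=1):
            for k in range(len(res.coords)):
                if res.elements[k] == "H":
                    continue
                coords.append(res.coords[k])
                elements.append(res.elements[k])
                owner.append((ch.chain_id, i))
    for lig in entry.ligands:
        for k in range(len(lig.coords)):
            coords.append(lig.coords[k])
            elements.append(lig.elements[k])
            owner.append(None)

    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["UNK"] * n)
    arr.atom_name = np.array(["X"] * n)
    arr.element = np.array([e.upper() for e in elements])
    arr.hetero = np.zeros(n, dtype=bool)
    atom_sasa = bst.sasa(arr, probe_radius=PROBE_RADIUS,
                         point_number=SASA_POINTS, vdw_radii="Single",
                         ignore_ions=False)
    totals: dict[tuple[str, int], float] = {}
    for area, who in zip(atom_sasa, owner):
        if who is None or not np.isfinite(area):
            continue
        totals[who] = totals.get(who, 0.0) + float(area)
    return totals


def relative_sasa(entry: StructureEntry, chain_id: str,
                  residue_index: int) -> float:
    """Relative solvent accessibility (%) of one residue.

    Residue accessible area divided by the residue type's theoretical maximum
    (Gly-X-Gly scale) times 100; values above 100 are possible for extended
    conformations and for coarse synthetic residues.  The whole-entry SASA is
    computed once per structure and cached.
    """
    if entry._atom_sasa is None:
        entry._atom_sasa = _compute_all_sasa(entry)
    res = entry.chain(chain_id).residue_by_index(residue_index)
    area = entry._atom_sasa.get((chain_id, residue_index), 0.0)
    aa = AA3_TO_1.get(res.name)
    max_asa = MAX_ASA.get(aa, float(np.mean(list(MAX_ASA.values()))))
    return 100.0 * area / max_asa


def residue_context(entry: StructureEntry, chain_id: str, residue_index: int,
                    exclude_het_codes: frozenset[str] = frozenset(),
                    ) -> ResidueContext:
    """Full per-residue annotation: distances plus relative accessibility."""
    sld, d_prot, d_dna, d_rna, per_lig = residue_distances(
        entry, chain_id, residue_index, exclude_het_codes)
    res = entry.chain(chain_id).residue_by_index(residue_index)
    return ResidueContext(
        structure_id=entry.structure_id, chain_id=chain_id,
        residue_index=residue_index, sld=sld, d_protein=d_prot, d_dna=d_dna,
        d_rna=d_rna, rsa=relative_sasa(entry, chain_id, residue_index),
        ligand_distances=per_lig, low_confidence=len(res.coords) < 4)
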