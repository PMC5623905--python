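"""Structure parsing rules (buffers, metals, drugs), minimum distances, and
Shrake-Rupley relative accessibility."""

import math

import numpy as np
import pytest

from varstruct.structure import (parse_structure, relative_sasa,
                                 residue_context, residue_distances,
                                 _compute_all_sasa, PROBE_RADIUS)
from varstruct.synthetic import ComplexSpec, make_toy_complex


def _pdb(lines):
    return "\n".join(lines) + "\nEND\n"


def _atom(serial, name, res, chain, num, x, y, z, elem, het=False):
    rec = "HETATM" if het else "ATOM  "
    return (f"{rec}{serial:>5d}  {name:<3s} {res:>3s} {chain}{num:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}")


def test_buffer_components_are_dropped():
    text = _pdb([
        _atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
        _atom(2, "O", "HOH", "B", 1, 5, 0, 0, "O", het=True),
        _atom(3, "S", "SO4", "B", 2, 6, 0, 0, "S", het=True),
    ])
    entry = parse_structure(text)
    assert entry.ligands == []


def test_metal_ions_are_kept_as_ligands():
    text = _pdb([
        _atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
        _atom(2, "ZN", "ZN", "B", 1, 3, 0, 0, "ZN", het=True),
    ])
    entry = parse_structure(text)
    assert len(entry.ligands) == 1
    assert entry.ligands[0].het_code == "ZN" and entry.ligands[0].is_metal


def test_drug_codes_flagged_not_removed():
    text = _pdb([
        _atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
        _atom(2, "C1", "STI", "B", 1, 3, 0, 0, "C", het=True),
    ])
    entry = parse_structure(text, drug_codes=frozenset({"STI"}))
    assert len(entry.ligands) == 1 and entry.ligands[0].drug_like


def test_no_atoms_fails():
    with pytest.raises(ValueError, match="no ATOM"):
        parse_structure("REMARK   2 RESOLUTION. 2.00 ANGSTROMS.\nEND\n")


def test_resolution_and_rvalue_parsed(study):
    entry = study.entries[0]
    assert entry.resolution == pytest.approx(1.8)
    assert entry.r_value == pytest.approx(0.2)


def test_first_model_only():
    text = _pdb([
        "MODEL        1",
        _atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
        "ENDMDL",
        "MODEL        2",
        _atom(2, "CA", "ALA", "A", 1, 9, 9, 9, "C"),
        "ENDMDL",
    ])
    entry = parse_structure(text)
    assert len(entry.chains) == 1
    assert np.allclose(entry.chains[0].residues[0].coords, [[0, 0, 0]])


def test_synthetic_counts_match_spec(study):
    entry = study.entries[0]
    # one gene chain + cage fragment merged, DNA duplex (2), partner chain (1)
    assert sum(1 for c in entry.chains if c.polymer_type == "DNA") == 2
    assert len(entry.ligands) == 1


def test_minimum_distance_hand_computed():
    # chain B atoms at x = 5.5 and 8; minimum to A1-CA at origin is 2.5 after
    # subtracting the 3.0 offset of the nearer atom: |5.5 - 3.0| with A at 3.0
    text = _pdb([
        _atom(1, "CA", "ALA", "A", 1, 3.0, 0, 0, "C"),
        _atom(2, "CB", "ALA", "A", 1, 3.0, 1.5, 0, "C"),
        _atom(3, "CA", "GLY", "B", 1, 5.5, 0, 0, "C"),
        _atom(4, "CA", "GLY", "B", 2, 8.0, 0, 0, "C"),
    ])
    entry = parse_structure(text)
    _, d_prot, _, _, _ = residue_distances(entry, "A", 1)
    assert d_prot == pytest.approx(2.5, abs=1e-9)


def test_distances_match_brute_force(study):
    entry = study.entries[0]
    chain = entry.chain("A")
    lig_coords = [l.coords for l in entry.ligands]
    for idx in range(1, len(chain.residues) + 1):
        sld, d_prot, d_dna, _, _ = residue_distances(entry, "A", idx)
        xyz = chain.residue_by_index(idx).coords
        if lig_coords:
            brute = min(float(np.linalg.norm(xyz[:, None] - lc[None], axis=-1)
                              .min()) for lc in lig_coords)
            assert sld == pytest.approx(brute, abs=1e-9)
        for ptype, got in (("protein", d_prot), ("DNA", d_dna)):
            others = [c for c in entry.chains if c.polymer_type == ptype
                      and not (ptype == "protein" and c.chain_id == "A")]
            if not others:
                assert got is None
                continue
            brute = min(float(np.linalg.norm(
                xyz[:, None] - c.coords()[None], axis=-1).min())
                for c in others)
            assert got == pytest.approx(brute, abs=1e-9)


def test_isolated_residue_fully_accessible():
    text = _pdb([_atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
                 _atom(2, "CB", "ALA", "A", 1, 1.5, 0, 0, "C")])
    entry = parse_structure(text)
    assert relative_sasa(entry, "A", 1) >= 95.0


def test_caged_residue_is_buried():
    spec = ComplexSpec(n_protein_chains=1, chain_lengths=(10,),
                       core_residues=(("A", 5),), seed=8)
    text, _ = make_toy_complex(spec)
    entry = parse_structure(text)
    assert relative_sasa(entry, "A", 5) < 5.0


def test_sasa_matches_spherical_cap_oracle():
    """Two overlapping carbon spheres against the closed-form cap area."""
    d = 4.0
    text = _pdb([_atom(1, "C", "UNK", "A", 1, 0, 0, 0, "C"),
                 _atom(2, "C", "UNK", "A", 2, d, 0, 0, "C")])
    entry = parse_structure(text)
    areas = _compute_all_sasa(entry)
    R = 1.7 + PROBE_RADIUS
    cos_theta = d / (2 * R)  # equal radii
    analytic = 4 * math.pi * R**2 - 2 * math.pi * R**2 * (1 - cos_theta)
    for key in ((("A", 1)), (("A", 2))):
        assert areas[key] == pytest.approx(analytic, rel=0.02)


def test_adding_occluders_never_increases_rsa():
    base = [_atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            _atom(2, "CB", "ALA", "A", 1, 1.5, 0, 0, "C")]
    rsa_prev = parse_structure(_pdb(base))
    rsa_prev = relative_sasa(rsa_prev, "A", 1)
    lines = list(base)
    for i, pos in enumerate([(3.0, 0, 0), (0, 3.0, 0), (0, -3.0, 0),
                             (0, 0, 3.0), (0, 0, -3.0), (-3.0, 0, 0)]):
        lines.append(_atom(10 + i, "C", "UNK", "B", i + 1, *pos, "C"))
        rsa = relative_sasa(parse_structure(_pdb(lines)), "A", 1)
        assert rsa <= rsa_prev + 1e-9
        rsa_prev = rsa


def test_parsing_is_idempotent(study):
    text = study.pdb_texts[0]
    e1, e2 = parse_structure(text), parse_structure(text)
    assert [c.chain_id for c in e1.chains] == [c.chain_id for c in e2.chains]
    assert len(e1.ligands) == len(e2.ligands)
    for c1, c2 in zip(e1.chains, e2.chains):
        assert np.array_equal(c1.coords(), c2.coords())


def test_low_atom_residue_flagged_low_confidence():
    text = _pdb([_atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C")])
    ctx = residue_context(parse_structure(text), "A", 1)
    assert ctx.low_confidence
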