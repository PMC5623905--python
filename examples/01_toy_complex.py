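"""Build one synthetic protein complex with planted interaction partners and
verify that the structural annotation recovers the planted geometry.

A 20-residue chain gets a small-molecule ligand 3.0 A from residue 5, a DNA
duplex 3.5 A from residue 12, and a buried residue at 16.  The annotation
stage reads the PDB file back and measures minimum inter-atomic distances and
relative solvent accessibility (RSA) per residue.
"""

from varstruct.structure import parse_structure, residue_context
from varstruct.synthetic import ComplexSpec, Placement, make_toy_complex

spec = ComplexSpec(
    n_protein_chains=1,
    chain_lengths=(20,),
    ligand_placements=(Placement("A", 5, 3.0),),
    dna_placements=(Placement("A", 12, 3.5),),
    core_residues=(("A", 16),),
    surface_residues=(("A", 2),),
    seed=7,
)
pdb_text, truth = make_toy_complex(spec)
entry = parse_structure(pdb_text)

print("planted ground truth:")
for r in truth.residues:
    d = f"{r.intended_distance:.2f} A" if r.intended_distance else "-"
    print(f"  residue {r.chain_id}{r.residue:<3d} {r.intended_class:<16s} {d}")

print("\nrecovered annotation (SLD = ligand dist, D_DNA = DNA dist, RSA %):")
for r in truth.residues:
    ctx = residue_context(entry, r.chain_id, r.residue)
    sld = f"{ctx.sld:6.2f}" if ctx.sld is not None else "     -"
    dna = f"{ctx.d_dna:6.2f}" if ctx.d_dna is not None else "     -"
    print(f"  residue {r.chain_id}{r.residue:<3d} SLD={sld}  D_DNA={dna}  "
          f"RSA={ctx.rsa:6.1f}")
print("\nA planted partner at d < 5 A makes the residue a contact residue;")
print("RSA < 16% with no contact marks the protein core.")
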