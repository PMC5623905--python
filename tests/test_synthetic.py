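"""Generator invariants: planted distances are realized, clearances hold,
genes translate, planted variants are single-nucleotide missense changes."""

import pandas as pd
import pytest
from Bio.Seq import Seq

from varstruct._aa import CODON_TABLE, NUCLEOTIDES
from varstruct.synthetic import (ComplexSpec, GeometryError, Placement,
                                 make_annotation_db, make_gene_set,
                                 make_toy_complex, missense_neighbors,
                                 plant_variants)
from varstruct.structure import parse_structure, residue_distances


def _spec(**kw):
    base = dict(n_protein_chains=1, chain_lengths=(20,), seed=3)
    base.update(kw)
    return ComplexSpec(**base)


@pytest.mark.parametrize("kind,dist", [
    ("ligand", 3.0), ("ligand", 4.6), ("dna", 3.2), ("partner", 4.0),
])
def test_placement_realizes_target_distance(kind, dist):
    key = {"ligand": "ligand_placements", "dna": "dna_placements",
           "partner": "partner_chain_placements"}[kind]
    spec = _spec(**{key: (Placement("A", 10, dist),)})
    text, truth = make_toy_complex(spec)
    entry = parse_structure(text)
    sld, d_prot, d_dna, _, _ = residue_distances(entry, "A", 10)
    realized = {"ligand": sld, "dna": d_dna, "partner": d_prot}[kind]
    assert abs(realized - dist) <= 0.2


def test_non_designated_residues_keep_clearance():
    spec = _spec(ligand_placements=(Placement("A", 5, 3.0),),
                 dna_placements=(Placement("A", 12, 4.0),))
    text, _ = make_toy_complex(spec)
    entry = parse_structure(text)
    for j in range(1, 21):
        if j in (5, 12):
            continue
        sld, d_prot, d_dna, _, _ = residue_distances(entry, "A", j)
        for d in (sld, d_dna):
            if d is not None:
                assert d >= 8.0 - 1e-6, f"residue {j} too close ({d:.2f} A)"


def test_no_partners_gives_only_surface_core_labels():
    spec = _spec(core_residues=(("A", 4),), surface_residues=(("A", 10),))
    _, truth = make_toy_complex(spec)
    labels = {r.intended_class for r in truth.residues}
    assert labels == {"Core", "Surface"}


def test_same_seed_byte_identical():
    spec = _spec(ligand_placements=(Placement("A", 7, 3.5),), seed=42)
    t1, _ = make_toy_complex(spec)
    t2, _ = make_toy_complex(spec)
    assert t1 == t2


def test_clashing_placements_rejected():
    spec = _spec(ligand_placements=(Placement("A", 6, 3.0),),
                 dna_placements=(Placement("A", 6, 3.0),))
    with pytest.raises(GeometryError, match="A6"):
        make_toy_complex(spec)


def test_cage_near_partner_rejected():
    spec = _spec(ligand_placements=(Placement("A", 6, 3.0),),
                 core_residues=(("A", 7),))
    with pytest.raises(GeometryError):
        make_toy_complex(spec)


def test_distance_exceeding_clearance_budget_rejected():
    with pytest.raises(GeometryError):
        make_toy_complex(_spec(ligand_placements=(Placement("A", 6, 9.0),)))


def test_gene_set_translates_and_sizes():
    genes = make_gene_set(5, length_range=(20, 30), seed=1)
    assert len(genes) == 5
    for g in genes:
        assert len(g.cds) == 3 * len(g.protein_seq) + 3
        # independent oracle: Biopython translation
        assert str(Seq(g.cds).translate(to_stop=True)) == g.protein_seq
    again = make_gene_set(5, length_range=(20, 30), seed=1)
    assert [g.cds for g in again] == [g.cds for g in genes]


def test_missense_neighbors_match_enumeration():
    for codon in ("ATG", "TGG", "CGA", "GGG"):
        expected = []
        for off in range(3):
            for base in NUCLEOTIDES:
                if base == codon[off]:
                    continue
                new = codon[:off] + base + codon[off + 1:]
                if CODON_TABLE[new] not in (CODON_TABLE[codon], "*"):
                    expected.append((off, base, CODON_TABLE[new]))
        assert missense_neighbors(codon) == expected


def test_plant_variants_respects_class_and_codon():
    genes = make_gene_set(4, length_range=(26, 26), seed=2)
    truths = []
    for i, g in enumerate(genes):
        spec = ComplexSpec(
            n_protein_chains=1, chain_lengths=(26,),
            chain_sequences=(g.protein_seq,), chain_gene_ids=(g.gene_id,),
            ligand_placements=(Placement("A", 3, 3.0),),
            core_residues=(("A", 10),), structure_id=f"S{i}", seed=i)
        _, truth = make_toy_complex(spec)
        truths.append(truth)
    variants = plant_variants(genes, truths, {"Ligand contact": 4}, seed=0)
    assert len(variants) == 4
    by_gene = {g.gene_id: g for g in genes}
    for v in variants:
        assert v.position == 3
        gene = by_gene[v.gene_id]
        assert v.ref_aa == gene.protein_seq[v.position - 1]
        assert v.ref_aa != v.alt_aa
        codon = gene.codon(v.position)
        # alt must be reachable by exactly one nucleotide change
        assert v.alt_aa in {aa for _, _, aa in missense_neighbors(codon)}


def test_plant_variants_exhausted_class_raises():
    genes = make_gene_set(1, length_range=(26, 26), seed=2)
    spec = ComplexSpec(n_protein_chains=1, chain_lengths=(26,),
                       chain_sequences=(genes[0].protein_seq,),
                       chain_gene_ids=(genes[0].gene_id,),
                       ligand_placements=(Placement("A", 3, 3.0),), seed=0)
    _, truth = make_toy_complex(spec)
    with pytest.raises(ValueError, match="Ligand contact"):
        plant_variants(genes, truth, {"Ligand contact": 2}, seed=0)


def test_annotation_db_counts_and_roundtrip(tmp_path):
    proteins = [f"G{i}" for i in range(12)]
    table, planted = make_annotation_db(4, proteins,
                                        planted_enriched=proteins[:3],
                                        seed=0, pathway_size=5)
    assert planted == ["PW0000"]
    sizes = table.groupby("term_id")["gene_id"].nunique()
    assert sizes["PW0000"] == 3
    assert all(sizes.drop("PW0000") == 5)
    # planted pathway holds exactly the enriched subset
    assert set(table[table.term_id == "PW0000"].gene_id) == set(proteins[:3])
    p = tmp_path / "annot.tsv"
    table.to_csv(p, sep="\t", index=False)
    back = pd.read_csv(p, sep="\t")
    assert back.equals(table)
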