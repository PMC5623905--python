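"""Template search filters, alignment position mapping, quality scores."""

import math

import pytest

from varstruct.synthetic import make_gene_set
from varstruct.templates import (ChainSeq, TemplateHit, align_global,
                                 alignment_stats, map_positions,
                                 passes_filters, resolution_weight,
                                 search_templates, template_score)


def _hit(alignment, **kw):
    base = dict(gene_id="g", structure_id="S", chain_id="A", seq_id=1.0,
                cov=1.0, aligned_length=len(alignment[0]),
                alignment=alignment, resolution=2.0, r_value=0.2)
    base.update(kw)
    return TemplateHit(**base)


def test_self_hit_has_full_identity_and_coverage():
    genes = make_gene_set(1, (60, 60), seed=0)
    lib = [ChainSeq("S1", "A", genes[0].protein_seq, 2.0, 0.2)]
    hits = search_templates(genes[0], lib)
    assert len(hits) == 1
    assert hits[0].seq_id == 1.0 and hits[0].cov == 1.0
    assert hits[0].aligned_length == 60


def test_filter_thresholds_by_hand():
    # 40 aligned residues at 90% identity on 120/120 sequences: excluded
    assert not passes_filters(0.9, 40, 120, 120)
    # 60 aligned residues: included through the >50-residue branch
    assert passes_filters(0.9, 60, 120, 120)
    # coverage branch: 40 of a 70-residue shorter partner is > 50%
    assert passes_filters(0.9, 40, 120, 70)
    # identity at or below 35% always excluded
    assert not passes_filters(0.35, 100, 120, 120)
    assert not passes_filters(0.30, 100, 120, 120)
    # external e-value gate
    assert not passes_filters(0.9, 100, 120, 120, evalue=1e-5)
    assert passes_filters(0.9, 100, 120, 120, evalue=1e-6)


def test_search_matches_brute_force_filtering():
    """Search equals exhaustive alignment + independently coded filters on a
    toy library of relatives at varying identity."""
    genes = make_gene_set(6, (55, 65), seed=5)
    target = genes[0]
    lib = []
    seq = target.protein_seq
    # relatives: mutate a growing prefix to scramble identity
    others = make_gene_set(6, (55, 65), seed=99)
    for i, frac in enumerate((0.0, 0.2, 0.4, 0.6, 0.8)):
        k = int(frac * len(seq))
        mutated = others[i].protein_seq[:k] + seq[k:]
        lib.append(ChainSeq(f"S{i}", "A", mutated, 2.0, 0.2))
    for i, g in enumerate(others):
        lib.append(ChainSeq(f"R{i}", "A", g.protein_seq, 2.0, 0.2))

    hits = search_templates(target, lib)
    found = {(h.structure_id, h.chain_id) for h in hits}

    expected = set()
    for cs in lib:
        gt, gq = align_global(target.protein_seq, cs.sequence)
        ident = sum(1 for a, b in zip(gt, gq) if a == b and a != "-")
        ncols = sum(1 for a, b in zip(gt, gq) if (a, b) != ("-", "-"))
        alen = sum(1 for a, b in zip(gt, gq) if a != "-" and b != "-")
        seq_id = ident / ncols
        shorter = min(len(target.protein_seq), len(cs.sequence))
        if seq_id > 0.35 and (alen / shorter > 0.5 or alen > 50):
            expected.add((cs.structure_id, cs.chain_id))
    assert found == expected


def test_hits_sorted_by_identity_descending():
    genes = make_gene_set(1, (60, 60), seed=1)
    seq = genes[0].protein_seq
    noise = make_gene_set(1, (60, 60), seed=2)[0].protein_seq
    lib = [ChainSeq("S2", "A", noise[:12] + seq[12:], 2.0, 0.2),
           ChainSeq("S1", "A", seq, 2.0, 0.2),
           ChainSeq("S3", "A", seq, 2.0, 0.2)]
    hits = search_templates(genes[0], lib)
    ids = [h.seq_id for h in hits]
    assert ids == sorted(ids, reverse=True)
    # ties broken lexicographically
    tied = [h.structure_id for h in hits if h.seq_id == 1.0]
    assert tied == sorted(tied)


def test_map_positions_identity_and_gap():
    h = _hit(("ABD", "ABD"))
    assert [m.template_index for m in map_positions(h, [1, 2, 3])] == [1, 2, 3]
    # target row has a gap column; template position 3 (C) is skipped
    h = _hit(("AB-D", "ABCD"))
    m = map_positions(h, [3])[0]
    assert m.mapped and m.template_index == 4
    # position falls on a template gap: discarded
    h = _hit(("ABCD", "AB-D"))
    m = map_positions(h, [3])[0]
    assert not m.mapped and m.template_index is None


def test_map_positions_roundtrip_inverse():
    gt, gq = align_global("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
                          "MKTAYIAKQISFVKSHFSRQLEERLGLIE")
    h = _hit((gt, gq))
    inv = _hit((gq, gt))
    for pos in range(1, 34):
        m = map_positions(h, [pos])[0]
        if m.mapped:
            back = map_positions(inv, [m.template_index])[0]
            assert back.mapped and back.template_index == pos


def test_resolution_sigmoid_midpoint_exact():
    assert resolution_weight(8.0 / 3.0) == pytest.approx(0.5, abs=1e-12)


def test_template_score_reference_points():
    # ideal template: identity 1, coverage 1, resolution -> 0, R-value 0
    h = _hit(("A", "A"), seq_id=1.0, cov=1.0, resolution=1e-9, r_value=0.0)
    expected = (1 + 1 + 1 / (1 + math.exp(-4)) + 1) / 4
    assert template_score(h) == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(0.9955, abs=1e-4)
    # the R-value term is linear: a full swing changes the mean by 1/4
    h0 = _hit(("A", "A"), r_value=0.0)
    h1 = _hit(("A", "A"), r_value=1.0)
    assert template_score(h0) - template_score(h1) == pytest.approx(0.25)


def test_template_score_monotonicity():
    for attr, direction in (("seq_id", 1), ("cov", 1), ("resolution", -1),
                            ("r_value", -1)):
        lo = _hit(("A", "A"), **{attr: 0.5})
        hi = _hit(("A", "A"), **{attr: 0.9})
        diff = template_score(hi) - template_score(lo)
        assert diff * direction > 0


def test_missing_quality_metadata_defaults_neutral():
    h = _hit(("A", "A"), seq_id=1.0, cov=1.0, resolution=None, r_value=None)
    assert template_score(h) == pytest.approx((1 + 1 + 0.5 + 0.5) / 4)


def test_alignment_stats_counts_columns():
    seq_id, cov, alen = alignment_stats("AB-D", "ABCD")
    assert alen == 3
    assert cov == pytest.approx(3 / 3)
    assert seq_id == pytest.approx(3 / 4)
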