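"""Bootstrap, rank-sum, matched sampling and spatial proximity statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from varstruct.scoring import AnnotatedVariant, CLASS_CORE, CLASS_SURFACE
from varstruct.stats import (bootstrap_sd, class_fractions,
                             matched_template_sampling, pair_proximity_test,
                             ranksum_test, template_count_histogram,
                             _exact_ranksum_p)
from varstruct.structure import parse_structure
from varstruct.synthetic import ComplexSpec, make_toy_complex
from varstruct.variants import Variant


def _annot(label, i=0):
    return AnnotatedVariant(variant=Variant(f"g{i}", 1, "A", "V", "d"),
                            structural_class=label)


def test_class_fractions_simple_cases():
    dist = class_fractions([_annot(CLASS_SURFACE, i) for i in range(10)])
    assert dist.fractions[CLASS_SURFACE] == 1.0 and dist.n_mapped == 10
    mixed = ([_annot(CLASS_SURFACE, i) for i in range(25)]
             + [_annot(CLASS_CORE, i) for i in range(25)]
             + [_annot("DNA contact", i) for i in range(25)]
             + [_annot("Ligand contact", i) for i in range(25)])
    dist = class_fractions(mixed)
    for cls in (CLASS_SURFACE, CLASS_CORE, "DNA contact", "Ligand contact"):
        assert dist.fractions[cls] == 0.25
    assert sum(dist.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_class_fractions_exclude_unmapped():
    annotated = [_annot(CLASS_SURFACE), _annot("Unmapped")]
    dist = class_fractions(annotated)
    assert dist.n_mapped == 1 and dist.n_unmapped == 1
    with pytest.raises(ValueError):
        class_fractions([_annot("Unmapped")])


def test_bootstrap_degenerate_set_has_zero_sd():
    sd = bootstrap_sd([_annot(CLASS_SURFACE, i) for i in range(20)],
                      B=200, seed=0)
    assert sd[CLASS_SURFACE] == 0.0


def test_bootstrap_matches_binomial_closed_form():
    annotated = ([_annot(CLASS_SURFACE, i) for i in range(50)]
                 + [_annot(CLASS_CORE, i) for i in range(50)])
    sd = bootstrap_sd(annotated, B=1000, seed=1)
    expected = math.sqrt(0.25 / 100)
    assert abs(sd[CLASS_SURFACE] - expected) / expected < 0.15


def test_bootstrap_sd_scales_inverse_sqrt_n():
    def sd_at(n, seed):
        annotated = ([_annot(CLASS_SURFACE, i) for i in range(n // 2)]
                     + [_annot(CLASS_CORE, i) for i in range(n // 2)])
        return bootstrap_sd(annotated, B=1000, seed=seed)[CLASS_SURFACE]
    ratio = sd_at(100, 2) / sd_at(400, 3)
    assert abs(ratio - 2.0) < 0.4


def test_ranksum_identical_samples():
    assert ranksum_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0
    assert ranksum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_ranksum_exact_textbook_value():
    assert ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_ranksum_exact_equals_enumeration_small_samples():
    """DP-based exact p with ties equals brute-force enumeration."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        na, nb = rng.integers(2, 5, size=2)
        values = rng.integers(0, 4, size=na + nb).astype(float)
        a, b = values[:na], values[na:]
        ranks = sps.rankdata(values)
        mean = na * (len(values) + 1) / 2
        obs = abs(ranks[:na].sum() - mean)
        hits = total = 0
        for comb in itertools.combinations(range(len(values)), int(na)):
            total += 1
            if abs(ranks[list(comb)].sum() - mean) >= obs - 1e-9:
                hits += 1
        assert _exact_ranksum_p(a, b) == pytest.approx(hits / total, abs=1e-12)


def test_ranksum_power_on_shifted_normals():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 200)
    b = rng.normal(1, 1, 200)
    assert ranksum_test(a, b) < 1e-6


def test_ranksum_empty_sample_rejected():
    with pytest.raises(ValueError):
        ranksum_test([], [1.0])


def test_matched_sampling_histogram_exact_when_feasible():
    pool = [(f"v{i}", c) for i, c in enumerate([1] * 10 + [2] * 10 + [5] * 4)]
    target = {1: 4, 2: 7, 5: 2}
    sample = matched_template_sampling(pool, target, seed=0)
    assert sample.fallback_moves == 0 and sample.with_replacement == 0
    got = template_count_histogram(
        [(v, dict(pool)[v]) for v in sample.variants])
    assert got == target
    assert len(set(sample.variants)) == len(sample.variants)


def test_matched_sampling_pool_equals_target_is_permutation():
    pool = [(f"v{i}", c) for i, c in enumerate([1, 1, 2, 3, 3, 3])]
    target = template_count_histogram(pool)
    sample = matched_template_sampling(pool, target, seed=1)
    assert sorted(sample.variants) == sorted(v for v, _ in pool)


def test_matched_sampling_fallback_and_failure():
    pool = [("a", 2), ("b", 2)]
    sample = matched_template_sampling(pool, {3: 1}, seed=0)
    assert sample.fallback_moves == 1
    with pytest.raises(ValueError, match="bin 3"):
        matched_template_sampling(pool, {3: 1}, seed=0, allow_fallback=False)


@pytest.fixture(scope="module")
def long_chain_entry():
    spec = ComplexSpec(n_protein_chains=1, chain_lengths=(200,), seed=17)
    text, _ = make_toy_complex(spec)
    return parse_structure(text)


def test_planted_cluster_is_significantly_close(long_chain_entry):
    mutated = [("A", i) for i in range(90, 96)]
    p, obs = pair_proximity_test(long_chain_entry, mutated, n_perm=2000,
                                 seed=0)
    assert p < 0.01
    assert obs < 30.0


def test_all_residues_gives_p_one(long_chain_entry):
    mutated = [("A", i) for i in range(1, 201)]
    p, _ = pair_proximity_test(long_chain_entry, mutated, n_perm=200, seed=0)
    assert p == 1.0


def test_proximity_p_bounded_and_needs_two_residues(long_chain_entry):
    p, _ = pair_proximity_test(long_chain_entry, [("A", 1), ("A", 200)],
                               n_perm=100, seed=0)
    assert 0.0 < p <= 1.0
    with pytest.raises(ValueError):
        pair_proximity_test(long_chain_entry, [("A", 1)])
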