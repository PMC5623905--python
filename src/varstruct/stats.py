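"""Statistical machinery: class-fraction bootstraps, distance tests,
template-count-matched controls, and spatial pair-proximity permutation
tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist

from .scoring import ALL_CLASSES, AnnotatedVariant, CLASS_UNMAPPED
from .structure import StructureEntry

DEFAULT_BOOTSTRAP_B = 1000
DEFAULT_N_PERM = 10_000


@dataclass
class ClassDistribution:
    """Per-class fractions of mapped variants, optionally with bootstrap SDs."""

    fractions: dict[str, float]
    n_mapped: int
    n_unmapped: int
    sd: dict[str, float] = field(default_factory=dict)


def class_fractions(annotated: Sequence[AnnotatedVariant]) -> ClassDistribution:
    """Fractions over mapped variants only; unmapped counted separately."""
    mapped = [a for a in annotated if a.structural_class != CLASS_UNMAPPED]
    n_un = len(annotated) - len(mapped)
    if not mapped:
        raise ValueError("no mapped variants")
    fr = {c: 0.0 for c in ALL_CLASSES}
    for a in mapped:
        fr[a.structural_class] = fr.get(a.structural_class, 0.0) + 1.0
    total = len(mapped)
    return ClassDistribution({c: v / total for c, v in fr.items()},
                             n_mapped=total, n_unmapped=n_un)


def bootstrap_sd(annotated: Sequence[AnnotatedVariant],
                 B: int = DEFAULT_BOOTSTRAP_B, seed: int = 0,
                 ) -> dict[str, float]:
    """SD of each class fraction over B bootstrap resamples (size n, with
    replacement) of the mapped variants."""
    mapped = [a for a in annotated if a.structural_class != CLASS_UNMAPPED]
    n = len(mapped)
    if n < 2:
        raise ValueError("need at least 2 mapped variants to bootstrap")
    rng = np.random.default_rng(seed)
    labels = np.array([a.structural_class for a in mapped])
    classes = list(dict.fromkeys(list(ALL_CLASSES) + sorted(set(labels))))
    idx = {c: i for i, c in enumerate(classes)}
    codes = np.array([idx[l] for l in labels])
    draws = rng.integers(0, n, size=(B, n))
    fracs = np.zeros((B, len(classes)))
    for b in range(B):
        counts = np.bincount(codes[draws[b]], minlength=len(classes))
        fracs[b] = counts / n
    sds = fracs.std(axis=0, ddof=1)
    return {c: float(sds[idx[c]]) for c in classes}


def _exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p over all group assignments of the observed
    (mid-)ranks; valid with ties.

    Mid-ranks are doubled to integers and the number of size-``na`` subsets
    per doubled rank sum is counted by dynamic programming, which is
    equivalent to full enumeration of all C(n, na) assignments.
    """
    combined = list(a) + list(b)
    ranks2 = np.rint(2 * sps.rankdata(combined)).astype(int)
    na = len(a)
    n = len(combined)
    obs2 = int(ranks2[:na].sum())
    mean2 = na * (n + 1)
    obs_dev = abs(obs2 - mean2)
    total_sum = int(ranks2.sum())
    # counts[k][s] = number of k-subsets with doubled rank sum s
    counts = np.zeros((na + 1, total_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        kmax = na
        for k in range(min(kmax, na) - 1, -1, -1):
            counts[k + 1, r:] += counts[k, :total_sum + 1 - r]
    sums = np.arange(total_sum + 1)
    extreme = np.abs(sums - mean2) >= obs_dev
    return float(counts[na, extreme].sum() / counts[na].sum())


def ranksum_test(a: Sequence[float], b: Sequence[float],
                 exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Small tie-free samples use the exact null distribution; larger samples or
    samples with ties use the tie-corrected normal approximation.  Two
    samples whose values are all identical give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    if a.size + b.size <= exact_max_n:
        return _exact_ranksum_p(a, b)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue)


@dataclass
class MatchedSample:
    variants: list
    fallback_moves: int = 0      # draws satisfied from a +-1/+-2 neighbour bin
    with_replacement: int = 0    # draws that had to reuse pool members


def matched_template_sampling(pool: Sequence[tuple[object, int]],
                              target_counts: Mapping[int, int], seed: int = 0,
                              allow_fallback: bool = True) -> MatchedSample:
    """Draw a control set whose template-count histogram matches a target.

    ``pool`` holds (variant, n_templates) pairs; ``target_counts`` maps a
    template count to the number of variants wanted in that bin.  Sampling is
    without replacement; when a bin runs dry, neighbouring bins (+-1, then
    +-2) are used, then sampling with replacement, each fallback counted.
    With ``allow_fallback=False`` an unsatisfiable bin raises instead.
    """
    rng = np.random.default_rng(seed)
    bins: dict[int, list] = {}
    for item, c in pool:
        bins.setdefault(int(c), []).append(item)
    for c in bins:
        order = rng.permutation(len(bins[c]))
        bins[c] = [bins[c][i] for i in order]
    out = MatchedSample(variants=[])
    for c in sorted(target_counts):
        need = target_counts[c]
        for _ in range(need):
            drawn = None
            if bins.get(c):
                drawn = bins[c].pop()
            elif allow_fallback:
                for delta in (1, -1, 2, -2):
                    if bins.get(c + delta):
                        drawn = bins[c + delta].pop()
                        out.fallback_moves += 1
                        break
                if drawn is None:
                    candidates = [it for it, cc in pool if cc == c]
                    if not candidates:
                        candidates = [it for it, _ in pool]
                    drawn = candidates[int(rng.integers(len(candidates)))]
                    out.with_replacement += 1
            if drawn is None:
                raise ValueError(f"template-count bin {c} cannot be satisfied")
            out.variants.append(drawn)
    return out


def template_count_histogram(items: Sequence[tuple[object, int]],
                             ) -> dict[int, int]:
    h: dict[int, int] = {}
    for _, c in items:
        h[int(c)] = h.get(int(c), 0) + 1
    return h


def _representative_coords(entry: StructureEntry,
                           residues: Sequence[tuple[str, int]],
                           ) -> np.ndarray:
    """C-beta coordinate per residue (C-alpha for glycine / when absent)."""
    pts = []
    for cid, idx in residues:
        res = entry.chain(cid).residue_by_index(idx)
        names = res.atom_names
        k = names.index("CB") if "CB" in names else (
            names.index("CA") if "CA" in names else 0)
        pts.append(res.coords[k])
    return np.asarray(pts)


def pair_proximity_test(entry: StructureEntry,
                        mutated: Sequence[tuple[str, int]],
                        n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                        ) -> tuple[float, float]:
    """Are the mutated residues of a complex closer to each other than chance?

    Statistic: mean pairwise C-beta distance among the mutated residues.
    Null: residue sets of the same per-chain sizes drawn uniformly without
    replacement from the protein chains of the complex.  Returns
    (p-value, observed statistic) with add-one smoothing,
    p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if len(mutated) < 2:
        raise ValueError("need at least 2 mutated residues")
    rng = np.random.default_rng(seed)
    obs = float(pdist(_representative_coords(entry, mutated)).mean())

    per_chain: dict[str, int] = {}
    for cid, _ in mutated:
        per_chain[cid] = per_chain.get(cid, 0) + 1
    chain_residues = {cid: len(entry.chain(cid).residues) for cid in per_chain}
    chain_coords = {}
    for cid in per_chain:
        chain_coords[cid] = _representative_coords(
            entry, [(cid, i + 1) for i in range(chain_residues[cid])])

    count = 0
    for _ in range(n_perm):
        pts = []
        for cid, k in per_chain.items():
            sel = rng.choice(chain_residues[cid], size=k, replace=False)
            pts.append(chain_coords[cid][sel])
        stat = float(pdist(np.vstack(pts)).mean())
        if stat <= obs + 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1), obs
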