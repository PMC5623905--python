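"""Chemical dissimilarity of amino-acid substitutions.

Each residue is represented by five standardised physico-chemical factors
(Atchley et al. 2005), condensing several hundred published property scales.
The chemical distance of a substitution is the Euclidean distance between the
two factor vectors; when a position carries several observed substitutions
the distances (or BLOSUM62 scores) are averaged over all of them.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._aa import AA1, ATCHLEY_FACTORS


def descriptor_table(
        table: Mapping[str, Sequence[float]] | None = None) -> dict[str, np.ndarray]:
    """The packaged five-factor table (or a user replacement) as arrays."""
    src = ATCHLEY_FACTORS if table is None else table
    return {aa: np.asarray(v, dtype=float) for aa, v in src.items()}


def _vector(aa: str, table: Mapping[str, np.ndarray]) -> np.ndarray:
    try:
        return table[aa]
    except KeyError:
        raise ValueError(f"non-standard residue {aa!r}") from None


def chemical_distance(ref_aa: str, alts: str | Iterable[str],
                      table: Mapping[str, Sequence[float]] | None = None,
                      ) -> float:
    """Mean Euclidean factor-space distance from ref to the observed alts."""
    tab = descriptor_table(table)
    if isinstance(alts, str):
        alts = list(alts)
    v_ref = _vector(ref_aa, tab)
    ds = [float(np.linalg.norm(v_ref - _vector(a, tab))) for a in alts]
    if not ds:
        raise ValueError("empty alternative set")
    return float(np.mean(ds))


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum_similarity(ref_aa: str, alts: str | Iterable[str]) -> float:
    """Mean BLOSUM62 substitution score from ref to the observed alts."""
    m = _blosum62()
    if isinstance(alts, str):
        alts = list(alts)
    if ref_aa not in AA1 or any(a not in AA1 for a in alts):
        raise ValueError("non-standard residue")
    scores = [float(m[ref_aa, a]) for a in alts]
    if not scores:
        raise ValueError("empty alternative set")
    return float(np.mean(scores))
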