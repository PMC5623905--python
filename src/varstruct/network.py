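"""Networks of complexes with mutated subunits.

Two mutated genes are connected when they map onto different chains of at
least one common template structure with sequence identity above 90% on both
chains; a gene mapping onto two or more chains of one structure gets a
self-loop (homooligomer).  Complexes with a single mutated subunit contribute
no edges and are not displayed.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import pandas as pd

from .scoring import AnnotatedVariant
from .templates import TemplateHit

DEFAULT_NETWORK_IDENTITY = 0.90


def build_network(hits: Sequence[TemplateHit],
                  annotated: Sequence[AnnotatedVariant],
                  identity_threshold: float = DEFAULT_NETWORK_IDENTITY,
                  ) -> nx.Graph:
    """Graph of mutated genes co-occurring as subunits of one structure.

    Nodes are genes carrying at least one mapped variant; an edge's
    ``structures`` attribute lists every supporting structure id.
    """
    mutated = {a.variant.gene_id for a in annotated if a.mapped}
    g = nx.Graph()
    by_structure: dict[str, dict[str, set[str]]] = {}
    for h in hits:
        if h.gene_id not in mutated or h.seq_id <= identity_threshold:
            continue
        by_structure.setdefault(h.structure_id, {}).setdefault(
            h.gene_id, set()).add(h.chain_id)

    def add_edge(gi: str, gj: str, sid: str) -> None:
        if g.has_edge(gi, gj):
            g[gi][gj]["structures"].add(sid)
        else:
            g.add_edge(gi, gj, structures={sid})

    for sid, gene_chains in by_structure.items():
        genes = sorted(gene_chains)
        for i, gi in enumerate(genes):
            # homooligomer: one gene on two or more chains of the structure
            if len(gene_chains[gi]) >= 2:
                add_edge(gi, gi, sid)
            for gj in genes[i + 1:]:
                # heteromer: the two genes occupy distinct chains
                if any(a != b for a in gene_chains[gi]
                       for b in gene_chains[gj]):
                    add_edge(gi, gj, sid)
    return g


def multi_mutated_complexes(g: nx.Graph) -> list[list[str]]:
    """Connected components representing complexes with several mutated
    subunits (>= 2 nodes, or a single node with a homooligomer self-loop),
    sorted by size descending then lexicographically."""
    comps = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) >= 2 or any(g.has_edge(n, n) for n in nodes):
            comps.append(nodes)
    comps.sort(key=lambda ns: (-len(ns), ns))
    return comps


def edges_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [(u, v, ";".join(sorted(d["structures"])))
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "structures"])


def write_graphml(g: nx.Graph, path) -> None:
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, structures=";".join(sorted(d["structures"])))
    nx.write_graphml(h, path)
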