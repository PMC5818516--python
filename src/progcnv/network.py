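"""Seed-neighborhood extraction from a supplied interaction network.

The network is an undirected edge list (self-loops removed, duplicate
edges collapsed).  Around a seed gene list the module extracts the
subnetwork induced by the seeds plus the top linker genes — non-seed
neighbors ranked by how many seeds they touch — and tabulates degrees
within that subnetwork.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def load_network(edges: pd.DataFrame) -> nx.Graph:
    """Build a clean undirected graph from an edge-list table.

    Expects columns ``gene_a``, ``gene_b`` and optionally ``weight``
    (preserved as an edge attribute, never used for ranking).
    Self-loops are dropped; duplicate edges collapse (last weight wins).
    """
    graph = nx.Graph()
    has_weight = "weight" in edges.columns
    for row in edges.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            continue
        if has_weight:
            graph.add_edge(a, b, weight=float(row.weight))
        else:
            graph.add_edge(a, b)
    return graph


def neighborhood(
    network: nx.Graph, seeds: Iterable[str], max_linkers: int = 20
) -> tuple[nx.Graph, list[str]]:
    """Induced subnetwork of seeds plus their top linker genes.

    Linkers are non-seed nodes adjacent to >= 1 seed, ranked by the
    number of distinct seeds they connect to (ties broken
    lexicographically by symbol).  Seeds absent from the network are
    warned about; no seed present at all is an error.
    """
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in network]
    absent = set(seeds) - set(present)
    if absent:
        logger.warning(
            "%d seed genes absent from the network, e.g. %s",
            len(absent),
            sorted(absent)[:5],
        )
    if not present:
        raise ValueError("no seed gene present in the network")

    seed_set = set(present)
    seed_links: dict[str, int] = {}
    for s in present:
        for nb in network.neighbors(s):
            if nb not in seed_set:
                seed_links[nb] = seed_links.get(nb, 0) + 1
    ranked = sorted(seed_links.items(), key=lambda item: (-item[1], item[0]))
    linkers = [gene for gene, _ in ranked[:max_linkers]]
    sub = network.subgraph(seed_set | set(linkers)).copy()
    return sub, linkers


def degree_table(subnetwork: nx.Graph) -> pd.DataFrame:
    """Per-gene connection counts within the subnetwork, sorted descending.

    Ties break lexicographically by gene symbol for determinism.
    """
    rows = sorted(subnetwork.degree(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"])
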