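"""Hypergeometric gene-set over-representation analysis.

For a query list of n genes drawn from a universe of N genes, the
over-representation p-value of a set with K members in the universe and
k members in the query is the upper-tail hypergeometric probability
P(X >= k).  Benjamini-Hochberg step-up adjustment controls the false
discovery rate across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a scoring universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        restricted: dict[str, set[str]] = {}
        dropped = []
        for name, members in self.sets.items():
            kept = set(members) & self.universe
            if kept:
                restricted[name] = kept
            else:
                dropped.append(name)
        if dropped:
            logger.warning(
                "dropped %d gene sets with no members in the universe, e.g. %s",
                len(dropped),
                dropped[:3],
            )
        self.sets = restricted

    @classmethod
    def from_mapping(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        return cls(
            sets={name: set(members) for name, members in sets.items()},
            universe=set(universe),
        )


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for overlap k, universe N, set K, query n."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, N={N}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Score every set in the collection against the query list.

    Query genes outside the universe are dropped with a warning; an
    empty restricted query is an error.  Returns a DataFrame with
    columns ``set``, ``k``, ``K``, ``n``, ``N``, ``p``, ``p_adj``
    sorted by adjusted p-value (ties by raw p, then set name).
    """
    query_set = set(query)
    inside = query_set & collection.universe
    outside = query_set - collection.universe
    if outside:
        logger.warning(
            "dropped %d query genes outside the universe, e.g. %s",
            len(outside),
            sorted(outside)[:5],
        )
    if not inside:
        raise ValueError("query is empty after restriction to the universe")

    N = len(collection.universe)
    n = len(inside)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(inside & members)
        rows.append((name, k, K, n, N, hypergeom_pvalue(k, N, K, n)))
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if result.empty:
        result["p_adj"] = []
        return result
    result["p_adj"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    return result.sort_values(
        ["p_adj", "p", "set"], kind="mergesort"
    ).reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: name, description, members, tab-separated."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("skipping malformed GMT line: %r", line[:60])
                continue
            name, _description, *members = fields
            sets[name] = {m for m in members if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as handle:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            handle.write(f"{name}\t{desc}\t{members}\n")
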