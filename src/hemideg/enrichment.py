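"""Hypergeometric over-representation analysis (ORA) of DEG lists.

Query = DEGs at nominal p < 0.05, universe = all detected genes (those
passing the expression filter), term sets intersected with the universe.
One-sided upper-tail hypergeometric p per term, BH adjustment across tested
terms. Up/down direction of overlapping genes is annotation only here (the
cell-type analysis tests directions separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, ValidationError
from .de import bh_adjust


@dataclass
class OraResult:
    """One enrichment test record.

    k = overlap count, K = term size within the universe, n = query size,
    N = universe size; p = P(X >= k), X ~ Hypergeometric(N, K, n).
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    adjusted_p: float = float("nan")
    overlap: frozenset = frozenset()
    members_up: list = field(default_factory=list)
    members_down: list = field(default_factory=list)


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def ora(query, universe, collection: GeneSetCollection,
        min_term: int = 5, max_term: int = 500) -> list[OraResult]:
    """Over-representation of a gene list against a gene-set collection.

    Terms whose universe-intersected size falls outside [min_term, max_term]
    are skipped. Results are BH-adjusted across tested terms and sorted by p.
    """
    query, universe = set(query), set(universe)
    stray = query - universe
    if stray:
        raise ValidationError(f"query gene(s) not in universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    results = []
    for term_id, term_name, members in collection:
        in_universe = members & universe
        K = len(in_universe)
        if not (min_term <= K <= max_term):
            continue
        overlap = in_universe & query
        k = len(overlap)
        results.append(OraResult(term_id, term_name, k, K, n, N,
                                 hypergeom_upper(k, N, K, n),
                                 overlap=frozenset(overlap)))
    if results:
        adj = bh_adjust(np.array([r.p for r in results]))
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def direction_split(result: OraResult, pain: pd.DataFrame) -> OraResult:
    """Fill members_up/members_down from the Pain contrast log2FC signs.

    Genes with exactly zero log2FC are assigned to neither list.
    """
    missing = [g for g in result.overlap if g not in pain.index]
    if missing:
        raise ValidationError(f"overlap gene(s) missing from contrast: {missing[:5]}")
    lfc = pain.loc[sorted(result.overlap), "log2fc"]
    result.members_up = lfc.index[lfc > 0].tolist()
    result.members_down = lfc.index[lfc < 0].tolist()
    return result


def ora_to_frame(results: list[OraResult]) -> pd.DataFrame:
    rows = [{
        "term_id": r.term_id, "term_name": r.term_name, "k": r.k, "K": r.K,
        "n": r.n, "N": r.N, "p": r.p, "adjusted_p": r.adjusted_p,
        "members_up": ",".join(r.members_up), "members_down": ",".join(r.members_down),
    } for r in results]
    return pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N",
                                       "p", "adjusted_p", "members_up", "members_down"])


def export_term_gene_network(results: list[OraResult],
                             domains: dict | None = None) -> pd.DataFrame:
    """Bipartite term-gene edge table for network export.

    Each overlapping gene contributes one edge per term, labeled with its
    regulation direction (from direction_split, 'none' if unsplit) and the
    term's user-supplied domain (neuronal / immune / glial / unassigned).
    Genes connected to terms of >= 2 distinct assigned domains are flagged
    as 'linking' hubs.
    """
    domains = dict(domains or {})
    known_terms = {r.term_id for r in results}
    for term_id in list(domains):
        if term_id not in known_terms:
            domains.pop(term_id)  # warn-and-skip: term absent from results
    rows = []
    for r in results:
        domain = domains.get(r.term_id, "unassigned")
        for gene in sorted(r.overlap):
            if gene in r.members_up:
                direction = "up"
            elif gene in r.members_down:
                direction = "down"
            else:
                direction = "none"
            rows.append({"term_id": r.term_id, "gene": gene,
                         "direction": direction, "domain": domain})
    edges = pd.DataFrame(rows, columns=["term_id", "gene", "direction", "domain"])
    if edges.empty:
        edges["linking"] = pd.Series(dtype=bool)
        return edges
    assigned = edges[edges["domain"] != "unassigned"]
    n_domains = assigned.groupby("gene")["domain"].nunique()
    linking_genes = set(n_domains.index[n_domains >= 2])
    edges["linking"] = edges["gene"].isin(linking_genes)
    return edges
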