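"""Query-centered co-expression networks with term and PPI overlays.

Given a log2 expression matrix, the neighbors of a query gene are the genes
whose Pearson correlation with the query strictly exceeds a cutoff (default
0.75), truncated to the top k (default 50) and ranked by correlation.
Functional-category terms (e.g. MapMan bins) annotate the nodes, term
over-representation is assessed with a one-sided hypergeometric test against
the annotated background, and known protein-protein interaction edges between
network members can be overlaid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CoexpressionNetwork",
    "EnrichmentResult",
    "coexpressed_genes",
    "attach_terms",
    "term_enrichment",
    "overlay_ppi",
    "CoexpressionNetworkBuilder",
]

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionNetwork:
    """A query gene, its ranked neighbors, and annotation/PPI overlays."""

    query: str
    neighbors: list[tuple[str, float]]  # (locus, pcc) sorted by pcc desc
    edges: list[tuple[str, str, str, float]] = field(default_factory=list)
    terms: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.edges:
            self.edges = [
                (self.query, locus, "coexpression", pcc)
                for locus, pcc in self.neighbors
            ]

    @property
    def nodes(self) -> list[str]:
        return [self.query] + [l for l, _ in self.neighbors]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, terms=self.terms.get(node, []))
        for a, b, kind, w in self.edges:
            g.add_edge(a, b, kind=kind, weight=w)
        return g


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_in_network: int
    K_in_background: int
    n_network: int
    N_background: int
    p_value: float

    def __post_init__(self) -> None:
        assert self.k_in_network <= self.K_in_background
        assert self.k_in_network <= self.n_network
        assert self.n_network <= self.N_background


def _pcc_to_query(matrix: pd.DataFrame, query: str) -> pd.Series:
    """Pearson correlation of every row against the query row."""
    q = matrix.loc[query].to_numpy(dtype=float)
    qc = q - q.mean()
    qnorm = np.sqrt(qc @ qc)
    if qnorm == 0:
        raise ValueError(f"query {query!r} has zero expression variance")
    arr = matrix.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered @ qc) / (norms * qnorm)
    return pd.Series(r, index=matrix.index)


def coexpressed_genes(
    matrix: pd.DataFrame,
    query: str,
    min_pcc: float = 0.75,
    top_k: int = 50,
) -> list[tuple[str, float]]:
    """Genes correlated with the query strictly above ``min_pcc``, top ``top_k``.

    The query is excluded from its own neighbor list; zero-variance genes can
    never qualify.  Ties at the truncation boundary are ordered
    lexicographically by locus id, then cut.
    """
    if query not in matrix.index:
        raise KeyError(f"query {query!r} not in expression matrix")
    r = _pcc_to_query(matrix, query).drop(query)
    r = r[r > min_pcc].dropna()
    ranked = sorted(r.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(locus, float(pcc)) for locus, pcc in ranked[:top_k]]


def attach_terms(
    network: CoexpressionNetwork,
    term_table: Mapping[str, Sequence[str]],
) -> CoexpressionNetwork:
    """Annotate every node; nodes missing from the table get 'unassigned'."""
    network.terms = {
        node: list(term_table.get(node)) if term_table.get(node) else [UNASSIGNED]
        for node in network.nodes
    }
    return network


def term_enrichment(
    network: CoexpressionNetwork,
    term_table: Mapping[str, Sequence[str]],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term among network nodes.

    The background is the annotated gene universe (genes of the expression
    matrix that carry at least one term).  For each term held by K of N
    background genes and k of the n annotated network genes, the upper-tail
    p-value P(X >= k) is computed; results are sorted by p.
    """
    bg = [g for g in background if term_table.get(g)]
    N = len(bg)
    bg_set = set(bg)
    net_annot = [g for g in network.nodes if g in bg_set]
    n = len(net_annot)
    term_bg: dict[str, int] = {}
    for g in bg:
        for t in term_table[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
    term_net: dict[str, int] = {}
    for g in net_annot:
        for t in term_table[g]:
            term_net[t] = term_net.get(t, 0) + 1
    results = []
    for t, k in term_net.items():
        K = term_bg.get(t)
        if K is None:
            continue  # term absent from background: skip
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(t, k, K, n, N, min(p, 1.0)))
    return sorted(results, key=lambda r: (r.p_value, r.term))


def overlay_ppi(
    network: CoexpressionNetwork,
    ppi_edges: Iterable[tuple[str, str]],
) -> CoexpressionNetwork:
    """Add protein-interaction edges between existing network nodes.

    Edges touching genes outside the network are ignored; no new nodes are
    introduced.
    """
    nodes = set(network.nodes)
    existing = {(min(a, b), max(a, b)) for a, b, kind, _ in network.edges if kind == "ppi"}
    for a, b in ppi_edges:
        key = (min(a, b), max(a, b))
        if a in nodes and b in nodes and a != b and key not in existing:
            network.edges.append((a, b, "ppi", 1.0))
            existing.add(key)
    return network


class CoexpressionNetworkBuilder(BaseEstimator):
    """Build query-centered co-expression networks from a log2 matrix.

    Parameters
    ----------
    min_pcc : float
        Strict lower bound on neighbor correlation (default 0.75).
    top_k : int
        Maximum number of neighbors kept (default 50).

    After ``fit(X)`` call :meth:`network` per query gene.
    """

    def __init__(self, min_pcc: float = 0.75, top_k: int = 50) -> None:
        self.min_pcc = min_pcc
        self.top_k = top_k

    def fit(self, X: pd.DataFrame, y=None) -> "CoexpressionNetworkBuilder":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a genes-by-samples DataFrame")
        self.matrix_ = X
        return self

    def network(
        self,
        query: str,
        term_table: Mapping[str, Sequence[str]] | None = None,
        ppi_edges: Iterable[tuple[str, str]] | None = None,
    ) -> CoexpressionNetwork:
        neighbors = coexpressed_genes(self.matrix_, query, self.min_pcc, self.top_k)
        net = CoexpressionNetwork(query, neighbors)
        if term_table is not None:
            attach_terms(net, term_table)
        if ppi_edges is not None:
            overlay_ppi(net, ppi_edges)
        return net
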