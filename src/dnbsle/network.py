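"""Template interaction network: I/O, local neighbourhoods, topological ranking.

The template network is an undirected gene-interaction graph (typically a
STRING protein-protein-interaction export) over which local entropies are
computed.  Each gene's *local network* is the gene plus its first-order
neighbours; a K-gene network yields K local networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

_MCC_MAX_NODES = 5000


class NetworkError(ValueError):
    """Raised for malformed edge lists or empty/invalid networks."""


def _check_gene_id(symbol: str) -> str:
    if not symbol or any(c.isspace() for c in symbol):
        raise NetworkError(f"invalid gene identifier: {symbol!r}")
    return symbol


@dataclass(frozen=True)
class LocalNetwork:
    """A center gene with its first-order neighbours (sorted, deterministic)."""

    center: str
    neighbors: tuple[str, ...]

    @property
    def M(self) -> int:
        return len(self.neighbors)


class TemplateNetwork:
    """Undirected gene-interaction graph with optional STRING-style edge scores.

    Thin wrapper around :class:`networkx.Graph` enforcing the domain
    invariants: no self-loops, symmetric edges, scores in [0, 1000].
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph() if graph is None else graph
        self._g.remove_edges_from(nx.selfloop_edges(self._g))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "TemplateNetwork":
        g = nx.Graph()
        for n in nodes:
            g.add_node(_check_gene_id(n))
        for e in edges:
            u, v = _check_gene_id(e[0]), _check_gene_id(e[1])
            if u == v:
                continue
            if len(e) >= 3 and e[2] is not None:
                g.add_edge(u, v, score=float(e[2]))
            else:
                g.add_edge(u, v)
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, gene: str) -> list[str]:
        return sorted(self._g.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self._g.degree(gene)

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self._g.edges):
                score = self._g.edges[u, v].get("score")
                if score is None:
                    fh.write(f"{u}\t{v}\n")
                else:
                    fh.write(f"{u}\t{v}\t{score:g}\n")


def _looks_like_header(tokens: list[str]) -> bool:
    # STRING exports head with e.g. "protein1 protein2 combined_score";
    # a numeric third token rules a data row out of being a header.
    lowered = [t.lower() for t in tokens]
    header_words = {"gene", "gene1", "gene2", "protein1", "protein2", "node1",
                    "node2", "combined_score", "score", "source", "target",
                    "genea", "geneb", "from", "to"}
    return any(t in header_words for t in lowered)


def read_edge_list(
    path: str | Path,
    score_cutoff: float | None = None,
    skip_header: bool | None = None,
) -> TemplateNetwork:
    """Read a 2- or 3-column whitespace/tab-separated edge list.

    Self-loops are dropped and duplicate (including swapped-order) edges are
    collapsed.  When ``score_cutoff`` is given and a third column is present,
    edges scoring below the cutoff are excluded.  ``skip_header=None``
    auto-detects a header row from common column-name tokens.
    """
    edges: list[tuple[str, str, float | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if lineno == 1 and (skip_header or (skip_header is None and _looks_like_header(tokens))):
                continue
            if len(tokens) not in (2, 3):
                raise NetworkError(
                    f"{path}: line {lineno}: expected 2-3 columns, got {len(tokens)}"
                )
            score: float | None = None
            if len(tokens) == 3:
                try:
                    score = float(tokens[2])
                except ValueError as exc:
                    raise NetworkError(
                        f"{path}: line {lineno}: non-numeric score {tokens[2]!r}"
                    ) from exc
                if score_cutoff is not None and score < score_cutoff:
                    continue
            u, v = tokens[0], tokens[1]
            if u == v:
                logger.debug("dropping self-loop %s-%s at line %d", u, v, lineno)
                continue
            edges.append((u, v, score))
    net = TemplateNetwork.from_edges(edges)
    if len(net) == 0:
        raise NetworkError(f"{path}: empty network after filtering")
    return net


def restrict_to_measured(network: TemplateNetwork, measured: set[str]) -> TemplateNetwork:
    """Induced subgraph on the genes that were actually measured.

    Measured genes absent from the template are logged, not an error; an
    empty intersection is an error.  Idempotent.
    """
    if not measured:
        raise NetworkError("measured gene set is empty")
    keep = network.nodes & measured
    missing = measured - network.nodes
    if missing:
        logger.info("%d measured genes absent from template network", len(missing))
    if not keep:
        raise NetworkError("no measured gene is present in the template network")
    return TemplateNetwork(network.graph.subgraph(keep).copy())


def local_networks(network: TemplateNetwork) -> list[LocalNetwork]:
    """One local network per node; neighbours sorted lexicographically.

    Isolated nodes yield M = 0 locals (flagged at DEBUG); they are retained
    here and skipped by the entropy scorer.
    """
    if len(network) == 0:
        raise NetworkError("empty network")
    out = []
    for node in sorted(network.graph.nodes):
        neigh = tuple(sorted(network.graph.neighbors(node)))
        if not neigh:
            logger.debug("isolated gene %s (M=0)", node)
        out.append(LocalNetwork(center=node, neighbors=neigh))
    return out


def first_order_neighbors(network: TemplateNetwork, genes: set[str]) -> set[str]:
    """Union of neighbours of the query genes, minus the query genes."""
    result: set[str] = set()
    for g in genes:
        if g not in network.graph:
            logger.info("query gene %s not in network; skipped", g)
            continue
        result.update(network.graph.neighbors(g))
    return result - genes


def _mcc_scores(g: nx.Graph) -> dict[str, float]:
    # Maximal Clique Centrality: MCC(v) = sum over maximal cliques C containing
    # v of (|C| - 1)!.  Exact enumeration; guarded by a node-count ceiling.
    if g.number_of_nodes() > _MCC_MAX_NODES:
        raise NetworkError(
            f"MCC restricted to graphs with <= {_MCC_MAX_NODES} nodes "
            f"(got {g.number_of_nodes()}); use method='degree'"
        )
    scores = {v: 0.0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def topological_rank(
    network: TemplateNetwork,
    genes: set[str],
    method: str = "degree",
) -> list[tuple[str, float]]:
    """Rank ``genes`` by a hub-centrality score on their induced subgraph.

    ``degree`` counts edges within the induced subgraph; ``mcc`` is the
    Maximal Clique Centrality.  Descending score, ties broken
    lexicographically.
    """
    unknown = genes - network.nodes
    if unknown:
        raise NetworkError(f"genes not in network: {sorted(unknown)[:5]}")
    sub = network.graph.subgraph(genes)
    if method == "degree":
        scores = {v: float(sub.degree(v)) for v in sub.nodes}
    elif method == "mcc":
        scores = _mcc_scores(nx.Graph(sub))
    else:
        raise NetworkError(f"unknown ranking method: {method!r}")
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
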