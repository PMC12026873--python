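"""Compound-target and protein-protein interaction network analysis.

Builds the bipartite compound-target (C-T) graph from predictions restricted
to disease-relevant "key" targets, loads STRING-style PPI edge tables, and
ranks nodes by degree and Brandes betweenness centrality.  Path counting is
always on the unweighted graph; PPI combined scores are kept as edge
attributes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AnnotatedGraph",
    "intersect_targets",
    "build_ct_network",
    "betweenness",
    "read_ppi_edges",
    "rank_hubs",
    "write_sif",
    "write_graphml",
    "write_node_attributes",
]


@dataclass
class AnnotatedGraph:
    """A simple undirected graph with typed nodes (compound|target).

    Wraps a :class:`networkx.Graph`; node attribute ``kind`` distinguishes
    compounds from targets, edge attribute ``weight`` (optional) carries the
    PPI combined score on a 0-1000 scale.
    """

    graph: nx.Graph

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def betweenness(self, normalized: bool = False) -> dict[str, float]:
        return betweenness(self, normalized=normalized)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == kind]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def intersect_targets(predicted: set[str], disease: set[str]) -> set[str]:
    """Key targets: exact intersection of predicted and disease gene sets."""
    key = set(predicted) & set(disease)
    log.info("intersect_targets: %d predicted ∩ %d disease -> %d key targets",
             len(predicted), len(disease), len(key))
    return key


def build_ct_network(predictions: Iterable, key_targets: set[str]) -> AnnotatedGraph:
    """Bipartite compound-target graph over predictions to key targets.

    One edge per prediction whose target gene symbol is a key target;
    compounds or targets without any such edge do not appear.
    """
    g = nx.Graph()
    for p in predictions:
        if p.gene_symbol in key_targets:
            g.add_node(p.compound_id, kind="compound")
            g.add_node(p.gene_symbol, kind="target")
            g.add_edge(p.compound_id, p.gene_symbol, z=float(p.z))
    return AnnotatedGraph(g)


def _as_nx(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, AnnotatedGraph) else graph


def betweenness(graph, normalized: bool = False) -> dict[str, float]:
    """Brandes betweenness centrality on the unweighted graph.

    Endpoints are excluded and each unordered pair is counted once
    (undirected convention); unnormalized by default.
    """
    return nx.betweenness_centrality(_as_nx(graph), normalized=normalized,
                                     weight=None)


def read_ppi_edges(path, score_min: float = 400,
                   allowed_nodes: Optional[set[str]] = None) -> AnnotatedGraph:
    """Load a STRING-export-style edge table (node1, node2, combined_score).

    Keeps edges with ``combined_score >= score_min`` and, when
    ``allowed_nodes`` is given, both endpoints inside it.  Symmetric
    duplicate rows collapse to a single edge (the larger score wins);
    self-loops are dropped.  Malformed rows raise with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"node1", "node2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    g = nx.Graph()
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        a, b = str(row["node1"]).strip().upper(), str(row["node2"]).strip().upper()
        try:
            score = float(row["combined_score"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:{lineno}: non-numeric combined_score "
                f"{row['combined_score']!r}")
        if not a or not b or a == "NAN" or b == "NAN":
            raise ValueError(f"{path}:{lineno}: empty node id")
        if a == b:
            continue
        if score < score_min:
            continue
        if allowed_nodes is not None and (a not in allowed_nodes
                                          or b not in allowed_nodes):
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], score)
        else:
            g.add_node(a, kind="target")
            g.add_node(b, kind="target")
            g.add_edge(a, b, weight=score)
    return AnnotatedGraph(g)


def rank_hubs(graph, deg_set: Optional[set[str]] = None,
              top_k: Optional[int] = None) -> tuple[list[str], list[str]]:
    """Rank target nodes by degree (ties: betweenness, then id).

    Returns ``(by_degree, core)`` where ``by_degree`` ranks every target node
    and ``core`` is the sub-ranking restricted to targets also present in
    ``deg_set`` (e.g. the expression-derived disease genes), truncated to
    ``top_k``.  Deterministic for fixed input.
    """
    g = _as_nx(graph)
    bc = betweenness(g)
    targets = [n for n, d in g.nodes(data=True) if d.get("kind") == "target"]
    by_degree = sorted(targets, key=lambda n: (-g.degree(n), -bc[n], n))
    if deg_set is None:
        core = []
    else:
        core = [n for n in by_degree if n in deg_set]
    if top_k is not None:
        core = core[:top_k]
    return by_degree, core


def write_sif(graph, path, interaction: str = "it") -> None:
    """Cytoscape SIF export: ``node<TAB>interaction<TAB>node`` per edge."""
    g = _as_nx(graph)
    with Path(path).open("w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_graphml(graph, path) -> None:
    nx.write_graphml(_as_nx(graph), str(path))


def write_node_attributes(graph, path) -> pd.DataFrame:
    """Node table (id, kind, degree, betweenness raw and normalized) as TSV."""
    g = _as_nx(graph)
    bc = betweenness(g, normalized=False)
    bcn = betweenness(g, normalized=True)
    df = pd.DataFrame({
        "id": list(g.nodes()),
        "kind": [g.nodes[n].get("kind", "") for n in g.nodes()],
        "degree": [g.degree(n) for n in g.nodes()],
        "betweenness": [bc[n] for n in g.nodes()],
        "betweenness_normalized": [bcn[n] for n in g.nodes()],
    }).sort_values(["degree", "betweenness", "id"],
                   ascending=[False, False, True], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
    return df
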