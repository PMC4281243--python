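"""Bipartite tissue-sharing network of enriched and group-enriched genes.

Enriched genes of the target tissue (a singleton tissue set) and group-enriched
genes shared with at most a few partner tissues are aggregated into one node
per distinct tissue combination.  Each group node carries the number of genes
with that combination and a display size equal to the square root of that
count, and connects to exactly the tissues in its combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import DataError
from .specificity_classifier import Category, GeneClassification

__all__ = ["SharingNetwork", "build_sharing_network", "write_network_edgelist", "read_network_edgelist"]

_ENRICHED = {Category.HIGHLY_ENRICHED, Category.MODERATELY_ENRICHED}


@dataclass
class SharingNetwork:
    """Bipartite graph with tissue nodes and tissue-combination (group) nodes."""

    graph: nx.Graph

    @property
    def tissue_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "tissue")

    @property
    def group_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "group")

    def gene_count(self, group_node: str) -> int:
        return int(self.graph.nodes[group_node]["gene_count"])

    def display_size(self, group_node: str) -> float:
        return float(self.graph.nodes[group_node]["display_size"])

    def tissues_of(self, group_node: str) -> frozenset[str]:
        return frozenset(self.graph.neighbors(group_node))

    @property
    def total_genes(self) -> int:
        return sum(self.gene_count(g) for g in self.group_nodes)


def _group_node_id(tissues: frozenset[str]) -> str:
    return "group:" + "+".join(sorted(tissues))


def build_sharing_network(
    classifications: Sequence[GeneClassification],
    target: str,
    max_partners: int = 3,
) -> SharingNetwork:
    """Aggregate enriched/group-enriched genes into the sharing network.

    Includes target-enriched genes (combination ``{target}``) and
    group-enriched genes whose group has at most *max_partners* tissues besides
    the target (i.e. total group size <= max_partners + 1).
    """
    combos: dict[frozenset[str], int] = {}
    for c in classifications:
        if c.category in _ENRICHED:
            combo = frozenset({target})
        elif c.category is Category.GROUP_ENRICHED:
            if target not in c.enriched_group:
                raise DataError(f"{c.gene_id}: enriched group lacks target tissue {target!r}")
            if len(c.enriched_group) - 1 > max_partners:
                continue
            combo = frozenset(c.enriched_group)
        else:
            continue
        combos[combo] = combos.get(combo, 0) + 1

    graph = nx.Graph()
    for combo, count in sorted(combos.items(), key=lambda kv: _group_node_id(kv[0])):
        node = _group_node_id(combo)
        graph.add_node(node, kind="group", gene_count=count, display_size=math.sqrt(count))
        for tissue in sorted(combo):
            if tissue not in graph:
                graph.add_node(tissue, kind="tissue")
            graph.add_edge(node, tissue)
    return SharingNetwork(graph)


def write_network_edgelist(network: SharingNetwork, node_path: str | Path, edge_path: str | Path) -> None:
    """Write node and edge tables as TSV (loadable by standard graph tools)."""
    nodes = pd.DataFrame(
        [
            {
                "id": n,
                "type": d["kind"],
                "gene_count": d.get("gene_count", ""),
                "display_size": d.get("display_size", ""),
            }
            for n, d in sorted(network.graph.nodes(data=True))
        ],
        columns=["id", "type", "gene_count", "display_size"],
    )
    edges = pd.DataFrame(
        sorted(
            (g, t)
            for g in network.group_nodes
            for t in network.graph.neighbors(g)
        ),
        columns=["source", "target"],
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)


def read_network_edgelist(node_path: str | Path, edge_path: str | Path) -> SharingNetwork:
    """Inverse of :func:`write_network_edgelist`."""
    nodes = pd.read_csv(node_path, sep="\t", dtype={"id": str, "type": str})
    edges = pd.read_csv(edge_path, sep="\t", dtype=str)
    graph = nx.Graph()
    for row in nodes.itertuples():
        if row.type == "group":
            graph.add_node(
                row.id,
                kind="group",
                gene_count=int(row.gene_count),
                display_size=float(row.display_size),
            )
        else:
            graph.add_node(row.id, kind="tissue")
    for row in edges.itertuples():
        graph.add_edge(row.source, row.target)
    return SharingNetwork(graph)
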