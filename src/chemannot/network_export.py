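"""Bipartite chemical-annotation networks and their serialization.

The enrichment view of an analysis is naturally a bipartite graph: input
chemicals on one side, enriched annotation terms on the other, with an edge
wherever a chemical carries a term.  This module builds that graph from an
enrichment result list and writes it in formats common graph viewers accept
(node-link JSON, SIF, GraphML).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .enrichment import EnrichmentResult
from .reference_space import ReferenceSpace


@dataclass
class BioactivityNetwork:
    """A strictly bipartite chemical-term graph.

    Node dicts carry ``id``, ``kind`` ("chemical" or "term"), ``label`` and,
    for term nodes, ``category`` and ``adjusted_p``.  Term node ids are
    ``database:term_id`` so identical codes from different databases stay
    distinct.  Every term node has at least one edge.
    """

    nodes: list[dict] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def node_ids(self, kind: str | None = None) -> list[str]:
        return [n["id"] for n in self.nodes if kind is None or n["kind"] == kind]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {k: v for k, v in node.items() if k != "id"}
            g.add_node(node["id"], **attrs)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        kinds = {n["id"]: n["kind"] for n in self.nodes}
        degree: dict[str, int] = {}
        for chem, term in self.edges:
            if kinds.get(chem) != "chemical" or kinds.get(term) != "term":
                raise ValueError(f"edge ({chem}, {term}) is not chemical->term")
            degree[term] = degree.get(term, 0) + 1
        for node_id, kind in kinds.items():
            if kind == "term" and degree.get(node_id, 0) == 0:
                raise ValueError(f"isolated term node {node_id}")


def build_network(
    results: list[EnrichmentResult],
    only_enriched: bool = True,
    space: ReferenceSpace | None = None,
) -> BioactivityNetwork:
    """Build the bipartite network over (by default) the enriched terms.

    One term node per retained result with at least one member, one chemical
    node per distinct member, one edge per (member, term) pair.  Chemical
    labels use the preferred name when a reference space is given.  Node
    order is deterministic: chemicals then terms, each lexicographic.
    """
    retained = [
        r
        for r in results
        if (r.enriched or not only_enriched) and r.members
    ]
    chem_ids = sorted({cid for r in retained for cid in r.members})
    term_nodes = []
    edges = []
    for r in retained:
        node_id = f"{r.term.database}:{r.term.term_id}"
        term_nodes.append(
            {
                "id": node_id,
                "kind": "term",
                "label": r.term.label,
                "category": r.term.category,
                "adjusted_p": r.adjusted_p,
            }
        )
        edges.extend((cid, node_id) for cid in r.members)
    term_nodes.sort(key=lambda n: n["id"])

    def chem_label(cid: str) -> str:
        if space is not None and cid in space.records:
            return space.records[cid].preferred_name or cid
        return cid

    chem_nodes = [
        {"id": cid, "kind": "chemical", "label": chem_label(cid)} for cid in chem_ids
    ]
    net = BioactivityNetwork(nodes=chem_nodes + term_nodes, edges=sorted(edges))
    net.validate()
    return net


FORMATS = ("json_graph", "sif", "graphml")


def write_network(net: BioactivityNetwork, path: str, format: str = "json_graph") -> None:
    """Serialize a network; output is byte-deterministic for equal networks."""
    net.validate()
    if format == "json_graph":
        payload = {
            "directed": False,
            "nodes": net.nodes,
            "edges": [{"source": c, "target": t} for c, t in net.edges],
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for chem, term in net.edges:
                fh.write(f"{chem}\tannotated_with\t{term}\n")
    elif format == "graphml":
        g = net.to_networkx()
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_network_json(path: str) -> BioactivityNetwork:
    """Inverse of ``write_network(..., format='json_graph')``."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    edges = [(e["source"], e["target"]) for e in payload["edges"]]
    return BioactivityNetwork(nodes=payload["nodes"], edges=edges)
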