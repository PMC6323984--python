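"""Plasmid relatedness network: thresholded MinHash edges and clusters.

Every unordered pair of curated plasmids is sketched and compared; an edge
is retained when the comparison is both significant (p <= 0.05 by default)
and close (Mash distance < 0.1 by default).  These cutoffs keep only pairs
whose distance correlates with an average nucleotide identity above ~90%.
Clusters are the connected components of the retained-edge graph;
plasmids with no retained edge are singletons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import networkx as nx

from .curate import PlasmidRecord
from .sketch import DistanceEdge, SketchParams, distance_edge, sketch_sequence

if TYPE_CHECKING:  # pragma: no cover
    from .metadata import MetadataStore

__all__ = [
    "EdgeThresholds",
    "PlasmidGraph",
    "build_network",
    "assign_clusters",
    "export_graph_json",
    "write_graph_json",
    "load_graph_json",
    "write_edge_list",
]

SINGLETON = None  # cluster marker for degree-0 nodes


@dataclass(frozen=True)
class EdgeThresholds:
    """Edge retention cutoffs.

    Defaults: p <= 0.05 (inclusive) and d < 0.1 (strict), the comparison
    semantics under which retained links correspond to ANI > 0.9.
    """

    max_p: float = 0.05
    max_d: float = 0.1
    p_inclusive: bool = True
    d_inclusive: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.max_p <= 1:
            raise ValueError(f"max_p must be in (0, 1], got {self.max_p}")
        if not 0 < self.max_d <= 1:
            raise ValueError(f"max_d must be in (0, 1], got {self.max_d}")

    def passes(self, edge: DistanceEdge) -> bool:
        p_ok = edge.p <= self.max_p if self.p_inclusive else edge.p < self.max_p
        d_ok = edge.d <= self.max_d if self.d_inclusive else edge.d < self.max_d
        return p_ok and d_ok


@dataclass
class PlasmidGraph:
    """Nodes (accessions), retained edges, and cluster labels.

    ``cluster_of`` maps each accession to a 1-based cluster id, or to
    ``None`` for singletons, once :func:`assign_clusters` has run.
    """

    nodes: list[str]
    edges: list[DistanceEdge]
    length_of: dict[str, int]
    cluster_of: dict[str, int | None] = field(default_factory=dict)

    @property
    def singletons(self) -> list[str]:
        return [n for n in self.nodes if self.cluster_of.get(n) is SINGLETON]

    @property
    def n_clusters(self) -> int:
        ids = {c for c in self.cluster_of.values() if c is not None}
        return len(ids)

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges:
            adj[e.accession_a].add(e.accession_b)
            adj[e.accession_b].add(e.accession_a)
        return adj


def build_network(
    records: Sequence[PlasmidRecord],
    params: SketchParams | None = None,
    thresholds: EdgeThresholds | None = None,
    *,
    cluster: bool = True,
) -> PlasmidGraph:
    """All-pairs sketch comparison of curated plasmids under the thresholds.

    Every record becomes a node, including plasmids that end up with no
    edges.  Edges are emitted in lexicographic pair order so repeated runs
    are byte-identical downstream.
    """
    if not records:
        raise ValueError("cannot build a network from zero records")
    params = params or SketchParams()
    thresholds = thresholds or EdgeThresholds()
    profiles = {
        r.accession: sketch_sequence(r.sequence, params, accession=r.accession)
        for r in records
    }
    edges: list[DistanceEdge] = []
    for acc_a, acc_b in combinations(sorted(profiles), 2):
        edge = distance_edge(profiles[acc_a], profiles[acc_b])
        if thresholds.passes(edge):
            edges.append(edge)
    graph = PlasmidGraph(
        nodes=[r.accession for r in records],
        edges=edges,
        length_of={r.accession: r.length_bp for r in records},
    )
    if cluster:
        assign_clusters(graph)
    return graph


def assign_clusters(graph: PlasmidGraph) -> PlasmidGraph:
    """Label connected components; degree-0 nodes are singletons.

    Cluster ids start at 1 and are assigned in order of each component's
    lexicographically smallest accession, so labels are deterministic for
    a given edge set.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.accession_a, e.accession_b) for e in graph.edges)
    components = [c for c in nx.connected_components(g) if len(c) > 1]
    components.sort(key=min)
    cluster_of: dict[str, int | None] = {n: SINGLETON for n in graph.nodes}
    for cid, comp in enumerate(components, start=1):
        for node in comp:
            cluster_of[node] = cid
    graph.cluster_of = cluster_of
    return graph


def export_graph_json(
    graph: PlasmidGraph, store: "MetadataStore | None" = None
) -> dict:
    """Graph as a JSON-ready document: nodes with metadata, links with metrics.

    Each link carries the shared-hash count, Jaccard estimate, distance,
    p-value and the size ratio min(length)/max(length) of its endpoints.
    The document is fully ordered, so serialization is byte-stable.
    """
    nodes = []
    for acc in sorted(graph.nodes):
        meta = store.meta_of(acc) if store is not None else None
        nodes.append(
            {
                "accession": acc,
                "length_bp": graph.length_of[acc],
                "cluster": graph.cluster_of.get(acc),
                "species": meta.species if meta is not None else None,
            }
        )
    links = []
    for e in sorted(graph.edges, key=lambda e: (e.accession_a, e.accession_b)):
        len_a = graph.length_of[e.accession_a]
        len_b = graph.length_of[e.accession_b]
        links.append(
            {
                "pair": [e.accession_a, e.accession_b],
                "x": e.x,
                "j": e.j,
                "d": e.d,
                "p": e.p,
                "size_ratio": min(len_a, len_b) / max(len_a, len_b),
            }
        )
    return {"nodes": nodes, "links": links}


def write_graph_json(
    graph: PlasmidGraph, path: str | Path, store: "MetadataStore | None" = None
) -> None:
    doc = export_graph_json(graph, store)
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def load_graph_json(path: str | Path) -> PlasmidGraph:
    """Reconstruct a :class:`PlasmidGraph` from an exported document."""
    doc = json.loads(Path(path).read_text())
    nodes = [n["accession"] for n in doc["nodes"]]
    length_of = {n["accession"]: n["length_bp"] for n in doc["nodes"]}
    cluster_of = {n["accession"]: n["cluster"] for n in doc["nodes"]}
    edges = [
        DistanceEdge(
            accession_a=l["pair"][0],
            accession_b=l["pair"][1],
            x=l["x"],
            j=l["j"],
            d=l["d"],
            p=l["p"],
        )
        for l in doc["links"]
    ]
    return PlasmidGraph(
        nodes=nodes, edges=edges, length_of=length_of, cluster_of=cluster_of
    )


def write_edge_list(graph: PlasmidGraph, path: str | Path) -> None:
    """Tab-separated edge list: acc_a, acc_b, x, j, d, p."""
    lines = ["accession_a\taccession_b\tx\tj\td\tp"]
    for e in sorted(graph.edges, key=lambda e: (e.accession_a, e.accession_b)):
        lines.append(
            f"{e.accession_a}\t{e.accession_b}\t{e.x}\t{e.j!r}\t{e.d!r}\t{e.p!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
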