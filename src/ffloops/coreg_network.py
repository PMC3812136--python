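"""TF-miRNA co-regulatory network assembly and topology analysis.

A network is the union of the edges of a list of FFLs: nodes typed TF, miRNA
or gene; directed edges typed by the regulator (TF_regulation or
miRNA_regulation). On top of it: undirected degree and the hub node,
per-regulator FFL occurrence rankings, the ego subnetwork of a node (its
direct neighbors and center-incident edges only), a log-log least-squares
power-law exponent of the degree distribution, and SIF/GraphML exports for
Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .ffl_builder import FFL, COMPOSITE_FFL, MIRNA_FFL, TF_FFL

TF_REGULATION = "TF_regulation"
MIRNA_REGULATION = "miRNA_regulation"


@dataclass
class CoRegNetwork:
    """Typed directed multigraph derived from a set of FFLs."""

    graph: nx.MultiDiGraph  # node attr node_type; edge attr regulation_type

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_type"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph


def _motif_edges(f: FFL) -> list[tuple[str, str, str]]:
    """(source, target, regulation_type) triples implied by one FFL."""
    edges = [
        (f.tf_id, f.target_gene_id, TF_REGULATION),
        (f.mirna_id, f.target_gene_id, MIRNA_REGULATION),
    ]
    if f.ffl_class in (TF_FFL, COMPOSITE_FFL):
        edges.append((f.tf_id, f.mirna_id, TF_REGULATION))
    if f.ffl_class in (MIRNA_FFL, COMPOSITE_FFL):
        edges.append((f.mirna_id, f.tf_id, MIRNA_REGULATION))
    return edges


def build_network(ffls: Iterable[FFL]) -> CoRegNetwork:
    """Union of the edges of all FFLs, deduplicated, with typed nodes.

    A TF that also appears as another motif's target gene keeps the TF type.
    """
    g = nx.MultiDiGraph()
    ffls = list(ffls)
    for f in ffls:
        g.add_node(f.tf_id, node_type="TF")
        g.add_node(f.mirna_id, node_type="miRNA")
    for f in ffls:
        if f.target_gene_id not in g:
            g.add_node(f.target_gene_id, node_type="gene")
    seen: set[tuple[str, str, str]] = set()
    for f in ffls:
        for src, tgt, rtype in _motif_edges(f):
            if (src, tgt, rtype) not in seen:
                seen.add((src, tgt, rtype))
                g.add_edge(src, tgt, regulation_type=rtype)
    return CoRegNetwork(graph=g)


def degree_and_hub(net: CoRegNetwork) -> tuple[dict[str, int], str]:
    """Undirected simple-graph degree per node and the maximum-degree hub.

    Parallel edges between the same node pair collapse; ties on degree break
    lexicographically on node id.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    simple = nx.Graph(net.graph.to_undirected())
    degrees = {n: int(d) for n, d in simple.degree()}
    hub = min(degrees, key=lambda n: (-degrees[n], n))
    return degrees, hub


def occurrence_ranking(ffl_sets: Mapping[str, Iterable[FFL]]) -> pd.DataFrame:
    """Per-regulator FFL occurrence counts and dense ranks per dataset.

    Returns a DataFrame indexed by regulator id with a ``regulator_kind``
    column plus ``<name>_ffls`` / ``<name>_rank`` per dataset and a total;
    ranks are 1-based within each regulator kind (TFs and miRNAs ranked
    separately) by descending count, ties sharing lexicographic order, and
    regulators with zero count in a dataset are unranked (NA) there.
    """
    if not ffl_sets:
        raise ValueError("at least one FFL set required")
    sets = {name: list(ffls) for name, ffls in ffl_sets.items()}
    kinds: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {name: {} for name in sets}
    for name, ffls in sets.items():
        for f in ffls:
            for rid, kind in ((f.tf_id, "TF"), (f.mirna_id, "miRNA")):
                kinds[rid] = kind
                counts[name][rid] = counts[name].get(rid, 0) + 1
    rows = {}
    for rid in sorted(kinds):
        rows[rid] = {"regulator_kind": kinds[rid]}
        for name in sets:
            rows[rid][f"{name}_ffls"] = counts[name].get(rid, 0)
        rows[rid]["total_ffls"] = sum(counts[name].get(rid, 0) for name in sets)
    df = pd.DataFrame.from_dict(rows, orient="index")
    for name in sets:
        ranks: dict[str, int] = {}
        for kind in ("TF", "miRNA"):
            ranked = sorted(
                (
                    rid for rid in df.index
                    if kinds[rid] == kind and df.at[rid, f"{name}_ffls"] > 0
                ),
                key=lambda rid: (-df.at[rid, f"{name}_ffls"], rid),
            )
            ranks.update({rid: i + 1 for i, rid in enumerate(ranked)})
        df[f"{name}_rank"] = pd.Series(ranks, dtype="Int64")
    return df.sort_values("total_ffls", ascending=False, kind="stable")


def ego_subnetwork(net: CoRegNetwork, node_id: str) -> CoRegNetwork:
    """The center node, its direct neighbors, and only center-incident edges."""
    if node_id not in net.graph:
        raise KeyError(f"unknown node {node_id!r}")
    g = nx.MultiDiGraph()
    g.add_node(node_id, **net.graph.nodes[node_id])
    for src, tgt, data in net.graph.edges(data=True):
        if node_id in (src, tgt):
            for n in (src, tgt):
                if n not in g:
                    g.add_node(n, **net.graph.nodes[n])
            g.add_edge(src, tgt, **data)
    return CoRegNetwork(graph=g)


def powerlaw_exponent(degrees: Mapping[str, int]) -> float:
    """Degree-distribution power-law exponent by log-log least squares.

    Fits log(count of nodes with degree k) against log(k) over the observed
    positive degrees and returns minus the slope; requires at least three
    distinct degree values.
    """
    vals = np.array([d for d in degrees.values() if d > 0], dtype=float)
    ks, counts = np.unique(vals, return_counts=True)
    if ks.size < 3:
        raise ValueError("need at least 3 distinct degree values")
    slope = np.polyfit(np.log(ks), np.log(counts), 1)[0]
    return float(-slope)


def export_sif(net: CoRegNetwork, path) -> None:
    """Cytoscape SIF: one `source<TAB>regulation_type<TAB>target` line per edge."""
    lines = sorted(
        f"{src}\t{data['regulation_type']}\t{tgt}"
        for src, tgt, data in net.graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def export_graphml(net: CoRegNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
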