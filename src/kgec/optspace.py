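"""Optimization-space extraction from the disease-targets-components network.

The disease-targets-components (DTC) network is the PPI subgraph induced on
the union of predicted component targets and pathogenic genes.  Nodes whose
degree strictly exceeds the network's average degree D_avg = (sum d_i)/k are
hubs; the hub-induced subgraph is the optimization space, and its nodes are
the "effective proteins" among which component selection is performed.

Effective proteins fall into three categories by set membership:
``essential_common`` (target AND pathogenic gene), ``disease_specific``
(pathogenic gene only) and ``component_specific`` (target only).  Although
named after disease, targets and components, the graph contains proteins
only; component linkage lives in the C-T network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "CATEGORIES",
    "build_dtc",
    "average_degree",
    "OptimizationSpace",
    "extract_optspace",
    "category_tables",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("essential_common", "disease_specific", "component_specific")


def _categorize(is_target: bool, is_disease: bool) -> str:
    if is_target and is_disease:
        return "essential_common"
    if is_disease:
        return "disease_specific"
    return "component_specific"


def build_dtc(ppi: nx.Graph, targets: Iterable[str],
              disease: Iterable[str]) -> nx.Graph:
    """PPI subgraph induced on (targets ∪ disease genes).

    Node attributes ``is_target``, ``is_disease`` and ``category`` record
    membership.  Genes absent from the PPI are dropped (counted in the log).
    """
    targets = set(targets)
    disease = set(disease)
    if not targets or not disease:
        raise ValueError("both target and disease gene sets must be non-empty")
    union = targets | disease
    mapped = sorted(union & set(ppi.nodes))
    if not mapped:
        raise ValueError("no target or disease gene maps to the PPI")
    dtc = ppi.subgraph(mapped).copy()
    for n in dtc.nodes:
        t, d = n in targets, n in disease
        dtc.nodes[n]["is_target"] = t
        dtc.nodes[n]["is_disease"] = d
        dtc.nodes[n]["category"] = _categorize(t, d)
    logger.info("DTC network: %d nodes, %d edges (%d genes not in PPI)",
                dtc.number_of_nodes(), dtc.number_of_edges(),
                len(union) - len(mapped))
    return dtc


def average_degree(g: nx.Graph) -> float:
    """Average degree (sum d_i)/k = 2|E|/k."""
    k = g.number_of_nodes()
    if k == 0:
        raise ValueError("average degree of an empty graph")
    return 2.0 * g.number_of_edges() / k


@dataclass(frozen=True)
class OptimizationSpace:
    """Hub subgraph of the DTC network.

    ``graph`` holds the retained nodes/edges with inherited category
    attributes (under the ``incident`` edge rule, non-hub edge endpoints are
    present with ``is_hub=False``); ``effective_proteins`` are the hub nodes
    only.  ``d_avg`` and ``k`` are the threshold and node count of the parent
    DTC network.
    """

    graph: nx.Graph
    d_avg: float
    k: int
    edge_rule: str

    @property
    def effective_proteins(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["is_hub"])

    @property
    def n_effective(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["is_hub"])

    def categories(self) -> dict[str, str]:
        """gene -> category over effective proteins."""
        return {n: self.graph.nodes[n]["category"]
                for n in self.effective_proteins}

    def write(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        rows = [
            (n, d["category"], self.graph.degree(n), d["is_hub"])
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        pd.DataFrame(rows, columns=["gene", "category", "degree", "is_hub"]).to_csv(
            nodes_path, sep="\t", index=False, lineterminator="\n")
        with open(edges_path, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                fh.write(f"{a}\t{b}\n")


def extract_optspace(dtc: nx.Graph, edge_rule: str = "induced") -> OptimizationSpace:
    """Extract hubs (degree > D_avg, strictly) and their edges.

    ``edge_rule="induced"`` (default) keeps only edges with both endpoints
    hubs, so the space is a self-contained network of effective proteins.
    ``edge_rule="incident"`` keeps every edge touching a hub; the non-hub
    endpoints then appear in the graph flagged ``is_hub=False`` and are not
    effective proteins.
    """
    if edge_rule not in ("induced", "incident"):
        raise ValueError(f"edge_rule must be 'induced' or 'incident', got {edge_rule!r}")
    if dtc.number_of_nodes() == 0:
        raise ValueError("empty DTC network")
    d_avg = average_degree(dtc)
    k = dtc.number_of_nodes()
    hubs = {n for n, deg in dtc.degree() if deg > d_avg}
    if not hubs:
        raise ValueError(
            "no node exceeds the average degree; the DTC network appears "
            "degree-regular, so the optimization space is empty"
        )
    if edge_rule == "induced":
        sub = dtc.subgraph(hubs).copy()
    else:
        keep_edges = [(a, b) for a, b in dtc.edges() if a in hubs or b in hubs]
        sub = dtc.edge_subgraph(keep_edges).copy()
        for n in hubs - set(sub.nodes):  # isolated hubs under incident rule
            sub.add_node(n, **dtc.nodes[n])
    for n in sub.nodes:
        sub.nodes[n]["is_hub"] = n in hubs
    space = OptimizationSpace(graph=sub, d_avg=d_avg, k=k, edge_rule=edge_rule)
    logger.info("optimization space: %d effective proteins, %d edges "
                "(D_avg=%.4f over k=%d nodes, rule=%s)",
                space.n_effective, sub.number_of_edges(), d_avg, k, edge_rule)
    return space


def category_tables(space: OptimizationSpace) -> dict[str, list[str]]:
    """Per-category sorted gene lists partitioning the effective proteins."""
    tables: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for gene, cat in sorted(space.categories().items()):
        tables[cat].append(gene)
    return tables
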