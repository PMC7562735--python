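"""Disease-side network construction.

Builds the weighted gene regulatory network of a disease: a background
protein-protein interaction (PPI) network is read from a plain-text edge
list, a table of pathogenic genes (weighted by literature-report count, in
the style of a DisGeNET export) is read, and the disease network is the PPI
subgraph induced on the pathogenic genes that map into the PPI, each node
carrying its report-count weight.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "load_ppi",
    "load_disease_genes",
    "build_weighted_network",
    "degree_summary",
    "write_network",
]

logger = logging.getLogger(__name__)


def load_ppi(path: str | Path) -> nx.Graph:
    """Read a PPI edge list into an undirected simple graph.

    Accepts two-column TSV (``geneA<TAB>geneB``) or three-column SIF
    (``geneA<TAB>interaction<TAB>geneB``).  Duplicate edges and self-loops
    are dropped; gene symbols are whitespace-trimmed and matched exactly
    (case-sensitive, no alias resolution).

    Raises
    ------
    ValueError
        On an empty file or a line that is not 2- or 3-column, reported
        with its line number.
    """
    path = Path(path)
    g = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: source, interaction type, target
                a, _, b = fields
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 (TSV) or 3 (SIF) "
                    f"tab-separated fields, got {len(fields)}"
                )
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty gene symbol")
            n_lines += 1
            if a != b:
                g.add_edge(a, b)
            else:
                g.add_node(a)  # self-loop: keep node, drop edge
    if n_lines == 0:
        raise ValueError(f"{path}: empty PPI file")
    logger.info(
        "loaded PPI: %d nodes, %d edges (%d input lines)",
        g.number_of_nodes(), g.number_of_edges(), n_lines,
    )
    return g


def load_disease_genes(path: str | Path) -> dict[str, int]:
    """Read a ``gene<TAB>weight`` table into a gene -> weight mapping.

    Weights are the non-negative integer literature-report counts.  A
    header line ``gene<TAB>weight`` is tolerated.  Duplicate genes are an
    error (the table is a set of genes).
    """
    path = Path(path)
    weights: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and fields[0].lower() == "gene":
                continue
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            gene, w_str = fields
            try:
                w = int(w_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: weight {w_str!r} is not an integer"
                ) from exc
            if w < 0:
                raise ValueError(f"{path}: line {lineno}: negative weight {w}")
            if gene in weights:
                raise ValueError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            weights[gene] = w
    if not weights:
        raise ValueError(f"{path}: empty disease-gene file")
    return weights


def build_weighted_network(ppi: nx.Graph, disease: dict[str, int]) -> nx.Graph:
    """Induce the weighted disease network on the PPI.

    Disease genes absent from the PPI node set are dropped (and counted in
    the log); genes present in the PPI but isolated within the induced
    subgraph are retained as weight-carrying isolated nodes.
    """
    mapped = sorted(set(disease) & set(ppi.nodes))
    if not mapped:
        raise ValueError("no disease genes map to PPI")
    dropped = len(disease) - len(mapped)
    net = ppi.subgraph(mapped).copy()
    nx.set_node_attributes(net, {g: disease[g] for g in mapped}, name="weight")
    logger.info(
        "weighted disease network: %d nodes, %d edges (%d disease genes not in PPI)",
        net.number_of_nodes(), net.number_of_edges(), dropped,
    )
    return net


def degree_summary(net: nx.Graph) -> tuple[pd.DataFrame, float]:
    """Per-node degree table plus the mean degree 2|E|/|N|."""
    if net.number_of_nodes() == 0:
        raise ValueError("degree summary of an empty graph")
    table = pd.DataFrame(
        sorted(net.degree()), columns=["gene", "degree"]
    )
    mean = 2.0 * net.number_of_edges() / net.number_of_nodes()
    return table, mean


def write_network(net: nx.Graph, edges_path: str | Path,
                  nodes_path: str | Path | None = None) -> None:
    """Write a graph as a TSV edge list plus an optional node-attribute TSV."""
    with open(edges_path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\n")
    if nodes_path is not None:
        attrs = sorted({k for _, d in net.nodes(data=True) for k in d})
        with open(nodes_path, "w") as fh:
            fh.write("gene" + "".join(f"\t{a}" for a in attrs) + "\n")
            for n in sorted(net.nodes):
                d = net.nodes[n]
                fh.write(n + "".join(f"\t{d.get(a, '')}" for a in attrs) + "\n")
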