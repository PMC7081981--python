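"""Cycle-rank (first Betti number) and node-deletion Betti centrality.

The Betti number of a graph counts its independent cycles ("rings"):
B(G) = |E| - |V| + C(G), where C is the number of connected components.
The Betti centrality of a node v is the drop in cycle count caused by
deleting v together with its incident edges:

    B(v) = B(G) - B(G - {v})

The node(s) whose removal destroys the most rings are the most central;
nodes attaining the same maximal value are "equivalent" centrality
proteins and are all reported, never tie-broken.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network_io import ProteinNetwork


@dataclass
class CentralityReport:
    """Betti number, per-node centralities and the maximal-centrality set."""

    betti_total: int
    centrality: dict[str, int]
    max_value: int
    max_set: set[str]


def betti_number(net: ProteinNetwork) -> int:
    """First Betti number (cycle rank) |E| - |V| + C; empty graph -> 0."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return 0
    return (
        g.number_of_edges()
        - g.number_of_nodes()
        + nx.number_connected_components(g)
    )


def _betti_raw(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def betti_centrality(net: ProteinNetwork) -> CentralityReport:
    """Per-node deletion centrality B(G) - B(G - v) with full tie reporting."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("Betti centrality undefined on the empty graph")
    total = _betti_raw(g)
    centrality: dict[str, int] = {}
    for v in g.nodes:
        h = g.copy()
        h.remove_node(v)
        centrality[v] = total - _betti_raw(h)
    max_value = max(centrality.values())
    max_set = {v for v, c in centrality.items() if c == max_value}
    return CentralityReport(
        betti_total=total,
        centrality=centrality,
        max_value=max_value,
        max_set=max_set,
    )


def write_centrality_report(
    report: CentralityReport, net: ProteinNetwork, path, header: str = ""
) -> None:
    """TSV report: symbol, degree, centrality, is_max flag."""
    order = sorted(
        report.centrality,
        key=lambda s: (-report.centrality[s], -net.degree(s), s),
    )
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        fh.write("symbol\tdegree\tcentrality\tis_max\n")
        for s in order:
            fh.write(
                f"{s}\t{net.degree(s)}\t{report.centrality[s]}\t"
                f"{int(s in report.max_set)}\n"
            )
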