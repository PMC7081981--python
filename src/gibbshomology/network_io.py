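"""Read, validate and write protein interaction networks.

A protein-protein interaction (PPI) network is modelled as a simple
undirected graph whose nodes are uppercased official gene symbols.
Self-loops and duplicate (or reversed-duplicate) edges are collapsed on
input: the Gibbs-energy functional already includes each node in its own
closed neighborhood, so a loop would double-count it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: BioGrid TAB-style header names for the two official-symbol columns.
_BIOGRID_SYMBOL_COLUMNS = (
    "official symbol interactor a",
    "official symbol interactor b",
)


class NetworkFormatError(ValueError):
    """Raised when an edge-list file cannot be parsed into a network."""


class ProteinNetwork:
    """Simple undirected graph over protein symbols.

    Parameters
    ----------
    edges
        Iterable of (symbol, symbol) pairs. Symbols are uppercased and
        stripped; self-loops and duplicates are dropped.
    nodes
        Optional extra nodes (e.g. isolated proteins).
    provenance
        Free-text tag recording where the network came from.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        provenance: str = "",
    ) -> None:
        g = nx.Graph()
        n_loops = 0
        n_dups = 0
        for a, b in edges:
            a, b = _clean_symbol(a), _clean_symbol(b)
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                n_dups += 1
                continue
            g.add_edge(a, b)
        for n in nodes:
            g.add_node(_clean_symbol(n))
        if n_loops or n_dups:
            logger.info(
                "collapsed %d self-loop(s) and %d duplicate edge(s)", n_loops, n_dups
            )
        self.graph: nx.Graph = g
        self.provenance = provenance

    # -- container views -------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, symbol: str) -> int:
        return int(self.graph.degree[symbol])

    def neighbors(self, symbol: str) -> set[str]:
        return set(self.graph.neighbors(symbol))

    def subgraph(self, symbols: Iterable[str]) -> "ProteinNetwork":
        """Induced subgraph on ``symbols`` (edges inherited from parent)."""
        keep = set(symbols)
        sub = self.graph.subgraph(keep)
        net = ProteinNetwork(provenance=self.provenance)
        net.graph = nx.Graph(sub)
        net.graph.add_nodes_from(keep & set(self.graph.nodes))
        return net

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"ProteinNetwork({self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges)"
        )


def _clean_symbol(raw: str) -> str:
    s = str(raw).strip().upper()
    if not s:
        raise NetworkFormatError("empty protein symbol")
    return s


def read_edge_list(path: str | Path, dialect: str = "plain2col") -> ProteinNetwork:
    """Read a protein network from a TSV edge list.

    ``plain2col`` expects at least two whitespace/tab separated symbol
    columns per row; lines starting with ``#`` are ignored.  ``biogrid_tab``
    expects a BioGrid TAB-style header and selects the two official-symbol
    columns.
    """
    path = Path(path)
    if dialect == "plain2col":
        edges = _parse_plain(path)
    elif dialect == "biogrid_tab":
        edges = _parse_biogrid(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    net = ProteinNetwork(edges, provenance=f"{dialect}:{path.name}")
    if net.graph.number_of_nodes() == 0:
        raise NetworkFormatError(f"no parsable edge rows in {path}")
    return net


def _parse_plain(path: Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected at least 2 columns"
                )
            edges.append((parts[0], parts[1]))
    return edges


def _parse_biogrid(path: Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = [c.strip().lower() for c in header.split("\t")]
        try:
            ia = cols.index(_BIOGRID_SYMBOL_COLUMNS[0])
            ib = cols.index(_BIOGRID_SYMBOL_COLUMNS[1])
        except ValueError as exc:
            raise NetworkFormatError(
                f"{path}: header lacks official-symbol columns "
                f"{_BIOGRID_SYMBOL_COLUMNS}"
            ) from exc
        edges = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(ia, ib):
                raise NetworkFormatError(f"{path}:{lineno}: short row")
            edges.append((parts[ia], parts[ib]))
    return edges


def write_graphml(
    net: ProteinNetwork,
    node_attrs: Mapping[str, Mapping[str, float | int | str]] | None,
    path: str | Path,
) -> None:
    """Write the network as GraphML with optional per-node attributes."""
    g = nx.Graph(net.graph)
    if node_attrs:
        for symbol, attrs in node_attrs.items():
            if symbol in g:
                g.nodes[symbol].update(attrs)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> ProteinNetwork:
    g = nx.read_graphml(str(path))
    net = ProteinNetwork(g.edges, nodes=g.nodes, provenance=f"graphml:{Path(path).name}")
    return net


def degree_report(net: ProteinNetwork) -> dict[str, int]:
    """Neighbor count per node (the informal "degree-entropy" report)."""
    return {n: int(d) for n, d in net.graph.degree}
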