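"""Topological filtration: induce the k lowest-energy subnetwork.

Raising a "filtration plane" from the deepest free-energy well captures
larger and larger energetic subnetworks.  Stopping when k nodes have been
captured yields the Gibbs-homology network for that sample (default
k = 32).  The threshold is a node count, not an energy value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .gibbs import EnergyField, sort_key
from .network_io import ProteinNetwork

logger = logging.getLogger(__name__)


@dataclass
class GibbsHomologyNetwork:
    """Induced subgraph of the k lowest-energy nodes plus their energies."""

    sample_id: str
    subgraph: ProteinNetwork
    energy: dict[str, float]
    threshold: int


def filter_network(
    net: ProteinNetwork,
    field: EnergyField,
    k: int = 32,
    connected_only: bool = False,
) -> GibbsHomologyNetwork:
    """Retain the min(k, |V|) lowest-energy nodes and induce their subgraph.

    Ties are broken deterministically by (energy asc, degree desc, symbol).
    With ``connected_only`` the largest connected component of the induced
    subgraph is returned instead; its size may fall below k.
    """
    if k < 1:
        raise ValueError(f"threshold k must be >= 1, got {k}")
    order = sorted(field.energy, key=sort_key(field, net))
    retained = order[: min(k, len(order))]
    sub = net.subgraph(retained)
    if connected_only and len(sub) > 0:
        comp = max(nx.connected_components(sub.graph), key=lambda c: (len(c), sorted(c)))
        if len(comp) < len(sub):
            logger.info(
                "connected_only: kept component of %d/%d retained nodes",
                len(comp),
                len(sub),
            )
        sub = net.subgraph(comp)
    energy = {s: field.energy[s] for s in sub.nodes}
    return GibbsHomologyNetwork(
        sample_id=field.sample_id, subgraph=sub, energy=energy, threshold=k
    )


def filtration_curve(
    net: ProteinNetwork, field: EnergyField, k_max: int
) -> list[tuple[int, int, int, int]]:
    """(k, n_nodes, n_edges, betti) for k = 1..k_max; node sets are nested."""
    from .betti import betti_number  # local import: avoid cycle at module load

    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    order = sorted(field.energy, key=sort_key(field, net))
    rows = []
    for k in range(1, k_max + 1):
        sub = net.subgraph(order[: min(k, len(order))])
        rows.append(
            (k, len(sub), sub.graph.number_of_edges(), betti_number(sub))
        )
    return rows
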