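"""Per-node Gibbs free energy of an expression profile on a PPI network.

For node i with rescaled concentration c_i in [0, 1] the energy is

    G_i = c_i * ln( c_i / sum_{j in N(i) + {i}} c_j )

where the sum runs over the *closed* neighborhood of i (all interaction
partners of i, including i itself).  Because 0 <= c_i <= sum, the log
argument never exceeds 1 and every G_i is non-positive: each expressed
protein sits in a free-energy well whose depth grows with both its own
concentration and the total concentration of its neighborhood (the
denominator acts as a degree-entropy term: hubs with many expressed
partners get deeper wells).

Conventions at the boundary: c_i = 0 gives G_i = 0 (the x ln x limit),
and an all-zero closed neighborhood gives G_i = 0 (guard against 0/0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .expression import ExpressionProfile
from .network_io import ProteinNetwork


@dataclass
class EnergyField:
    """Per-node Gibbs energies for one sample.

    ``neighbor_sum`` holds the closed-neighborhood concentration sum
    (the denominator of the energy functional) for reporting.
    """

    sample_id: str
    energy: dict[str, float]
    neighbor_sum: dict[str, float]


def gibbs_energy(net: ProteinNetwork, profile: ExpressionProfile) -> EnergyField:
    """Compute G_i for every node of ``net`` under ``profile``.

    Every network node must carry a concentration: apply the
    network/expression intersection mapping first.
    """
    conc = profile.conc
    missing = [n for n in net.graph.nodes if n not in conc]
    if missing:
        raise KeyError(
            f"{len(missing)} node(s) lack a concentration value, "
            f"e.g. {sorted(missing)[:5]}"
        )
    energy: dict[str, float] = {}
    nsum: dict[str, float] = {}
    for i in net.graph.nodes:
        ci = conc[i]
        s = ci + sum(conc[j] for j in net.graph.neighbors(i))
        nsum[i] = s
        if ci <= 0.0 or s <= 0.0:
            energy[i] = 0.0
        else:
            energy[i] = ci * math.log(ci / s)
    return EnergyField(sample_id=profile.sample_id, energy=energy, neighbor_sum=nsum)


def sort_key(field: EnergyField, net: ProteinNetwork):
    """Deterministic node ordering: energy ascending (deepest well first),
    then degree descending, then symbol."""

    def key(symbol: str):
        return (field.energy[symbol], -net.degree(symbol), symbol)

    return key


def energy_table(
    field: EnergyField, net: ProteinNetwork
) -> list[tuple[str, float, int, float]]:
    """Rows of (symbol, energy, degree, neighbor_sum), most negative first."""
    order = sorted(field.energy, key=sort_key(field, net))
    return [
        (s, field.energy[s], net.degree(s), field.neighbor_sum[s]) for s in order
    ]


def write_energy_table(
    field: EnergyField, net: ProteinNetwork, path: str | Path, header: str = ""
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        fh.write("symbol\tenergy\tdegree\tneighbor_sum\n")
        for sym, e, d, s in energy_table(field, net):
            fh.write(f"{sym}\t{e:.10g}\t{d}\t{s:.10g}\n")
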