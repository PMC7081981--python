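"""Cohort-level pipeline: per-patient runs and Pareto aggregation.

For each sample the pipeline composes rescale -> Gibbs energy ->
filtration -> Betti centrality, producing that patient's Gibbs-homology
network and centrality report.  Aggregation then counts, per protein,
(a) the patients in which it attains the maximal Betti centrality
(the Pareto table — ties contribute every equivalent protein, so the
Pareto total can exceed the number of patients) and (b) the patients
whose threshold-k network contains it at all (presence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .betti import CentralityReport, betti_centrality
from .expression import ExpressionTable, rescale_sample
from .filtration import GibbsHomologyNetwork, filter_network
from .gibbs import gibbs_energy
from .network_io import ProteinNetwork

logger = logging.getLogger(__name__)


@dataclass
class CohortResult:
    per_sample: dict[str, tuple[GibbsHomologyNetwork, CentralityReport]]
    pareto: dict[str, int]
    presence: dict[str, int]
    n_samples: int


def intersect(
    net: ProteinNetwork, table: ExpressionTable
) -> tuple[ProteinNetwork, set[str]]:
    """Restrict the network to genes with expression; report the gene set.

    Genes absent from the network are dropped at rescale time; network
    nodes without expression are removed from the working graph.  Both
    counts are logged once per cohort run.
    """
    genes = set(table.genes)
    keep = net.nodes & genes
    n_net_dropped = len(net.nodes) - len(keep)
    n_expr_dropped = len(genes) - len(keep)
    if not keep:
        raise ValueError("network and expression table share no symbols")
    if n_net_dropped or n_expr_dropped:
        logger.info(
            "intersection mapping: dropped %d network node(s) without "
            "expression and %d expressed gene(s) absent from the network",
            n_net_dropped,
            n_expr_dropped,
        )
    return net.subgraph(keep), keep


def run_patient(
    net: ProteinNetwork,
    table: ExpressionTable,
    sample_id: str,
    k: int = 32,
    connected_only: bool = False,
    rescale_mode: str = "per_sample",
    _working: tuple[ProteinNetwork, set[str]] | None = None,
) -> tuple[GibbsHomologyNetwork, CentralityReport]:
    """Run the full per-patient pipeline for one sample.

    ``_working`` lets cohort drivers pass the precomputed
    network/expression intersection instead of recomputing it per sample.
    """
    try:
        wnet, keep = _working if _working is not None else intersect(net, table)
        profile = rescale_sample(table, sample_id, restrict_to=keep, mode=rescale_mode)
        field = gibbs_energy(wnet, profile)
        ghn = filter_network(wnet, field, k=k, connected_only=connected_only)
        report = betti_centrality(ghn.subgraph)
    except Exception as exc:
        raise type(exc)(f"[sample {sample_id}] {exc}") from exc
    return ghn, report


def run_cohort(
    net: ProteinNetwork,
    table: ExpressionTable,
    k: int = 32,
    connected_only: bool = False,
    rescale_mode: str = "per_sample",
) -> CohortResult:
    """Run every sample of the table and aggregate."""
    working = intersect(net, table)
    results = {
        sid: run_patient(
            net,
            table,
            sid,
            k=k,
            connected_only=connected_only,
            rescale_mode=rescale_mode,
            _working=working,
        )
        for sid in table.samples
    }
    return aggregate(results)


def aggregate(
    results: dict[str, tuple[GibbsHomologyNetwork, CentralityReport]],
) -> CohortResult:
    """Pareto and presence counts over per-sample outputs.

    The Pareto table counts each sample's *entire* maximal-centrality set:
    patients with equivalent top proteins contribute one count per
    equivalent protein, which is why the Pareto total can exceed the
    sample count.
    """
    if not results:
        raise ValueError("no per-sample results to aggregate")
    pareto: dict[str, int] = {}
    presence: dict[str, int] = {}
    for ghn, report in results.values():
        for s in report.max_set:
            pareto[s] = pareto.get(s, 0) + 1
        for s in ghn.subgraph.nodes:
            presence[s] = presence.get(s, 0) + 1
    order = lambda d: dict(sorted(d.items(), key=lambda kv: (-kv[1], kv[0])))
    return CohortResult(
        per_sample=dict(results),
        pareto=order(pareto),
        presence=order(presence),
        n_samples=len(results),
    )


def gene_list_overlap(
    result: CohortResult, gene_list: set[str], scope: str = "all_nodes"
) -> set[str]:
    """Intersect a disease gene list with the cohort's captured proteins.

    ``all_nodes`` (default) uses the union of every patient's threshold-k
    node set; ``max_only`` uses only the maximal-centrality sets.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    genes = {str(g).strip().upper() for g in gene_list}
    if scope == "all_nodes":
        universe = set(result.presence)
    elif scope == "max_only":
        universe = set(result.pareto)
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    return genes & universe


def write_pareto_table(result: CohortResult, path, header: str = "") -> None:
    """TSV: symbol, pareto count, presence count (descending, ties lexical)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# n_samples\t{result.n_samples}\n")
        fh.write("symbol\tpareto\tpresence\n")
        for s, c in result.pareto.items():
            fh.write(f"{s}\t{c}\t{result.presence.get(s, 0)}\n")


def write_presence_table(result: CohortResult, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# n_samples\t{result.n_samples}\n")
        fh.write("symbol\tpresence\n")
        for s, c in result.presence.items():
            fh.write(f"{s}\t{c}\n")
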