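"""Hamming-distance-1 networks over enriched protein variants.

Nodes are variant amino-acid strings that survive an enrichment-rate
threshold; an edge joins two variants that differ at exactly one
position, i.e. are one substitution apart.  Each edge is annotated with
its lower-rate endpoint, the direction Darwinian evolution would favour,
and each node carries its rate (and epistasis class when known) so that
downstream layout tools can size and colour the graph.  Sparse edge sets
and disconnected components around the most enriched variants are the
network signature of epistasis: only specific residue combinations reach
high rates, so few single-step paths lead there.

Neighbour search uses wildcard bucketing — masking one position at a
time and grouping identical masked strings — which finds every
distance-1 pair exactly, in near-linear time, without the all-pairs scan
(the all-pairs computation remains the test oracle).
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from .variant_quant import EnrichmentRecord

__all__ = [
    "hamming",
    "build_network",
    "isolate_subnetwork",
    "write_graphml",
    "write_edge_tsv",
]


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def build_network(
    records: Iterable[EnrichmentRecord], threshold: float = 1.0
) -> nx.Graph:
    """Graph of all threshold-passing variants at Hamming distance 1.

    Nodes are ``aa_string`` keys with ``rate`` (and ``klass`` if present)
    attributes; only records with a defined rate >= ``threshold`` enter.
    Every edge carries ``low`` / ``high``: the endpoints with the lower
    and higher enrichment rate.
    """
    graph = nx.Graph(threshold=float(threshold))
    for rec in records:
        if rec.rate is None or rec.rate < threshold:
            continue
        attrs = {"rate": float(rec.rate)}
        if rec.klass is not None:
            attrs["klass"] = rec.klass
        graph.add_node(rec.aa_string, **attrs)
    buckets: defaultdict[tuple[int, str], list[str]] = defaultdict(list)
    for aa in graph.nodes:
        for pos in range(len(aa)):
            buckets[(pos, aa[:pos] + "\x00" + aa[pos + 1 :])].append(aa)
    for bucket in buckets.values():
        # Distinct equal-length strings sharing a masked form differ at
        # exactly the masked position, hence distance 1.
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                a, b = bucket[i], bucket[j]
                if graph.nodes[a]["rate"] <= graph.nodes[b]["rate"]:
                    graph.add_edge(a, b, low=a, high=b)
                else:
                    graph.add_edge(a, b, low=b, high=a)
    return graph


def isolate_subnetwork(
    graph: nx.Graph, focus: str, mode: str = "neighbors"
) -> nx.Graph:
    """Subgraph around one variant of interest.

    ``neighbors`` keeps the focus plus every distance-1 node;
    ``lower_rate_neighbors`` additionally requires a neighbour's rate to
    be below the focus rate — the construction that shows the parent
    variants from which the focus is reachable by one beneficial step.
    """
    if focus not in graph:
        raise KeyError(f"variant {focus!r} not in network")
    if mode == "neighbors":
        keep = {focus, *graph.neighbors(focus)}
    elif mode == "lower_rate_neighbors":
        focus_rate = graph.nodes[focus]["rate"]
        keep = {focus} | {
            n for n in graph.neighbors(focus) if graph.nodes[n]["rate"] < focus_rate
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub = graph.subgraph(keep).copy()
    sub.graph.update(graph.graph, focus=focus, mode=mode)
    return sub


def write_graphml(graph: nx.Graph, path: Union[str, Path]) -> None:
    """Export with node/edge attributes for external layout tools."""
    nx.write_graphml(graph, str(path))


def write_edge_tsv(graph: nx.Graph, path: Union[str, Path]) -> None:
    """Edge list as TSV: endpoints plus the lower-rate endpoint."""
    with open(path, "w") as fh:
        fh.write("variant_a\tvariant_b\tlow\thigh\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['low']}\t{data['high']}\n")
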