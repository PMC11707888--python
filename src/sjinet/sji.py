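"""Signal Jaccard Index and the SJI-weighted protein network.

The SJI between two seeds is the Jaccard index of their signal sets,
|S_u ∩ S_v| / |S_u ∪ S_v|, computed on the *augmented* sets that include each
seed's own id.  The augmentation makes SJI(u, u) = 1 well defined and stops a
pair of recent duplicates — each present in the other's signal set — from
being penalized for the trivial absence of self.  Seeds with empty signal
sets still enter the network as isolated nodes, so the final ortholog groups
partition every input protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .records import InvalidInputError
from .signals import SeedPlot


@dataclass(frozen=True)
class SignalSet:
    """One seed's signal set; members never include the seed itself."""

    seed_id: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.seed_id in self.members:
            object.__setattr__(self, "members", self.members - {self.seed_id})

    @property
    def augmented(self) -> frozenset[str]:
        return self.members | {self.seed_id}


def signal_sets_from_plots(plots: Iterable[SeedPlot]) -> dict[str, SignalSet]:
    return {p.seed_id: SignalSet(p.seed_id, frozenset(p.signal_ids)) for p in plots}


def signal_jaccard(u: SignalSet, v: SignalSet) -> float:
    """SJI of two seeds on their augmented signal sets; 0 on an empty union."""
    su, sv = u.augmented, v.augmented
    union = len(su | sv)
    if union == 0:
        return 0.0
    return len(su & sv) / union


def candidate_pairs(signal_sets: Mapping[str, SignalSet]) -> Iterator[tuple[str, str]]:
    """Unordered seed pairs whose augmented sets overlap, each yielded once.

    Built from an inverted index protein_id -> seeds containing it; every
    other pair has SJI 0 and never needs computing.
    """
    index: dict[str, list[str]] = {}
    for seed_id in sorted(signal_sets):
        for member in signal_sets[seed_id].augmented:
            index.setdefault(member, []).append(seed_id)
    seen: set[tuple[str, str]] = set()
    for seeds in index.values():
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                pair = (seeds[i], seeds[j]) if seeds[i] < seeds[j] else (seeds[j], seeds[i])
                if pair not in seen:
                    seen.add(pair)
                    yield pair


def build_network(signal_sets: Mapping[str, SignalSet] | Iterable[SignalSet]) -> nx.Graph:
    """SJI-weighted undirected network over all seeds.

    Nodes are all seeds, isolated ones included; edges carry weight = SJI for
    every overlapping pair (zero-weight pairs are absent).  The result is
    independent of input order.
    """
    if not isinstance(signal_sets, Mapping):
        as_map: dict[str, SignalSet] = {}
        for s in signal_sets:
            if s.seed_id in as_map:
                raise InvalidInputError(f"duplicate seed_id {s.seed_id!r}")
            as_map[s.seed_id] = s
        signal_sets = as_map
    graph = nx.Graph()
    graph.add_nodes_from(sorted(signal_sets))
    for u, v in candidate_pairs(signal_sets):
        w = signal_jaccard(signal_sets[u], signal_sets[v])
        if w > 0:
            graph.add_edge(u, v, weight=w)
    return graph


def write_edges(graph: nx.Graph, path) -> None:
    """Edge list TSV `protein_a  protein_b  sji`, a < b, 6 decimals."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tsji\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\t{graph[u][v]['weight']:.6f}\n")


def read_edges(path, nodes: Iterable[str] | None = None) -> nx.Graph:
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_a", "protein_b", "sji"]:
            raise InvalidInputError(f"unexpected edge header {header}")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            graph.add_edge(u, v, weight=float(w))
    return graph
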