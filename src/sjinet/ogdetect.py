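"""Ortholog group detection by recursive Louvain with a density stopping rule.

The weighted density of a community with node set N is

    D = 2 * sum_{u<v in N} W(u, v) / (|N| * (|N| - 1)),

missing edges contributing 0, with D = 1 by convention for singletons.  The
initial SJI network is huge and loosely connected, so it is cut recursively:
a component whose density reaches the threshold is accepted as an ortholog
group (OG); otherwise Louvain splits it, edge weights are recomputed inside
each sub-community from the signal sets restricted to its nodes, and the
procedure recurses.  A community Louvain cannot split is accepted with an
``indivisible`` flag so the output always partitions the node set.

Each member's degree centrality DC(v) = sum_u W(v, u) / (|OG| - 1), taken
over the final restricted weights at acceptance, is the per-protein
confidence score (1 only in unit-weight cliques; 0 for singletons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .records import InvalidInputError
from .sji import SignalSet, signal_jaccard

#: Density presets: strict (mean pairwise SJI >= 0.25) and permissive.
THRESHOLD_STRICT = 0.25
THRESHOLD_PERMISSIVE = 0.1


@dataclass(frozen=True)
class DensityReport:
    n_nodes: int
    weight_sum: float
    density: float


@dataclass
class OrthologGroup:
    og_id: str
    members: frozenset[str]
    density: float
    indivisible_flag: bool
    dc: dict[str, float]

    @property
    def size(self) -> int:
        return len(self.members)


def community_density(subnetwork: nx.Graph) -> DensityReport:
    """Weighted density D of a community; singleton D = 1 by convention."""
    n = subnetwork.number_of_nodes()
    weight_sum = float(subnetwork.size(weight="weight"))
    if n <= 1:
        return DensityReport(n_nodes=n, weight_sum=weight_sum, density=1.0)
    return DensityReport(n, weight_sum, 2.0 * weight_sum / (n * (n - 1)))


def restrict_weights(
    nodes: Iterable[str], signal_sets: Mapping[str, SignalSet]
) -> nx.Graph:
    """Rebuild a sub-network's edges from signal sets restricted to its nodes.

    Each member's augmented signal set is intersected with the node set and
    SJI recomputed; pairs left with an empty intersection lose their edge.
    The restricted augmented set always keeps the seed itself, so the Jaccard
    union is never empty within the sub-network.
    """
    node_set = frozenset(nodes)
    restricted = {
        v: SignalSet(v, (signal_sets[v].augmented & node_set) - {v}) for v in node_set
    }
    graph = nx.Graph()
    graph.add_nodes_from(sorted(node_set))
    items = sorted(node_set)
    # inverted index over restricted members, as in the full network build
    index: dict[str, list[str]] = {}
    for v in items:
        for m in restricted[v].augmented:
            index.setdefault(m, []).append(v)
    seen: set[tuple[str, str]] = set()
    for seeds in index.values():
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                pair = (seeds[i], seeds[j]) if seeds[i] < seeds[j] else (seeds[j], seeds[i])
                if pair in seen:
                    continue
                seen.add(pair)
                w = signal_jaccard(restricted[pair[0]], restricted[pair[1]])
                if w > 0:
                    graph.add_edge(*pair, weight=w)
    return graph


def degree_centrality(og_members: Iterable[str], subnetwork: nx.Graph) -> dict[str, float]:
    """Size-normalized weighted degree within the OG: sum of SJI / (|OG|-1)."""
    members = sorted(og_members)
    n = len(members)
    if n == 1:
        return {members[0]: 0.0}
    return {
        v: sum(d["weight"] for _, _, d in subnetwork.edges(v, data=True)) / (n - 1)
        for v in members
    }


def detect_ogs(
    network: nx.Graph,
    signal_sets: Mapping[str, SignalSet] | None = None,
    threshold: float = THRESHOLD_PERMISSIVE,
    max_depth: int = 50,
    louvain_seed: int = 17,
    og_prefix: str = "OG",
) -> list[OrthologGroup]:
    """Partition the SJI network into ortholog groups.

    Connected components are processed independently.  Each community is
    accepted once its density reaches ``threshold`` (inclusive), or flagged
    indivisible when Louvain returns a single community or the recursion
    depth cap is hit; otherwise its Louvain sub-communities are re-weighted
    via :func:`restrict_weights` and recursed into.  The returned OGs
    partition the network's nodes; ids are assigned in deterministic order.

    When ``signal_sets`` is None (a bare weighted graph with no signal-set
    provenance, e.g. a planted benchmark graph) sub-communities keep their
    original edge weights restricted to the induced subgraph.
    """
    if not (0 < threshold <= 1):
        raise InvalidInputError("threshold must be in (0, 1]")
    for _, _, d in network.edges(data=True):
        if d.get("weight", 0) <= 0:
            raise InvalidInputError("edge weights must be positive")

    accepted: list[tuple[frozenset[str], float, bool, dict[str, float]]] = []

    def accept(sub: nx.Graph, density: float, indivisible: bool) -> None:
        members = frozenset(sub.nodes)
        accepted.append((members, density, indivisible, degree_centrality(members, sub)))

    def recurse(sub: nx.Graph, depth: int) -> None:
        components = sorted(nx.connected_components(sub), key=min)
        if len(components) > 1:
            for comp in components:
                recurse(sub.subgraph(comp).copy(), depth)
            return
        report = community_density(sub)
        if report.density >= threshold:
            accept(sub, report.density, False)
            return
        if depth >= max_depth:
            accept(sub, report.density, True)
            return
        parts = louvain_communities(sub, weight="weight", seed=louvain_seed)
        if len(parts) <= 1:
            accept(sub, report.density, True)
            return
        for part in sorted(parts, key=min):
            if signal_sets is None:
                recurse(sub.subgraph(part).copy(), depth + 1)
            else:
                recurse(restrict_weights(part, signal_sets), depth + 1)

    recurse(network, 0)
    accepted.sort(key=lambda item: min(item[0]))
    width = max(4, len(str(len(accepted))))
    return [
        OrthologGroup(f"{og_prefix}{i:0{width}d}", members, density, flag, dc)
        for i, (members, density, flag, dc) in enumerate(accepted, start=1)
    ]


def og_partition(ogs: Iterable[OrthologGroup]) -> dict[str, str]:
    """protein_id -> og_id map (the partition the evaluation module consumes)."""
    assignment: dict[str, str] = {}
    for og in ogs:
        for v in og.members:
            if v in assignment:
                raise InvalidInputError(f"protein {v!r} assigned to two OGs")
            assignment[v] = og.og_id
    return assignment


OG_HEADER = ["protein_id", "og_id", "dc", "og_size", "og_density", "indivisible"]


def write_og_table(ogs: Iterable[OrthologGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(OG_HEADER) + "\n")
        for og in sorted(ogs, key=lambda g: g.og_id):
            for v in sorted(og.members):
                fh.write(
                    f"{v}\t{og.og_id}\t{og.dc[v]:.4f}\t{og.size}\t"
                    f"{og.density:.4f}\t{int(og.indivisible_flag)}\n"
                )


def read_og_table(path) -> list[OrthologGroup]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != OG_HEADER:
            raise InvalidInputError(f"unexpected OG table header {header}")
        for line in fh:
            pid, og_id, dc, size, density, flag = line.rstrip("\n").split("\t")
            entry = rows.setdefault(
                og_id, {"members": set(), "dc": {}, "density": float(density), "flag": flag == "1"}
            )
            entry["members"].add(pid)
            entry["dc"][pid] = float(dc)
    return [
        OrthologGroup(og_id, frozenset(e["members"]), e["density"], e["flag"], e["dc"])
        for og_id, e in sorted(rows.items())
    ]
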