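"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are connected when their mutational step count (number of
differing sites among pairwise-comparable columns; gaps and missing data
uninformative) does not exceed the parsimony connection limit.  Connected
components of that threshold graph are the separate networks — the
putative species.  Within each component the displayed edge set is reduced
to a minimum-spanning network: all edges tied at minimal weight are kept
(the PopART convention), so the result is a network, not a tree.

The connection limit is the largest step count whose probability of being
parsimonious (no superimposed substitutions) still reaches the configured
confidence (95% by default).  The estimator used here treats each
additional step as carrying a superimposition risk of ``5 / (2 m)`` for an
``m``-column alignment, calibrated against the limits the original TCS
software prints for typical alignment lengths (13 steps at 658 columns,
9 at ~440).  Published limits can be replayed exactly via ``fixed_limit``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .alignments import HaplotypeSet

__all__ = [
    "ParsimonyConfig",
    "HaploNetwork",
    "NetworkError",
    "connection_limit",
    "step_count",
    "step_matrix",
    "build_networks",
    "networks_to_partition",
    "export_network",
    "import_network",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MISS = 255


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class ParsimonyConfig:
    connection_probability: float = 0.95
    gap_policy: str = "missing"
    fixed_limit: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.connection_probability < 1.0:
            raise NetworkError("connection_probability must be in (0, 1)")


@dataclass
class HaploNetwork:
    """One connected haplotype network.

    ``nodes``: haplotype labels in first-occurrence order with multiplicity
    and optional per-region membership counts.  ``edges``: retained
    minimum-spanning-network edges with step counts.  ``median_vectors``:
    display-only counts of inferred unsampled intermediates per edge
    (steps − 1); they never affect component membership.
    """

    nodes: list[str]
    multiplicity: dict[str, int]
    members: dict[str, list[str]]
    edges: list[tuple[str, str, int]]
    connection_limit: int
    regions: dict[str, dict[str, int]] = field(default_factory=dict)
    median_vectors: list[tuple[tuple[str, str], int]] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return sum(self.multiplicity.values())


def connection_limit(alignment_length: int, config: ParsimonyConfig | None = None) -> int:
    """Largest parsimonious step count at the configured confidence."""
    config = config or ParsimonyConfig()
    if config.fixed_limit is not None:
        return int(config.fixed_limit)
    if alignment_length < 1:
        raise NetworkError("alignment_length must be >= 1")
    q = 2.5 / alignment_length
    if q >= 1.0:
        return 1
    # (1 - q)^j >= P  <=>  j <= ln P / ln(1 - q)
    j = int(math.floor(math.log(config.connection_probability) / math.log(1.0 - q)))
    return max(j, 1)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(ch, _MISS) for ch in seq], dtype=np.uint8)


def step_count(seq_a: str, seq_b: str) -> int:
    """Mutational steps: differing pairwise-comparable sites."""
    a, b = _encode(seq_a), _encode(seq_b)
    comp = (a != _MISS) & (b != _MISS)
    return int(((a != b) & comp).sum())


def step_matrix(haps: HaplotypeSet) -> np.ndarray:
    enc = np.vstack([_encode(seq) for seq, _ in haps.haplotypes])
    n = enc.shape[0]
    steps = np.zeros((n, n), dtype=int)
    ok = enc != _MISS
    for i in range(n):
        comp = ok[i] & ok[i + 1 :]
        steps[i, i + 1 :] = ((enc[i] != enc[i + 1 :]) & comp).sum(axis=1)
        steps[i + 1 :, i] = steps[i, i + 1 :]
    return steps


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _minimum_spanning_network(
    nodes: Sequence[int], steps: np.ndarray
) -> list[tuple[int, int, int]]:
    """Kruskal with tie batching: all edges of a weight class that connect
    previously distinct components are kept."""
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [
        (int(steps[a, b]), a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    ]
    edges.sort()
    uf = _UnionFind(len(nodes))
    kept: list[tuple[int, int, int]] = []
    i = 0
    while i < len(edges):
        j = i
        batch = []
        while j < len(edges) and edges[j][0] == edges[i][0]:
            w, a, b = edges[j]
            if uf.find(idx[a]) != uf.find(idx[b]):
                batch.append((a, b, w))
            j += 1
        for a, b, w in batch:
            uf.union(idx[a], idx[b])
            kept.append((a, b, w))
        i = j
    return kept


def build_networks(
    haps: HaplotypeSet,
    config: ParsimonyConfig | None = None,
    region_of: Mapping[str, str] | None = None,
) -> list[HaploNetwork]:
    """Threshold graph over haplotypes; connected components in
    deterministic (first-occurrence) order, each reduced to its
    minimum-spanning network."""
    config = config or ParsimonyConfig()
    if not haps.haplotypes:
        raise NetworkError("empty haplotype set")
    limit = connection_limit(len(haps.haplotypes[0][0]), config)
    steps = step_matrix(haps)
    n = len(haps.haplotypes)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if steps[i, j] <= limit:
                graph.add_edge(i, j)

    labels = [members[0] for _, members in haps.haplotypes]
    components = sorted(nx.connected_components(graph), key=min)
    networks = []
    for comp in components:
        order = sorted(comp)
        msn = _minimum_spanning_network(order, steps)
        mult = {labels[i]: len(haps.haplotypes[i][1]) for i in order}
        members = {labels[i]: list(haps.haplotypes[i][1]) for i in order}
        regions: dict[str, dict[str, int]] = {}
        if region_of:
            for i in order:
                counts: dict[str, int] = {}
                for m in haps.haplotypes[i][1]:
                    r = region_of.get(m)
                    if r is not None:
                        counts[r] = counts.get(r, 0) + 1
                regions[labels[i]] = counts
        edges = [(labels[a], labels[b], w) for a, b, w in msn]
        networks.append(
            HaploNetwork(
                nodes=[labels[i] for i in order],
                multiplicity=mult,
                members=members,
                edges=edges,
                connection_limit=limit,
                regions=regions,
                median_vectors=[((a, b), w - 1) for a, b, w in edges if w > 1],
            )
        )
    return networks


def networks_to_partition(
    networks: Sequence[HaploNetwork],
    id_map: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Specimen id -> network index (its haplotype's component)."""
    out: dict[str, int] = {}
    for k, net in enumerate(networks):
        for members in net.members.values():
            for sid in members:
                out[id_map.get(sid, sid) if id_map else sid] = k
    return out


def export_network(network: HaploNetwork, path) -> None:
    """Write one network as GraphML with multiplicity/region attributes."""
    graph = nx.Graph(connection_limit=network.connection_limit)
    for node in network.nodes:
        graph.add_node(
            node,
            multiplicity=network.multiplicity[node],
            members=";".join(network.members[node]),
            regions=json.dumps(network.regions.get(node, {}), sort_keys=True),
        )
    for a, b, w in network.edges:
        graph.add_edge(a, b, steps=int(w))
    nx.write_graphml(graph, str(path))


def import_network(path) -> HaploNetwork:
    graph = nx.read_graphml(str(path))
    nodes = list(graph.nodes)
    mult = {n: int(graph.nodes[n]["multiplicity"]) for n in nodes}
    members = {n: graph.nodes[n]["members"].split(";") for n in nodes}
    regions = {n: json.loads(graph.nodes[n].get("regions", "{}")) for n in nodes}
    edges = [(a, b, int(d["steps"])) for a, b, d in graph.edges(data=True)]
    return HaploNetwork(
        nodes=nodes,
        multiplicity=mult,
        members=members,
        edges=edges,
        connection_limit=int(graph.graph.get("connection_limit", 0)),
        regions={k: v for k, v in regions.items() if v},
        median_vectors=[((a, b), w - 1) for a, b, w in edges if w > 1],
    )
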