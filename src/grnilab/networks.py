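"""Directed gene-network container and synthetic ground-truth generators.

The true regulatory network is a directed graph over gene identifiers whose
edges optionally carry a regulatory sign: an *activator* edge increases the
target's expression with the regulator, a *repressor* edge decreases it.
Three synthetic structure families are provided (directed acyclic graphs,
preferential-attachment scale-free networks and Erdos-Renyi-style random
networks), together with a neighborhood-expansion subnetwork sampler for
carving small networks out of a larger user-supplied one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

ACTIVATOR = "activator"
REPRESSOR = "repressor"

#: TSV/SIF sign tokens <-> internal sign labels
SIGN_TOKENS = {"+": ACTIVATOR, "-": REPRESSOR}
TOKEN_OF_SIGN = {ACTIVATOR: "+", REPRESSOR: "-"}

Edge = tuple[str, str]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or invalid generator arguments."""


@dataclass
class DirectedNetwork:
    """A directed, optionally signed, regulatory network.

    Parameters
    ----------
    nodes : list of str
        Ordered gene identifiers. The order is load-bearing: deterministic
        tie-breaking downstream always refers to this order.
    edges : set of (source, target)
        Directed edges. Self-loops and dangling endpoints are rejected.
    signs : dict edge -> {"activator", "repressor"}
        Optional regulatory signs; may cover no, some or all edges.
    """

    nodes: list[str]
    edges: set[Edge] = field(default_factory=set)
    signs: dict[Edge, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        self.edges = {tuple(e) for e in self.edges}
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node identifiers")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise NetworkError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise NetworkError(f"edge ({u!r}, {v!r}) references unknown node")
        for e, s in self.signs.items():
            if tuple(e) not in self.edges:
                raise NetworkError(f"sign assigned to non-edge {e!r}")
            if s not in (ACTIVATOR, REPRESSOR):
                raise NetworkError(f"unknown sign {s!r} on edge {e!r}")

    # -- structural queries -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.nodes)

    @property
    def is_signed(self) -> bool:
        """True when every edge carries a sign (vacuously true without edges)."""
        return all(e in self.signs for e in self.edges)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def sorted_edges(self) -> list[Edge]:
        """Edges in deterministic (source-index, target-index) order."""
        idx = self.index()
        return sorted(self.edges, key=lambda e: (idx[e[0]], idx[e[1]]))

    def in_degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.nodes}
        for _, v in self.edges:
            deg[v] += 1
        return deg

    def out_degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.nodes}
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.sorted_edges():
            g.add_edge(*e, sign=self.signs.get(e))
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        """Topological node order; raises NetworkError on cyclic networks."""
        try:
            order = list(nx.topological_sort(self.to_networkx()))
        except nx.NetworkXUnfeasible as exc:  # pragma: no cover - message only
            raise NetworkError("network contains a directed cycle") from exc
        return order


def undirected_skeleton(net: DirectedNetwork) -> set[frozenset]:
    """Unordered gene pairs connected in either direction.

    A reciprocal pair (i->j and j->i) collapses onto a single skeleton edge,
    which is the comparison universe for undirected inference output.
    """
    return {frozenset(e) for e in net.edges}


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def generate_dag(n_genes: int, edge_density: float, seed: int) -> DirectedNetwork:
    """Random directed acyclic graph.

    A uniformly random node order is drawn, and every forward pair (with
    respect to that order) becomes an edge independently with probability
    ``edge_density``. Acyclicity is guaranteed by construction.
    """
    if n_genes < 2:
        raise NetworkError("generate_dag requires n_genes >= 2")
    if not 0 < edge_density <= 1:
        raise NetworkError("edge_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    nodes = _gene_names(n_genes)
    order = rng.permutation(n_genes)
    a_idx, b_idx = np.triu_indices(n_genes, k=1)
    keep = rng.random(a_idx.size) < edge_density
    edges = {
        (nodes[order[a]], nodes[order[b]])
        for a, b, k in zip(a_idx, b_idx, keep)
        if k
    }
    return DirectedNetwork(nodes, edges)


def generate_scale_free(n_genes: int, edges_per_node: int, seed: int) -> DirectedNetwork:
    """Scale-free network by undirected preferential attachment.

    Each edge is oriented from the older node (attached earlier) to the newer
    one, which is automatically acyclic and keeps the heavy-tailed degree
    sequence of the undirected attachment process.
    """
    if edges_per_node < 1:
        raise NetworkError("edges_per_node must be >= 1")
    if n_genes <= edges_per_node:
        raise NetworkError("n_genes must exceed edges_per_node")
    g = nx.barabasi_albert_graph(n_genes, edges_per_node, seed=int(seed))
    nodes = _gene_names(n_genes)
    # Attachment order equals node index, so min->max orientation is old->new.
    edges = {(nodes[min(u, v)], nodes[max(u, v)]) for u, v in g.edges()}
    return DirectedNetwork(nodes, edges)


def generate_random(n_genes: int, p_edge: float, seed: int) -> DirectedNetwork:
    """Random network: each unordered pair is linked independently with
    probability ``p_edge``; the direction of each link is uniform.
    """
    if n_genes < 1:
        raise NetworkError("n_genes must be >= 1")
    if not 0 <= p_edge <= 1:
        raise NetworkError("p_edge must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = _gene_names(n_genes)
    a_idx, b_idx = np.triu_indices(n_genes, k=1)
    keep = rng.random(a_idx.size) < p_edge
    flip = rng.random(a_idx.size) < 0.5
    edges = set()
    for a, b, k, f in zip(a_idx, b_idx, keep, flip):
        if k:
            edges.add((nodes[b], nodes[a]) if f else (nodes[a], nodes[b]))
    return DirectedNetwork(nodes, edges)


def sample_subnetwork(source: DirectedNetwork, size: int, seed: int) -> DirectedNetwork:
    """Induced subnetwork grown by random neighborhood expansion.

    A seed node is chosen uniformly; the node set then grows by repeatedly
    adding a uniform random (undirected) neighbor of the current set until the
    requested size is reached, so a weakly connected source yields a weakly
    connected sample. If the current component is exhausted first, growth
    restarts from a uniform unvisited node. Edges are exactly the edges of the
    source induced by the sampled nodes; signs are preserved.
    """
    if size < 1 or size > source.n_genes:
        raise NetworkError(
            f"subnetwork size {size} must lie in [1, {source.n_genes}]"
        )
    rng = np.random.default_rng(seed)
    idx = source.index()
    neighbors: dict[str, set[str]] = {g: set() for g in source.nodes}
    for u, v in source.edges:
        neighbors[u].add(v)
        neighbors[v].add(u)

    chosen: set[str] = set()
    start = source.nodes[rng.integers(source.n_genes)]
    chosen.add(start)
    while len(chosen) < size:
        frontier = sorted(
            {n for g in chosen for n in neighbors[g]} - chosen, key=idx.get
        )
        if frontier:
            chosen.add(frontier[rng.integers(len(frontier))])
        else:
            rest = sorted(set(source.nodes) - chosen, key=idx.get)
            chosen.add(rest[rng.integers(len(rest))])

    nodes = [g for g in source.nodes if g in chosen]
    edges = {(u, v) for u, v in source.edges if u in chosen and v in chosen}
    signs = {e: s for e, s in source.signs.items() if e in edges}
    return DirectedNetwork(nodes, edges, signs)


def assign_edge_signs(net: DirectedNetwork, p_activator: float, seed: int) -> DirectedNetwork:
    """Return a copy of ``net`` with every edge independently labelled
    activator (probability ``p_activator``) or repressor."""
    if not net.edges:
        raise NetworkError("cannot assign signs: network has no edges")
    if not 0 <= p_activator <= 1:
        raise NetworkError("p_activator must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ordered = net.sorted_edges()
    draw = rng.random(len(ordered)) < p_activator
    signs = {e: (ACTIVATOR if a else REPRESSOR) for e, a in zip(ordered, draw)}
    return DirectedNetwork(net.nodes, set(net.edges), signs)


def triples(net: DirectedNetwork):
    """All unordered 3-node combinations, in node order."""
    return itertools.combinations(net.nodes, 3)
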