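"""Biconnected-component decomposition of the compressed de Bruijn graph.

Every simple cycle - hence every bubble - lies entirely inside one
biconnected component (BCC) of the underlying undirected graph, and the
BCCs partition the undirected edges.  Decomposing first and enumerating
bubbles per component drastically shrinks the search space: edges not on
any cycle form singleton BCCs and are dropped outright.

The decomposition is Tarjan's lowpoint method, implemented iteratively
(an explicit stack) so that chain-like graphs of arbitrary length do not
overflow Python's recursion limit, and on the *multigraph* projection:
mirror arc pairs collapse to a single undirected edge, while parallel
edges between the same node pair with different strand labels stay
distinct (two parallel edges form a two-node cycle and must not be read
as a bridge).  Self-loops cannot take part in a bubble (a bubble needs
at least three distinct nodes) and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_graph import BiDBG, GraphNode, Arc

logger = logging.getLogger("kisbubble")


@dataclass
class BCC:
    """One biconnected component, materialised as an induced subgraph."""

    id: int
    node_ids: frozenset[int]
    edge_ids: frozenset[int]
    graph: BiDBG

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)


def _adjacency(g: BiDBG) -> dict[int, list[tuple[int, int]]]:
    """node -> [(edge_id, neighbour)], mirror pairs collapsed, self-loops dropped."""
    adj: dict[int, list[tuple[int, int]]] = {n: [] for n in g.nodes}
    for eid, (u, v, _lab) in sorted(g.undirected_edges().items()):
        if u == v:
            continue
        adj[u].append((eid, v))
        adj[v].append((eid, u))
    return adj


def _edge_partition(g: BiDBG) -> list[list[int]]:
    """Partition the undirected edges into biconnected components."""
    adj = _adjacency(g)
    disc: dict[int, int] = {}
    low: dict[int, int] = {}
    timer = 0
    comps: list[list[int]] = []

    for root in sorted(adj):
        if root in disc:
            continue
        disc[root] = low[root] = timer
        timer += 1
        estack: list[int] = []
        # frame: [node, parent_edge_id, neighbour iterator]
        stack = [(root, -1, iter(adj[root]))]
        while stack:
            v, pedge, it = stack[-1]
            descended = False
            for eid, w in it:
                if eid == pedge:
                    continue
                if w not in disc:
                    estack.append(eid)
                    disc[w] = low[w] = timer
                    timer += 1
                    stack.append((w, eid, iter(adj[w])))
                    descended = True
                    break
                elif disc[w] < disc[v]:
                    # back edge to an ancestor
                    estack.append(eid)
                    if disc[w] < low[v]:
                        low[v] = disc[w]
            if descended:
                continue
            stack.pop()
            if stack:
                u = stack[-1][0]
                if low[v] < low[u]:
                    low[u] = low[v]
                if low[v] >= disc[u]:
                    comp = []
                    while True:
                        e = estack.pop()
                        comp.append(e)
                        if e == pedge:
                            break
                    comps.append(comp)
    return comps


def _induced_subgraph(g: BiDBG, edge_ids: set[int]) -> BiDBG:
    sub = BiDBG(g.k)
    arcs = [a for a in g.arcs.values() if a.edge_id in edge_ids]
    for a in arcs:
        for nid in (a.src, a.dst):
            if nid not in sub.nodes:
                n = g.nodes[nid]
                sub.nodes[nid] = GraphNode(nid, n.fwd, n.rev, n.ksum.copy(), n.nk)
                sub._out[nid] = []
    for a in sorted(arcs, key=lambda a: a.id):
        sub.arcs[a.id] = Arc(a.id, a.src, a.dst, a.label, a.edge_id, a.mirror_id)
        sub._out[a.src].append(a.id)
    sub._next_node = g._next_node
    sub._next_arc = g._next_arc
    sub._next_edge = g._next_edge
    return sub


def decompose(graph: BiDBG, min_edges: int = 2) -> list[BCC]:
    """Split a cDBG into its biconnected components and keep the cyclic ones.

    Components with fewer than ``min_edges`` undirected edges (bridges,
    i.e. edges on no cycle) are discarded, since they cannot contain a
    bubble.  Each retained component is returned as an induced bidirected
    subgraph that preserves arc labels, node sequences and coverages.
    """
    if not graph.nodes:
        return []
    comps = _edge_partition(graph)
    out: list[BCC] = []
    for comp in comps:
        if len(comp) < min_edges:
            continue
        edge_ids = set(comp)
        sub = _induced_subgraph(graph, edge_ids)
        out.append(BCC(id=len(out), node_ids=frozenset(sub.nodes), edge_ids=frozenset(edge_ids), graph=sub))
    largest = max((len(b.node_ids) for b in out), default=0)
    logger.info("BCC decomposition: %d components retained, largest has %d nodes", len(out), largest)
    return out
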