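"""Bubble enumeration: four-node (substitution) compression and cycle search.

A bubble is a simple cycle of at least three distinct nodes with exactly
two switching nodes; the cycle splits at the switching nodes into two
valid paths whose internal sequences are the two variants of a
polymorphism.  Substitutions generate four-node bubbles (two anchors,
two equal-length internal nodes differing at one position); enumerating
them alongside everything else causes a combinatorial explosion, so they
are detected first, reported as SNP candidates, and squashed into a
single consensus node with ``N`` at the variant position.

Remaining bubbles are found by a backtracking simple-cycle search
(Tiernan-style) with lossless prunings built around the two defining
constraints: a cycle with more than two switching nodes can never be a
bubble, and the shorter of the two paths may not exceed the bound
(``2k - 2`` by default, the maximum spelled length of the exon-junction
path of an alternative-splicing event).  Each cycle is sought from its
minimal switching node with its bounded arm first, so the expensive
part of the search inherits the length bound; see
``_enumerate_backtracking`` for the exact cuts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from typing import Sequence

from .core_graph import BiDBG, Arc, Walk, reverse_walk, spell_path

__all__ = [
    "Bubble",
    "SnpCandidate",
    "BubbleSearch",
    "enumerate_bubbles",
    "compress_four_node_bubbles",
    "make_bubble_from_cycle",
]


@dataclass
class Bubble:
    """A simple cycle with exactly two switching nodes, split into two paths.

    Both walks run from ``sn_left`` (the smaller switching-node id) to
    ``sn_right``; ``seq_short``/``seq_long`` are the internal sequences
    (the spelled sequence of the internal nodes, anchors excluded), with
    ``len_short <= len_long``.  ``full_short``/``full_long`` spell the
    whole walks including the anchor nodes.
    """

    bcc_id: int
    sn_left: int
    sn_right: int
    path_short: Walk
    path_long: Walk
    seq_short: str
    seq_long: str
    len_short: int
    len_long: int
    full_short: str
    full_long: str
    anchor_left_len: int
    anchor_right_len: int
    key: tuple = None

    @property
    def length_difference(self) -> int:
        return self.len_long - self.len_short


@dataclass
class SnpCandidate:
    """A four-node substitution bubble, reported before being squashed.

    ``bubble`` preserves the full two-path structure; ``consensus`` is
    the internal sequence with the substituted position replaced by N.
    """

    bubble: Bubble
    consensus: str


@dataclass
class BubbleSearch:
    """Result of enumerating one component: bubbles plus search diagnostics."""

    bubbles: list[Bubble]
    aborted: bool
    explored: int


def _internal_length(g: BiDBG, node_ids: Sequence[int]) -> int:
    c = len(node_ids)
    if c == 0:
        return 0
    return sum(g.nodes[n].length for n in node_ids) - (g.k - 1) * (c - 1)


def _path_internal_seq(g: BiDBG, walk: Walk, anchor_left_len: int, internal_len: int) -> tuple[str, str]:
    full = spell_path(g, walk.arcs)
    start = anchor_left_len - (g.k - 1)
    return full, full[start : start + internal_len]


def make_bubble_from_cycle(g: BiDBG, cycle: Sequence[Arc], bcc_id: int,
                           max_shorter_path: int | None = None) -> Bubble | None:
    """Evaluate a closed arc cycle against the bubble definition.

    Returns a canonical ``Bubble`` if the cycle has at least three
    distinct nodes, exactly two switching nodes, and a shorter internal
    path no longer than ``max_shorter_path``; otherwise ``None``.
    """
    m = len(cycle)
    if m < 3:
        return None
    nodes = [a.src for a in cycle]
    if len(set(nodes)) != m:
        return None
    sw = [i for i in range(m) if cycle[i - 1].label[1] != cycle[i].label[0]]
    if len(sw) != 2:
        return None
    i1, i2 = sw
    path_a = list(cycle[i1:i2])                     # nodes[i1] -> nodes[i2]
    path_b = list(cycle[i2:]) + list(cycle[:i1])    # nodes[i2] -> nodes[i1]
    int_a = nodes[i1 + 1 : i2]
    int_b = nodes[i2 + 1 :] + nodes[:i1]
    len_a = _internal_length(g, int_a)
    len_b = _internal_length(g, int_b)
    bound = 2 * g.k - 2 if max_shorter_path is None else max_shorter_path
    if min(len_a, len_b) > bound:
        return None

    sna, snb = nodes[i1], nodes[i2]
    if sna <= snb:
        sn_left, sn_right = sna, snb
        arcs_a = [a.id for a in path_a]
        arcs_b = reverse_walk(g, [a.id for a in path_b])
        int_b = list(reversed(int_b))
    else:
        sn_left, sn_right = snb, sna
        arcs_a = reverse_walk(g, [a.id for a in path_a])
        arcs_b = [a.id for a in path_b]
        int_a = list(reversed(int_a))

    walk_a = Walk(tuple([sn_left] + int_a + [sn_right]), tuple(arcs_a))
    walk_b = Walk(tuple([sn_left] + int_b + [sn_right]), tuple(arcs_b))
    al_len = g.nodes[sn_left].length
    ar_len = g.nodes[sn_right].length
    full_a, seq_a = _path_internal_seq(g, walk_a, al_len, len_a)
    full_b, seq_b = _path_internal_seq(g, walk_b, al_len, len_b)

    if (len_a, seq_a, walk_a.nodes) <= (len_b, seq_b, walk_b.nodes):
        short = (walk_a, seq_a, len_a, full_a)
        long = (walk_b, seq_b, len_b, full_b)
    else:
        short = (walk_b, seq_b, len_b, full_b)
        long = (walk_a, seq_a, len_a, full_a)

    key = (sn_left, sn_right, tuple(sorted([walk_a.nodes[1:-1], walk_b.nodes[1:-1]])))
    return Bubble(
        bcc_id=bcc_id,
        sn_left=sn_left,
        sn_right=sn_right,
        path_short=short[0],
        path_long=long[0],
        seq_short=short[1],
        seq_long=long[1],
        len_short=short[2],
        len_long=long[2],
        full_short=short[3],
        full_long=long[3],
        anchor_left_len=al_len,
        anchor_right_len=ar_len,
        key=key,
    )


def _flip(letter: str) -> str:
    return "R" if letter == "F" else "F"


def _reach_sets(g: BiDBG, s: int, x: str) -> tuple[set, set]:
    """Reachability pruning sets for a search rooted at ``s`` leaving on side ``x``.

    States are ``(node, side)`` pairs: "standing on ``node`` having
    entered it on strand ``side``".  ``A`` holds states from which a
    valid (switch-free) walk can reach an arc that closes the cycle at
    ``s`` as a switching node (arc into ``s`` with second letter !=
    ``x``); ``B`` additionally allows one future switching node (with id
    > ``s``) on the way.  Node-disjointness is ignored, so membership is
    a necessary condition and discarding non-members is lossless.
    """
    # reverse valid transitions: state (m, z) is reached from (n, y) via
    # arc n->m labelled yz; build predecessor map on demand
    preds: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for a in g.arcs.values():
        preds.setdefault((a.dst, a.label[1]), []).append((a.src, a.label[0]))

    def closure(seeds: set) -> set:
        out = set(seeds)
        todo = list(seeds)
        while todo:
            state = todo.pop()
            for p in preds.get(state, ()):
                if p not in out:
                    out.add(p)
                    todo.append(p)
        return out

    closing = {
        (a.src, a.label[0])
        for a in g.arcs.values()
        if a.dst == s and a.label[1] != x and a.src != s
    }
    A = closure(closing)
    # states where switching once (at a node with id > s) lands in A or
    # closes immediately: entering u on the opposite side of an out-arc
    # and leaving through it is the one allowed switch
    switch_seeds = set()
    for u in g.nodes:
        if u <= s:
            continue
        for arc in g.out_arcs(u):
            nxt = (arc.dst, arc.label[1])
            if nxt in A or (arc.dst == s and arc.label[1] != x):
                switch_seeds.add((u, _flip(arc.label[0])))
    B = closure(A | switch_seeds)
    return A, B


def _enumerate_backtracking(
    g: BiDBG,
    bcc_id: int,
    bound: int,
    max_cycles: int | None,
    prune: bool,
) -> BubbleSearch:
    """Backtracking cycle search; see ``enumerate_bubbles``.

    With pruning on, every cycle is sought from its minimal *switching*
    node ``s``, traversing one arm and returning through the other; this
    admits three lossless cuts: at most one switching node may appear
    inside the open path (the closure at ``s`` supplies the second), the
    first arm's internal length may not exceed the shorter-path bound
    (every bubble is discovered with its short arm first), and any state
    from which no valid continuation can close the cycle at ``s``
    (side-aware reachability) is dead.  Without pruning, all simple
    cycles are enumerated from their minimal node and filtered on
    closure only.
    """
    found: dict[tuple, Bubble] = {}
    explored = 0
    aborted = False

    # explore well-supported nodes first: if the cycle cap aborts a
    # dense component, the strongly covered (true-path) bubbles have
    # already been reported; pure ordering, the result set is unchanged
    weight = {nid: -float(np.sum(n.ksum) / n.nk) for nid, n in g.nodes.items()}

    def ordered_arcs(node: int) -> list[Arc]:
        return sorted(g.out_arcs(node), key=lambda a: (weight[a.dst], a.dst, a.label, a.id))

    for s in sorted(g.nodes):
        if aborted:
            break
        reach_cache: dict[str, tuple[set, set]] = {}
        path: list[Arc] = []
        sw_count: list[int] = []  # switching count after each pushed arc
        on_path = {s}
        stack = [iter(ordered_arcs(s))]
        while stack:
            arc = next(stack[-1], None)
            if arc is None:
                stack.pop()
                if path:
                    done = path.pop()
                    sw_count.pop()
                    on_path.discard(done.dst)
                continue
            if max_cycles is not None:
                explored += 1
                if explored > max_cycles:
                    aborted = True
                    break
            if arc.dst == s:
                if len(path) >= 2:
                    if prune and arc.label[1] == path[0].label[0]:
                        continue  # s would not be switching: found elsewhere
                    bub = make_bubble_from_cycle(g, path + [arc], bcc_id, bound)
                    if bub is not None:
                        found.setdefault(bub.key, bub)
                continue
            if arc.dst in on_path:
                continue
            if not prune:
                if arc.dst < s:  # canonical start: minimal node of the cycle
                    continue
                path.append(arc)
                sw_count.append(0)
                on_path.add(arc.dst)
                stack.append(iter(ordered_arcs(arc.dst)))
                continue

            # --- pruned mode: s is the minimal switching node ---
            count = sw_count[-1] if path else 0
            switching = bool(path) and path[-1].label[1] != arc.label[0]
            if switching:
                if path[-1].dst <= s:
                    continue  # its cycles belong to a smaller start
                count += 1
                if count > 1:
                    continue
                # the old tip is the second switching node; the first
                # arm's interior is now fixed and must obey the bound
                if _internal_length(g, [a.dst for a in path[:-1]]) > bound:
                    continue
            elif count == 0:
                # all current path nodes are prospective first-arm interior
                if _internal_length(g, [a.dst for a in path]) > bound:
                    continue
            x = path[0].label[0] if path else arc.label[0]
            if x not in reach_cache:
                reach_cache[x] = _reach_sets(g, s, x)
            A, B = reach_cache[x]
            state = (arc.dst, arc.label[1])
            if count == 0:
                if state not in B:
                    continue
            elif state not in A:
                continue
            path.append(arc)
            sw_count.append(count)
            on_path.add(arc.dst)
            stack.append(iter(ordered_arcs(arc.dst)))

    bubbles = sorted(
        found.values(),
        key=lambda b: (b.sn_left, b.sn_right, b.seq_short, b.seq_long),
    )
    return BubbleSearch(bubbles=bubbles, aborted=aborted, explored=explored)


def enumerate_bubbles(
    bcc_graph: BiDBG,
    k: int | None = None,
    bcc_id: int = 0,
    max_shorter_path: int | None = None,
    max_cycles: int | None = 100_000,
    prune: bool = True,
) -> BubbleSearch:
    """Enumerate every bubble of one component by backtracking cycle search.

    Returns exactly the simple cycles with at least three distinct
    nodes, exactly two switching nodes, and a shorter internal path of
    at most ``max_shorter_path`` nt (default ``2k - 2``), each reported
    once in canonical form and in deterministic order.  ``prune=False``
    disables the search prunings (useful to verify they are lossless);
    the result set is identical either way.

    If more than ``max_cycles`` partial paths are explored the component
    is abandoned and flagged ``aborted``, keeping the bubbles found so
    far - components generated by approximate tandem repeats can hold an
    exponential number of cycles.
    """
    g = bcc_graph
    if k is not None and k != g.k:
        raise ValueError(f"k mismatch: graph built with k={g.k}, asked {k}")
    bound = 2 * g.k - 2 if max_shorter_path is None else max_shorter_path
    return _enumerate_backtracking(g, bcc_id, bound, max_cycles, prune)


# ---------------------------------------------------------------------------
# four-node compression
# ---------------------------------------------------------------------------


def _hamming1_pos(a: str, b: str) -> int | None:
    """Position of the unique mismatch between equal-length strings, else None.

    ``N`` matches any base (it only arises from earlier consensus merges).
    """
    if len(a) != len(b):
        return None
    pos = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y and x != "N" and y != "N":
            if pos >= 0:
                return None
            pos = i
    return pos if pos >= 0 else None


def compress_four_node_bubbles(bcc_graph: BiDBG, bcc_id: int = 0) -> tuple[BiDBG, list[SnpCandidate]]:
    """Report and squash all four-node substitution bubbles of a component.

    Repeatedly finds pairs of non-branching internal nodes that share
    the same two anchors on the same strand sides and store equal-length
    sequences differing at exactly one position; each such bubble is
    emitted as a ``SnpCandidate`` and the two internal nodes are merged
    into one consensus node carrying ``N`` at the substituted position,
    until no further four-node bubble exists.  After each squash the
    component is unitig-recompressed: collapsing one substitution bubble
    can simplify the anchors of an overlapping neighbour into a clean
    four-node bubble, so dense sequencing-error tangles unravel as a
    cascade.  Returns the reduced component graph.
    """
    from .core_graph import compress as _compress

    g = bcc_graph
    candidates: list[SnpCandidate] = []
    changed = True
    while changed:
        changed = False
        g = _compress(g)
        # internal candidates: exactly two undirected edges, to two distinct anchors
        internals: dict[tuple, list[tuple[int, str, Arc, Arc]]] = {}
        for nid in sorted(g.nodes):
            out = [g.arcs[a] for a in g._out[nid]]
            if len({a.edge_id for a in out}) != 2:
                continue
            edges = {}
            for a in out:
                edges.setdefault(a.edge_id, a)
            e1, e2 = sorted(edges)
            a_out1, a_out2 = edges[e1], edges[e2]
            u, w = a_out1.dst, a_out2.dst
            if u == w or nid in (u, w):
                continue
            # a valid anchor->nid->anchor traversal exists iff the two out
            # arcs leave nid on opposite strands (enter on X, leave on X)
            if a_out1.label[0] == a_out2.label[0]:
                continue
            # orient the traversal u -> nid -> w with nid read on side O
            # entering arc u->nid is the mirror of a_out1
            in_arc = g.arcs[a_out1.mirror_id]
            o = in_arc.label[1]
            sig_nodes = (min(u, w), max(u, w))
            if u <= w:
                x_side = in_arc.label[0]
                y_side = a_out2.label[1]
                first, last = in_arc, a_out2
            else:
                # orient from w instead: mirror of a_out2 enters nid
                in_arc = g.arcs[a_out2.mirror_id]
                o = in_arc.label[1]
                x_side = in_arc.label[0]
                y_side = a_out1.label[1]
                first, last = in_arc, a_out1
            sig = (sig_nodes, x_side, y_side)
            internals.setdefault(sig, []).append((nid, o, first, last))

        for sig in sorted(internals):
            group = internals[sig]
            if len(group) < 2:
                continue
            merged = False
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    p, op, pf, pl = group[i]
                    q, oq, qf, ql = group[j]
                    if p not in g.nodes or q not in g.nodes:
                        continue
                    sp = g.nodes[p].seq(op)
                    sq = g.nodes[q].seq(oq)
                    pos = _hamming1_pos(sp, sq)
                    if pos is None:
                        continue
                    cycle = [pf, pl, g.arcs[ql.mirror_id], g.arcs[qf.mirror_id]]
                    # substitution bubbles have path length 2k-1 > 2k-2, so
                    # the shorter-path bound must not apply here
                    bub = make_bubble_from_cycle(g, cycle, bcc_id, max_shorter_path=10**9)
                    if bub is None:
                        continue
                    consensus = sp[:pos] + "N" + sp[pos + 1 :]
                    candidates.append(SnpCandidate(bubble=bub, consensus=consensus))
                    _squash_pair(g, p, op, q, consensus)
                    changed = True
                    merged = True
                    break
                if merged:
                    break
            if merged:
                break
    return g, candidates


def _squash_pair(g: BiDBG, p: int, op: str, q: int, consensus: str) -> None:
    """Replace internal node pair (p, q) by p carrying the consensus sequence."""
    from .core_graph import reverse_complement, GraphNode

    np_ = g.nodes[p]
    nq = g.nodes[q]
    fwd = consensus if op == "F" else reverse_complement(consensus)
    g.nodes[p] = GraphNode(p, fwd, reverse_complement(fwd), np_.ksum + nq.ksum, np_.nk + nq.nk)
    for aid in list(g._out[q]):
        a = g.arcs[aid]
        mid = a.mirror_id
        if mid in g.arcs:
            m = g.arcs[mid]
            g._out[m.src] = [x for x in g._out[m.src] if x != mid]
            del g.arcs[mid]
        if aid in g.arcs:
            del g.arcs[aid]
    del g.nodes[q], g._out[q]
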