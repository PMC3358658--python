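"""Bidirected de Bruijn graph construction and path semantics.

The graph model follows the double-stranded convention of assembly
practice: every node ``N`` stores a forward sequence ``F(N)`` together
with its reverse complement ``R(N)``, and an arc from ``N1`` to ``N2``
labelled ``XY`` (``X, Y`` in ``{F, R}``) records that the ``(k-1)``-suffix
of side ``X`` of ``N1`` equals the ``(k-1)``-prefix of side ``Y`` of
``N2``.  Because of reverse complements every arc ``(u, v, XY)`` is
accompanied by its mirror ``(v, u, Y'X')`` with ``F' = R`` and ``R' = F``,
so the total arc count is even (self-mirror loops excepted).

A path is *valid* when, at every traversed node, the strand letter used
to enter the node matches the letter used to leave it; nodes where the
letters disagree are *switching* nodes.  Bubbles - the graph signature
of polymorphisms - are simple cycles with exactly two switching nodes.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("kisbubble")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic min of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _flip(letter: str) -> str:
    return "R" if letter == "F" else "F"


def mirror_label(label: str) -> str:
    """Label of the mirror arc: FF<->RR, FR and RF are self-mirror."""
    return _flip(label[1]) + _flip(label[0])


def _as_sequence(read) -> str:
    """Accept plain strings, Bio.SeqRecord, or anything with ``.seq``."""
    if isinstance(read, str):
        return read.upper()
    seq = getattr(read, "seq", None)
    if seq is not None:
        return str(seq).upper()
    return str(read).upper()


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------


@dataclass
class KmerTable:
    """Canonical k-mer counts, one count vector per experiment.

    Attributes
    ----------
    k : int
        Odd k-mer size.
    n_experiments : int
        Number of read sets whose counts are tracked separately.
    counts : dict
        Maps canonical k-mer -> list of per-experiment occurrence counts.
    """

    k: int
    n_experiments: int
    counts: dict[str, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)


def count_kmers(
    reads_per_experiment: Sequence[Iterable],
    k: int,
    min_coverage: int = 1,
    min_per_experiment: int = 0,
) -> KmerTable:
    """Count canonical k-mers per experiment and apply the coverage filter.

    Every k-mer occurrence is counted under its canonical form; k-mers
    containing a non-ACGT character are skipped, as are reads shorter
    than ``k``.  k-mers whose total count summed over all experiments is
    below ``min_coverage`` (the minimal k-mer coverage, used to shed most
    sequencing errors) are removed.  If ``min_per_experiment`` is
    positive, a k-mer is additionally required to reach that count in at
    least one experiment (off by default).

    Raises
    ------
    ValueError
        If ``k`` is even (palindromic k-mers would be their own reverse
        complement) or smaller than 3.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    n_exp = len(reads_per_experiment)
    if n_exp < 1:
        raise ValueError("at least one experiment is required")

    counts: dict[str, list[int]] = {}
    n_reads = 0
    n_short = 0
    for e, reads in enumerate(reads_per_experiment):
        for read in reads:
            seq = _as_sequence(read)
            n_reads += 1
            if len(seq) < k:
                n_short += 1
                continue
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if not _ACGT.issuperset(km):
                    continue
                c = canonical(km)
                vec = counts.get(c)
                if vec is None:
                    vec = [0] * n_exp
                    counts[c] = vec
                vec[e] += 1

    if n_short:
        logger.warning("%d of %d reads shorter than k=%d were skipped", n_short, n_reads, k)
    if n_reads and not counts:
        logger.warning("no k-mers counted: k=%d exceeds every read length", k)

    kept = {
        km: vec
        for km, vec in counts.items()
        if sum(vec) >= min_coverage
        and (min_per_experiment <= 0 or max(vec) >= min_per_experiment)
    }
    return KmerTable(k=k, n_experiments=n_exp, counts=kept)


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------


@dataclass
class GraphNode:
    """A (possibly compressed) node storing both strands of its sequence.

    ``ksum``/``nk`` keep the per-experiment sum of constituent k-mer
    counts and the number of constituent k-mers, so that a merged node
    reports the arithmetic mean coverage of the k-mers it absorbed.
    """

    id: int
    fwd: str
    rev: str
    ksum: np.ndarray
    nk: int

    def seq(self, side: str) -> str:
        return self.fwd if side == "F" else self.rev

    @property
    def length(self) -> int:
        return len(self.fwd)

    @property
    def counts(self) -> list[float]:
        """Mean per-experiment coverage of the constituent k-mers (2 decimals)."""
        return [round(float(s) / self.nk, 2) for s in self.ksum]


@dataclass
class Arc:
    id: int
    src: int
    dst: int
    label: str
    edge_id: int
    mirror_id: int


class BiDBG:
    """Bidirected (compressed) de Bruijn multigraph.

    Arcs are stored directed; mirror arcs share an ``edge_id``, which is
    also the identity of the corresponding undirected edge used by the
    biconnected-component decomposition.
    """

    def __init__(self, k: int):
        self.k = k
        self.nodes: dict[int, GraphNode] = {}
        self.arcs: dict[int, Arc] = {}
        self._out: dict[int, list[int]] = {}
        self._next_node = 0
        self._next_arc = 0
        self._next_edge = 0

    # -- construction ------------------------------------------------------

    def add_node(self, fwd: str, ksum: np.ndarray, nk: int, node_id: int | None = None) -> int:
        nid = self._next_node if node_id is None else node_id
        self._next_node = max(self._next_node, nid + 1)
        self.nodes[nid] = GraphNode(nid, fwd, reverse_complement(fwd), np.asarray(ksum, dtype=float), nk)
        self._out[nid] = []
        return nid

    def add_arc_pair(self, u: int, v: int, label: str) -> tuple[int, int]:
        """Insert arc ``(u, v, label)`` together with its mirror.

        A self-mirror arc (``u == v`` and ``mirror_label(label) == label``)
        is stored once, being its own mirror.
        """
        eid = self._next_edge
        self._next_edge += 1
        a = self._next_arc
        self._next_arc += 1
        mlab = mirror_label(label)
        if u == v and mlab == label:
            self.arcs[a] = Arc(a, u, v, label, eid, a)
            self._out[u].append(a)
            return a, a
        b = self._next_arc
        self._next_arc += 1
        self.arcs[a] = Arc(a, u, v, label, eid, b)
        self.arcs[b] = Arc(b, v, u, mlab, eid, a)
        self._out[u].append(a)
        self._out[v].append(b)
        return a, b

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def out_arcs(self, node: int) -> list[Arc]:
        """Arcs leaving ``node``, deterministically ordered."""
        arcs = [self.arcs[a] for a in self._out[node]]
        arcs.sort(key=lambda a: (a.dst, a.label, a.id))
        return arcs

    def out_degree(self, node: int, side: str) -> int:
        return sum(1 for a in self._out[node] if self.arcs[a].label[0] == side)

    def in_degree(self, node: int, side: str) -> int:
        # mirror symmetry: arcs entering `node` on side Y are mirrors of
        # arcs leaving it on side flip(Y)
        return self.out_degree(node, _flip(side))

    def mirror(self, arc_id: int) -> Arc:
        return self.arcs[self.arcs[arc_id].mirror_id]

    def undirected_edges(self) -> dict[int, tuple[int, int, str]]:
        """edge_id -> (u, v, label) keeping one representative arc per edge."""
        edges: dict[int, tuple[int, int, str]] = {}
        for a in self.arcs.values():
            if a.edge_id not in edges or a.id <= a.mirror_id:
                edges[a.edge_id] = (a.src, a.dst, a.label)
        return edges

    def copy(self) -> "BiDBG":
        g = BiDBG(self.k)
        for nid, n in self.nodes.items():
            g.nodes[nid] = GraphNode(nid, n.fwd, n.rev, n.ksum.copy(), n.nk)
            g._out[nid] = list(self._out[nid])
        for aid, a in self.arcs.items():
            g.arcs[aid] = Arc(a.id, a.src, a.dst, a.label, a.edge_id, a.mirror_id)
        g._next_node = self._next_node
        g._next_arc = self._next_arc
        g._next_edge = self._next_edge
        return g


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_graph(table: KmerTable) -> BiDBG:
    """Build the uncompressed bidirected de Bruijn graph from a k-mer table.

    One node is created per canonical k-mer; arcs are exactly the
    ``(k-1)``-overlaps among stored k-mers in either orientation,
    labelled with the strand pair that overlaps.  Mirror arcs arise
    automatically because an overlap of ``F(u)`` with ``F(v)`` is also an
    overlap of ``R(v)`` with ``R(u)``.
    """
    k = table.k
    g = BiDBG(k)
    ids: dict[str, int] = {}
    for km in sorted(table.counts):
        ids[km] = g.add_node(km, np.asarray(table.counts[km], dtype=float), 1)

    # (k-1)-prefix index over both sides of every node
    prefix: dict[str, list[tuple[int, str]]] = {}
    for km, nid in ids.items():
        node = g.nodes[nid]
        for side in ("F", "R"):
            prefix.setdefault(node.seq(side)[: k - 1], []).append((nid, side))

    seen: set[tuple[int, int, str]] = set()
    descriptors: list[tuple[int, int, str]] = []
    for km in sorted(table.counts):
        u = ids[km]
        node = g.nodes[u]
        for x in ("F", "R"):
            suf = node.seq(x)[1:]
            for v, y in prefix.get(suf, ()):
                d = (u, v, x + y)
                if d not in seen:
                    seen.add(d)
                    descriptors.append(d)

    # pair each descriptor with its mirror and insert the pair once
    for u, v, lab in sorted(descriptors):
        m = (v, u, mirror_label(lab))
        if m not in seen:  # defensive; cannot happen for true overlaps
            raise AssertionError(f"mirror arc missing for {(u, v, lab)}")
        if (u, v, lab) <= m:
            g.add_arc_pair(u, v, lab)
    return g


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------


def _mergeable(g: BiDBG, a: Arc) -> bool:
    if a.src == a.dst:
        return False
    x, y = a.label[0], a.label[1]
    if g.out_degree(a.src, x) != 1:
        return False
    if g.in_degree(a.dst, y) != 1:
        return False
    return True


def _merge(g: BiDBG, a: Arc) -> tuple[int, list[int]]:
    """Merge across arc ``a`` (eligibility checked by caller).

    Returns the new node id and the ids of arcs now incident to it.
    """
    u, v = a.src, a.dst
    x, y = a.label[0], a.label[1]
    nu, nv = g.nodes[u], g.nodes[v]
    s = nu.seq(x) + nv.seq(y)[g.k - 1 :]
    rc = reverse_complement(s)
    if s <= rc:
        fwd, m = s, "F"
    else:
        fwd, m = rc, "R"
    new = g.add_node(fwd, nu.ksum + nv.ksum, nu.nk + nv.nk)

    drop = {a.id, a.mirror_id}
    incident = [aid for aid in set(g._out[u] + g._out[v]) if aid not in drop]
    # arcs entering u/v are mirrors of arcs leaving them, so the set of
    # undirected edges touched is covered by the two out-lists
    touched: set[int] = set()
    for aid in list(incident):
        touched.add(aid)
        touched.add(g.arcs[aid].mirror_id)

    fm = _flip(m)
    for aid in sorted(touched):
        b = g.arcs[aid]
        src, dst = b.src, b.dst
        first, second = b.label[0], b.label[1]
        if src == u:
            # only arcs on the far side of u can remain (side x had out-degree 1)
            src, first = new, fm
        elif src == v:
            src, first = new, m
        if dst == u:
            dst, second = new, m
        elif dst == v:
            dst, second = new, fm
        g.arcs[aid] = Arc(b.id, src, dst, first + second, b.edge_id, b.mirror_id)

    # rebuild adjacency for the affected nodes
    for aid in drop:
        if aid in g.arcs:
            del g.arcs[aid]
    g._out[new] = sorted(
        {aid for aid in touched if aid in g.arcs and g.arcs[aid].src == new}
    )
    for w in {g.arcs[aid].dst for aid in g._out[new]} | {
        g.arcs[aid].src for aid in touched if aid in g.arcs
    }:
        if w in (u, v) or w not in g.nodes:
            continue
        g._out[w] = [aid for aid in g._out[w] if aid in g.arcs]
    del g.nodes[u], g.nodes[v], g._out[u], g._out[v]
    return new, list(g._out[new])


def compress(graph: BiDBG) -> BiDBG:
    """Merge maximal runs of unambiguously adjacent nodes (unitigs).

    An arc ``(u, v, XY)`` is contracted when side ``X`` of ``u`` has
    out-degree 1 and side ``Y`` of ``v`` has in-degree 1, so the spelled
    sequence of every valid path is preserved.  A run of ``i`` k-mer
    nodes collapses into one node of length ``k + (i - 1)``.  The
    operation is idempotent and returns a new graph.
    """
    g = graph.copy()
    work = deque(sorted(g.arcs))
    while work:
        aid = work.popleft()
        a = g.arcs.get(aid)
        if a is None:
            continue
        if not _mergeable(g, a):
            continue
        _, incident = _merge(g, a)
        work.extend(sorted(incident))
    return g


# ---------------------------------------------------------------------------
# path semantics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Walk:
    """An oriented path: node ids plus the arc ids linking them."""

    nodes: tuple[int, ...]
    arcs: tuple[int, ...]


def _check_contiguous(g: BiDBG, arc_ids: Sequence[int]) -> list[Arc]:
    arcs = [g.arcs[a] for a in arc_ids]
    for a, b in zip(arcs, arcs[1:]):
        if a.dst != b.src:
            raise ValueError(f"non-contiguous path: arc {a.id} ends at {a.dst}, arc {b.id} starts at {b.src}")
    return arcs


def switching_nodes(g: BiDBG, arc_ids: Sequence[int], cyclic: bool = False) -> list[int]:
    """Ids of nodes at which the path is invalid (entering strand != leaving strand).

    For an open path only internal nodes can be switching; with
    ``cyclic=True`` the arc list is taken as a closed cycle and the start
    node is checked against the wrap-around pair as well.
    """
    arcs = _check_contiguous(g, arc_ids)
    out = []
    for a, b in zip(arcs, arcs[1:]):
        if a.label[1] != b.label[0]:
            out.append(a.dst)
    if cyclic and arcs:
        if arcs[-1].dst != arcs[0].src:
            raise ValueError("cycle does not close")
        if arcs[-1].label[1] != arcs[0].label[0]:
            out.append(arcs[0].src)
    return out


def is_valid_path(g: BiDBG, arc_ids: Sequence[int]) -> bool:
    """True iff the path has no switching node (single nodes are valid)."""
    if not arc_ids:
        return True
    return not switching_nodes(g, arc_ids)


def spell_path(g: BiDBG, arc_ids: Sequence[int], node: int | None = None, side: str = "F") -> str:
    """Spell the DNA sequence of a valid path.

    Node orientations are dictated by the arc labels; consecutive node
    sequences overlap by ``k - 1`` characters, which are written once.
    A single-node path is spelled as the requested side of ``node``.
    Spelling the mirror traversal yields the reverse complement.
    """
    if not arc_ids:
        if node is None:
            raise ValueError("empty path needs an explicit node")
        return g.nodes[node].seq(side)
    arcs = _check_contiguous(g, arc_ids)
    if not is_valid_path(g, arc_ids):
        raise ValueError("cannot spell an invalid path")
    first = arcs[0]
    parts = [g.nodes[first.src].seq(first.label[0])]
    for a in arcs:
        parts.append(g.nodes[a.dst].seq(a.label[1])[g.k - 1 :])
    return "".join(parts)


def reverse_walk(g: BiDBG, arc_ids: Sequence[int]) -> list[int]:
    """Arc ids of the mirror traversal (reverse order, mirror arcs)."""
    return [g.arcs[a].mirror_id for a in reversed(list(arc_ids))]


# ---------------------------------------------------------------------------
# debug dump
# ---------------------------------------------------------------------------


def dump_graph(g: BiDBG, nodes_path: str, edges_path: str) -> None:
    """Write tab-separated node and edge tables (debugging aid)."""
    with open(nodes_path, "w") as fh:
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            fh.write("\t".join([str(nid), n.fwd] + [f"{c}" for c in n.counts]) + "\n")
    with open(edges_path, "w") as fh:
        for aid in sorted(g.arcs):
            a = g.arcs[aid]
            fh.write(f"{a.src}\t{a.dst}\t{a.label}\n")
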