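"""Shared test helpers: toy sequences, random graphs, brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from kisbubble.core_graph import BiDBG
from kisbubble.bubble_enum import make_bubble_from_cycle

# the three worked example transcript pairs (k = 5): a substitution, a
# skipped 5-nt exon, and an inexact tandem repeat
SUBSTITUTION_PAIR = ("CATCTACGCAG", "CATCTCCGCAG")
EXON_SKIP_PAIR = ("CATCTACGCA", "CATCTGCTCGACGCA")
TANDEM_REPEAT_PAIR = ("CATCTTAGGA", "CATCTCATCATAGGA")


def random_bidigraph(rng: np.random.Generator, n_max: int = 15, k: int = 5) -> BiDBG:
    """Random abstract bidirected multigraph with mirror-consistent arcs.

    Node sequences are random DNA of length k..k+5 (arc overlaps are not
    enforced: enumeration semantics depend only on labels and lengths).
    """
    n = int(rng.integers(3, n_max + 1))
    g = BiDBG(k)
    for _ in range(n):
        ln = int(rng.integers(k, k + 6))
        seq = "".join(rng.choice(list("ACGT"), ln))
        g.add_node(seq, np.ones(1), 1)
    m = int(rng.integers(n, int(1.5 * n) + 1))
    for _ in range(m):
        u, v = int(rng.integers(0, n)), int(rng.integers(0, n))
        if u == v:
            continue
        lab = "".join(rng.choice(list("FR"), 2))
        g.add_arc_pair(u, v, lab)
    return g


def brute_force_bubbles(g: BiDBG, bound: int) -> set:
    """All bubble keys via networkx simple-cycle enumeration + arc expansion."""
    dg = nx.MultiDiGraph()
    dg.add_nodes_from(g.nodes)
    for a in g.arcs.values():
        dg.add_edge(a.src, a.dst, key=a.id)
    keys = set()
    for nodes in nx.simple_cycles(dg):
        if len(set(nodes)) < 3 or len(set(nodes)) != len(nodes):
            continue
        arc_opts = []
        for u, v in zip(nodes, nodes[1:] + nodes[:1]):
            arc_opts.append([g.arcs[aid] for aid in g._out[u] if g.arcs[aid].dst == v])
        for combo in itertools.product(*arc_opts):
            b = make_bubble_from_cycle(g, list(combo), 0, bound)
            if b is not None:
                keys.add(b.key)
    return keys


def random_reads(rng: np.random.Generator, n: int = 4, lo: int = 20, hi: int = 40) -> list[str]:
    return [
        "".join(rng.choice(list("ACGT"), int(rng.integers(lo, hi + 1))))
        for _ in range(n)
    ]
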