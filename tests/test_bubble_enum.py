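"""Four-node compression and bubble enumeration."""

import numpy as np
import pytest

from kisbubble.bcc import decompose
from kisbubble.bubble_enum import compress_four_node_bubbles, enumerate_bubbles
from kisbubble.core_graph import build_graph, compress, count_kmers, reverse_complement
from _graphs import (
    EXON_SKIP_PAIR,
    SUBSTITUTION_PAIR,
    TANDEM_REPEAT_PAIR,
    brute_force_bubbles,
    random_bidigraph,
)


def _component(pair, k=5):
    g = compress(build_graph(count_kmers([list(pair)], k)))
    comps = decompose(g)
    assert len(comps) == 1
    return comps[0]


def _matches_either_strand(seq, expected):
    return seq in (expected, reverse_complement(expected))


class TestFourNodeCompression:
    def test_substitution_bubble_reported_and_squashed(self):
        comp = _component(SUBSTITUTION_PAIR)
        reduced, cands = compress_four_node_bubbles(comp.graph, comp.id)
        assert len(cands) == 1
        cand = cands[0]
        assert cand.bubble.len_short == cand.bubble.len_long == 9  # 2k-1
        assert {cand.bubble.seq_short, cand.bubble.seq_long} in (
            {"ATCTACGCA", "ATCTCCGCA"},
            {reverse_complement("ATCTACGCA"), reverse_complement("ATCTCCGCA")},
        )
        assert _matches_either_strand(cand.consensus, "ATCTNCGCA")
        # the component collapses to a single consensus-bearing chain node
        assert reduced.n_nodes == 1
        node = next(iter(reduced.nodes.values()))
        assert _matches_either_strand(node.fwd, "CATCTNCGCAG")
        assert enumerate_bubbles(reduced).bubbles == []

    def test_unequal_path_lengths_left_untouched(self):
        comp = _component(EXON_SKIP_PAIR)
        before = enumerate_bubbles(comp.graph, bcc_id=comp.id).bubbles
        reduced, cands = compress_four_node_bubbles(comp.graph, comp.id)
        assert cands == []  # arms differ in length: nothing to squash
        after = enumerate_bubbles(reduced, bcc_id=comp.id).bubbles
        assert [(b.len_short, b.len_long, b.seq_short, b.seq_long) for b in before] == [
            (b.len_short, b.len_long, b.seq_short, b.seq_long) for b in after
        ]

    def test_two_consecutive_substitution_bubbles_both_squashed(self):
        from kisbubble.core_graph import canonical

        k = 9
        rng = np.random.default_rng(17)
        while True:
            a, mid, b = ("".join(rng.choice(list("ACGT"), n)) for n in (25, 30, 25))
            t1 = a + "A" + mid + "C" + b
            t2 = a + "G" + mid + "T" + b
            mers = [t1[i : i + k - 1] for i in range(len(t1) - k + 2)]
            for var_at in (25, len(a) + 1 + len(mid)):
                mers += [
                    t2[i : i + k - 1]
                    for i in range(max(0, var_at - k + 2), var_at + 1)
                ]
            cmers = [canonical(m) for m in mers]
            if len(set(cmers)) == len(cmers) and all(
                m != reverse_complement(m) for m in mers
            ):
                break
        g = compress(build_graph(count_kmers([[t1, t2]], k)))
        total = []
        for comp in decompose(g):
            reduced, cands = compress_four_node_bubbles(comp.graph, comp.id)
            total.extend(cands)
            assert reduced.n_nodes == 1  # fully linearised
        assert len(total) == 2
        assert all(c.bubble.len_short == c.bubble.len_long == 2 * k - 1 for c in total)


class TestEnumeration:
    def test_exon_skip_bubble_lengths_and_sequence(self):
        comp = _component(EXON_SKIP_PAIR)
        res = enumerate_bubbles(comp.graph, bcc_id=comp.id)
        assert not res.aborted
        assert len(res.bubbles) == 1
        b = res.bubbles[0]
        assert (b.len_short, b.len_long) == (8, 13)  # 2k-2 and 2k-2 + exon
        assert "GCTCG" in b.seq_long or "CGAGC" in b.seq_long  # the skipped exon
        assert _matches_either_strand(b.seq_short, "ATCTACGC")

    def test_substitution_bubble_without_prior_compression(self):
        comp = _component(SUBSTITUTION_PAIR)
        # the SNP rule: both internal paths spell exactly 2k-1 nt
        res = enumerate_bubbles(comp.graph, max_shorter_path=2 * 5 - 1)
        assert len(res.bubbles) == 1
        assert res.bubbles[0].len_short == res.bubbles[0].len_long == 9
        # and the default 2k-2 bound excludes it
        assert enumerate_bubbles(comp.graph).bubbles == []

    def test_cycle_without_two_switching_nodes_yields_nothing(self):
        from kisbubble.core_graph import BiDBG

        g = BiDBG(5)
        for _ in range(4):
            g.add_node("ACGGT", np.ones(1), 1)
        # a 4-cycle of FF arcs: valid all the way round, zero switching nodes
        for u, v in ((0, 1), (1, 2), (2, 3), (3, 0)):
            g.add_arc_pair(u, v, "FF")
        assert enumerate_bubbles(g).bubbles == []

    def test_two_node_parallel_cycle_excluded(self):
        from kisbubble.core_graph import BiDBG

        g = BiDBG(5)
        for _ in range(2):
            g.add_node("ACGGT", np.ones(1), 1)
        g.add_arc_pair(0, 1, "FF")
        g.add_arc_pair(0, 1, "FR")
        assert enumerate_bubbles(g).bubbles == []

    def test_abort_flag_on_tiny_budget(self):
        comp = _component(TANDEM_REPEAT_PAIR)
        res = enumerate_bubbles(comp.graph, max_cycles=3)
        assert res.aborted

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_exhaustive_oracle_and_prunings_are_lossless(self, trial):
        """Pruned search == unpruned search == brute-force cycle filter."""
        rng = np.random.default_rng(4000 + trial)
        g = random_bidigraph(rng, n_max=12)
        bound = 2 * g.k - 2
        pruned = {b.key for b in enumerate_bubbles(g, prune=True, max_cycles=None).bubbles}
        plain = {b.key for b in enumerate_bubbles(g, prune=False, max_cycles=None).bubbles}
        assert pruned == plain == brute_force_bubbles(g, bound)

    @pytest.mark.parametrize("trial", range(10))
    def test_raising_the_bound_only_adds_bubbles(self, trial):
        rng = np.random.default_rng(6000 + trial)
        g = random_bidigraph(rng, n_max=10)
        small = {b.key for b in enumerate_bubbles(g, max_shorter_path=6, max_cycles=None).bubbles}
        large = {b.key for b in enumerate_bubbles(g, max_shorter_path=12, max_cycles=None).bubbles}
        assert small <= large

    @pytest.mark.parametrize("trial", range(10))
    def test_no_duplicate_reports(self, trial):
        rng = np.random.default_rng(7000 + trial)
        g = random_bidigraph(rng, n_max=10)
        res = enumerate_bubbles(g, max_cycles=None)
        keys = [b.key for b in res.bubbles]
        assert len(keys) == len(set(keys))
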