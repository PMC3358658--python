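"""Graph construction, compression and path semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kisbubble.core_graph import (
    BiDBG,
    build_graph,
    canonical,
    compress,
    count_kmers,
    is_valid_path,
    reverse_complement,
    spell_path,
    switching_nodes,
)
from _graphs import SUBSTITUTION_PAIR

dna = st.text(alphabet="ACGT", min_size=12, max_size=40)


def _chain_safe_sequence(rng, length, k):
    """Random sequence whose canonical (k-1)-mers are unique and non-palindromic,
    so its graph is a single simple chain."""
    while True:
        cand = "".join(rng.choice(list("ACGT"), length))
        mers = [cand[i : i + k - 1] for i in range(length - k + 2)]
        cmers = [canonical(m) for m in mers]
        if len(set(cmers)) == len(cmers) and all(
            m != reverse_complement(m) for m in mers
        ):
            return cand


class TestCountKmers:
    def test_substitution_pair_has_12_distinct_5mers(self):
        t = count_kmers([list(SUBSTITUTION_PAIR)], 5)
        assert len(t) == 12
        # the two transcripts share their 5' and 3' anchor k-mers
        assert canonical("CATCT") in t.counts and canonical("CGCAG") in t.counts

    def test_min_coverage_above_total_empties_table(self):
        t = count_kmers([list(SUBSTITUTION_PAIR)], 5, min_coverage=100)
        assert len(t) == 0

    def test_repeated_read_counts_add_up(self):
        # every canonical 5-mer of this read is unique, so each counts 3
        t = count_kmers([["ACGGTCATT"] * 3], 5)
        assert t.counts and all(v == [3] for v in t.counts.values())

    def test_reverse_complement_occurrences_share_one_canonical_kmer(self):
        # ACGTA recurs and TACGT is its reverse complement: one key, count 9
        t = count_kmers([["ACGTACGTA"] * 3], 5)
        assert t.counts["ACGTA"] == [9]

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            count_kmers([["ACGTACGT"]], 4)

    def test_k_beyond_read_length_gives_empty_table(self):
        assert len(count_kmers([["ACGTA"]], 7)) == 0

    def test_kmers_with_n_are_skipped(self):
        t = count_kmers([["ACGNACGTACG"]], 5)
        assert all("N" not in km for km in t.counts)

    def test_per_experiment_counts_tracked_separately(self):
        t = count_kmers([["ACGGTCATT"], ["ACGGTCATT", "ACGGTCATT"]], 5)
        assert all(v == [1, 2] for v in t.counts.values())

    @given(dna)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_strand_symmetry(self, seq):
        """Counting reverse-complemented reads yields the same table."""
        fwd = count_kmers([[seq]], 5)
        rev = count_kmers([[reverse_complement(seq)]], 5)
        assert fwd.counts == rev.counts


class TestBuildGraph:
    def test_single_kmer(self):
        g = build_graph(count_kmers([["ACGGT"]], 5))
        assert g.n_nodes == 1 and g.n_arcs == 0

    def test_palindromic_suffix_makes_hairpin_self_arc(self):
        # suffix of R(ACGTA)=TACGT is ACGT = prefix of F: a self-mirror RF loop
        g = build_graph(count_kmers([["ACGTA"]], 5))
        assert g.n_nodes == 1 and g.n_arcs == 1
        arc = next(iter(g.arcs.values()))
        assert arc.src == arc.dst and arc.label in ("RF", "FR")
        assert arc.mirror_id == arc.id

    def test_substitution_pair_topology(self):
        """Two chains of 5 internal k-mer nodes between the shared anchors."""
        g = build_graph(count_kmers([list(SUBSTITUTION_PAIR)], 5))
        assert g.n_nodes == 12
        degrees = sorted(
            len({g.arcs[a].edge_id for a in g._out[n]}) for n in g.nodes
        )
        # 10 chain nodes of degree 2, two branching anchors of degree 2+2
        assert degrees == [2] * 12
        assert g.n_arcs == 24  # 12 overlaps, each with its mirror

    def test_chain_arc_count(self):
        seq = _chain_safe_sequence(np.random.default_rng(5), 60, k=9)
        t = count_kmers([[seq]], 9)
        g = build_graph(t)
        assert g.n_arcs == 2 * (len(t) - 1)

    @given(st.lists(dna, min_size=1, max_size=3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_arcs_match_brute_force_overlap_check(self, reads):
        """Arc set equals the all-pairs (k-1)-overlap relation, both strands."""
        k = 5
        t = count_kmers([reads], k)
        g = build_graph(t)
        got = {(a.src, a.dst, a.label) for a in g.arcs.values()}
        want = set()
        for u in g.nodes:
            for v in g.nodes:
                for x in "FR":
                    for y in "FR":
                        if g.nodes[u].seq(x)[1:] == g.nodes[v].seq(y)[: k - 1]:
                            want.add((u, v, x + y))
        assert got == want

    @given(st.lists(dna, min_size=1, max_size=3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mirror_symmetry(self, reads):
        g = build_graph(count_kmers([reads], 5))
        for a in g.arcs.values():
            m = g.arcs[a.mirror_id]
            assert (m.src, m.dst) == (a.dst, a.src)
            assert m.label == {"FF": "RR", "RR": "FF", "FR": "FR", "RF": "RF"}[a.label]


class TestCompress:
    def test_substitution_pair_compresses_to_four_nodes(self):
        g = compress(build_graph(count_kmers([list(SUBSTITUTION_PAIR)], 5)))
        assert g.n_nodes == 4
        lengths = sorted(n.length for n in g.nodes.values())
        assert lengths == [5, 5, 9, 9]  # two anchors, two 2k-1 arms
        seqs = {n.fwd for n in g.nodes.values()} | {n.rev for n in g.nodes.values()}
        assert {"ATCTACGCA", "ATCTCCGCA"} <= seqs

    def test_simple_chain_becomes_single_node(self):
        seq = _chain_safe_sequence(np.random.default_rng(11), 30, k=7)
        g = compress(build_graph(count_kmers([[seq]], 7)))
        assert g.n_nodes == 1
        node = next(iter(g.nodes.values()))
        assert seq in (node.fwd, node.rev)

    def test_compressed_node_counts_are_mean_of_kmers(self):
        t = count_kmers([["ACGGTCATT", "ACGGTCATT", "GTCATTGCA"]], 5)
        g = compress(build_graph(t))
        node = next(iter(g.nodes.values()))
        # 5 k-mers counted twice, 2 counted twice+once... mean over kmers
        expected = round(sum(sum(v) for v in t.counts.values()) / len(t), 2)
        assert node.counts == [expected]

    @given(st.lists(dna, min_size=1, max_size=3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent(self, reads):
        g = compress(build_graph(count_kmers([reads], 5)))
        g2 = compress(g)
        assert g2.n_nodes == g.n_nodes and g2.n_arcs == g.n_arcs

    @given(dna)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_lossless_on_single_sequence(self, seq):
        """A repeat-free sequence is spelled verbatim by one compressed node."""
        k = 5
        mers = [seq[i : i + k - 1] for i in range(len(seq) - k + 2)]
        cmers = [canonical(m) for m in mers]
        if len(set(cmers)) != len(cmers) or any(m == reverse_complement(m) for m in mers):
            return  # only chain-shaped inputs compress to a single node
        g = compress(build_graph(count_kmers([[seq]], k)))
        assert g.n_nodes == 1
        node = next(iter(g.nodes.values()))
        assert seq in (node.fwd, node.rev)


class TestPathSemantics:
    @pytest.fixture()
    def fig_sub(self):
        return compress(build_graph(count_kmers([list(SUBSTITUTION_PAIR)], 5)))

    def _arm_cycle(self, g):
        """Arcs of the 4-node bubble cycle: anchor->arm->anchor->arm->anchor."""
        anchors = sorted(n for n in g.nodes if g.nodes[n].length == 5)
        arms = sorted(n for n in g.nodes if g.nodes[n].length == 9)
        a0 = anchors[0]
        path1, path2 = [], []
        for arm, store in zip(arms, (path1, path2)):
            first = next(a for a in g.out_arcs(a0) if a.dst == arm)
            second = next(
                a for a in g.out_arcs(arm)
                if a.dst == anchors[1] and a.label[0] == first.label[1]
            )
            store.extend([first, second])
        back = [g.arcs[a.mirror_id] for a in reversed(path2)]
        return path1, [a.id for a in path1 + back]

    def test_upper_path_is_valid_and_spells_transcript(self, fig_sub):
        path1, _ = self._arm_cycle(fig_sub)
        arcs = [a.id for a in path1]
        assert is_valid_path(fig_sub, arcs)
        spelled = spell_path(fig_sub, arcs)
        assert spelled in SUBSTITUTION_PAIR or reverse_complement(spelled) in SUBSTITUTION_PAIR

    def test_single_node_path_valid_and_spells_forward_side(self, fig_sub):
        nid = min(fig_sub.nodes)
        assert is_valid_path(fig_sub, [])
        assert spell_path(fig_sub, [], node=nid) == fig_sub.nodes[nid].fwd

    def test_full_cycle_has_exactly_two_switching_nodes(self, fig_sub):
        _, cycle = self._arm_cycle(fig_sub)
        sw = switching_nodes(fig_sub, cycle, cyclic=True)
        anchors = {n for n in fig_sub.nodes if fig_sub.nodes[n].length == 5}
        assert set(sw) == anchors and len(sw) == 2

    def test_reverse_traversal_spells_reverse_complement(self, fig_sub):
        from kisbubble.core_graph import reverse_walk

        path1, _ = self._arm_cycle(fig_sub)
        arcs = [a.id for a in path1]
        fwd = spell_path(fig_sub, arcs)
        rev = spell_path(fig_sub, reverse_walk(fig_sub, arcs))
        assert rev == reverse_complement(fwd)

    def test_non_contiguous_path_rejected(self, fig_sub):
        arcs = sorted(fig_sub.arcs)
        bad = None
        for i in arcs:
            for j in arcs:
                if fig_sub.arcs[i].dst != fig_sub.arcs[j].src:
                    bad = [i, j]
                    break
            if bad:
                break
        with pytest.raises(ValueError):
            switching_nodes(fig_sub, bad)
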