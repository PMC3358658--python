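"""Read mapping back to bubble paths, coherence filtering, coverage.

Each bubble path is turned into a mapping sequence: the internal
sequence plus up to ``k - 1`` nt of anchor context on each side, so that
junction-spanning reads can be placed.  Reads are mapped ungapped, in
either orientation, anchored by exact shared k-mers, allowing a small
number of substitutions; a read whose overlap with the path is shorter
than ``k`` nt is discarded, mirroring the graph's own resolution.  The
read k-mer index is built once per run and shared across bubbles.

Discarding short overlaps systematically deflates the counts of the
``k - 1`` outermost positions; under locally uniform coverage the bias
is exactly ``(L - i) / L`` at distance ``i`` from the first unbiased
position, so the correction multiplies those positions by ``L/(L - i)``.

A bubble is *read-coherent* when every position of both paths is
covered by at least one read (raw counts, pooled over experiments);
incoherent bubbles are discarded as unsupported by the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bubble_enum import Bubble
from .classify import EventCall
from .core_graph import reverse_complement, _as_sequence

logger = logging.getLogger("kisbubble")


@dataclass
class PathCoverage:
    """Per-position coverage of one bubble path.

    ``raw`` holds uncorrected pooled counts (used for the coherence
    test); ``corrected`` holds one border-corrected vector per
    experiment; ``mean_coverage`` averages the corrected counts over the
    internal sequence, per experiment.
    """

    sequence: str
    internal_slice: tuple[int, int]
    raw: np.ndarray
    raw_per_experiment: list[np.ndarray]
    corrected: list[np.ndarray]
    mean_coverage: list[float]
    read_coherent: bool
    per_experiment_coherent: list[bool]


class ReadIndex:
    """Exact k-mer index over all reads, both orientations.

    Maps k-mer -> list of ``(experiment, read_id, strand, position)``;
    built once and reused for every bubble path of a run.
    """

    def __init__(self, reads_per_experiment, k: int):
        self.k = k
        self.reads: list[list[str]] = [
            [_as_sequence(r) for r in reads] for reads in reads_per_experiment
        ]
        self.mean_read_length: list[int] = [
            int(round(float(np.mean([len(r) for r in reads])))) if reads else 0
            for reads in self.reads
        ]
        self.index: dict[str, list[tuple[int, int, int, int]]] = {}
        for e, reads in enumerate(self.reads):
            for rid, seq in enumerate(reads):
                if len(seq) < k:
                    continue
                for strand, oriented in ((0, seq), (1, reverse_complement(seq))):
                    for j in range(len(oriented) - k + 1):
                        self.index.setdefault(oriented[j : j + k], []).append(
                            (e, rid, strand, j)
                        )

    @property
    def n_experiments(self) -> int:
        return len(self.reads)

    def oriented_read(self, e: int, rid: int, strand: int) -> str:
        seq = self.reads[e][rid]
        return seq if strand == 0 else reverse_complement(seq)


def _map_with_index(
    path_sequence: str, index: ReadIndex, max_mismatches: int
) -> list[np.ndarray]:
    """Per-experiment raw per-position counts for one path sequence."""
    k = index.k
    n = len(path_sequence)
    out = [np.zeros(n, dtype=float) for _ in range(index.n_experiments)]
    if n < k:
        return out
    candidates: dict[tuple[int, int, int], set[int]] = {}
    for i in range(n - k + 1):
        for e, rid, strand, j in index.index.get(path_sequence[i : i + k], ()):
            candidates.setdefault((e, rid, strand), set()).add(i - j)
    accepted: dict[int, set[tuple[int, int, int]]] = {}
    for (e, rid, strand), offsets in candidates.items():
        oriented = index.oriented_read(e, rid, strand)
        m = len(oriented)
        for off in offsets:
            lo, hi = max(0, off), min(n, off + m)
            if hi - lo < k:
                continue
            mism = 0
            ok = True
            for p in range(lo, hi):
                x = path_sequence[p]
                y = oriented[p - off]
                if x != y and x != "N" and y != "N":
                    mism += 1
                    if mism > max_mismatches:
                        ok = False
                        break
            if ok:
                # a read and its reverse complement at mirrored offsets
                # cover the same span; count each read span once
                accepted.setdefault(e, set()).add((rid, lo, hi))
    for e, spans in accepted.items():
        for _rid, lo, hi in spans:
            out[e][lo:hi] += 1
    return out


def map_reads(path_sequence: str, reads, k: int, max_mismatches: int = 2) -> np.ndarray:
    """Raw per-position read counts along a path sequence.

    A read contributes +1 to every position it overlaps, in either
    orientation, provided the overlap is at least ``k`` nt and carries
    at most ``max_mismatches`` substitutions (``N`` in the path matches
    anything).  Placement is anchored on exact shared k-mers, ungapped.
    """
    index = ReadIndex([reads], k)
    return _map_with_index(path_sequence, index, max_mismatches)[0]


def correct_borders(raw_counts: np.ndarray, L: int, k: int) -> np.ndarray:
    """Scale the ``k - 1`` outermost positions at each end by ``L / (L - i)``.

    ``i`` is the distance to the first unbiased position: 1 next to it,
    up to ``k - 1`` at the outermost position.  Interior positions are
    unchanged.  If ``L <= k - 1`` the factor is undefined and the counts
    are returned uncorrected with a warning.
    """
    out = np.asarray(raw_counts, dtype=float).copy()
    if L <= k - 1:
        logger.warning("read length L=%d <= k-1=%d: border correction skipped", L, k - 1)
        return out
    n = len(out)
    for j in range(min(k - 1, n)):
        i = k - 1 - j  # outermost position first
        factor = L / (L - i)
        out[j] *= factor
        out[n - 1 - j] *= factor
    return out


def path_mapping_sequence(
    bubble: Bubble, which: str, flank: int | None = None, k: int | None = None
) -> tuple[str, tuple[int, int]]:
    """Mapping sequence for one path ('short'/'long') and its internal span.

    The full spelled path (anchors included) is trimmed so that at most
    ``flank`` anchor nt remain on each side of the internal sequence
    (default ``k - 1``).  Returns the sequence and the slice of the
    internal sequence within it.
    """
    if k is None:
        raise ValueError("k is required to trim anchor flanks")
    f = k - 1 if flank is None else flank
    full = bubble.full_short if which == "short" else bubble.full_long
    ln = bubble.len_short if which == "short" else bubble.len_long
    s0 = bubble.anchor_left_len - (k - 1)
    e0 = s0 + ln
    start = max(0, s0 - f)
    end = min(len(full), e0 + f)
    return full[start:end], (s0 - start, s0 - start + ln)


def quantify_bubble(
    event: EventCall,
    reads_per_experiment=None,
    k: int | None = None,
    max_mismatches: int = 2,
    flank: int | None = None,
    index: ReadIndex | None = None,
) -> EventCall | None:
    """Map reads to both paths; keep the event only if read-coherent.

    Coherence requires every position of each path's mapping sequence
    to be covered by at least one read, pooled over experiments
    (per-experiment coherence is reported but does not discard).  The
    read length used for the border correction is the mean read length
    of each experiment.  Returns the event with ``coverage`` filled, or
    ``None`` if the bubble is discarded.
    """
    if index is None:
        if reads_per_experiment is None or k is None:
            raise ValueError("need either a ReadIndex or reads plus k")
        index = ReadIndex(reads_per_experiment, k)
    k = index.k
    coverage: dict[str, PathCoverage] = {}
    coherent = True
    for which in ("short", "long"):
        seq, internal = path_mapping_sequence(event.bubble, which, flank=flank, k=k)
        per_exp = _map_with_index(seq, index, max_mismatches)
        pooled = np.sum(per_exp, axis=0) if per_exp else np.zeros(len(seq))
        corrected = [
            correct_borders(v, L, k) if L > 0 else v.copy()
            for v, L in zip(per_exp, index.mean_read_length)
        ]
        lo, hi = internal
        means = []
        for v in corrected:
            window = v[lo:hi] if hi > lo else v
            means.append(float(np.mean(window)) if len(window) else 0.0)
        ok = bool(np.all(pooled >= 1))
        coverage[which] = PathCoverage(
            sequence=seq,
            internal_slice=internal,
            raw=pooled,
            raw_per_experiment=per_exp,
            corrected=corrected,
            mean_coverage=means,
            read_coherent=ok,
            per_experiment_coherent=[bool(np.all(v >= 1)) for v in per_exp],
        )
        coherent = coherent and ok
    event.coverage = coverage
    if not coherent:
        for which in ("short", "long"):
            pc = coverage[which]
            if not pc.read_coherent:
                holes = np.flatnonzero(pc.raw < 1)
                logger.info(
                    "bubble discarded (not read-coherent): %s path, %d uncovered positions %s",
                    which, len(holes), holes[:10].tolist(),
                )
        return None
    return event
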