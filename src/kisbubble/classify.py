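"""Bubble classification: AS event, SNP, short indel, or tandem repeat.

Path lengths carry most of the signal.  A substitution yields two paths
of exactly ``2k - 1`` nt; an alternative-splicing (AS) event yields a
shorter path of at most ``2k - 2`` nt (the k-mers covering the exon-exon
junction); a genomic indel looks like a small AS event but with a path
length difference strictly below 3 nt for the vast majority of human
indels; and an approximate tandem repeat betrays itself by sequence: the
whole shorter path re-occurs, almost exactly, at one end of the longer
path, because the longer path carries an extra (inexact) copy of
sequence already present next to the junction.

The repeat test compares the shorter path against the two end windows
of the longer path with an ungapped positional identity.  An edit-
distance identity would be fooled by plain insertions (a d-nt insertion
bubble aligns to an end window with only ~2d edits and would pass any
reasonable threshold for small d); the ungapped comparison only scores
high when the window really is a shifted copy, which is exactly the
tandem-repeat signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .bubble_enum import Bubble


class EventClass(str, Enum):
    AS = "AS"
    SNP = "SNP"
    INDEL = "INDEL"
    REPEAT = "REPEAT"


@dataclass
class AlignmentSummary:
    """Ungapped identities of the shorter path vs the longer path's ends."""

    identity_left: float
    identity_right: float

    @property
    def best_identity(self) -> float:
        return max(self.identity_left, self.identity_right)

    @property
    def best_end(self) -> str:
        return "left" if self.identity_left >= self.identity_right else "right"


@dataclass
class EventCall:
    """A classified bubble; quantification fields are filled in later."""

    bubble: Bubble
    event_class: EventClass
    alignment_identity: float
    length_difference: int
    coverage: dict | None = None  # path -> PathCoverage, set by quantify


def _identity(a: str, b: str) -> float:
    """Positionwise identity; ``N`` (consensus wildcard) matches anything."""
    if not a:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y or x == "N" or y == "N")
    return matches / len(a)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings, N matching anything."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def align_paths(bubble: Bubble) -> AlignmentSummary:
    """Compare the shorter path with each end of the longer path.

    Both windows have the shorter path's length; identities are
    ungapped.  An empty shorter path scores 0 at both ends.
    """
    s, l = bubble.seq_short, bubble.seq_long
    if not s:
        return AlignmentSummary(0.0, 0.0)
    return AlignmentSummary(
        identity_left=_identity(s, l[: len(s)]),
        identity_right=_identity(s, l[len(l) - len(s) :]),
    )


def classify(
    bubble: Bubble,
    k: int,
    indel_max_diff: int = 3,
    repeat_identity_min: float = 0.8,
) -> EventCall:
    """Assign exactly one event class to a bubble.

    Decision cascade:

    1. both paths of length exactly ``2k - 1`` at Hamming distance 1
       -> SNP (a safety net: most substitutions are consumed earlier by
       four-node compression);
    2. whole shorter path matches an end window of the longer path with
       identity >= ``repeat_identity_min`` -> REPEAT;
    3. ``0 < len_long - len_short < indel_max_diff`` -> INDEL;
    4. otherwise -> AS.

    The thresholds are deliberately exposed: the boundary between short
    AS events, indels and repeats is a heuristic, not a theorem.
    """
    diff = bubble.len_long - bubble.len_short
    aln = align_paths(bubble)
    if (
        bubble.len_short == bubble.len_long == 2 * k - 1
        and hamming(bubble.seq_short, bubble.seq_long) == 1
    ):
        cls = EventClass.SNP
    elif aln.best_identity >= repeat_identity_min:
        cls = EventClass.REPEAT
    elif 0 < diff < indel_max_diff:
        cls = EventClass.INDEL
    else:
        cls = EventClass.AS
    return EventCall(
        bubble=bubble,
        event_class=cls,
        alignment_identity=aln.best_identity,
        length_difference=diff,
    )
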