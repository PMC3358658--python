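"""Synthetic data: planted polymorphisms and a single-end read simulator.

The generator plants one polymorphism between a pair of transcripts
built as ``a + s + b`` / ``a + b`` (or ``a + x + b`` / ``a + y + b`` for
substitutions): random flanks ``a`` and ``b`` around a variable part,
rejection-sampled so that no short substring recurs anywhere in either
transcript - the condition under which the event creates exactly one
clean bubble in the graph.  Read simulation draws uniform start
positions (which produces the Poisson-like heterogeneous depth of real
experiments), a uniform strand, and i.i.d. base substitution errors.

``sensitivity_sweep`` reruns the whole pipeline over a grid of
coverages, k values and replicates and records whether the planted
event was recovered, reproducing the coverage-sensitivity protocol used
to characterise the method (75-bp reads, a 200-nt skipped exon,
coverages of a few fold to ~20 fold, 3 replicates per point).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_graph import canonical, reverse_complement

_BASES = "ACGT"


@dataclass
class SimScenario:
    """Specification of one planted polymorphism and its read simulation.

    Defaults follow the sensitivity protocol: 350-nt flanks (so
    transcripts dwarf the reads), a 200-nt skipped exon, 75-bp
    single-end reads, 1% substitution errors, three replicates.
    """

    event_type: str = "exon_skip"  # exon_skip | snp | tandem_repeat | indel
    flank_length: int = 350
    variable_length: int = 200
    coverage: float = 8.0
    read_length: int = 75
    error_rate: float = 0.01
    n_replicates: int = 3
    seed: int = 0
    unique_mer: int = 15  # rejection-sampling uniqueness scale

    def __post_init__(self):
        if self.flank_length < 1 or self.coverage <= 0:
            raise ValueError("flank_length and coverage must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must lie in [0, 0.1)")
        if self.event_type not in ("exon_skip", "snp", "tandem_repeat", "indel"):
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass
class TruthRecord:
    """Ground truth for one planted event."""

    event_type: str
    a: str
    b: str
    variable: str  # inserted sequence s' (variant base for snp)
    transcript_inclusion: str
    transcript_exclusion: str

    def expected_paths(self, k: int) -> tuple[str, str]:
        """Expected internal (shorter, longer) path sequences for a given k."""
        if self.event_type == "snp":
            raise ValueError("snp truth has equal-length paths; use expected_snp_paths")
        short = self.a[-(k - 1) :] + self.b[: k - 1]
        long = self.a[-(k - 1) :] + self.variable + self.b[: k - 1]
        return short, long

    def expected_lengths(self, k: int) -> tuple[int, int]:
        short, long = self.expected_paths(k)
        return len(short), len(long)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _mer_multiset(seq: str, m: int) -> list[str]:
    return [canonical(seq[i : i + m]) for i in range(len(seq) - m + 1)]


def _no_repeats(seq: str, m: int) -> bool:
    """No canonical m-mer occurs twice within ``seq``."""
    mers = _mer_multiset(seq, m)
    return len(mers) == len(set(mers))


def _variant_mers_disjoint(seq1: str, pos: int, var_len: int, seq2: str, m: int) -> bool:
    """m-mers of ``seq1`` touching its variant region must not occur in ``seq2``.

    Shared variant-spanning m-mers would let the two bubble paths share
    k-mers and split or merge the bubble.
    """
    window = seq1[max(0, pos - m + 1) : pos + var_len + m - 1]
    others = set(_mer_multiset(seq2, m))
    return not any(km in others for km in _mer_multiset(window, m))


def make_transcript_pair(
    scenario: SimScenario, seed: int | None = None, max_tries: int = 200
) -> tuple[str, str, TruthRecord]:
    """Draw a transcript pair with one planted polymorphism.

    Flanks and the variable part are uniform random DNA,
    rejection-sampled until no ``unique_mer``-mer repeats within either
    transcript (guaranteeing a single clean bubble for any
    ``k > unique_mer``).  For insertion-type events the first/last
    nucleotide of the variable part is forced distinct from the adjacent
    flank nucleotide, which pins the shorter path length to exactly
    ``2k - 2``.

    Returns ``(inclusion, exclusion, truth)``; identical seeds give
    identical outputs.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    m = scenario.unique_mer
    for _ in range(max_tries):
        a = _rand_dna(rng, scenario.flank_length)
        b = _rand_dna(rng, scenario.flank_length)
        if scenario.event_type == "snp":
            x = _rand_dna(rng, 1)
            y = str(rng.choice([c for c in _BASES if c != x]))
            incl = a + x + b
            excl = a + y + b
            if (
                _no_repeats(incl, m)
                and _no_repeats(excl, m)
                and _variant_mers_disjoint(incl, len(a), 1, excl, m)
                and _variant_mers_disjoint(excl, len(a), 1, incl, m)
            ):
                truth = TruthRecord("snp", a, b, x + "/" + y, incl, excl)
                return incl, excl, truth
            continue
        if scenario.event_type == "tandem_repeat":
            # the insert is an inexact copy of the tail of `a`: the
            # hallmark by which repeat bubbles are recognised
            d = max(scenario.variable_length, m + 1)
            unit = list(a[-d:])
            p = int(rng.integers(1, d - 1))
            unit[p] = str(rng.choice([c for c in _BASES if c != unit[p]]))
            s = "".join(unit)
            incl = a + s + b
            excl = a + b
            if _no_repeats(excl, m):
                truth = TruthRecord("tandem_repeat", a, b, s, incl, excl)
                return incl, excl, truth
            continue
        # exon_skip and indel share the insertion generator
        s = list(_rand_dna(rng, scenario.variable_length))
        if s[-1] == a[-1]:
            s[-1] = str(rng.choice([c for c in _BASES if c != a[-1]]))
        if s[0] == b[0]:
            s[0] = str(rng.choice([c for c in _BASES if c != b[0]]))
        s = "".join(s)
        incl = a + s + b
        excl = a + b
        if (
            _no_repeats(incl, m)
            and _no_repeats(excl, m)
            and _variant_mers_disjoint(excl, len(a), 0, incl, m)
        ):
            truth = TruthRecord(scenario.event_type, a, b, s, incl, excl)
            return incl, excl, truth
    raise RuntimeError(
        f"could not sample a clean transcript pair in {max_tries} tries; "
        "parameters are too repetitive"
    )


def simulate_reads(
    transcripts: Sequence[str],
    coverage: float,
    L: int = 75,
    error_rate: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Simulate single-end reads at a target mean per-base depth.

    Each transcript yields ``ceil(coverage * length / L)`` reads with
    uniform start positions, uniform strand, and i.i.d. substitution
    errors at ``error_rate`` per base.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    reads: list[str] = []
    for t in transcripts:
        t = str(t)
        if len(t) < L:
            raise ValueError(f"transcript length {len(t)} < read length {L}")
        n = ceil(coverage * len(t) / L)
        starts = rng.integers(0, len(t) - L + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        for start, strand in zip(starts, strands):
            read = t[start : start + L]
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(L) < error_rate)
                if len(errs):
                    chars = list(read)
                    for p in errs:
                        chars[p] = _BASES[
                            (_BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4
                        ]
                    read = "".join(chars)
            if strand:
                read = reverse_complement(read)
            reads.append(read)
    return reads


def _seq_matches(found: str, expected: str) -> bool:
    """Equality with N treated as a wildcard (consensus positions)."""
    return len(found) == len(expected) and all(
        x == y or x == "N" or y == "N" for x, y in zip(found, expected)
    )


def event_matches_truth(event, truth: TruthRecord, k: int) -> bool:
    """Does an AS call reproduce the planted event's two path sequences?

    Compared against both strands, since the bubble's reported
    orientation is an arbitrary function of node identities; ``N``
    positions (from four-node consensus merges of sequencing-error
    bubbles) match any base.
    """
    exp_short, exp_long = truth.expected_paths(k)
    fs, fl = event.bubble.seq_short, event.bubble.seq_long
    if _seq_matches(fs, exp_short) and _seq_matches(fl, exp_long):
        return True
    return _seq_matches(fs, reverse_complement(exp_short)) and _seq_matches(
        fl, reverse_complement(exp_long)
    )


def sensitivity_sweep(
    scenario: SimScenario,
    coverages: Iterable[float],
    ks: Iterable[int],
    min_kmer_coverage: int = 1,
    seed: int | None = None,
    truth: TruthRecord | None = None,
    transcripts: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over a coverage x k x replicate grid.

    One transcript pair is drawn once (or supplied) and reused for the
    whole grid; reads are drawn per (coverage, replicate) cell with
    seeds derived deterministically from ``seed``, and every k is tested
    against the same reads, as in the original protocol.  Returns a
    tidy table with columns ``coverage, k, replicate, event_found,
    n_false_positives`` where a false positive is any kept AS call not
    matching the planted truth.
    """
    from .pipeline import RunConfig, run_pipeline

    base_seed = scenario.seed if seed is None else seed
    if transcripts is None or truth is None:
        incl, excl, truth = make_transcript_pair(scenario, seed=base_seed)
    else:
        incl, excl = transcripts
    rows = []
    coverages = list(coverages)
    ks = list(ks)
    for ci, cov in enumerate(coverages):
        for rep in range(scenario.n_replicates):
            ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(ci, rep))
            rng = np.random.default_rng(ss)
            reads = simulate_reads(
                [incl, excl], cov, scenario.read_length, scenario.error_rate, rng=rng
            )
            for k in ks:
                if k > scenario.read_length:
                    rows.append((cov, k, rep, False, 0))
                    continue
                cfg = RunConfig(k=k, min_kmer_coverage=min_kmer_coverage)
                result = run_pipeline(cfg, reads_per_experiment=[reads])
                as_calls = [e for e in result.events if e.event_class.value == "AS"]
                hits = [e for e in as_calls if event_matches_truth(e, truth, k)]
                rows.append((cov, k, rep, bool(hits), len(as_calls) - len(hits)))
    return pd.DataFrame(
        rows, columns=["coverage", "k", "replicate", "event_found", "n_false_positives"]
    )


def k_window(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-coverage k_min/k_max: k values recovering exactly the true event.

    A k qualifies when every replicate found the planted event with no
    false positives.
    """
    rows = []
    for cov, grp in sweep.groupby("coverage"):
        ok = (
            grp.groupby("k")
            .apply(
                lambda d: bool(d["event_found"].all() and (d["n_false_positives"] == 0).all()),
                include_groups=False,
            )
        )
        good = [k for k, v in ok.items() if v]
        rows.append((cov, min(good) if good else None, max(good) if good else None))
    return pd.DataFrame(rows, columns=["coverage", "k_min", "k_max"])


def detection_by_coverage(sweep: pd.DataFrame) -> pd.DataFrame:
    """Fraction of replicates recovering the event, per coverage (any k pooled)."""
    out = (
        sweep.groupby(["coverage", "replicate"])["event_found"]
        .any()
        .groupby("coverage")
        .mean()
        .rename("detection_fraction")
        .reset_index()
    )
    return out
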