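"""End-to-end pipeline: reads in, classified and quantified events out.

The six stages run in order: (1) canonical k-mer counting with the
minimal-coverage filter and bidirected graph construction with unitig
compression; (2) biconnected-component decomposition, dropping bridges;
(3) four-node substitution compression, emitting SNP candidates;
(4) bubble enumeration per component with the shorter-path bound;
(5) classification into AS / SNP / INDEL / REPEAT; (6) read mapping,
read-coherence filtering and border-corrected coverage.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from . import bcc as bcc_mod
from .bubble_enum import compress_four_node_bubbles, enumerate_bubbles
from .classify import EventCall, EventClass, classify
from .core_graph import build_graph, compress, count_kmers
from .quantify import ReadIndex, quantify_bubble

logger = logging.getLogger("kisbubble")


class ConfigError(ValueError):
    """Invalid run configuration (CLI maps this to exit code 2)."""


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    ``max_shorter_path`` defaults to ``2k - 2`` (the AS shorter-path
    bound) and ``flank`` to ``k - 1`` when left as ``None``.
    """

    k: int = 25
    min_kmer_coverage: int = 1
    indel_max_diff: int = 3
    repeat_identity_min: float = 0.8
    max_shorter_path: int | None = None
    max_cycles_per_bcc: int = 100_000
    max_mismatches: int = 2
    flank: int | None = None
    experiments: list[list[str]] = field(default_factory=list)  # file paths per condition
    output_prefix: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ConfigError(f"k must be odd and >= 3, got {self.k}")
        if self.min_kmer_coverage < 1:
            raise ConfigError("min_kmer_coverage must be >= 1")
        if self.indel_max_diff < 1 or self.max_cycles_per_bcc < 1:
            raise ConfigError("thresholds must be positive")
        if not (0 < self.repeat_identity_min <= 1):
            raise ConfigError("repeat_identity_min must lie in (0, 1]")


@dataclass
class RunResult:
    config: RunConfig
    events: list[EventCall]            # read-coherent, quantified calls
    snp_candidates: list               # SnpCandidate objects from stage 3
    discarded: list[EventCall]         # failed read coherence
    report: dict


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path) -> list[str]:
    """Load a FASTA or FASTQ file (optionally gzipped) as a list of strings.

    The format is sniffed from the first character; qualities are
    ignored.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if not first:
            return []
        fmt = "fastq" if first == "@" else "fasta"
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def _fasta_record(header: str, seq: str) -> str:
    return f">{header}\n{seq}\n"


def event_fasta_records(event: EventCall, bcc_id: int, cycle_id: int) -> str:
    """Two FASTA records per event: upper (longer) then lower (shorter) path.

    Header grammar:
    ``bcc<id>|cycle<id>|type<CLASS>|<upper|lower>_path|length<int>|cov_exp<j>:<float>``
    """
    out = []
    for role, which, ln in (
        ("upper", "long", event.bubble.len_long),
        ("lower", "short", event.bubble.len_short),
    ):
        cov = event.coverage[which] if event.coverage else None
        cov_bits = (
            "".join(
                f"|cov_exp{j + 1}:{mean:.2f}" for j, mean in enumerate(cov.mean_coverage)
            )
            if cov
            else ""
        )
        seq = cov.sequence if cov else (
            event.bubble.full_long if which == "long" else event.bubble.full_short
        )
        header = (
            f"bcc{bcc_id}|cycle{cycle_id}|type{event.event_class.value}"
            f"|{role}_path|length{ln}{cov_bits}"
        )
        out.append(_fasta_record(header, seq))
    return "".join(out)


def write_outputs(result: RunResult, prefix: str) -> None:
    """Write per-class FASTA files, the discarded-bubble log and a report."""
    by_class: dict[str, list[str]] = {c.value: [] for c in EventClass}
    for i, ev in enumerate(result.events):
        by_class[ev.event_class.value].append(
            event_fasta_records(ev, ev.bubble.bcc_id, i)
        )
    for cls, records in by_class.items():
        with open(f"{prefix}_{cls}.fa", "w") as fh:
            fh.writelines(records)
    with open(f"{prefix}_discarded.log", "w") as fh:
        for ev in result.discarded:
            fh.write(
                f"bcc{ev.bubble.bcc_id}\t{ev.event_class.value}\t"
                f"len {ev.bubble.len_short}/{ev.bubble.len_long}\tnot read-coherent\n"
            )
    with open(f"{prefix}_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig,
    reads_per_experiment: Sequence[Iterable[str]] | None = None,
) -> RunResult:
    """Execute all six stages and return classified, quantified events.

    ``reads_per_experiment`` may be given directly (lists of sequence
    strings, one list per condition); otherwise ``config.experiments``
    names the input files per condition.
    """
    config.validate()
    if reads_per_experiment is None:
        if not config.experiments:
            raise ConfigError("no input reads: set experiments or pass reads directly")
        reads_per_experiment = [
            [s for path in paths for s in read_sequences(path)]
            for paths in config.experiments
        ]
    reads_per_experiment = [list(r) for r in reads_per_experiment]

    k = config.k
    report: dict = {
        "k": k,
        "min_kmer_coverage": config.min_kmer_coverage,
        "n_experiments": len(reads_per_experiment),
        "n_reads": [len(r) for r in reads_per_experiment],
    }

    # stage 1: k-mer table -> bidirected graph -> unitig compression
    table = count_kmers(reads_per_experiment, k, min_coverage=config.min_kmer_coverage)
    report["n_kmers"] = len(table)
    if not table.counts:
        report.update(n_bcc=0, largest_bcc=0, aborted_bccs=0,
                      counts={c.value: 0 for c in EventClass}, n_discarded=0)
        return RunResult(config, [], [], [], report)
    graph = compress(build_graph(table))
    report["n_nodes"] = graph.n_nodes
    report["n_arcs"] = graph.n_arcs

    # stage 2: biconnected components
    components = bcc_mod.decompose(graph)
    report["n_bcc"] = len(components)
    report["largest_bcc"] = max((len(c.node_ids) for c in components), default=0)

    # stages 3-5
    snp_candidates = []
    calls: list[EventCall] = []
    aborted = 0
    for comp in components:
        reduced, cands = compress_four_node_bubbles(comp.graph, bcc_id=comp.id)
        snp_candidates.extend(cands)
        for cand in cands:
            calls.append(
                EventCall(
                    bubble=cand.bubble,
                    event_class=EventClass.SNP,
                    alignment_identity=1.0 - (1.0 / max(1, cand.bubble.len_short)),
                    length_difference=0,
                )
            )
        search = enumerate_bubbles(
            reduced,
            bcc_id=comp.id,
            max_shorter_path=config.max_shorter_path,
            max_cycles=config.max_cycles_per_bcc,
        )
        if search.aborted:
            aborted += 1
            logger.warning("BCC %d aborted after %d explored paths", comp.id, search.explored)
        for bub in search.bubbles:
            calls.append(
                classify(
                    bub,
                    k,
                    indel_max_diff=config.indel_max_diff,
                    repeat_identity_min=config.repeat_identity_min,
                )
            )
    report["aborted_bccs"] = aborted

    # stage 6: read coherence + coverage (shared read index)
    index = ReadIndex(reads_per_experiment, k)
    kept: list[EventCall] = []
    discarded: list[EventCall] = []
    for ev in calls:
        out = quantify_bubble(
            ev,
            max_mismatches=config.max_mismatches,
            flank=config.flank,
            index=index,
        )
        (kept if out is not None else discarded).append(ev)

    report["counts"] = {
        c.value: sum(1 for e in kept if e.event_class == c) for c in EventClass
    }
    report["n_discarded"] = len(discarded)
    result = RunResult(config, kept, snp_candidates, discarded, report)
    if config.output_prefix:
        write_outputs(result, config.output_prefix)
    return result
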