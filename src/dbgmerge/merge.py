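"""Redundancy removal, locus grouping and the end-to-end merge pipeline.

After threading, extension and the c1 filter, the surviving transcripts are
ranked by the number of graph nodes forming each transcript's path (more
nodes usually means longer, and empirically fewer translocations than
ranking by raw length).  Redundancy is then removed with a single greedy
pass over the ranking: "long" nodes — unitigs whose string exceeds the
length cutoff ``c2`` — are the unit of coverage, and a transcript is
retained only if it contributes at least one long node not covered by the
higher-ranked retained transcripts.  Retained transcripts sharing a long
node are grouped, transitively, into loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from dbgmerge.graph import CompactedGraph, build_graph
from dbgmerge.io_formats import SeqRecord, read_fasta
from dbgmerge.kmer import Params
from dbgmerge.threading import (
    ThreadingError,
    TranscriptPath,
    extend_ends,
    filter_by_avg_len,
    thread_transcript,
)

__all__ = [
    "RankedSelection",
    "Locus",
    "MergeReport",
    "long_nodes",
    "rank_transcripts",
    "remove_redundant",
    "group_loci",
    "summary_stats",
    "compute_n50",
    "merge_assemblies",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedSelection:
    """The ranked transcript list with retention flags after the greedy pass."""

    order: list[TranscriptPath]
    retained: list[bool]
    covered_long_nodes: set[int]

    def retained_transcripts(self) -> list[TranscriptPath]:
        return [tp for tp, keep in zip(self.order, self.retained) if keep]


@dataclass
class Locus:
    """A transitively-closed group of retained transcripts sharing long nodes."""

    id: int
    members: list[TranscriptPath]
    long_nodes: set[int]


@dataclass
class MergeReport:
    """Summary statistics of a merged transcriptome."""

    transcripts: int
    loci: int
    n50: int
    total_bases: int

    def as_tsv(self) -> str:
        head = "transcripts\tloci\tn50\ttotal_bases"
        row = f"{self.transcripts}\t{self.loci}\t{self.n50}\t{self.total_bases}"
        return head + "\n" + row + "\n"


def long_nodes(graph: CompactedGraph, tp: TranscriptPath, c2: int) -> set[int]:
    """Distinct path nodes whose string is strictly longer than ``c2``."""
    return {nid for nid in tp.distinct_nodes() if len(graph.nodes[nid].seq) > c2}


def _rank_key(tp: TranscriptPath) -> tuple:
    # node count desc, extended length desc, then id and sequence for full determinism
    return (-tp.node_count, -len(tp.extended_seq), tp.record.id, tp.extended_seq)


def rank_transcripts(tps: Iterable[TranscriptPath]) -> list[TranscriptPath]:
    """Sort transcripts by decreasing path node count.

    Ties break by extended length (longer first), then record id, then the
    sequence itself, so the ranking is invariant to input order.
    """
    return sorted(tps, key=_rank_key)


def remove_redundant(
    ranked: Sequence[TranscriptPath],
    long_node_map: Callable[[TranscriptPath], set[int]] | Sequence[set[int]],
    keep_nodeless: bool = False,
) -> RankedSelection:
    """Greedy single pass: retain a transcript iff it adds an uncovered long node.

    ``long_node_map`` is either a callable mapping a transcript to its set of
    long node ids, or a sequence/mapping indexed by position in ``ranked``.
    Coverage accumulates over *retained* transcripts only, so every long
    node of the input survives in some retained transcript.  Transcripts
    with no long node at all are dropped unless ``keep_nodeless`` is set.
    """
    covered: set[int] = set()
    flags: list[bool] = []
    for i, tp in enumerate(ranked):
        lns = long_node_map(tp) if callable(long_node_map) else long_node_map[i]
        if lns - covered:
            flags.append(True)
            covered |= lns
        elif not lns and keep_nodeless:
            flags.append(True)
        else:
            flags.append(False)
    return RankedSelection(order=list(ranked), retained=flags, covered_long_nodes=covered)


def group_loci(
    selection: RankedSelection,
    long_node_map: Callable[[TranscriptPath], set[int]],
) -> list[Locus]:
    """Partition retained transcripts into loci by transitive long-node sharing.

    Loci are the connected components of the graph whose vertices are the
    retained transcripts, with an edge whenever two share at least one long
    node.  Transcripts without long nodes form singleton loci.  Loci are
    numbered by the rank of their best member.
    """
    retained = selection.retained_transcripts()
    parent = list(range(len(retained)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    node_owner: dict[int, int] = {}
    ln_sets = [long_node_map(tp) for tp in retained]
    for i, lns in enumerate(ln_sets):
        for nid in lns:
            if nid in node_owner:
                union(node_owner[nid], i)
            else:
                node_owner[nid] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(retained)):
        groups.setdefault(find(i), []).append(i)

    loci = []
    for lid, root in enumerate(sorted(groups), start=1):
        members = [retained[i] for i in groups[root]]
        lns = set().union(*(ln_sets[i] for i in groups[root]))
        loci.append(Locus(id=lid, members=members, long_nodes=lns))
    return loci


def compute_n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that sequences of length >= L hold >= half the bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    return min(lengths)  # unreachable; defensive


def summary_stats(selection: RankedSelection, loci: Sequence[Locus]) -> MergeReport:
    """Transcript count, locus count, N50 and total bases of the retained set."""
    lengths = [len(tp.extended_seq) for tp in selection.retained_transcripts()]
    return MergeReport(
        transcripts=len(lengths),
        loci=len(loci),
        n50=compute_n50(lengths),
        total_bases=sum(lengths),
    )


def merge_assemblies(
    fasta_paths: Sequence[str | Path],
    params: Params | None = None,
    keep_nodeless: bool = False,
) -> tuple[list[SeqRecord], MergeReport]:
    """Run the full merge pipeline over per-library transcript FASTA files.

    Reads all transcripts, builds the compacted de Bruijn graph, threads and
    end-extends every transcript, applies the c1 filter, ranks, removes
    redundant transcripts via long-node coverage (c2), groups the survivors
    into loci and returns the merged records (named
    ``Locus_<L>_Transcript_<T>``) together with summary statistics.
    """
    params = params or Params()
    if not fasta_paths:
        raise ValueError("at least one input FASTA is required")
    records: list[SeqRecord] = []
    for path in fasta_paths:
        records.extend(read_fasta(path))
    logger.info("read %d transcripts from %d file(s)", len(records), len(fasta_paths))

    graph = build_graph(records, params)
    logger.info("graph: %d nodes, %d edges, %d k-mers", len(graph.nodes), len(graph.edges), graph.n_kmers)

    tps: list[TranscriptPath] = []
    skipped = 0
    for rec in records:
        try:
            tp = thread_transcript(graph, rec)
        except ThreadingError as exc:  # graph was built from these records; defensive
            raise RuntimeError(f"internal threading failure: {exc}") from exc
        if not tp.path:
            skipped += 1
            continue
        tps.append(extend_ends(graph, tp))
    if skipped:
        logger.warning("dropped %d transcript(s) shorter than k=%d (no valid k-mer)", skipped, params.k)

    kept = filter_by_avg_len(tps, params.c1)
    logger.info("c1 filter: %d of %d transcripts retained", len(kept), len(tps))

    ranked = rank_transcripts(kept)
    ln = lambda tp: long_nodes(graph, tp, params.c2)
    selection = remove_redundant(ranked, ln, keep_nodeless=keep_nodeless)
    loci = group_loci(selection, ln)
    report = summary_stats(selection, loci)
    logger.info(
        "retained %d transcripts in %d loci (N50=%d, %d bases)",
        report.transcripts, report.loci, report.n50, report.total_bases,
    )
    if report.transcripts == 0:
        logger.warning("no transcript retained; output will be empty")

    out: list[SeqRecord] = []
    for locus in loci:
        for t, tp in enumerate(locus.members, start=1):
            out.append(SeqRecord(id=f"Locus_{locus.id}_Transcript_{t}", seq=tp.extended_seq))
    return out, report
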