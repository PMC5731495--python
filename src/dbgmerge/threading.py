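"""Thread transcripts through the compacted graph and extend their ends.

Every input transcript corresponds to a walk in the de Bruijn graph built
from the full transcript set.  Threading recovers that walk as an ordered
list of (node id, orientation) steps by looking up each consecutive k-mer in
the graph's k-mer index and merging runs of contiguous offsets within one
node into a single step.

The first and last nodes of the walk may carry bases beyond the transcript's
entry and exit offsets; these are unambiguous extensions and are prepended/
appended to the transcript (never crossing a node boundary).  Finally the
average-length filter retains a transcript only when its extended length per
path node is strictly above the cutoff ``c1`` — short transcripts whose
paths wander through many tiny nodes are noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable

from dbgmerge.graph import CompactedGraph
from dbgmerge.io_formats import SeqRecord
from dbgmerge.kmer import canonical, reverse_complement

__all__ = [
    "TranscriptPath",
    "ThreadingError",
    "thread_transcript",
    "extend_ends",
    "filter_by_avg_len",
]

_VALID = frozenset("ACGT")


class ThreadingError(ValueError):
    """A k-mer of the transcript is missing from the graph (graph/input mismatch)."""


@dataclass
class _Anchor:
    """Where a terminal window of the transcript sits: node, orientation,
    offset within the node string, and position within the transcript."""

    node: int
    orient: str
    node_off: int
    seq_pos: int


@dataclass
class TranscriptPath:
    """A transcript with its oriented walk through compacted graph nodes."""

    record: SeqRecord
    path: list[tuple[int, str]]
    extended_seq: str
    entry: _Anchor | None = None
    exit: _Anchor | None = None

    @property
    def node_count(self) -> int:
        """Number of path steps (repeat traversals count separately)."""
        return len(self.path)

    @property
    def avg_len(self) -> Fraction:
        """Extended length per path node, the operand of the c1 filter."""
        return Fraction(len(self.extended_seq), self.node_count)

    def distinct_nodes(self) -> set[int]:
        return {nid for nid, _ in self.path}


def thread_transcript(graph: CompactedGraph, rec: SeqRecord) -> TranscriptPath:
    """Map a transcript to its oriented node path.

    Windows containing non-ACGT characters are skipped (they were never
    indexed); an ACGT window absent from the graph raises
    :class:`ThreadingError` naming the offending position, which signals
    that the graph was not built from a set containing this transcript.
    """
    k = graph.k
    seq = rec.seq
    path: list[tuple[int, str]] = []
    entry: _Anchor | None = None
    exit_: _Anchor | None = None
    prev: tuple[int, str, int] | None = None  # (node, orient, node_off)
    for pos in range(len(seq) - k + 1):
        w = seq[pos : pos + k]
        if not _VALID.issuperset(w):
            prev = None
            continue
        cw = canonical(w)
        hit = graph.kmer_index.get(cw)
        if hit is None:
            raise ThreadingError(
                f"transcript {rec.id!r}: {k}-mer at position {pos} not in graph"
            )
        nid, off, _ = hit
        node_seq = graph.nodes[nid].seq
        orient = "+" if node_seq[off : off + k] == w else "-"
        step = off + 1 if orient == "+" else off - 1
        if prev is not None and prev[0] == nid and prev[1] == orient and off == prev[2] + (1 if orient == "+" else -1):
            pass  # same contiguous traversal of the same node
        else:
            path.append((nid, orient))
        prev = (nid, orient, off)
        if entry is None:
            entry = _Anchor(nid, orient, off, pos)
        exit_ = _Anchor(nid, orient, off, pos)
    return TranscriptPath(record=rec, path=path, extended_seq=seq, entry=entry, exit=exit_)


def extend_ends(graph: CompactedGraph, tp: TranscriptPath) -> TranscriptPath:
    """Add the terminal nodes' leftover bases to the transcript ends.

    Only bases inside the first and last nodes of the walk are added; the
    extension never crosses an edge, even when the continuation would be
    unique.  Extending an already-extended path is a no-op.
    """
    if not tp.path or tp.entry is None or tp.exit is None:
        raise ValueError(f"transcript {tp.record.id!r} has an empty path")
    k = graph.k
    seq = tp.extended_seq
    entry, exit_ = tp.entry, tp.exit

    prefix = ""
    if entry.seq_pos == 0:
        node_seq = graph.nodes[entry.node].seq
        if entry.orient == "+":
            prefix = node_seq[: entry.node_off]
            new_entry = replace(entry, node_off=0, seq_pos=0)
        else:
            prefix = reverse_complement(node_seq[entry.node_off + k :])
            new_entry = replace(entry, node_off=len(node_seq) - k, seq_pos=0)
    else:
        new_entry = entry

    suffix = ""
    if exit_.seq_pos + k == len(seq):
        node_seq = graph.nodes[exit_.node].seq
        if exit_.orient == "+":
            suffix = node_seq[exit_.node_off + k :]
            new_exit = replace(exit_, node_off=len(node_seq) - k)
        else:
            suffix = reverse_complement(node_seq[: exit_.node_off])
            new_exit = replace(exit_, node_off=0)
    else:
        new_exit = exit_

    extended = prefix + seq + suffix
    new_exit = replace(new_exit, seq_pos=len(prefix) + exit_.seq_pos + len(suffix))
    return TranscriptPath(
        record=tp.record,
        path=list(tp.path),
        extended_seq=extended,
        entry=new_entry,
        exit=new_exit,
    )


def filter_by_avg_len(tps: Iterable[TranscriptPath], c1: float) -> list[TranscriptPath]:
    """Retain transcripts whose extended length / path node count is > ``c1``.

    The comparison is strict: a ratio exactly equal to ``c1`` is removed.
    """
    return [tp for tp in tps if tp.avg_len > c1]
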