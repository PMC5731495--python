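"""Bidirected de Bruijn graph construction and unitig compaction.

Vertices are the canonical k-mers of the input transcripts.  A directed edge
joins two k-mers when the (k-1)-suffix of the first equals the (k-1)-prefix
of the second *and* the implied (k+1)-mer is itself observed in the
transcripts; the second condition rejects chimeric junctions that arise from
k-mer sharing alone.  Maximal non-branching linear paths are collapsed into
single nodes (unitigs), each stored once as the canonical form of its
spelled string.  Walks through the graph carry an orientation per node.

Compaction never merges through a palindromic k-mer (its two orientations
coincide, making the walk direction ambiguous) nor through a self-loop; both
terminate unitigs, which is the standard safe rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from dbgmerge.io_formats import SeqRecord
from dbgmerge.kmer import KmerSet, Params, canonical, enumerate_kmers, reverse_complement

__all__ = [
    "Node",
    "CompactedGraph",
    "EmptyGraphError",
    "build_graph",
    "node_degree",
    "write_gfa",
]

_BASES = "ACGT"

Orientation = Literal["+", "-"]


class EmptyGraphError(ValueError):
    """No input transcript is long enough to contribute a single k-mer."""


@dataclass
class Node:
    """A unitig: a maximal non-branching path collapsed to one string.

    ``seq`` is the canonical form (lexicographic minimum of the spelled
    string and its reverse complement); a node and its reverse complement
    are the same node.
    """

    id: int
    seq: str
    k: int

    @property
    def kmer_count(self) -> int:
        """Number of constituent k-mers (== len(seq) - k + 1)."""
        return len(self.seq) - self.k + 1

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CompactedGraph:
    """Compacted bidirected de Bruijn graph.

    Attributes
    ----------
    k:
        k-mer length.
    nodes:
        node id -> :class:`Node`; ids are assigned in sorted order of the
        canonical node strings, so the graph is deterministic in the input
        *set* regardless of record order.
    edges:
        set of bidirected edges, each stored once in a canonical tuple form
        ``((u, ou), (v, ov))``.
    kmer_index:
        canonical k-mer -> ``(node id, offset, orientation)``: the node
        string spells the k-mer at ``offset`` forward (``+``) or
        reverse-complemented (``-``).
    adjacency:
        oriented adjacency ``(node id, orientation) -> list of
        (node id, orientation)`` successors.
    """

    k: int
    nodes: dict[int, Node]
    edges: set[tuple[tuple[int, str], tuple[int, str]]]
    kmer_index: dict[str, tuple[int, int, str]]
    adjacency: dict[tuple[int, str], list[tuple[int, str]]] = field(default_factory=dict)

    @property
    def n_kmers(self) -> int:
        return len(self.kmer_index)

    def node_seqs(self) -> list[str]:
        return [self.nodes[i].seq for i in sorted(self.nodes)]

    def oriented_seq(self, node_id: int, orient: str) -> str:
        seq = self.nodes[node_id].seq
        return seq if orient == "+" else reverse_complement(seq)


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


class _KmerDBG:
    """Uncompacted view: oriented successor/predecessor queries on k-mer sets."""

    def __init__(self, kset: KmerSet, k1set: KmerSet):
        self.kset = kset
        self.k1set = k1set

    def successors(self, oriented: str) -> list[str]:
        suffix = oriented[1:]
        out = []
        for b in _BASES:
            if canonical(suffix + b) in self.kset and canonical(oriented + b) in self.k1set:
                out.append(suffix + b)
        return out

    def predecessors(self, oriented: str) -> list[str]:
        prefix = oriented[:-1]
        out = []
        for b in _BASES:
            if canonical(b + prefix) in self.kset and canonical(b + oriented) in self.k1set:
                out.append(b + prefix)
        return out


def _is_palindrome(kmer: str) -> bool:
    return kmer == reverse_complement(kmer)


def _forward_link(dbg: _KmerDBG, oriented: str) -> str | None:
    """Unique mutual successor of an oriented k-mer, or None at a junction.

    The link exists when ``oriented`` has exactly one successor ``t``, ``t``
    has exactly one predecessor (necessarily ``oriented``), neither end is a
    palindrome, and the link is not a self-loop or hairpin.
    """
    if _is_palindrome(oriented):
        return None
    succ = dbg.successors(oriented)
    if len(succ) != 1:
        return None
    t = succ[0]
    if _is_palindrome(t) or canonical(t) == canonical(oriented):
        return None
    if len(dbg.predecessors(t)) != 1:
        return None
    return t


def _build_unitigs(kset: KmerSet, k1set: KmerSet) -> list[str]:
    """Partition the canonical k-mers into maximal non-branching paths."""
    dbg = _KmerDBG(kset, k1set)
    used: set[str] = set()
    unitigs: list[str] = []
    for start in sorted(kset.counts):
        if start in used:
            continue
        chain = [start]
        in_chain = {start}
        # walk backward from the seed's forward orientation
        cur = start
        while True:
            succ_back = None
            pred = dbg.predecessors(cur)
            # mutual-unique backward link mirrors _forward_link
            if not _is_palindrome(cur) and len(pred) == 1:
                p = pred[0]
                if (
                    not _is_palindrome(p)
                    and canonical(p) != canonical(cur)
                    and len(dbg.successors(p)) == 1
                ):
                    succ_back = p
            if succ_back is None or canonical(succ_back) in in_chain:
                break
            chain.insert(0, succ_back)
            in_chain.add(canonical(succ_back))
            cur = succ_back
        # walk forward from the seed
        cur = start
        while True:
            nxt = _forward_link(dbg, cur)
            if nxt is None or canonical(nxt) in in_chain:
                break
            chain.append(nxt)
            in_chain.add(canonical(nxt))
            cur = nxt
        used.update(canonical(x) for x in chain)
        seq = chain[0] + "".join(x[-1] for x in chain[1:])
        unitigs.append(min(seq, reverse_complement(seq)))
    return unitigs


def build_graph(transcripts: Sequence[SeqRecord], params: Params) -> CompactedGraph:
    """Build the compacted bidirected de Bruijn graph of a transcript set.

    The vertex set is the canonical ``k``-mer set of the transcripts and the
    edge set obeys the (k+1)-mer validation rule; the coverage cutoff
    ``params.c`` is applied uniformly to both (it defaults to 1 at merge
    time, i.e. no filtering).

    Raises
    ------
    EmptyGraphError
        If no transcript contributes a valid k-mer.
    """
    k = params.k
    seqs = [t.seq for t in transcripts]
    kset = enumerate_kmers(seqs, k, params.c)
    if kset.n == 0:
        raise EmptyGraphError(
            f"no transcript yields a valid {k}-mer (need length >= {k} without N)"
        )
    k1set = enumerate_kmers(seqs, k + 1, params.c)
    unitigs = _build_unitigs(kset, k1set)

    nodes: dict[int, Node] = {}
    kmer_index: dict[str, tuple[int, int, str]] = {}
    for nid, seq in enumerate(sorted(unitigs)):
        nodes[nid] = Node(id=nid, seq=seq, k=k)
        for off in range(len(seq) - k + 1):
            w = seq[off : off + k]
            cw = canonical(w)
            kmer_index[cw] = (nid, off, "+" if w == cw else "-")

    dbg = _KmerDBG(kset, k1set)
    adjacency: dict[tuple[int, str], list[tuple[int, str]]] = {}
    edges: set[tuple[tuple[int, str], tuple[int, str]]] = set()
    for nid, node in nodes.items():
        for orient in "+-":
            oseq = node.seq if orient == "+" else reverse_complement(node.seq)
            targets = []
            for t in dbg.successors(oseq[-k:]):
                tn, toff, torient = kmer_index[canonical(t)]
                # entering the neighbour forward if t is spelled forward there
                tnode_seq = nodes[tn].seq
                if tnode_seq[toff : toff + k] == t:
                    targets.append((tn, "+"))
                else:
                    targets.append((tn, "-"))
            targets = sorted(set(targets))
            adjacency[(nid, orient)] = targets
            for tgt in targets:
                e = ((nid, orient), tgt)
                rev = ((tgt[0], _flip(tgt[1])), (nid, _flip(orient)))
                edges.add(min(e, rev))
    return CompactedGraph(k=k, nodes=nodes, edges=edges, kmer_index=kmer_index, adjacency=adjacency)


def node_degree(graph: CompactedGraph, node_id: int, side: str) -> int:
    """Number of distinct oriented edges attached at one side of a node.

    ``side="right"`` counts edges leaving the node read forward;
    ``side="left"`` counts edges leaving it read reverse-complemented.
    """
    if node_id not in graph.nodes:
        raise KeyError(f"unknown node id {node_id}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    orient = "+" if side == "right" else "-"
    return len(graph.adjacency.get((node_id, orient), []))


def write_gfa(graph: CompactedGraph, path: str | Path) -> None:
    """Dump the compacted graph as GFA1 (S-lines, L-lines with k-1 overlaps)."""
    ov = graph.k - 1
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes):
            fh.write(f"S\t{nid}\t{graph.nodes[nid].seq}\n")
        for (u, ou), (v, ovr) in sorted(graph.edges):
            fh.write(f"L\t{u}\t{ou}\t{v}\t{ovr}\t{ov}M\n")
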