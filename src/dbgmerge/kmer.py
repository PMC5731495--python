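"""Canonical k-mer enumeration over transcript sequences.

The de Bruijn graph is strand-free: a k-mer and its reverse complement are
the same vertex, represented by the lexicographically smaller of the two
(the *canonical* form).  Counts accumulate one per window, regardless of the
orientation the window happens to be observed in, so enumerating a sequence
set and its reverse complement gives identical results.

Two enumeration pathways are provided: direct sliding-window counting
(:func:`enumerate_kmers`) and iterative one-letter extension from shorter
k-mers (:func:`extend_kmers`), which reproduces direct enumeration exactly
when the coverage cutoff is 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Params",
    "KmerSet",
    "reverse_complement",
    "canonical",
    "enumerate_kmers",
    "extend_kmers",
]

_COMP = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class Params:
    """Tuning parameters of the merge pipeline.

    Attributes
    ----------
    k:
        k-mer length of the de Bruijn graph (default 25).
    c:
        k-mer coverage cutoff; k-mers seen fewer than ``c`` times are
        dropped.  Coverage filtering belongs to the upstream per-library
        assemblies, so the merge step defaults to ``c=1`` (no filtering).
    c1:
        average length cutoff: a transcript is retained only if its extended
        length divided by the number of nodes in its graph path is strictly
        above ``c1`` (default 25).
    c2:
        node length cutoff: a compacted node is "long" when its string is
        strictly longer than ``c2`` bases (default 50).  Long nodes are the
        unit of redundancy removal and locus grouping.
    """

    k: int = 25
    c: int = 1
    c1: float = 25.0
    c2: int = 50

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        if self.c1 < 0:
            raise ValueError(f"c1 must be >= 0, got {self.c1}")
        if self.c2 < 1:
            raise ValueError(f"c2 must be >= 1, got {self.c2}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Return the lexicographic minimum of ``kmer`` and its reverse complement."""
    if not _VALID.issuperset(kmer):
        bad = sorted(set(kmer) - _VALID)
        raise ValueError(f"non-ACGT character(s) {bad} in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerSet:
    """Canonical k-mers of a sequence set, with occurrence counts.

    Every key has length ``k``, contains only ACGT and is canonical; counts
    total the occurrences over both orientations of all input sequences
    (a window equal to its own reverse complement counts once).
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        """Number of distinct canonical k-mers."""
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


def _valid_windows(seq: str, k: int) -> Iterator[str]:
    """Yield the length-k windows of ``seq`` that contain only ACGT.

    Windows containing N (or any other ambiguity code) are skipped whole.
    """
    if len(seq) < k:
        return
    # Track the most recent invalid position to skip N windows in one pass.
    last_bad = -1
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            yield seq[i - k + 1 : i + 1]


def enumerate_kmers(seqs: Iterable[str], k: int, c: int = 1) -> KmerSet:
    """Count all canonical k-mers of ``seqs``, keeping those seen >= ``c`` times."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts: Counter[str] = Counter()
    for seq in seqs:
        for window in _valid_windows(seq, k):
            counts[canonical(window)] += 1
    if c > 1:
        counts = Counter({kmer: n for kmer, n in counts.items() if n >= c})
    return KmerSet(k=k, counts=dict(counts))


def extend_kmers(kset: KmerSet, seqs: Iterable[str]) -> KmerSet:
    """Grow a k'-mer set to the (k'+1)-mers of ``seqs`` by one-letter extension.

    A (k'+1)-mer of ``seqs`` is kept exactly when its k'-prefix, in either
    orientation, survives in ``kset``.  With a coverage cutoff of 1 the
    iteration from k'=2 upward reproduces direct enumeration at every step.
    """
    k1 = kset.k + 1
    counts: Counter[str] = Counter()
    for seq in seqs:
        for window in _valid_windows(seq, k1):
            # prefix in forward orientation, or in the reverse-complement
            # orientation (where the prefix is the rc of the window's suffix)
            if canonical(window[:-1]) in kset or canonical(window[1:]) in kset:
                counts[canonical(window)] += 1
    return KmerSet(k=k1, counts=dict(counts))
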