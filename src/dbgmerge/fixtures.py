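"""Synthetic transcript sets and reads with planned redundancy structure.

Real inputs to the merge step are per-library assemblies of the same
underlying transcriptome, so copies of a transcript recur across libraries,
often truncated at the ends and occasionally carrying base errors.  The
generators here emulate exactly that: a planted "true" transcript set
(optionally with pairs sharing a long common block, to exercise locus
grouping), library files holding full and truncated/mutated copies, and
uniform-coverage reads with synthetic quality strings for the trimming
utility.  Everything is a pure function of its inputs and the seed, and a
JSON manifest records the ground truth for recovery scoring.

Noise is substitution-only; there is no expression model or splice isoform
generator — these fixtures test the merging machinery, not read simulators.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from dbgmerge.io_formats import SeqRecord, write_fasta

__all__ = [
    "FixtureSpec",
    "make_true_set",
    "make_library_assemblies",
    "make_reads",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic merge scenario.

    ``shared_block_len``/``shared_pair_frac`` plant identical blocks into
    pairs of true transcripts so that they end up sharing a long node
    (keep the block longer than the ``c2`` cutoff in use, default 60 > 50).
    """

    seed: int = 0
    n_true: int = 50
    length_range: tuple[int, int] = (300, 1200)
    n_libraries: int = 3
    truncation_rate: float = 0.3
    duplicate_rate: float = 0.5
    snp_rate: float = 0.0
    shared_block_len: int = 60
    shared_pair_frac: float = 0.2

    def __post_init__(self) -> None:
        for name in ("truncation_rate", "duplicate_rate", "snp_rate", "shared_pair_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_libraries < 1:
            raise ValueError("need at least one library")


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def make_true_set(spec: FixtureSpec) -> list[SeqRecord]:
    """Generate the planted true transcripts, deterministically from the seed."""
    rng = random.Random(spec.seed)
    records = [
        SeqRecord(id=f"true_{i:04d}", seq=_random_seq(rng, rng.randint(*spec.length_range)))
        for i in range(spec.n_true)
    ]
    # plant shared blocks into disjoint consecutive pairs
    n_pairs = int(spec.shared_pair_frac * spec.n_true / 2)
    for p in range(n_pairs):
        a, b = records[2 * p], records[2 * p + 1]
        if min(len(a.seq), len(b.seq)) <= spec.shared_block_len:
            continue
        block = _random_seq(rng, spec.shared_block_len)
        for rec in (a, b):
            pos = rng.randint(0, len(rec.seq) - spec.shared_block_len)
            rec.seq = rec.seq[:pos] + block + rec.seq[pos + spec.shared_block_len :]
    return records


def _truncate(rng: random.Random, seq: str, min_keep: int = 50) -> str:
    """Cut random amounts off both ends, keeping at least ``min_keep`` bases."""
    if len(seq) <= min_keep:
        return seq
    max_cut = len(seq) - min_keep
    left = rng.randint(0, max_cut)
    right = rng.randint(0, max_cut - left)
    return seq[left : len(seq) - right]


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in _BASES if x != b])
    return "".join(out)


def make_library_assemblies(
    truth: Sequence[SeqRecord],
    spec: FixtureSpec,
    out_dir: str | Path,
) -> list[Path]:
    """Write per-library FASTA files emulating independent assemblies.

    Every true transcript appears full length in one "home" library (an
    independent assembly of the library it was expressed in); copies land in
    each other library with probability ``duplicate_rate``, truncated with
    probability ``truncation_rate`` and mutated at ``snp_rate`` per base.
    A ``manifest.json`` in ``out_dir`` records the ground truth.
    """
    if not truth:
        raise ValueError("truth set is empty")
    rng = random.Random(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    libraries: list[list[SeqRecord]] = [[] for _ in range(spec.n_libraries)]
    manifest: dict = {
        "spec": {**asdict(spec), "length_range": list(spec.length_range)},
        "truth": {rec.id: len(rec.seq) for rec in truth},
        "copies": [],
    }
    for rec in truth:
        home = rng.randrange(spec.n_libraries)
        libraries[home].append(SeqRecord(id=rec.id, seq=rec.seq))
        manifest["copies"].append({"truth": rec.id, "library": home, "kind": "full"})
        for lib in range(spec.n_libraries):
            if lib == home or rng.random() >= spec.duplicate_rate:
                continue
            seq = rec.seq
            kind = "full"
            if rng.random() < spec.truncation_rate:
                seq = _truncate(rng, seq)
                kind = "truncated"
            seq = _mutate(rng, seq, spec.snp_rate)
            copy_id = f"{rec.id}_lib{lib}"
            libraries[lib].append(SeqRecord(id=copy_id, seq=seq))
            manifest["copies"].append({"truth": rec.id, "library": lib, "kind": kind})
    paths = []
    for i, recs in enumerate(libraries):
        path = out_dir / f"library_{i}.fasta"
        write_fasta(recs, path)
        paths.append(path)
    write_fasta(truth, out_dir / "truth.fasta")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def make_reads(
    truth: Sequence[SeqRecord],
    read_len: int,
    depth: float,
    seed: int,
    base_quality: int = 40,
    low_tail_rate: float = 0.2,
    tail_quality: int = 2,
) -> list[SeqRecord]:
    """Simulate uniform-coverage single-end reads with synthetic qualities.

    A fraction ``low_tail_rate`` of reads gets a low-quality tail (quality
    ``tail_quality`` from a random position onward), the planted trigger for
    the quality-trimming rule.
    """
    if truth and read_len > min(len(r.seq) for r in truth):
        raise ValueError("read_len exceeds the shortest transcript")
    rng = random.Random(seed)
    reads: list[SeqRecord] = []
    for rec in truth:
        n_reads = math.ceil(len(rec.seq) * depth / read_len) if depth > 0 else 0
        for j in range(n_reads):
            start = rng.randint(0, len(rec.seq) - read_len)
            seq = rec.seq[start : start + read_len]
            qual = [base_quality] * read_len
            if rng.random() < low_tail_rate:
                p = rng.randint(1, read_len - 1)
                qual[p:] = [tail_quality] * (read_len - p)
            reads.append(SeqRecord(id=f"{rec.id}_read{j}", seq=seq, qual=qual))
    return reads
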