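"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive and self-contained (its own reverse
complement, its own canonicalisation, no imports from dbgmerge) so that
agreement with the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from collections import Counter

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def canon(kmer: str) -> str:
    r = rc(kmer)
    return kmer if kmer <= r else r


def sliding_window_counts(seqs, k, c=1):
    """Naive canonical k-mer counter: every ACGT window, canonicalised."""
    counts = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                counts[canon(w)] += 1
    return {k_: v for k_, v in counts.items() if v >= c}


def greedy_retention(long_node_sets, keep_nodeless=False):
    """Re-simulation of the greedy redundancy rule on ranked long-node sets."""
    covered = set()
    flags = []
    for lns in long_node_sets:
        if set(lns) - covered:
            flags.append(True)
            covered |= set(lns)
        elif not lns and keep_nodeless:
            flags.append(True)
        else:
            flags.append(False)
    return flags


def pairwise_components(items, share):
    """Connected components by exhaustive pairwise testing + union-find.

    ``share(a, b)`` says whether two items are linked; transitive closure is
    taken over all pairs.
    """
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if share(items[i], items[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(frozenset(c) for c in comps.values())


def cumulative_n50(lengths):
    """N50 by explicit cumulative sum over the sorted lengths."""
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
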