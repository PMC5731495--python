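# Methods

## Model

`dbgmerge` treats a collection of per-library transcript sets as redundant
samples of one underlying transcriptome and reduces them on a bidirected
de Bruijn graph.

**Vertices.** The canonical k-mers of all input transcripts. A k-mer and
its reverse complement are one vertex, represented by the lexicographically
smaller string; counts accumulate once per sequence window regardless of
orientation, and a window equal to its own reverse complement counts once
(palindromes are not double-counted). Windows containing `N` are skipped
whole: ambiguity codes cannot index the graph.

**Edges.** A directed edge joins k-mers `s₁…s_k → s₂…s_{k+1}` when the
(k−1)-overlap matches *and* the (k+1)-mer `s₁…s_{k+1}` occurs in the
transcripts. The second condition is what distinguishes the graph from a
pure overlap graph: two transcripts that merely share a k−1 word are not
connected. When the coverage cutoff *c* is raised above 1 it is applied
uniformly to the k-mer and (k+1)-mer sets, so edges whose support falls
below *c* disappear along with their vertices.

**Compaction.** Maximal non-branching paths collapse into unitigs. A link
between consecutive k-mers is compacted only when it is *mutual-unique*
(out-degree 1 meets in-degree 1) and neither endpoint is a palindromic
k-mer or a self-loop/hairpin; palindromes make the walk direction
ambiguous, so they terminate unitigs — the standard safe rule. Isolated
cycles are broken deterministically at their lexicographically smallest
canonical k-mer. Each unitig is stored once in canonical form, and node
ids are assigned in sorted order of the node strings, which together with
the tie-break rules below makes every output byte-deterministic in the
input *set*, independent of file and record order.

The k-mer sets can be built either by direct sliding-window counting or by
iterative one-letter extension from 2-mers upward; with *c* = 1 the two are
provably identical at every length, and the test suite asserts the exact
equality. The package uses hash maps rather than any particular sorted
array layout: the operation contracts, not the storage strategy, are the
semantics.

## Transcript selection

Each transcript is threaded through the graph as an ordered list of
(node, orientation) steps; consecutive k-mers at contiguous offsets within
one node merge into a single step, and a transcript that revisits a node
counts each traversal separately (the path, not the node set, is what the
c₁ ratio divides by). Bases of the first and last node outside the
transcript's entry/exit offsets are unambiguous and are prepended/appended;
extension never crosses a node boundary, even when the continuation is
unique — crossing would commit to a junction the transcript itself does not
witness. Extension is idempotent.

The c₁ filter keeps a transcript iff extended length / path-node count is
**strictly** above c₁ (a ratio of exactly c₁ is removed); the ratio uses
the post-extension length, matching the order in which the two operations
are defined. Ranking is by path node count descending — preferring
transcripts assembled from more graph evidence over raw length, which
empirically favours long transcripts while penalising translocated
chimeras — with deterministic tie-breaks: extended length descending, then
record id, then the sequence itself (ids are only unique per input file,
so the final tie-break guarantees order-invariance even with identically
named records in different libraries).

Redundancy removal is one greedy pass down the ranking with *long nodes*
(node string strictly longer than c₂) as the coverage currency: a
transcript is kept iff it contributes at least one long node not covered by
the *kept* higher-ranked transcripts. Accounting coverage over kept
transcripts only (rather than all higher-ranked ones) guarantees that every
long node of the input survives in some output transcript; the alternative
would let a discarded transcript shadow sequence that then appears nowhere.
Transcripts with no long node at all cannot satisfy the rule and are
dropped by default; `--keep-nodeless` retains them as singleton loci for
short-transcript use cases. Loci are the connected components of the
"shares a long node" relation on the retained set, numbered by the rank of
their best member.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| k    | k-mer length (bases) | 25 | must match the scale of the upstream assemblies |
| c    | k-mer coverage cutoff (occurrences) | 1 | coverage filtering belongs upstream; >1 prunes both vertices and edges |
| c₁   | average length cutoff (bases per path node) | 25 | strict comparison |
| c₂   | long-node length cutoff (bases) | 50 | strict comparison |
| quality threshold | Phred score below which a read is cut | 15 | Phred+33 assumed; `--phred64` available |

## Synthetic data

The fixture generator emulates what the merge step actually receives:
a planted "true" transcript set (uniform random sequence, 300–1200 bp by
default, optionally with pairs sharing an identical block longer than c₂
so that they fall into one locus), split across libraries so that every
transcript appears full-length in one home library while extra copies land
elsewhere with configurable duplication, end-truncation and per-base
substitution rates. Reads for the trimming utility carry synthetic quality
strings with planted low-quality tails. All generators are pure functions
of their seed.

What the generator does **not** model: expression levels, splice isoforms,
indels (substitution-only noise keeps the k-mer-sharing structure
analysable; an indel mode is deliberately out of scope), sequencing-error
profiles, and the biased, repeat-rich composition of real transcriptomes.
Passing tests therefore demonstrate the correctness of the merging
machinery — exact k-mer accounting, sound compaction, the stated selection
and grouping rules, determinism — not assembly quality on real data, which
depends on the upstream assemblers.

Test and acceptance problem sizes (up to 200 sequences × 500 bp per random
set, 50 planted transcripts end-to-end) were chosen so the whole suite runs
in well under a minute of pure-Python time per property; the iterative
one-letter-extension equivalence, whose cost grows with k passes over every
set, is checked on a third of the random sets with the same size
distribution.

## Numerical and degenerate-input choices

- Strict inequalities everywhere the contracts say "above"; boundaries are
  tested explicitly.
- The c₁ ratio is computed as an exact rational, so a ratio equal to the
  cutoff can never leak through floating-point rounding.
- Transcripts shorter than k (or with no N-free window) cannot thread and
  are dropped with a logged warning; an input in which *no* transcript
  reaches k raises an error rather than emitting an empty graph silently.
- Reads trimmed to length zero are dropped from FASTQ output by default
  (`--keep-empty` retains them); `--min-len` defaults to 0.
- `U` is mapped to `T` and sequences are uppercased on input, so RNA-style
  FASTA files merge correctly.

## Limitations

- The whole graph and all transcripts are held in memory in pure Python;
  the package is built for correctness and moderate inputs, not for
  hundred-gigabase k-mer tables (no disk-backed or probabilistic counting,
  single-threaded by design).
- No graph simplification beyond compaction: tips and bubbles are assumed
  to have been handled by the upstream assemblers.
- Selection is purely structural; there is no expression-based scoring,
  ORF assessment, or reference-based validation.
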