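# dbgmerge

Merge many small *de novo* transcriptome assemblies into one large,
low-redundancy transcriptome.

Assembling a deep RNA-Seq experiment in one shot can need hundreds of
gigabytes of memory. A divide-and-conquer alternative assembles each
sequencing library independently — cheap, and embarrassingly parallel — and
then merges the per-library transcript sets. The merge is the hard part:
the same transcript recurs across libraries, often truncated or slightly
different, and naive concatenation produces a hugely redundant
transcriptome. `dbgmerge` implements that merging step for users of any
upstream assembler (Oases, Trinity, SOAPdenovo-Trans, Trans-ABySS, ...):
the inputs are plain transcript FASTA files, one per library.

## Algorithm

Given transcript sets *T₁ … T_m* and a k-mer length *k* (default 25):

1. **Graph.** Build a bidirected de Bruijn graph over the canonical k-mers
   of ⋃*Tᵢ*. An edge joins two k-mers when they overlap by *k*−1 letters
   **and** the implied (*k*+1)-mer occurs in the transcripts. Maximal
   non-branching paths are compacted into single nodes (unitigs). A k-mer
   coverage cutoff *c* is available but defaults to 1: coverage filtering
   belongs to the per-library assemblies, not the merge.
2. **Threading & extension.** Each transcript corresponds to an oriented
   path of nodes. Leftover bases of the first and last node form an
   unambiguous extension and are added to the transcript.
3. **Filter (c₁).** Retain a transcript only if extended length / number of
   path nodes > *c₁* (default 25); short transcripts wandering through many
   tiny nodes are noise.
4. **Rank & de-duplicate (c₂).** Rank transcripts by decreasing path node
   count (a proxy for length that is more robust to translocated
   chimeras). Call a node *long* if its string exceeds *c₂* (default 50).
   In a single greedy pass, keep a transcript only if it contains a long
   node not yet covered by the higher-ranked kept transcripts.
5. **Loci.** Group retained transcripts that share at least one long node,
   transitively, into loci — an approximation of genes — and emit records
   named `Locus_<L>_Transcript_<T>` plus a summary report
   (transcript count, locus count, N50, total bases).

A read quality-trimming utility is included (`trim`): each read is cut
immediately before its first base with Phred quality < 15.

## Worked example

Generate a small synthetic scenario — 8 planted transcripts scattered over
3 "library assemblies" with truncated duplicate copies — and merge it:

```sh
$ dbgmerge fixtures -o demo --seed 7 --n-true 8 --libraries 3
$ dbgmerge --log-level warning merge demo/library_*.fasta \
      -o demo/merged.fasta --report demo/report.tsv
transcripts	loci	n50	total_bases
8	8	1087	6689
```

The three libraries hold 17 records in total (5 + 7 + 5: every planted
transcript once in full, plus redundant truncated copies). The merge
collapses them back to exactly the 8 planted transcripts — redundant copies
thread through already-covered long nodes and are removed — in 8
single-transcript loci, with an N50 of 1087 bp over 6689 output bases.
Output records are named by locus:

```
>Locus_1_Transcript_1
```

The same pipeline is available as a library:

```python
from dbgmerge import Params, merge_assemblies
records, report = merge_assemblies(["lib1.fa", "lib2.fa"], Params(k=25, c1=25, c2=50))
```

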