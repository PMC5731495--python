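import random

import pytest

from _oracles import cumulative_n50, greedy_retention, pairwise_components
from conftest import random_seq
from dbgmerge.fixtures import FixtureSpec, make_library_assemblies, make_true_set
from dbgmerge.graph import build_graph
from dbgmerge.io_formats import SeqRecord, read_fasta, write_fasta
from dbgmerge.kmer import Params, reverse_complement
from dbgmerge.merge import (
    compute_n50,
    group_loci,
    long_nodes,
    merge_assemblies,
    rank_transcripts,
    remove_redundant,
    summary_stats,
)
from dbgmerge.threading import TranscriptPath, thread_transcript


def tp_stub(ident, length, nodes):
    return TranscriptPath(
        record=SeqRecord(ident, "A" * length),
        path=[(n, "+") for n in nodes],
        extended_seq="A" * length,
    )


class TestLongNodes:
    @pytest.mark.parametrize("node_len, c2, included", [(51, 50, True), (50, 50, False), (15, 0, True)])
    def test_strict_boundary(self, node_len, c2, included):
        # find a sequence that compacts to a single node of exactly node_len
        # (k large enough that k-mer repeats within ~50 bases are unlikely)
        for seed in range(100):
            seq = random_seq(random.Random(seed), node_len)
            rec = SeqRecord("t", seq)
            g = build_graph([rec], Params(k=15, c1=0, c2=1))
            if len(g.nodes) == 1 and len(g.nodes[0].seq) == node_len:
                break
        else:
            pytest.fail("no single-node sequence found")
        tp = thread_transcript(g, rec)
        lns = long_nodes(g, tp, c2)
        assert (0 in lns) is included


class TestRanking:
    def test_node_count_descending(self):
        tps = [tp_stub("a", 50, [1, 2, 3]), tp_stub("b", 50, [1, 2, 3, 4, 5]), tp_stub("c", 50, [1])]
        assert [t.record.id for t in rank_transcripts(tps)] == ["b", "a", "c"]

    def test_tie_break_by_length_then_id(self):
        tps = [tp_stub("a", 100, [1, 2]), tp_stub("b", 200, [3, 4]), tp_stub("c", 200, [5, 6])]
        assert [t.record.id for t in rank_transcripts(tps)] == ["b", "c", "a"]

    def test_permutation_invariance(self, rng):
        tps = [tp_stub(f"t{i}", rng.randint(30, 300), list(range(rng.randint(1, 6)))) for i in range(20)]
        expected = [t.record.id for t in rank_transcripts(tps)]
        for _ in range(5):
            rng.shuffle(tps)
            assert [t.record.id for t in rank_transcripts(tps)] == expected


class TestRemoveRedundant:
    def test_exact_duplicates_collapse(self):
        a, b = tp_stub("a", 100, [1]), tp_stub("b", 100, [1])
        sel = remove_redundant([a, b], [{1}, {1}])
        assert sel.retained == [True, False]

    def test_subset_removed(self):
        a, b = tp_stub("a", 200, [1, 2, 3]), tp_stub("b", 100, [2])
        sel = remove_redundant([a, b], [{1, 2, 3}, {2}])
        assert sel.retained == [True, False]
        assert sel.covered_long_nodes == {1, 2, 3}

    def test_nodeless_dropped_unless_flagged(self):
        a = tp_stub("a", 100, [1])
        sel = remove_redundant([a], [set()])
        assert sel.retained == [False]
        sel = remove_redundant([a], [set()], keep_nodeless=True)
        assert sel.retained == [True]

    def test_matches_greedy_oracle(self, rng):
        for _ in range(50):
            n = rng.randint(1, 25)
            ln_sets = [set(rng.sample(range(12), rng.randint(0, 4))) for _ in range(n)]
            ranked = [tp_stub(f"t{i}", 100, [0]) for i in range(n)]
            sel = remove_redundant(ranked, ln_sets)
            assert sel.retained == greedy_retention(ln_sets)

    def test_no_retained_set_fully_covered_by_higher_ranks(self, rng):
        # direct assertion of the retention rule
        n = 30
        ln_sets = [set(rng.sample(range(15), rng.randint(1, 5))) for _ in range(n)]
        ranked = [tp_stub(f"t{i}", 100, [0]) for i in range(n)]
        sel = remove_redundant(ranked, ln_sets)
        seen = set()
        for lns, keep in zip(ln_sets, sel.retained):
            if keep:
                assert lns - seen
                seen |= lns


class TestLoci:
    def _selection(self, ln_sets):
        ranked = [tp_stub(f"t{i}", 100, [0]) for i in range(len(ln_sets))]
        return remove_redundant(ranked, ln_sets, keep_nodeless=True), ranked, ln_sets

    def test_transitive_chain_is_one_locus(self):
        sel, ranked, ln_sets = self._selection([{1, 2}, {2, 3}, {3, 4}])
        lookup = {id(tp): lns for tp, lns in zip(ranked, ln_sets)}
        loci = group_loci(sel, lambda tp: lookup[id(tp)])
        assert len(loci) == 1
        assert {m.record.id for m in loci[0].members} == {"t0", "t1", "t2"}

    def test_no_sharing_gives_singletons(self):
        sel, ranked, ln_sets = self._selection([{1}, {2}, set()])
        lookup = {id(tp): lns for tp, lns in zip(ranked, ln_sets)}
        loci = group_loci(sel, lambda tp: lookup[id(tp)])
        assert len(loci) == 3
        assert all(len(l.members) == 1 for l in loci)

    def test_matches_pairwise_component_oracle(self, rng):
        import networkx as nx

        for _ in range(30):
            n = rng.randint(1, 20)
            ln_sets = [set(rng.sample(range(10), rng.randint(0, 3))) for _ in range(n)]
            sel, ranked, _ = self._selection(ln_sets)
            retained = sel.retained_transcripts()
            kept_sets = [ln_sets[i] for i, k in enumerate(sel.retained) if k]
            lookup = {id(tp): lns for tp, lns in zip(ranked, ln_sets)}
            loci = group_loci(sel, lambda tp: lookup[id(tp)])
            got = sorted(frozenset(retained.index(m) for m in l.members) for l in loci)
            expected = pairwise_components(kept_sets, lambda a, b: bool(a & b))
            assert got == expected
            # independent cross-check with networkx components
            G = nx.Graph()
            G.add_nodes_from(range(len(kept_sets)))
            for i in range(len(kept_sets)):
                for j in range(i + 1, len(kept_sets)):
                    if kept_sets[i] & kept_sets[j]:
                        G.add_edge(i, j)
            assert sorted(frozenset(c) for c in nx.connected_components(G)) == expected


class TestStats:
    @pytest.mark.parametrize("lengths, expected", [([100], 100), ([2, 2, 2], 2), ([1, 1, 5], 5), ([3, 4, 5, 6], 5)])
    def test_n50_examples(self, lengths, expected):
        assert compute_n50(lengths) == expected

    def test_n50_matches_cumulative_oracle(self, rng):
        for _ in range(100):
            lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 40))]
            assert compute_n50(lengths) == cumulative_n50(lengths)

    def test_summary_report(self):
        a, b = tp_stub("a", 300, [1]), tp_stub("b", 100, [2])
        sel = remove_redundant([a, b], [{1}, {2}])
        lookup = {id(a): {1}, id(b): {2}}
        loci = group_loci(sel, lambda tp: lookup[id(tp)])
        rep = summary_stats(sel, loci)
        assert (rep.transcripts, rep.loci, rep.n50, rep.total_bases) == (2, 2, 300, 400)
        assert rep.as_tsv().splitlines()[1] == "2\t2\t300\t400"


class TestPipeline:
    def test_single_transcript_identity(self, tmp_path, rng):
        rec = SeqRecord("t1", random_seq(rng, 200))
        path = tmp_path / "in.fa"
        write_fasta([rec], path)
        records, report = merge_assemblies([path])
        assert len(records) == 1
        assert records[0].id == "Locus_1_Transcript_1"
        assert records[0].seq in (rec.seq, reverse_complement(rec.seq))
        assert (report.transcripts, report.loci) == (1, 1)

    def test_same_file_twice_collapses(self, tmp_path, rng):
        recs = [SeqRecord(f"t{i}", random_seq(rng, 150)) for i in range(5)]
        path = tmp_path / "in.fa"
        write_fasta(recs, path)
        once, rep1 = merge_assemblies([path])
        twice, rep2 = merge_assemblies([path, path])
        assert once == twice
        assert rep1 == rep2

    def test_planted_transcripts_recovered(self, tmp_path):
        spec = FixtureSpec(seed=11, n_true=12, n_libraries=3, length_range=(200, 600))
        truth = make_true_set(spec)
        paths = make_library_assemblies(truth, spec, tmp_path)
        records, report = merge_assemblies(paths)
        merged = [r.seq for r in records]
        for t in truth:
            assert any(t.seq in m or reverse_complement(t.seq) in m for m in merged)
        n_inputs = sum(1 for p in paths for _ in read_fasta(p))
        assert report.transcripts <= n_inputs
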