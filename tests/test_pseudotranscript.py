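import numpy as np
import pytest

from protannot import (
    AlignmentChain,
    GenomicInterval,
    cluster_chains,
    extract_spliced_sequence,
    merge_blocks,
)
from protannot.pseudotranscript import Locus, build_pseudotranscript, merge_all_loci

from conftest import random_locus_pt


def _chain(blocks, strand="+", seqid="c", query="q"):
    return AlignmentChain(
        query_id=query, seqid=seqid, strand=strand,
        blocks=[GenomicInterval(seqid, s, e, strand) for s, e in blocks],
        identity=1.0,
    )


class TestClusterChains:
    def test_overlapping_blocks_join_one_locus(self):
        loci = cluster_chains([_chain([(100, 200)]), _chain([(150, 300)])])
        assert len(loci) == 1
        assert len(loci[0].members) == 2

    def test_opposite_strands_never_merge(self):
        loci = cluster_chains([_chain([(100, 200)], "+"), _chain([(100, 200)], "-")])
        assert len(loci) == 2

    def test_bridging_chain_links_three_into_one(self):
        a, b, c = _chain([(100, 200)]), _chain([(250, 350)]), _chain([(180, 260)])
        loci = cluster_chains([a, b, c])
        assert len(loci) == 1
        assert len(loci[0].members) == 3

    def test_book_ended_blocks_do_not_merge(self):
        loci = cluster_chains([_chain([(100, 200)]), _chain([(201, 300)])])
        assert len(loci) == 2

    def test_nested_gene_in_intron_stays_separate(self):
        outer = _chain([(100, 200), (900, 1000)])
        inner = _chain([(400, 600)])
        assert len(cluster_chains([outer, inner])) == 2

    def test_partition_invariant_under_permutation(self):
        rng = np.random.default_rng(11)
        chains = []
        for i in range(30):
            s = int(rng.integers(1, 5000))
            chains.append(_chain([(s, s + int(rng.integers(20, 200)))],
                                 strand="+" if rng.random() < 0.5 else "-"))
        base = cluster_chains(chains)
        assert sum(len(l.members) for l in base) == len(chains)
        for seed in (1, 2, 3):
            perm = list(rng.permutation(len(chains)))
            loci = cluster_chains([chains[i] for i in perm])
            key = lambda ls: sorted((l.seqid, l.strand, l.start, l.end, len(l.members)) for l in ls)
            assert key(loci) == key(base)


class TestMergeBlocks:
    def test_union_of_overlapping_blocks(self):
        loc = Locus("c", "+", [_chain([(100, 200)]), _chain([(150, 300)])])
        merged = merge_blocks(loc, 0, {"c": 10_000})
        assert [(b.start, b.end) for b in merged] == [(100, 300)]

    def test_terminal_flank_extends_outermost_edges(self):
        loc = Locus("c", "+", [_chain([(100, 200)])])
        merged = merge_blocks(loc, 50, {"c": 10_000})
        assert [(b.start, b.end) for b in merged] == [(50, 250)]

    def test_flank_clipped_at_contig_start(self):
        loc = Locus("c", "+", [_chain([(5, 100)])])
        merged = merge_blocks(loc, 50, {"c": 10_000})
        assert [(b.start, b.end) for b in merged] == [(1, 150)]

    def test_internal_junctions_never_move(self):
        loc = Locus("c", "+", [_chain([(100, 200), (400, 500)])])
        merged = merge_blocks(loc, 50, {"c": 10_000})
        assert [(b.start, b.end) for b in merged] == [(50, 200), (400, 550)]

    def test_flank_never_crosses_adjacent_locus(self):
        chains = [_chain([(100, 200)]), _chain([(260, 400)])]
        loci = cluster_chains(chains)
        merge_all_loci(loci, 300, {"c": 10_000})
        left, right = loci
        assert left.merged_blocks[-1].end == 259
        assert right.merged_blocks[0].start == 201

    def test_idempotent_under_remerge_with_zero_flank(self):
        loc = Locus("c", "+", [_chain([(100, 200)]), _chain([(150, 300)])])
        merged = merge_blocks(loc, 40, {"c": 10_000})
        loc2 = Locus("c", "+", [_chain([(b.start, b.end) for b in merged])])
        again = merge_blocks(loc2, 0, {"c": 10_000})
        assert [(b.start, b.end) for b in again] == [(b.start, b.end) for b in merged]


class TestBuildPseudoTranscript:
    GENOME = {"c": "ATGAAATAA"}

    def _pt(self, blocks, strand):
        loc = Locus("c", strand, [],
                    merged_blocks=[GenomicInterval("c", s, e, strand) for s, e in blocks])
        return build_pseudotranscript(loc, self.GENOME, pt_id="t")

    def test_plus_strand_identity_map(self):
        pt = self._pt([(1, 9)], "+")
        assert pt.sequence == "ATGAAATAA"
        assert pt.transcript_to_genome(1) == 1

    def test_minus_strand_reverse_complement_and_map(self):
        pt = self._pt([(1, 9)], "-")
        assert pt.sequence == "TTATTTCAT"
        assert pt.transcript_to_genome(1) == 9

    def test_junction_map(self):
        pt = self._pt([(1, 3), (7, 9)], "+")
        assert len(pt) == 6
        assert pt.sequence == "ATGTAA"
        assert pt.transcript_to_genome(4) == 7


class TestMapToGenome:
    def _pt(self, blocks, genome, strand="+"):
        loc = Locus("c", strand, [],
                    merged_blocks=[GenomicInterval("c", s, e, strand) for s, e in blocks])
        return build_pseudotranscript(loc, genome, pt_id="t")

    def test_single_block_subrange(self):
        pt = self._pt([(1, 9)], {"c": "ATGAAATAA"})
        assert [(iv.start, iv.end) for iv in pt.map_to_genome(2, 4)] == [(2, 4)]

    def test_split_at_junction(self):
        pt = self._pt([(1, 3), (7, 9)], {"c": "ATGAAATAA"})
        assert [(iv.start, iv.end) for iv in pt.map_to_genome(2, 5)] == [(2, 3), (7, 8)]

    def test_full_range_round_trip(self):
        pt = self._pt([(2, 4), (6, 9)], {"c": "ATGAAATAAG"})
        ivs = pt.map_to_genome(1, len(pt))
        assert extract_spliced_sequence({"c": "ATGAAATAAG"}, ivs, "+") == pt.sequence

    def test_out_of_range_rejected(self):
        pt = self._pt([(1, 9)], {"c": "ATGAAATAA"})
        with pytest.raises(ValueError):
            pt.map_to_genome(0, 5)
        with pytest.raises(ValueError):
            pt.map_to_genome(3, 10)

    def test_fuzz_round_trip_on_random_loci(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            pt, genome = random_locus_pt(rng)
            L = len(pt)
            for _ in range(5):
                a = int(rng.integers(1, L + 1))
                b = int(rng.integers(a, L + 1))
                ivs = pt.map_to_genome(a, b)
                assert sum(len(iv) for iv in ivs) == b - a + 1
                back = extract_spliced_sequence(genome, ivs, pt.locus.strand)
                assert back == pt.sequence[a - 1 : b]
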