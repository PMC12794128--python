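"""Locus clustering and pseudo-transcript assembly.

Alignment chains are grouped into strand-aware loci by single-linkage over
block overlap, their blocks merged into a disjoint cover, and each locus
spliced into a pseudo-transcript — an mRNA stand-in without UTRs — carrying
an exact bijection between transcript and genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import AlignmentChain
from .formats import GenomicInterval, extract_spliced_sequence

DEFAULT_TERMINAL_FLANK = 300


@dataclass
class Locus:
    seqid: str
    strand: str
    members: list[AlignmentChain]
    merged_blocks: list[GenomicInterval] = field(default_factory=list)

    @property
    def start(self) -> int:
        blocks = self.merged_blocks or [b for c in self.members for b in c.blocks]
        return min(b.start for b in blocks)

    @property
    def end(self) -> int:
        blocks = self.merged_blocks or [b for c in self.members for b in c.blocks]
        return max(b.end for b in blocks)


@dataclass
class PseudoTranscript:
    """A spliced locus sequence with its transcript↔genome coordinate map.

    ``sequence`` is strand-oriented (reverse-complemented for minus-strand
    loci); transcript position 1 is the 5' end.  The map is held as the
    array of genome positions in transcript order: strictly increasing for
    ``+``, strictly decreasing for ``-``.
    """

    pt_id: str
    locus: Locus
    sequence: str
    genome_positions: np.ndarray  # int64, length == len(sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def transcript_to_genome(self, pos: int) -> int:
        self._check_range(pos, pos)
        return int(self.genome_positions[pos - 1])

    def genome_to_transcript(self, gpos: int) -> int:
        hits = np.nonzero(self.genome_positions == gpos)[0]
        if hits.size == 0:
            raise ValueError(f"{self.pt_id}: genome position {gpos} not in transcript")
        return int(hits[0]) + 1

    def _check_range(self, t_start: int, t_end: int) -> None:
        if not (1 <= t_start <= t_end <= len(self)):
            raise ValueError(
                f"{self.pt_id}: transcript range {t_start}-{t_end} outside 1-{len(self)}"
            )

    def map_to_genome(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Project a transcript range onto the genome.

        Returns the minimal interval list (5'→3' in transcript sense) whose
        strand-ordered concatenation is exactly positions t_start..t_end;
        splits occur only at merged-block junctions, and summed lengths equal
        t_end - t_start + 1.
        """
        self._check_range(t_start, t_end)
        pos = self.genome_positions[t_start - 1 : t_end]
        step = 1 if self.locus.strand == "+" else -1
        breaks = np.nonzero(np.diff(pos) != step)[0]
        intervals = []
        run_start = 0
        for b in list(breaks) + [len(pos) - 1]:
            lo, hi = int(pos[run_start]), int(pos[b])
            if lo > hi:
                lo, hi = hi, lo
            intervals.append(GenomicInterval(self.locus.seqid, lo, hi, self.locus.strand))
            run_start = b + 1
        return intervals


def _coalesce(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals, merging overlapping or book-ended neighbours."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: iv.start)
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end + 1:
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.seqid, last.start, iv.end, last.strand)
        else:
            out.append(iv)
    return out


def cluster_chains(chains: Sequence[AlignmentChain]) -> list[Locus]:
    """Single-linkage clustering of chains into loci.

    Two chains join one locus iff they share seqid and strand and at least
    one pair of their blocks overlaps by >= 1 bp.  Overlap is block-level,
    not span-level, so a gene nested in another gene's intron stays separate.
    Loci are sorted by (seqid, leftmost start); the partition is invariant
    under permutation of the input.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(chains):
        groups.setdefault((c.seqid, c.strand), []).append(i)

    parent = list(range(len(chains)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for idx in groups.values():
        events = []  # (start, end, chain index) per block
        for i in idx:
            for b in chains[i].blocks:
                events.append((b.start, b.end, i))
        events.sort()
        # sweep: link blocks that overlap the running frontier
        active_end = -1
        active_chain = -1
        for start, end, i in events:
            if start <= active_end:
                union(active_chain, i)
                if end > active_end:
                    active_end = end
                    active_chain = find(i)
            else:
                active_end = end
                active_chain = i

    clusters: dict[int, list[AlignmentChain]] = {}
    for i, c in enumerate(chains):
        clusters.setdefault(find(i), []).append(c)
    loci = [
        Locus(seqid=members[0].seqid, strand=members[0].strand, members=members)
        for members in clusters.values()
    ]
    loci.sort(key=lambda loc: (loc.seqid, loc.start, loc.end))
    return loci


def merge_blocks(
    locus: Locus,
    terminal_flank: int,
    genome_lengths: Mapping[str, int],
    left_bound: int | None = None,
    right_bound: int | None = None,
) -> list[GenomicInterval]:
    """Merge member blocks and extend the outer edges by ``terminal_flank``.

    Internal block boundaries (putative splice junctions) are never moved;
    only the two outermost edges are extended, clipped to the contig and to
    ``left_bound``/``right_bound`` (the nearest block of an adjacent locus
    on the same strand, exclusive).
    """
    if terminal_flank < 0:
        raise ValueError("terminal_flank must be >= 0")
    merged = _coalesce([b for c in locus.members for b in c.blocks])
    contig_len = genome_lengths[locus.seqid]
    lo = merged[0].start - terminal_flank
    lo = max(lo, 1)
    if left_bound is not None:
        lo = max(lo, left_bound + 1)
    lo = min(lo, merged[0].start)
    hi = merged[-1].end + terminal_flank
    hi = min(hi, contig_len)
    if right_bound is not None:
        hi = min(hi, right_bound - 1)
    hi = max(hi, merged[-1].end)
    merged[0] = GenomicInterval(locus.seqid, lo, merged[0].end, locus.strand)
    merged[-1] = GenomicInterval(locus.seqid, merged[-1].start, hi, locus.strand)
    merged = _coalesce(merged)  # flanks may have bridged a short gap at the edges
    locus.merged_blocks = merged
    return merged


def merge_all_loci(
    loci: Sequence[Locus],
    terminal_flank: int,
    genome_lengths: Mapping[str, int],
) -> None:
    """merge_blocks for every locus, clipping flanks against same-strand neighbours."""
    by_group: dict[tuple[str, str], list[Locus]] = {}
    for loc in loci:
        by_group.setdefault((loc.seqid, loc.strand), []).append(loc)
    for group in by_group.values():
        group.sort(key=lambda loc: loc.start)
        # base unions first, so neighbour bounds are flank-independent
        unions = [_coalesce([b for c in loc.members for b in c.blocks]) for loc in group]
        for i, loc in enumerate(group):
            left = unions[i - 1][-1].end if i > 0 else None
            right = unions[i + 1][0].start if i + 1 < len(group) else None
            merge_blocks(loc, terminal_flank, genome_lengths, left, right)


def build_pseudotranscript(
    locus: Locus, genome: Mapping[str, str], pt_id: str | None = None
) -> PseudoTranscript:
    """Splice the merged blocks into a strand-oriented pseudo-transcript."""
    if not locus.merged_blocks:
        raise ValueError("merge_blocks must be applied before assembly")
    seq = extract_spliced_sequence(genome, locus.merged_blocks, locus.strand)
    pieces = [
        np.arange(b.start, b.end + 1, dtype=np.int64)
        for b in sorted(locus.merged_blocks, key=lambda b: b.start)
    ]
    positions = np.concatenate(pieces)
    if locus.strand == "-":
        positions = positions[::-1]
    if pt_id is None:
        pt_id = f"pt:{locus.seqid}:{locus.start}-{locus.end}:{locus.strand}"
    return PseudoTranscript(pt_id=pt_id, locus=locus, sequence=seq, genome_positions=positions)
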