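"""Self-contained synthetic fixtures: genomes with planted genes, diverged
homolog proteins, and aligner-style GFF3 derived from the planted truth.

The generator emulates the three inputs of the annotation pipeline so that
every module is testable without any external data: (1) a genome in which
multi-exon protein-coding genes are planted — ATG…stop CDS with codons drawn
from a fixed hexamer-biased table (so coding sequence is statistically
separable from the iid intergenic background), canonical GT-AG introns,
random strands; (2) homolog proteins produced by per-site substitution of
the truth proteins at a chosen divergence; (3) spliced-alignment GFF3 with
one mRNA record per truth transcript, CDS blocks at the truth coordinates
and an Identity attribute equal to the realized protein identity plus
optional Gaussian reporting noise.

All randomness flows from a single seed through one generator stream, so
every output is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    extract_spliced_sequence,
    translate,
    write_fasta,
    write_gff3,
)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

# Position-specific nucleotide weights of the planted coding model (GC3-rich,
# purine-leaning first positions — the usual signature of real codon usage).
_POS_WEIGHTS = np.array(
    [
        [0.30, 0.18, 0.34, 0.18],  # codon position 1
        [0.32, 0.22, 0.18, 0.28],  # codon position 2
        [0.16, 0.30, 0.34, 0.20],  # codon position 3
    ]
)


def _codon_table() -> tuple[list[str], np.ndarray]:
    codons, weights = [], []
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            for k, c in enumerate(BASES):
                cod = a + b + c
                if cod in STOPS:
                    continue
                codons.append(cod)
                weights.append(_POS_WEIGHTS[0, i] * _POS_WEIGHTS[1, j] * _POS_WEIGHTS[2, k])
    w = np.array(weights)
    return codons, w / w.sum()


_CODONS, _CODON_P = _codon_table()

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset (defaults = the standard fixture)."""

    n_contigs: int = 1
    contig_length: int = 500_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (180, 450)
    intron_length: tuple[int, int] = (80, 500)
    intergenic_min: int = 800
    gc: float = 0.42
    protein_divergence: float = 0.0
    alignment_identity_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo},{hi}) is empty or invalid")
        if not 0.0 <= self.protein_divergence < 1.0:
            raise ValueError("protein_divergence must be in [0,1)")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0,1)")


@dataclass
class SyntheticData:
    spec: SyntheticSpec
    genome: dict[str, str]
    truth: list[GeneModel]
    proteins: dict[str, str]  # transcript_id -> peptide (no stop)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + hexamer-biased stop-free body + a stop codon; n_codons total."""
    body = rng.choice(len(_CODONS), size=n_codons - 2, p=_CODON_P)
    stop = STOPS[rng.choice(3, p=np.array([0.5, 0.2, 0.3]))]
    return "ATG" + "".join(_CODONS[i] for i in body) + stop


def generate_genome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SyntheticData:
    """Plant ``spec.n_genes`` genes across the contigs.

    Genes are placed left-to-right with at least ``intergenic_min`` bp between
    neighbouring gene bodies; strands are random; introns begin GT and end AG.
    Raises if the contigs cannot hold the requested genes.
    """
    rng = rng or np.random.default_rng(spec.seed)
    contig_names = [f"ctg{i+1}" for i in range(spec.n_contigs)]
    contigs = {name: [] for name in contig_names}
    cursors = {name: 1 for name in contig_names}

    truth: list[GeneModel] = []
    proteins: dict[str, str] = {}

    contig_idx = 0
    for g in range(spec.n_genes):
        # draw the gene structure
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        total = sum(exon_lens)
        exon_lens[-1] -= total % 3  # codon-align the CDS
        total = sum(exon_lens)
        intron_lens = [
            int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
            for _ in range(n_exons - 1)
        ]
        span = total + sum(intron_lens)
        strand = "+" if rng.random() < 0.5 else "-"

        # find a contig with room
        placed = False
        attempts = 0
        while not placed and attempts < spec.n_contigs:
            name = contig_names[contig_idx % spec.n_contigs]
            gap = spec.intergenic_min + int(rng.integers(0, spec.intergenic_min + 1))
            g0 = cursors[name] + gap
            if g0 + span - 1 + spec.intergenic_min <= spec.contig_length:
                placed = True
            else:
                contig_idx += 1
                attempts += 1
        if not placed:
            raise ValueError(
                f"unsatisfiable spec: gene {g+1} of {spec.n_genes} (span {span} bp) "
                f"does not fit in {spec.n_contigs} contig(s) of {spec.contig_length} bp"
            )

        cds = _coding_sequence(rng, total // 3)
        # assemble the gene body on the coding strand
        pieces = []
        offsets = []  # (segment offset, exon length) of each exon
        pos = 0
        cpos = 0
        for e, elen in enumerate(exon_lens):
            pieces.append(cds[cpos : cpos + elen])
            offsets.append((pos, elen))
            pos += elen
            cpos += elen
            if e < n_exons - 1:
                ilen = intron_lens[e]
                intron = "GT" + _random_dna(rng, ilen - 4, spec.gc) + "AG"
                pieces.append(intron)
                pos += ilen
        segment = "".join(pieces)
        if strand == "-":
            from .formats import reverse_complement

            segment = reverse_complement(segment)

        # pad the gap, then insert the gene body
        contigs[name].append(_random_dna(rng, g0 - cursors[name], spec.gc))
        contigs[name].append(segment)
        cursors[name] = g0 + span

        intervals = []
        for off, elen in offsets:
            if strand == "+":
                lo = g0 + off
                hi = lo + elen - 1
            else:
                hi = g0 + span - 1 - off
                lo = hi - elen + 1
            intervals.append(GenomicInterval(name, lo, hi, strand))
        gid = f"tg{g+1}"
        tm = TranscriptModel(
            transcript_id=f"{gid}.t1",
            gene_id=gid,
            cds_intervals=intervals,
            phases=_phases(exon_lens),
        )
        truth.append(GeneModel(gene_id=gid, transcripts=[tm]))
        contig_idx += 1  # spread genes round-robin across contigs

    genome = {}
    for name in contig_names:
        tail = spec.contig_length - cursors[name] + 1
        contigs[name].append(_random_dna(rng, tail, spec.gc))
        genome[name] = "".join(contigs[name])

    for gm in truth:
        tm = gm.transcripts[0]
        cds = extract_spliced_sequence(genome, tm.cds_intervals, tm.strand)
        tr = translate(cds)
        assert not tr.internal_stop, "planted gene translated with internal stop"
        proteins[tm.transcript_id] = tr.peptide[:-1]
    return SyntheticData(spec=spec, genome=genome, truth=truth, proteins=proteins)


def _phases(exon_lens: Sequence[int]) -> list[int]:
    phases, cum = [], 0
    for elen in exon_lens:
        phases.append((3 - (cum % 3)) % 3)
        cum += elen
    return phases


def mutate_proteins(
    proteins: Mapping[str, str],
    divergence: float,
    rng: np.random.Generator | int = 0,
) -> dict[str, tuple[str, float]]:
    """Per-site substitution at the given rate to a random different residue.

    Returns name -> (mutated sequence, realized identity).
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0,1)")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    out = {}
    for name in proteins:
        seq = proteins[name]
        chars = list(seq)
        hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
        for i in hits:
            choices = [a for a in AA_ALPHABET if a != chars[i]]
            chars[i] = choices[int(rng.integers(len(choices)))]
        mutated = "".join(chars)
        matches = sum(a == b for a, b in zip(seq, mutated))
        identity = matches / len(seq) if seq else 1.0
        out[name] = (mutated, identity)
    return out


def simulate_alignments(
    truth: Sequence[GeneModel],
    identities: Mapping[str, float],
    noise: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> str:
    """Aligner-style GFF3 text: one mRNA per truth transcript with CDS blocks
    at the truth coordinates and Identity = realized identity + N(0, noise),
    clamped to [0, 1]."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    lines = ["##gff-version 3"]
    n = 0
    for gm in truth:
        for tm in gm.transcripts:
            n += 1
            ident = identities.get(tm.transcript_id, 1.0)
            if noise > 0:
                ident = float(np.clip(ident + rng.normal(0.0, noise), 0.0, 1.0))
            sp = tm.span
            aln_id = f"aln{n}"
            lines.append(
                f"{sp.seqid}\tsimaln\tmRNA\t{sp.start}\t{sp.end}\t0\t{sp.strand}\t.\t"
                f"ID={aln_id};Identity={ident:.4f};Target={tm.transcript_id} 1 {tm.cds_length // 3}"
            )
            for i, iv in enumerate(sorted(tm.cds_intervals, key=lambda iv: iv.start), 1):
                lines.append(
                    f"{iv.seqid}\tsimaln\tCDS\t{iv.start}\t{iv.end}\t0\t{iv.strand}\t.\t"
                    f"ID={aln_id}.cds{i};Parent={aln_id};Identity={ident:.4f}"
                )
    return "\n".join(lines) + "\n"


def write_synthetic(spec: SyntheticSpec, prefix) -> dict[str, Path]:
    """Generate a dataset and write the five fixture files plus a spec echo."""
    rng = np.random.default_rng(spec.seed)
    data = generate_genome(spec, rng)
    mutated = mutate_proteins(data.proteins, spec.protein_divergence, rng)
    aln = simulate_alignments(
        data.truth,
        {name: ident for name, (_, ident) in mutated.items()},
        noise=spec.alignment_identity_noise,
        rng=rng,
    )
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": Path(f"{prefix}.genome.fa"),
        "truth_gff3": Path(f"{prefix}.truth.gff3"),
        "truth_pep": Path(f"{prefix}.truth.pep.fa"),
        "homologs": Path(f"{prefix}.homologs.pep.fa"),
        "alignments": Path(f"{prefix}.aln.gff3"),
        "spec": Path(f"{prefix}.spec.json"),
    }
    write_fasta(data.genome, paths["genome"])
    write_gff3(data.truth, paths["truth_gff3"], source="synthetic",
               seqid_order=list(data.genome))
    write_fasta(data.proteins, paths["truth_pep"])
    write_fasta(
        [(f"{name} identity={ident:.4f}", seq) for name, (seq, ident) in mutated.items()],
        paths["homologs"],
    )
    paths["alignments"].write_text(aln)
    paths["spec"].write_text(json.dumps(dataclasses.asdict(spec), indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Markov-chain sampling helpers (used by model-recovery and scoring tests)


def random_frame_markov(
    order: int,
    rng: np.random.Generator,
    concentration: float = 0.5,
) -> np.ndarray:
    """A random frame-periodic transition table, shape (3, 4**order, 4).

    Rows are Dirichlet(concentration) draws; small concentration gives the
    peaked conditionals typical of real coding hexamer statistics.
    """
    return rng.dirichlet([concentration] * 4, size=(3, 4**order))


def sample_frame_markov(
    table: np.ndarray,
    order: int,
    n_bases: int,
    rng: np.random.Generator,
) -> str:
    """Sample a sequence from a frame-periodic Markov chain.

    The first ``order`` bases are drawn uniformly; thereafter base i follows
    table[i % 3, context_code, :].
    """
    cum = table.cumsum(axis=2)
    u = rng.random(n_bases)
    codes = np.empty(n_bases, dtype=np.int64)
    codes[:order] = rng.integers(0, 4, size=min(order, n_bases))
    if n_bases > order:
        weights = 4 ** np.arange(order - 1, -1, -1, dtype=np.int64)
        ctx = int(np.dot(codes[:order], weights))
        mask = 4 ** (order - 1)
        cum_list = cum.tolist()  # plain lists: much faster scalar lookup
        for i in range(order, n_bases):
            row = cum_list[i % 3][ctx]
            x = u[i]
            c = 0
            while c < 3 and x >= row[c]:
                c += 1
            codes[i] = c
            ctx = (ctx % mask) * 4 + c
    return "".join(BASES[c] for c in codes)
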