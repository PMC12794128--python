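"""Genome-coordinate gene-model containers and FASTA/GFF3 input/output.

Coordinates follow the GFF3 convention everywhere: 1-based, inclusive on
both ends.  CDS interval chains are stored 5'→3' in transcript sense, so on
the minus strand the chain runs from the highest genomic coordinate down;
writers re-sort rows into ascending genomic order as GFF3 requires.

CDS chains of complete models include the stop codon, matching the
convention of spliced protein aligners and most reference annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement as _bio_revcomp


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval [start, end] on one strand of one contig."""

    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript's CDS chain in genome coordinates.

    ``cds_intervals`` are ordered 5'→3' in transcript sense; ``phases`` give
    the per-segment GFF3 phase (bases to skip to reach the next codon
    boundary).  ``score`` is the coding log-odds of the underlying ORF (nats).
    """

    transcript_id: str
    gene_id: str
    cds_intervals: list[GenomicInterval]
    phases: list[int]
    score: float = 0.0
    source_proteins: list[str] = field(default_factory=list)
    peptide_length: int | None = None

    def __post_init__(self) -> None:
        if not self.cds_intervals:
            raise ValueError(f"{self.transcript_id}: empty CDS chain")
        seqids = {iv.seqid for iv in self.cds_intervals}
        strands = {iv.strand for iv in self.cds_intervals}
        if len(seqids) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: CDS chain spans multiple seqids/strands")
        ivs = sorted(self.cds_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.transcript_id}: overlapping CDS intervals")
        if len(self.phases) != len(self.cds_intervals):
            raise ValueError(f"{self.transcript_id}: phases/CDS length mismatch")
        if any(p not in (0, 1, 2) for p in self.phases):
            raise ValueError(f"{self.transcript_id}: phase outside {{0,1,2}}")

    @property
    def seqid(self) -> str:
        return self.cds_intervals[0].seqid

    @property
    def strand(self) -> str:
        return self.cds_intervals[0].strand

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_intervals)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seqid,
            min(iv.start for iv in self.cds_intervals),
            max(iv.end for iv in self.cds_intervals),
            self.strand,
        )


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a locus."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene has no transcripts")

    @property
    def span(self) -> GenomicInterval:
        spans = [t.span for t in self.transcripts]
        return GenomicInterval(
            spans[0].seqid,
            min(s.start for s in spans),
            max(s.end for s in spans),
            spans[0].strand,
        )


class Translation(NamedTuple):
    peptide: str
    internal_stop: bool

    def __str__(self) -> str:  # lets callers treat the result as the peptide
        return self.peptide


_STANDARD_TABLE_CACHE: dict[int, tuple[dict[str, str], frozenset[str]]] = {}


def _codon_table(table: int) -> tuple[dict[str, str], frozenset[str]]:
    if table not in _STANDARD_TABLE_CACHE:
        ct = CodonTable.unambiguous_dna_by_id[table]
        _STANDARD_TABLE_CACHE[table] = (dict(ct.forward_table), frozenset(ct.stop_codons))
    return _STANDARD_TABLE_CACHE[table]


def translate(cds: str, table: int = 1) -> Translation:
    """Translate a CDS with the given NCBI translation table (default standard).

    The trailing stop codon is rendered ``*``; any internal stop sets the
    ``internal_stop`` flag.  Codons containing non-ACGT characters (soft
    masking is uppercased first; Ns and IUPAC codes are kept) yield ``X``.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    fwd, stops = _codon_table(table)
    seq = cds.upper().replace("U", "T")
    aa = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in stops:
            aa.append("*")
        else:
            aa.append(fwd.get(codon, "X"))
    peptide = "".join(aa)
    return Translation(peptide, "*" in peptide[:-1])


def reverse_complement(seq: str) -> str:
    return _bio_revcomp(seq)


def extract_spliced_sequence(
    genome: Mapping[str, str],
    intervals: Sequence[GenomicInterval],
    strand: str,
) -> str:
    """Concatenate interval substrings in ascending genomic order and
    reverse-complement the whole on the minus strand."""
    if not intervals:
        return ""
    parts = []
    for iv in sorted(intervals, key=lambda iv: iv.start):
        contig = genome[iv.seqid]
        if iv.end > len(contig):
            raise IndexError(
                f"interval {iv.seqid}:{iv.start}-{iv.end} beyond contig end ({len(contig)} bp)"
            )
        parts.append(contig[iv.start - 1 : iv.end])
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id→sequence dict (sequence case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path, width: int = 60) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _prevalidate_gff3(path) -> int:
    """Cheap structural check so errors can name a line number.

    Returns the number of feature lines.
    """
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            attrs = fields[8]
            for token in attrs.split(";"):
                token = token.strip()
                if token and "=" not in token:
                    raise GFF3ParseError(
                        f"{path}: line {lineno}: malformed attribute token {token!r}"
                    )
            n_features += 1
    return n_features


def load_gff3_db(path) -> gffutils.FeatureDB | None:
    """Parse GFF3 into an in-memory feature DB; None for a feature-less file."""
    if _prevalidate_gff3(path) == 0:
        return None
    try:
        return gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001 — re-raise with file context
        raise GFF3ParseError(f"{path}: failed to parse GFF3: {exc}") from exc


def read_gff3(path) -> list[GeneModel]:
    """Read gene/mRNA/CDS models from a GFF3 file.

    CDS features are attached to their mRNA via ``Parent``; an orphan CDS
    (unresolvable parent) is an error.  Output is sorted by (seqid, start).
    """
    db = load_gff3_db(path)
    if db is None:
        return []

    mrna_by_id: dict[str, gffutils.Feature] = {}
    for mrna in db.features_of_type("mRNA"):
        mrna_by_id[mrna.id] = mrna

    orphans = []
    cds_by_mrna: dict[str, list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        resolved = [p for p in parents if p in mrna_by_id]
        if not resolved:
            orphans.append(cds.id or cds.attributes.get("ID", ["<no ID>"])[0])
            continue
        for p in resolved:
            cds_by_mrna.setdefault(p, []).append(cds)
    if orphans:
        raise GFF3ParseError(
            f"{path}: CDS feature(s) with no resolvable mRNA parent: {', '.join(orphans)}"
        )

    genes: dict[str, list[TranscriptModel]] = {}
    for mrna_id, mrna in mrna_by_id.items():
        cds_feats = cds_by_mrna.get(mrna_id)
        if not cds_feats:
            continue
        cds_feats.sort(key=lambda f: f.start)
        if mrna.strand == "-":
            cds_feats = cds_feats[::-1]  # 5'→3' on minus strand
        intervals = [
            GenomicInterval(f.seqid, f.start, f.end, f.strand) for f in cds_feats
        ]
        phases = [int(f.frame) if f.frame not in (".", None) else 0 for f in cds_feats]
        parent_gene = mrna.attributes.get("Parent", [None])[0] or mrna_id
        try:
            score = float(mrna.score) if mrna.score not in (".", None) else 0.0
        except ValueError:
            score = 0.0
        tm = TranscriptModel(
            transcript_id=mrna_id,
            gene_id=parent_gene,
            cds_intervals=intervals,
            phases=phases,
            score=score,
        )
        genes.setdefault(parent_gene, []).append(tm)

    models = []
    for gene_id, transcripts in genes.items():
        transcripts.sort(key=lambda t: t.transcript_id)
        models.append(GeneModel(gene_id=gene_id, transcripts=transcripts))
    models.sort(key=lambda g: (g.span.seqid, g.span.start, g.gene_id))
    return models


def write_gff3(
    genes: Sequence[GeneModel],
    path,
    source: str = "protannot",
    header_comments: Sequence[str] = (),
    seqid_order: Sequence[str] | None = None,
) -> None:
    """Write gene/mRNA/CDS rows with ID/Parent links and phases.

    Ordering is deterministic: (seqid, span start, gene_id), with seqids
    following ``seqid_order`` (e.g. genome FASTA order) when given,
    lexicographic otherwise.  CDS rows are emitted in ascending genomic order.
    """
    rank = {s: i for i, s in enumerate(seqid_order)} if seqid_order else None

    def seq_key(seqid: str):
        if rank is not None and seqid in rank:
            return (0, rank[seqid])
        return (1, seqid)

    ordered = sorted(genes, key=lambda g: (seq_key(g.span.seqid), g.span.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for comment in header_comments:
            fh.write(f"#{comment}\n")
        for gene in ordered:
            sp = gene.span
            fh.write(
                f"{sp.seqid}\t{source}\tgene\t{sp.start}\t{sp.end}\t.\t{sp.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for tm in gene.transcripts:
                ts = tm.span
                attrs = f"ID={tm.transcript_id};Parent={gene.gene_id}"
                if tm.source_proteins:
                    attrs += ";source_proteins=" + ",".join(tm.source_proteins)
                fh.write(
                    f"{ts.seqid}\t{source}\tmRNA\t{ts.start}\t{ts.end}\t{tm.score:.3f}\t"
                    f"{ts.strand}\t.\t{attrs}\n"
                )
                rows = sorted(
                    zip(tm.cds_intervals, tm.phases), key=lambda ivp: ivp[0].start
                )
                for i, (iv, phase) in enumerate(rows, start=1):
                    fh.write(
                        f"{iv.seqid}\t{source}\tCDS\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t"
                        f"{phase}\tID={tm.transcript_id}.cds{i};Parent={tm.transcript_id}\n"
                    )


def longest_isoform(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Reduce every gene to its longest isoform (summed CDS length).

    Ties break to the lexicographically smallest transcript_id.  Idempotent;
    never changes the gene count.
    """
    reduced = []
    for gene in genes:
        best = max(gene.transcripts, key=lambda t: (t.cds_length, _NegStr(t.transcript_id)))
        reduced.append(GeneModel(gene_id=gene.gene_id, transcripts=[best]))
    return reduced


class _NegStr(str):
    """String whose ordering is reversed, for use inside max() keys."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
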