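"""Parsing and filtering of spliced protein-to-genome alignments.

The input is the GFF3 dialect written by spliced protein aligners such as
miniprot: one ``mRNA`` record per aligned copy of a protein, carrying an
``Identity`` attribute (fraction of matching residues), with child ``CDS``
records giving the aligned exon blocks.  A protein aligned to several loci
yields several independent chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .formats import GFF3ParseError, GenomicInterval, load_gff3_db

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_KEY = "Identity"
#: Conservative default; distant references may warrant lowering to 0.8.
DEFAULT_MIN_IDENTITY = 0.9


@dataclass
class AlignmentChain:
    """One protein's spliced alignment: ordered exon blocks plus identity."""

    query_id: str
    seqid: str
    strand: str
    blocks: list[GenomicInterval]
    identity: float
    aln_score: float = 0.0
    chain_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.query_id}: identity {self.identity} outside [0,1]")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.query_id}: overlapping alignment blocks")

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


def parse_alignment_gff3(path, identity_key: str = DEFAULT_IDENTITY_KEY) -> list[AlignmentChain]:
    """Parse miniprot-style GFF3 into alignment chains, one per mRNA record.

    mRNA records without CDS children are skipped with a warning; an mRNA
    whose identity attribute is missing or unparseable is an error.
    """
    db = load_gff3_db(path)
    if db is None:
        return []
    chains: list[AlignmentChain] = []
    for mrna in db.features_of_type("mRNA"):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            logger.warning("alignment record %s has no CDS children; skipped", mrna.id)
            continue
        raw = mrna.attributes.get(identity_key)
        if raw is None:
            raise GFF3ParseError(
                f"{path}: record {mrna.id}: missing {identity_key!r} attribute"
            )
        try:
            identity = float(raw[0])
        except (TypeError, ValueError) as exc:
            raise GFF3ParseError(
                f"{path}: record {mrna.id}: unparseable {identity_key!r} value {raw[0]!r}"
            ) from exc
        try:
            score = float(mrna.score) if mrna.score not in (".", None) else 0.0
        except ValueError:
            score = 0.0
        target = mrna.attributes.get("Target", [mrna.id])[0]
        query_id = target.split()[0] if target else mrna.id
        chains.append(
            AlignmentChain(
                query_id=query_id,
                seqid=mrna.seqid,
                strand=mrna.strand,
                blocks=[GenomicInterval(f.seqid, f.start, f.end, f.strand) for f in cds],
                identity=identity,
                aln_score=score,
                chain_id=mrna.id,
            )
        )
    return chains


def filter_chains(chains: Sequence[AlignmentChain], min_identity: float) -> list[AlignmentChain]:
    """Keep chains with identity >= min_identity (inclusive), order preserved."""
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError(f"min_identity {min_identity} outside [0,1]")
    return [c for c in chains if c.identity >= min_identity]
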