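"""Gene-model construction and the end-to-end annotation pipeline.

Selected ORFs are projected from transcript to genome coordinates with GFF3
phases, multi-gene pseudo-transcripts are split (one gene per retained
non-overlapping ORF), low-quality models are filtered with an auditable
rejection log, exact and overlapping duplicates are resolved, and the
results are written as GFF3 plus CDS/protein FASTA and a statistics table.
The whole run is deterministic: identical inputs and configuration give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .align import (
    DEFAULT_IDENTITY_KEY,
    DEFAULT_MIN_IDENTITY,
    AlignmentChain,
    filter_chains,
    parse_alignment_gff3,
)
from .formats import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    extract_spliced_sequence,
    read_fasta,
    translate,
    write_fasta,
    write_gff3,
)
from .orf import (
    DEFAULT_MIN_LEN_AA,
    DEFAULT_MIN_SCORE,
    DEFAULT_ORDER,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_TOP_N,
    OpenReadingFrame,
    enumerate_orfs,
    refine_start,
    score_orf,
    select_orfs,
    train_model,
)
from .pseudotranscript import (
    DEFAULT_TERMINAL_FLANK,
    PseudoTranscript,
    build_pseudotranscript,
    cluster_chains,
    merge_all_loci,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """The tunable parameter set of one annotation run.

    All values are echoed into the output GFF3 header so a run is fully
    reproducible from its own output.
    """

    min_identity: float = DEFAULT_MIN_IDENTITY
    terminal_flank: int = DEFAULT_TERMINAL_FLANK
    min_orf_aa: int = DEFAULT_MIN_LEN_AA
    min_score: float = DEFAULT_MIN_SCORE
    markov_order: int = DEFAULT_ORDER
    train_top_n: int = DEFAULT_TOP_N
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    start_refine: bool = True
    allow_partial: bool = True
    identity_key: str = DEFAULT_IDENTITY_KEY
    seed: int = 0
    id_prefix: str = "PA"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0,1]")
        if self.terminal_flank < 0 or self.min_orf_aa < 1 or self.markov_order < 1:
            raise ValueError("terminal_flank, min_orf_aa, markov_order out of range")

    def header_comments(self) -> list[str]:
        items = ";".join(f"{k}={v}" for k, v in dataclasses.asdict(self).items())
        return [f"!annotator protannot v{__version__}", f"!config {items}"]


@dataclass
class PipelineResult:
    genes: list[GeneModel]
    pseudo_transcripts: list[PseudoTranscript]
    rejections: pd.DataFrame
    config: PipelineConfig
    outputs: dict[str, Path] = field(default_factory=dict)


def project_orf(pt: PseudoTranscript, orf: OpenReadingFrame, transcript_id: str, gene_id: str) -> TranscriptModel:
    """Project an ORF to a genome-coordinate CDS chain with GFF3 phases.

    Phases are cumulative from the 5' end: phase_i = (3 - L_i mod 3) mod 3
    where L_i is the CDS length preceding segment i.  The projected chain is
    checked by re-translation against the ORF peptide; an internal stop here
    indicates a coordinate-map defect and is a hard error.
    """
    intervals = pt.map_to_genome(orf.t_start, orf.t_end)
    phases = []
    cum = 0
    for iv in intervals:
        phases.append((3 - (cum % 3)) % 3)
        cum += len(iv)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        cds_intervals=intervals,
        phases=phases,
        score=orf.score,
        peptide_length=len(orf.peptide),
    )


def _verify_projection(tm: TranscriptModel, orf: OpenReadingFrame, genome: Mapping[str, str]) -> None:
    cds = extract_spliced_sequence(genome, tm.cds_intervals, tm.strand)
    tr = translate(cds)
    if tr.internal_stop:
        raise RuntimeError(
            f"{tm.transcript_id}: projected CDS translates with an internal stop "
            "(coordinate-map defect)"
        )
    pep = tr.peptide[:-1] if tr.peptide.endswith("*") else tr.peptide
    if pep != orf.peptide:
        raise RuntimeError(f"{tm.transcript_id}: projected CDS does not reproduce the ORF peptide")


def split_locus(
    pt: PseudoTranscript,
    retained_orfs: Sequence[OpenReadingFrame],
    locus_tag: str,
    genome: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """One gene per retained ORF, numbered left-to-right in genome order.

    When ``genome`` is given every projection is verified by re-translation
    against its ORF peptide (hard error on mismatch or internal stop).
    """
    for a in retained_orfs:
        for b in retained_orfs:
            if a is not b and a.overlaps(b):
                raise ValueError("retained ORFs overlap in transcript coordinates")
    drafts = []
    for orf in retained_orfs:
        gid = f"{locus_tag}.tmp"
        tm = project_orf(pt, orf, transcript_id=gid + ".t", gene_id=gid)
        if genome is not None:
            _verify_projection(tm, orf, genome)
        drafts.append((tm, orf))
    drafts.sort(key=lambda d: d[0].span.start)
    genes = []
    for i, (tm, orf) in enumerate(drafts, start=1):
        gid = f"{locus_tag}.g{i}" if len(drafts) > 1 else locus_tag
        tm.gene_id = gid
        tm.transcript_id = gid + ".t1"
        tm.source_proteins = sorted({c.query_id for c in pt.locus.members})
        genes.append(GeneModel(gene_id=gid, transcripts=[tm]))
    return genes


def filter_models(
    models: Sequence[GeneModel],
    min_orf_aa: int,
    min_score: float,
) -> tuple[list[GeneModel], list[dict]]:
    """Drop models failing the peptide-length or score threshold.

    Returns (kept models, rejection records); each rejection names the gene,
    the failed criterion, the measured value and the threshold.
    """
    kept, rejected = [], []
    for g in models:
        tm = g.transcripts[0]
        if tm.peptide_length is not None:
            pep_len = tm.peptide_length
        else:
            pep_len = tm.cds_length // 3 - 1  # stop codon included in the chain
        if pep_len < min_orf_aa:
            rejected.append(
                {"gene_id": g.gene_id, "seqid": tm.seqid, "start": g.span.start,
                 "end": g.span.end, "criterion": "length", "value": pep_len,
                 "threshold": min_orf_aa}
            )
        elif tm.score < min_score:
            rejected.append(
                {"gene_id": g.gene_id, "seqid": tm.seqid, "start": g.span.start,
                 "end": g.span.end, "criterion": "score", "value": round(tm.score, 3),
                 "threshold": min_score}
            )
        else:
            kept.append(g)
    return kept, rejected


def _chains_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.seqid != b.seqid or a.strand != b.strand:
        return False
    return any(x.overlaps(y) for x in a.cds_intervals for y in b.cds_intervals)


def deduplicate(models: Sequence[GeneModel], id_prefix: str = "PA") -> list[GeneModel]:
    """Collapse identical CDS chains and resolve residual overlaps.

    Models with identical (seqid, strand, CDS chain) merge into one, pooling
    source proteins.  Among same-strand models whose CDS chains still overlap
    the higher-scoring (then longer, then leftmost) survives.  Output is
    sorted by genome position with sequential IDs ``{prefix}gene-N``.
    """
    by_chain: dict[tuple, GeneModel] = {}
    for g in models:
        tm = g.transcripts[0]
        key = (tm.seqid, tm.strand, tuple((iv.start, iv.end) for iv in tm.cds_intervals))
        if key in by_chain:
            prev = by_chain[key].transcripts[0]
            prev.source_proteins = sorted(set(prev.source_proteins) | set(tm.source_proteins))
        else:
            by_chain[key] = g
    unique = list(by_chain.values())
    ranked = sorted(
        unique,
        key=lambda g: (
            -g.transcripts[0].score,
            -g.transcripts[0].cds_length,
            g.span.seqid,
            g.span.start,
            g.gene_id,
        ),
    )
    survivors: list[GeneModel] = []
    for g in ranked:
        if not any(_chains_overlap(g.transcripts[0], s.transcripts[0]) for s in survivors):
            survivors.append(g)
    survivors.sort(key=lambda g: (g.span.seqid, g.span.start, g.span.end, g.gene_id))
    out = []
    for i, g in enumerate(survivors, start=1):
        gid = f"{id_prefix}gene-{i}"
        tm = g.transcripts[0]
        tm.gene_id = gid
        tm.transcript_id = f"{gid}.t1"
        out.append(GeneModel(gene_id=gid, transcripts=[tm]))
    return out


def annotate(
    genome: Mapping[str, str],
    chains: Sequence[AlignmentChain],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the in-memory annotation pipeline on a genome and alignment chains."""
    cfg = config or PipelineConfig()
    missing = sorted({c.seqid for c in chains} - set(genome))
    if missing:
        raise ValueError(f"alignment contigs absent from genome: {', '.join(missing)}")
    genome_lengths = {name: len(seq) for name, seq in genome.items()}

    chains = filter_chains(chains, cfg.min_identity)
    logger.info("%d chains pass identity >= %.2f", len(chains), cfg.min_identity)
    if not chains:
        logger.warning("no chains pass the identity filter; outputs will be empty")
        return PipelineResult([], [], _rejection_frame([]), cfg)

    loci = cluster_chains(chains)
    merge_all_loci(loci, cfg.terminal_flank, genome_lengths)
    pts = [
        build_pseudotranscript(loc, genome, pt_id=f"{cfg.id_prefix}pt-{i}")
        for i, loc in enumerate(loci, start=1)
    ]
    logger.info("%d loci / pseudo-transcripts assembled", len(pts))

    model = train_model(
        pts,
        top_n=cfg.train_top_n,
        order=cfg.markov_order,
        pseudocount=cfg.pseudocount,
        min_len_aa=cfg.min_orf_aa,
    )

    drafts: list[GeneModel] = []
    for pt in pts:
        orfs = enumerate_orfs(pt, min_len_aa=cfg.min_orf_aa, allow_partial=cfg.allow_partial)
        scored = []
        for o in orfs:
            if cfg.start_refine:
                o = refine_start(model, o, min_len_aa=cfg.min_orf_aa)
            o.score = score_orf(model, o.nt)
            scored.append(o)
        retained = select_orfs(scored, min_score=cfg.min_score, min_len_aa=cfg.min_orf_aa)
        genes = split_locus(pt, retained, locus_tag=pt.pt_id.replace("pt-", "locus-"),
                            genome=genome)
        drafts.extend(genes)

    kept, rejected = filter_models(drafts, cfg.min_orf_aa, cfg.min_score)
    final = deduplicate(kept, id_prefix=cfg.id_prefix)
    for g in final:  # three-way consistency is a hard guarantee of every run
        tm = g.transcripts[0]
        cds = extract_spliced_sequence(genome, tm.cds_intervals, tm.strand)
        if translate(cds).internal_stop:
            raise RuntimeError(f"{g.gene_id}: output CDS contains an internal stop")
    logger.info("%d gene models kept (%d rejected, %d after deduplication)",
                len(kept), len(rejected), len(final))
    return PipelineResult(final, pts, _rejection_frame(rejected), cfg)


def _rejection_frame(records: list[dict]) -> pd.DataFrame:
    cols = ["gene_id", "seqid", "start", "end", "criterion", "value", "threshold"]
    return pd.DataFrame(records, columns=cols)


def run_pipeline(
    genome_fasta,
    alignment_gff3,
    out_prefix,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-level pipeline: FASTA + alignment GFF3 in, annotation set out.

    Writes ``<prefix>.gff3``, ``<prefix>.cds.fa``, ``<prefix>.pep.fa``,
    ``<prefix>.stats.tsv`` and ``<prefix>.rejected.tsv``.
    """
    from .stats import compute_stats  # local import to avoid a cycle

    cfg = config or PipelineConfig()
    genome = read_fasta(genome_fasta)
    chains = parse_alignment_gff3(alignment_gff3, identity_key=cfg.identity_key)
    result = annotate(genome, chains, cfg)

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": Path(str(prefix) + ".gff3"),
        "cds": Path(str(prefix) + ".cds.fa"),
        "pep": Path(str(prefix) + ".pep.fa"),
        "stats": Path(str(prefix) + ".stats.tsv"),
        "rejected": Path(str(prefix) + ".rejected.tsv"),
    }
    write_gff3(
        result.genes,
        paths["gff3"],
        header_comments=cfg.header_comments(),
        seqid_order=list(genome),
    )
    cds_records, pep_records = [], []
    for g in result.genes:
        tm = g.transcripts[0]
        cds = extract_spliced_sequence(genome, tm.cds_intervals, tm.strand)
        pep = translate(cds).peptide
        cds_records.append((tm.transcript_id, cds))
        pep_records.append((tm.transcript_id, pep[:-1] if pep.endswith("*") else pep))
    write_fasta(cds_records, paths["cds"])
    write_fasta(pep_records, paths["pep"])

    if result.genes:
        stats = compute_stats(result.genes)
        stats.to_frame().to_csv(paths["stats"], sep="\t", index=False)
    else:
        pd.DataFrame(columns=["metric", "value"]).to_csv(paths["stats"], sep="\t", index=False)
    result.rejections.to_csv(paths["rejected"], sep="\t", index=False)
    result.outputs = paths
    return result
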