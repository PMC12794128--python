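"""ORF enumeration and coding-potential scoring.

Candidate open reading frames are enumerated in the three forward frames of
each pseudo-transcript (the strand is already fixed by the protein
alignment) and scored with a self-trained, frame-periodic 5th-order Markov
log-odds model: for each base, log P(base | preceding 5 bases, codon frame)
under a coding model estimated from the longest complete ORFs, against a
frame-free background estimated from all pseudo-transcript sequence.  This
is the classic hexamer coding statistic used by transcript coding-region
finders, trained on the input data itself so no species-specific model is
needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .pseudotranscript import PseudoTranscript

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN_AA = 100
DEFAULT_ORDER = 5
DEFAULT_TOP_N = 500
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_SCORE = 0.0
DEFAULT_MIN_TRAINING = 50
#: context-count scale of the order-interpolation weight n/(n + ridge):
#: rows with few observations defer to the next-shorter context.
DEFAULT_RIDGE = 100.0

STOP_CODONS = ("TAA", "TAG", "TGA")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class OpenReadingFrame:
    """A candidate coding region in transcript coordinates (1-based, inclusive).

    ``t_end`` includes the stop codon for stop-terminated forms; ``peptide``
    excludes the stop.  ``completeness`` is one of ``complete``,
    ``5prime_partial``, ``3prime_partial``, ``internal``.
    """

    pt_id: str
    t_start: int
    t_end: int
    completeness: str
    peptide: str
    nt: str
    score: float = 0.0

    @property
    def length_nt(self) -> int:
        return self.t_end - self.t_start + 1

    def overlaps(self, other: "OpenReadingFrame") -> bool:
        return self.t_start <= other.t_end and other.t_start <= self.t_end


def _translate_no_stop(nt: str) -> str:
    from .formats import translate

    pep = translate(nt).peptide
    return pep[:-1] if pep.endswith("*") else pep


def enumerate_orfs(
    pt: PseudoTranscript | str,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    allow_partial: bool = True,
    pt_id: str | None = None,
) -> list[OpenReadingFrame]:
    """All maximal ORFs in the three forward frames with peptide >= min_len_aa.

    Within one stop-to-stop segment only the longest ATG-initiated ORF (the
    first ATG) is kept.  Complete ORFs are always reported; ORFs truncated by
    the transcript ends are reported only when ``allow_partial``, labelled
    ``5prime_partial`` (no start, runs from the transcript 5' end to a stop),
    ``3prime_partial`` (ATG but no stop before the 3' end) or ``internal``
    (neither boundary codon inside the transcript).
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    if isinstance(pt, PseudoTranscript):
        seq = pt.sequence.upper()
        name = pt.pt_id
    else:
        seq = pt.upper()
        name = pt_id or "seq"
    n = len(seq)
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        stops = [i for i in codon_starts if seq[i : i + 3] in STOP_CODONS]
        seg_bounds = []  # (first codon start, stop codon start or None)
        prev = frame
        for s in stops:
            seg_bounds.append((prev, s))
            prev = s + 3
        if prev <= n - 3:
            seg_bounds.append((prev, None))
        for idx, (seg_start, stop_at) in enumerate(seg_bounds):
            at_5p_edge = idx == 0  # no upstream in-frame stop
            atg = next(
                (i for i in range(seg_start, (stop_at if stop_at is not None else n - 2), 3)
                 if seq[i : i + 3] == "ATG"),
                None,
            )
            if atg is not None:
                if stop_at is not None:
                    start, end = atg, stop_at + 3
                    completeness = "complete"
                else:
                    end = atg + 3 * ((n - atg) // 3)
                    start = atg
                    completeness = "3prime_partial"
            elif allow_partial and at_5p_edge:
                if stop_at is not None:
                    start, end = seg_start, stop_at + 3
                    completeness = "5prime_partial"
                else:
                    start = seg_start
                    end = seg_start + 3 * ((n - seg_start) // 3)
                    completeness = "internal"
            else:
                continue
            if completeness != "complete" and not allow_partial:
                continue
            if end - start < 3:
                continue
            nt = seq[start:end]
            pep = _translate_no_stop(nt)
            if len(pep) < min_len_aa:
                continue
            orfs.append(
                OpenReadingFrame(
                    pt_id=name,
                    t_start=start + 1,
                    t_end=end,
                    completeness=completeness,
                    peptide=pep,
                    nt=nt,
                )
            )
    orfs.sort(key=lambda o: (o.t_start, o.t_end))
    return orfs


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else to -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


def _count_contexts(seqs: Iterable[str], order: int, framed: bool) -> np.ndarray:
    """Full-order context counts.

    Returns shape (3, 4**order, 4) when framed (frame of the scored base,
    0-based from each sequence start) else (1, 4**order, 4).  Positions whose
    context window contains a non-ACGT character are skipped.
    """
    n_ctx = 4**order
    counts = np.zeros((3 if framed else 1, n_ctx, 4), dtype=np.float64)
    weights = 4 ** np.arange(order - 1, -1, -1, dtype=np.int64)
    for seq in seqs:
        codes = _encode(seq.upper())
        m = len(codes)
        if m <= order:
            continue
        valid = codes >= 0
        # context code for position i is codes[i-order:i] in base 4
        windows = np.lib.stride_tricks.sliding_window_view(codes, order)[:-1]
        ctx_codes = (windows.astype(np.int64) * weights).sum(axis=1)
        ctx_valid = np.lib.stride_tricks.sliding_window_view(valid, order)[:-1].all(axis=1)
        pos = np.arange(order, m)
        ok = ctx_valid & valid[order:]
        frames = (pos % 3) if framed else np.zeros(m - order, dtype=np.int64)
        np.add.at(counts, (frames[ok], ctx_codes[ok], codes[order:][ok]), 1.0)
    return counts


def _marginalize(counts: np.ndarray, order: int) -> list[np.ndarray]:
    """Derive lower-order context counts by summing out leading context bases.

    Returns a list indexed by context length k = 0..order.
    """
    tables = [None] * (order + 1)
    tables[order] = counts
    cur = counts
    for k in range(order - 1, -1, -1):
        nf, n_ctx, _ = cur.shape
        cur = cur.reshape(nf, 4, n_ctx // 4, 4).sum(axis=1)
        tables[k] = cur
    return tables  # type: ignore[return-value]


def _interpolated_probs(
    count_tables: Sequence[np.ndarray], pseudocount: float, ridge: float
) -> list[np.ndarray]:
    """Count-adaptive interpolation across context lengths (IMM-style).

    The order-k conditional for a context is a mixture of its own smoothed
    maximum-likelihood estimate (weight n/(n + ridge), n = context count) and
    the order-(k-1) estimate for the context's suffix.  Sparse contexts thus
    defer to well-estimated shorter ones, which keeps the coding and
    background models comparable even where hexamer counts are thin.
    """
    t0 = count_tables[0] + pseudocount
    probs = [t0 / t0.sum(axis=2, keepdims=True)]
    for k in range(1, len(count_tables)):
        counts = count_tables[k]
        n = counts.sum(axis=2, keepdims=True)
        ml = (counts + pseudocount) / (n + 4.0 * pseudocount)
        lam = n / (n + ridge)
        lower = np.tile(probs[k - 1], (1, 4, 1))  # suffix drops the leading base
        probs.append(lam * ml + (1.0 - lam) * lower)
    return probs


@dataclass
class MarkovCodingModel:
    """Frame-periodic hexamer log-odds model with 5'-end context back-off.

    ``log_odds[k]`` has shape (3, 4**k, 4): log-odds of a base given its k
    preceding bases and its codon frame, for k = 0..order.  Conditional
    probabilities are interpolated across orders by context count (see
    ``_interpolated_probs``).  A zero-information model (``is_zero``) scores
    everything 0, so downstream selection degrades to length-based ranking.
    """

    order: int
    pseudocount: float
    log_odds: list[np.ndarray]
    coding_probs: list[np.ndarray]
    background_probs: list[np.ndarray]
    n_training: int
    is_zero: bool = False

    @classmethod
    def zero(cls, order: int = DEFAULT_ORDER) -> "MarkovCodingModel":
        lo = [np.zeros((3, 4**k, 4)) for k in range(order + 1)]
        flat = [np.full((3, 4**k, 4), 0.25) for k in range(order + 1)]
        return cls(order, 0.0, lo, flat, flat, 0, is_zero=True)

    @classmethod
    def train(
        cls,
        coding_seqs: Sequence[str],
        background_seqs: Sequence[str],
        order: int = DEFAULT_ORDER,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        ridge: float = DEFAULT_RIDGE,
    ) -> "MarkovCodingModel":
        """Estimate log-odds tables from coding and background sequences.

        Coding counts are conditioned on codon frame (position mod 3 from
        each coding sequence's start, which must be a codon boundary);
        background counts are frame-free.  Counts are smoothed by
        ``pseudocount`` per cell and interpolated across orders with weight
        n/(n + ridge).
        """
        c_tables = _marginalize(_count_contexts(coding_seqs, order, framed=True), order)
        b_tables = _marginalize(_count_contexts(background_seqs, order, framed=False), order)
        c_probs = _interpolated_probs(c_tables, pseudocount, ridge)
        b_probs_raw = _interpolated_probs(b_tables, pseudocount, ridge)
        log_odds, b_probs = [], []
        for k in range(len(c_probs)):
            bp = np.broadcast_to(b_probs_raw[k], c_probs[k].shape).copy()
            b_probs.append(bp)
            log_odds.append(np.log(c_probs[k]) - np.log(bp))
        return cls(order, pseudocount, log_odds, c_probs, b_probs, len(coding_seqs))

    def position_scores(self, nt: str, prev_context: str = "", frame_offset: int = 0) -> np.ndarray:
        """Per-base log-odds contributions for ``nt``.

        ``prev_context`` carries bases preceding ``nt`` (for additivity over
        concatenation); ``frame_offset`` is the codon frame of nt's first
        base.  Positions with a non-ACGT base, or whose usable context is
        interrupted by one, back off to the longest clean context suffix.
        """
        out = np.zeros(len(nt))
        if self.is_zero:
            return out
        full = (prev_context + nt).upper()
        codes = _encode(full)
        off = len(prev_context)
        weights = [4 ** np.arange(k - 1, -1, -1, dtype=np.int64) for k in range(self.order + 1)]
        for i in range(off, len(full)):
            base = codes[i]
            if base < 0:
                continue
            frame = (i - off + frame_offset) % 3
            k = min(i, self.order)
            # back off past any non-ACGT character in the context window
            while k > 0 and (codes[i - k : i] < 0).any():
                k -= 1
            ctx = int((codes[i - k : i].astype(np.int64) * weights[k]).sum()) if k else 0
            out[i - off] = self.log_odds[k][frame, ctx, base]
        return out

    def score(self, nt: str, prev_context: str = "", frame_offset: int = 0) -> float:
        """Summed log-odds (nats) of a sequence read in codon frame.

        Additive over in-frame concatenation when the right-hand piece is
        scored with the left piece as ``prev_context`` and the matching
        ``frame_offset``.
        """
        return float(self.position_scores(nt, prev_context, frame_offset).sum())

    def to_tsv(self, path) -> None:
        """Dump full-order log-odds as TSV (frame, context, base, log_odds)."""
        bases = "ACGT"
        k = self.order
        with open(path, "w") as fh:
            fh.write("frame\tcontext\tbase\tlog_odds\n")
            for frame in range(3):
                for ctx in range(4**k):
                    ctx_str = "".join(bases[(ctx >> (2 * (k - 1 - j))) & 3] for j in range(k))
                    for b in range(4):
                        fh.write(
                            f"{frame}\t{ctx_str}\t{bases[b]}\t{self.log_odds[k][frame, ctx, b]:.6f}\n"
                        )


def score_orf(model: MarkovCodingModel, orf_nt: str, prev_context: str = "", frame_offset: int = 0) -> float:
    if len(orf_nt) % 3 != 0:
        raise ValueError(f"ORF length {len(orf_nt)} is not a multiple of 3")
    return model.score(orf_nt, prev_context, frame_offset)


def train_model(
    pts: Sequence[PseudoTranscript],
    top_n: int = DEFAULT_TOP_N,
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    min_training: int = DEFAULT_MIN_TRAINING,
) -> MarkovCodingModel:
    """Self-train the coding model on a set of pseudo-transcripts.

    Positives are the ``top_n`` longest complete ORFs across all
    pseudo-transcripts, deduplicated by exact nucleotide sequence; the
    background is the full pseudo-transcript sequence set.  With fewer than
    ``min_training`` positives a zero-information model is returned (with a
    warning) so selection degrades to length-based ranking.
    """
    if not pts:
        raise ValueError("cannot train on an empty pseudo-transcript set")
    complete = []
    for pt in pts:
        complete.extend(
            o for o in enumerate_orfs(pt, min_len_aa=min_len_aa, allow_partial=False)
            if o.completeness == "complete"
        )
    complete.sort(key=lambda o: (-o.length_nt, o.nt))
    seen: set[str] = set()
    training: list[str] = []
    for o in complete:
        if o.nt not in seen:
            seen.add(o.nt)
            training.append(o.nt)
        if len(training) >= top_n:
            break
    if len(training) < min_training:
        logger.warning(
            "only %d training ORFs (< %d): falling back to zero-information model",
            len(training), min_training,
        )
        return MarkovCodingModel.zero(order)
    background = [pt.sequence for pt in pts]
    return MarkovCodingModel.train(training, background, order=order, pseudocount=pseudocount)


def refine_start(
    model: MarkovCodingModel,
    orf: OpenReadingFrame,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
) -> OpenReadingFrame:
    """Move an ORF's start to the in-frame ATG that maximises the coding score.

    Enumeration keeps the longest (5'-most) ATG-initiated ORF per stop-bounded
    segment, which can absorb upstream non-coding sequence whenever a chance
    in-frame ATG precedes the true start.  This refinement scores every
    candidate start whose resulting peptide still meets ``min_len_aa`` and
    keeps the maximum-score one (ties: 5'-most).  Only ATG-initiated forms are
    refined; partial/internal ORFs without a start are returned unchanged.
    """
    if model.is_zero or orf.completeness not in ("complete", "3prime_partial"):
        return orf
    seq = orf.nt
    contrib = model.position_scores(seq)
    suffix = np.concatenate([contrib[::-1].cumsum()[::-1], [0.0]])
    tail = 3 if orf.completeness == "complete" else 0  # stop codon excluded from peptide
    best_d, best_score = 0, suffix[0]
    for d in range(3, len(seq) - tail - 3 * min_len_aa + 1, 3):
        if seq[d : d + 3] == "ATG" and suffix[d] > best_score:
            best_d, best_score = d, suffix[d]
    if best_d == 0:
        return orf
    new_nt = seq[best_d:]
    return replace(
        orf,
        t_start=orf.t_start + best_d,
        nt=new_nt,
        peptide=_translate_no_stop(new_nt),
    )


def select_orfs(
    orfs: Sequence[OpenReadingFrame],
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
) -> list[OpenReadingFrame]:
    """Greedy non-overlapping ORF selection within one pseudo-transcript.

    ORFs passing both thresholds are taken in order of descending score,
    complete before partial at equal score, then descending length, then
    leftmost start; an ORF is retained iff it does not overlap any
    already-retained ORF in transcript coordinates.  Two or more retained
    ORFs license a downstream gene split.
    """
    passing = [o for o in orfs if o.score >= min_score and len(o.peptide) >= min_len_aa]
    ranked = sorted(
        passing,
        key=lambda o: (-o.score, 0 if o.completeness == "complete" else 1, -o.length_nt, o.t_start),
    )
    kept: list[OpenReadingFrame] = []
    for o in ranked:
        if not any(o.overlaps(k) for k in kept):
            kept.append(o)
    kept.sort(key=lambda o: o.t_start)
    return kept
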