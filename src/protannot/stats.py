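"""Annotation-set statistics and base-level prediction accuracy.

``compute_stats`` reproduces the usual gene-model diagnostics (gene count,
CDS segments per gene, CDS segment length, summed CDS length per gene, and
the mono-/multi-exonic ratio — a fragmentation indicator).  ``base_level_eval``
measures base-level sensitivity (fraction of reference coding bases
recovered) and specificity/precision (fraction of predicted coding bases
that are correct), strand-aware, with F1 as their harmonic mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import GeneModel, longest_isoform


@dataclass
class AnnotationStats:
    gene_count: int
    mean_cds_per_gene: float
    mean_cds_length: float
    mean_cds_length_per_gene: float
    mono_multi_ratio: float  # math.inf when there are no multi-exonic genes
    cds_lengths: list[int]  # per-gene summed CDS length (nt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "gene_count",
                    "mean_cds_per_gene",
                    "mean_cds_length",
                    "mean_cds_length_per_gene",
                    "mono_multi_ratio",
                ],
                "value": [
                    self.gene_count,
                    self.mean_cds_per_gene,
                    self.mean_cds_length,
                    self.mean_cds_length_per_gene,
                    self.mono_multi_ratio,
                ],
            }
        )


@dataclass
class EvaluationResult:
    sensitivity: float
    specificity: float
    f1: float
    tp_bases: int
    ref_bases: int
    pred_bases: int
    undefined_specificity: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["tp_bases", "ref_bases", "pred_bases",
                           "sensitivity", "specificity", "f1"],
                "value": [self.tp_bases, self.ref_bases, self.pred_bases,
                          self.sensitivity, self.specificity, self.f1],
            }
        )


def compute_stats(genes: Sequence[GeneModel]) -> AnnotationStats:
    """Gene-model statistics over an annotation reduced to longest isoforms."""
    if not genes:
        raise ValueError("no genes in annotation")
    if any(len(g.transcripts) > 1 for g in genes):
        genes = longest_isoform(genes)
    seg_counts = [len(g.transcripts[0].cds_intervals) for g in genes]
    cds_lengths = [g.transcripts[0].cds_length for g in genes]
    total_segments = sum(seg_counts)
    total_nt = sum(cds_lengths)
    mono = sum(1 for c in seg_counts if c == 1)
    multi = len(genes) - mono
    if multi == 0:
        warnings.warn("no multi-exonic genes: mono/multi ratio is infinite", stacklevel=2)
        ratio = math.inf
    else:
        ratio = mono / multi
    return AnnotationStats(
        gene_count=len(genes),
        mean_cds_per_gene=total_segments / len(genes),
        mean_cds_length=total_nt / total_segments,
        mean_cds_length_per_gene=total_nt / len(genes),
        mono_multi_ratio=ratio,
        cds_lengths=cds_lengths,
    )


def _merged_intervals(genes: Sequence[GeneModel]) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Per (seqid, strand): the merged union of all CDS intervals."""
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes:
        for tm in g.transcripts:
            for iv in tm.cds_intervals:
                raw.setdefault((iv.seqid, iv.strand), []).append((iv.start, iv.end))
    merged = {}
    for key, ivs in raw.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[key] = [(s, e) for s, e in out]
    return merged


def _intersect_total(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def base_level_eval(pred: Sequence[GeneModel], ref: Sequence[GeneModel]) -> EvaluationResult:
    """Strand-aware base-level sensitivity/specificity of pred against ref.

    A genome base counts as coding on a strand if covered by at least one
    CDS on that strand; bases coding on both strands count once per strand.
    The denominator is whole-genome (reference loci on contigs absent from
    the prediction still count against sensitivity).
    """
    pred_merged = _merged_intervals(pred)
    ref_merged = _merged_intervals(ref)
    pred_bases = sum(e - s + 1 for ivs in pred_merged.values() for s, e in ivs)
    ref_bases = sum(e - s + 1 for ivs in ref_merged.values() for s, e in ivs)
    tp = sum(
        _intersect_total(pred_merged[key], ref_merged[key])
        for key in pred_merged.keys() & ref_merged.keys()
    )
    sensitivity = tp / ref_bases if ref_bases else 0.0
    if pred_bases == 0:
        warnings.warn("no predicted coding bases: specificity undefined", stacklevel=2)
        return EvaluationResult(
            sensitivity=0.0, specificity=math.nan, f1=0.0,
            tp_bases=tp, ref_bases=ref_bases, pred_bases=0,
            undefined_specificity=True,
        )
    specificity = tp / pred_bases
    return EvaluationResult(
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1(sensitivity, specificity),
        tp_bases=tp,
        ref_bases=ref_bases,
        pred_bases=pred_bases,
    )


def f1(sensitivity: float, specificity: float) -> float:
    """Harmonic mean: 2·Sn·Sp / (Sn + Sp); defined as 0 when both are 0."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0,1]")
    if sensitivity == 0.0 and specificity == 0.0:
        warnings.warn("both sensitivity and specificity are 0; F1 defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


def length_distribution(genes: Sequence[GeneModel], bin_width: int) -> pd.DataFrame:
    """Histogram of per-gene summed CDS length; counts sum to the gene count."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not genes:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lengths = np.array([g.transcripts[0].cds_length for g in longest_isoform(genes)])
    bins = lengths // bin_width
    idx, counts = np.unique(bins, return_counts=True)
    return pd.DataFrame(
        {
            "bin_start": idx * bin_width,
            "bin_end": (idx + 1) * bin_width - 1,
            "count": counts,
        }
    )
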