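"""Annotation edit distance (AED) between a candidate transcript and an
assembled evidence transcript.

AED = 1 − (SN + SP)/2 at single-base exon-level congruence, where
SN = shared exonic bases / evidence exonic bases and
SP = shared exonic bases / candidate exonic bases.  Scores range from 0
(base-identical exon chains) to 1 (no exonic overlap).

Because shallow samples often assemble only part of a transcript, the
clipped variant first restricts the candidate to the genomic span of the
evidence, forgiving missing terminal exons while still penalizing
internal structure disagreements such as retained introns.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import (
    AssembledTranscript,
    TranscriptModel,
    clip_to_span,
    intersection_length,
    interval_union_length,
)

__all__ = ["AedScore", "aed", "clipped_aed"]


@dataclass(frozen=True)
class AedScore:
    value: float
    sn: float
    sp: float
    clipped: bool = False
    strand_mismatch: bool = False


def _strand_compatible(candidate: TranscriptModel, evidence: AssembledTranscript) -> bool:
    return evidence.strand == "." or evidence.strand == candidate.strand


def _score(cand_exons, ev_exons, clipped: bool) -> AedScore:
    cand_len = interval_union_length(cand_exons)
    ev_len = interval_union_length(ev_exons)
    if cand_len == 0 or ev_len == 0:
        return AedScore(value=1.0, sn=0.0, sp=0.0, clipped=clipped)
    shared = intersection_length(cand_exons, ev_exons)
    sn = shared / ev_len
    sp = shared / cand_len
    return AedScore(value=1.0 - (sn + sp) / 2.0, sn=sn, sp=sp, clipped=clipped)


def aed(candidate: TranscriptModel, evidence: AssembledTranscript) -> AedScore:
    """Exon-level AED between a candidate and an evidence transcript.

    Raises on mismatched chromosomes; an incompatible strand yields a
    score of exactly 1 with the ``strand_mismatch`` flag set.
    """
    if candidate.chrom != evidence.chrom:
        raise ValueError(
            f"candidate on {candidate.chrom}, evidence on {evidence.chrom}"
        )
    if not _strand_compatible(candidate, evidence):
        return AedScore(value=1.0, sn=0.0, sp=0.0, strand_mismatch=True)
    return _score(list(candidate.exons), list(evidence.exons), clipped=False)


def clipped_aed(candidate: TranscriptModel, evidence: AssembledTranscript) -> AedScore:
    """AED with the candidate restricted to the evidence's genomic span.

    Candidate exons are intersected with ``[min start, max end)`` of the
    evidence exon chain before scoring.  If clipping empties the
    candidate, the score is 1.
    """
    if candidate.chrom != evidence.chrom:
        raise ValueError(
            f"candidate on {candidate.chrom}, evidence on {evidence.chrom}"
        )
    if not _strand_compatible(candidate, evidence):
        return AedScore(value=1.0, sn=0.0, sp=0.0, clipped=True, strand_mismatch=True)
    span_start, span_end = evidence.span
    clipped_exons = clip_to_span(candidate.exons, span_start, span_end)
    return _score(clipped_exons, list(evidence.exons), clipped=True)
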