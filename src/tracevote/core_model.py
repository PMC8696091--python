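"""Domain types and interval arithmetic shared by all other modules.

All coordinates are 0-based half-open ``[start, end)``; the GFF3/GTF
readers convert from the 1-based closed convention at the I/O boundary.
Half-open arithmetic makes adjacency unambiguous: ``[0,10)`` and
``[10,20)`` share no base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneLocus",
    "AssembledTranscript",
    "DomainHit",
    "interval_union_length",
    "intersection_length",
    "merge_intervals",
    "clip_to_span",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on one strand of one sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise TypeError("interval coordinates must be integers")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval [{self.start},{self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _check_single_chrom(intervals: Iterable[GenomicInterval]) -> None:
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple sequences: {sorted(chroms)}")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals into a disjoint sorted list."""
    _check_single_chrom(intervals)
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[tuple[int, int]] = [(ivs[0].start, ivs[0].end)]
    for iv in ivs[1:]:
        s, e = merged[-1]
        if iv.start <= e:
            merged[-1] = (s, max(e, iv.end))
        else:
            merged.append((iv.start, iv.end))
    chrom, strand = ivs[0].chrom, ivs[0].strand
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def interval_union_length(intervals: Sequence[GenomicInterval]) -> int:
    """Number of distinct bases covered by at least one interval."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersection_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Number of bases covered by both interval unions (symmetric in a, b)."""
    _check_single_chrom(list(a) + list(b))
    ma, mb = merge_intervals(a), merge_intervals(b)
    i = j = shared = 0
    while i < len(ma) and j < len(mb):
        lo = max(ma[i].start, mb[j].start)
        hi = min(ma[i].end, mb[j].end)
        if hi > lo:
            shared += hi - lo
        if ma[i].end <= mb[j].end:
            i += 1
        else:
            j += 1
    return shared


def clip_to_span(
    intervals: Sequence[GenomicInterval], span_start: int, span_end: int
) -> list[GenomicInterval]:
    """Intersect intervals with the span ``[span_start, span_end)``."""
    out = []
    for iv in intervals:
        s, e = max(iv.start, span_start), min(iv.end, span_end)
        if s < e:
            out.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    return out


def _sorted_disjoint(intervals: Sequence[GenomicInterval], what: str) -> tuple:
    ivs = tuple(sorted(intervals, key=lambda iv: (iv.start, iv.end)))
    for prev, cur in zip(ivs, ivs[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"{what} overlap: [{prev.start},{prev.end}) and "
                f"[{cur.start},{cur.end})"
            )
    return ivs


@dataclass(frozen=True)
class TranscriptModel:
    """A candidate reference transcript: exon/CDS structure and lengths.

    ``cds_includes_stop`` records the annotation dialect: when True
    (Ensembl-style) and the CDS length is a multiple of 3, one residue
    (the stop) is excluded from ``protein_length``.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    cds_includes_stop: bool = True

    def __init__(
        self,
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        cds: Sequence[GenomicInterval] = (),
        cds_includes_stop: bool = True,
    ) -> None:
        if not exons:
            raise ValueError(f"transcript {transcript_id} has no exons")
        _check_single_chrom(exons)
        if len({iv.strand for iv in exons}) > 1:
            raise ValueError(f"transcript {transcript_id} has exons on both strands")
        exon_t = _sorted_disjoint(exons, f"exons of {transcript_id}")
        cds_t = tuple(sorted(cds, key=lambda iv: (iv.start, iv.end)))
        for c in cds_t:
            if intersection_length([c], list(exon_t)) != len(c):
                warnings.warn(
                    f"CDS [{c.start},{c.end}) of {transcript_id} extends outside "
                    "the exon footprint",
                    stacklevel=2,
                )
        object.__setattr__(self, "transcript_id", transcript_id)
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(self, "exons", exon_t)
        object.__setattr__(self, "cds", cds_t)
        object.__setattr__(self, "cds_includes_stop", cds_includes_stop)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    @property
    def protein_length(self) -> int:
        """Residues encoded by the CDS, excluding the stop codon when the
        dialect includes it and the CDS is a whole number of codons."""
        n = self.cds_length
        if n == 0:
            return 0
        residues = n // 3
        if self.cds_includes_stop and n % 3 == 0:
            residues -= 1
        return max(residues, 0)


@dataclass(frozen=True)
class GeneLocus:
    """A gene with its candidate transcripts and their merged exon footprint."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __init__(self, gene_id: str, transcripts: Sequence[TranscriptModel]) -> None:
        if not transcripts:
            raise ValueError(f"locus {gene_id} has no transcripts")
        for t in transcripts:
            if t.gene_id != gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} belongs to {t.gene_id}, "
                    f"not {gene_id}"
                )
        chroms = {t.chrom for t in transcripts}
        strands = {t.strand for t in transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"locus {gene_id} mixes chromosomes or strands")
        ts = tuple(sorted(transcripts, key=lambda t: t.transcript_id))
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(self, "transcripts", ts)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def exon_footprint(self) -> list[GenomicInterval]:
        """Union of all candidate exon intervals."""
        all_exons = [iv for t in self.transcripts for iv in t.exons]
        return merge_intervals(all_exons)

    @property
    def is_multi_transcript(self) -> bool:
        return len(self.transcripts) > 1

    def get(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class AssembledTranscript:
    """A sample-specific assembled transcript with TPM expression."""

    sample_id: str
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    tpm: float
    strand: str = "."

    def __init__(
        self,
        sample_id: str,
        transcript_id: str,
        exons: Sequence[GenomicInterval],
        tpm: float,
        strand: str = ".",
    ) -> None:
        if not exons:
            raise ValueError(f"assembly {transcript_id} has no exons")
        _check_single_chrom(exons)
        if tpm < 0:
            raise ValueError(f"negative TPM {tpm} for {transcript_id}")
        if strand not in _STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        exon_t = _sorted_disjoint(exons, f"exons of {transcript_id}")
        object.__setattr__(self, "sample_id", sample_id)
        object.__setattr__(self, "transcript_id", transcript_id)
        object.__setattr__(self, "exons", exon_t)
        object.__setattr__(self, "tpm", float(tpm))
        object.__setattr__(self, "strand", strand)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [min start, max end) of the exon chain."""
        return self.exons[0].start, self.exons[-1].end


@dataclass(frozen=True)
class DomainHit:
    """A Pfam domain match on a reference protein, 1-based closed residues."""

    protein_id: str
    start_aa: int
    end_aa: int
    db: str = "Pfam"
    accession: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"invalid residue range {self.start_aa}-{self.end_aa} "
                f"on {self.protein_id}"
            )
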