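"""Electorate construction for one gene locus.

Each RNA-seq sample casts at most one ballot: its assemblies are filtered
on expression (TPM), exonic overlap with the locus footprint, and strand;
the surviving top-TPM assembly ranks the candidate transcripts by clipped
AED, with an AED ceiling beyond which a candidate receives no vote.  Three
length-based voters rank all candidates by Pfam domain coverage, protein
length and spliced transcript length.  With many samples, sample weights
are scaled down so the sample electorate cannot overwhelm the length
voters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import yaml

from .aed import clipped_aed
from .core_model import (
    AssembledTranscript,
    DomainHit,
    GeneLocus,
    TranscriptModel,
    intersection_length,
    interval_union_length,
)

__all__ = [
    "Ballot",
    "TraceConfig",
    "assign_assemblies",
    "sample_ballot",
    "domain_coverage",
    "length_ballots",
    "balance_weights",
    "dense_ranks",
]

DOMAIN_VOTER = "domain_coverage"
PROTEIN_VOTER = "protein_length"
TRANSCRIPT_VOTER = "transcript_length"


@dataclass(frozen=True)
class Ballot:
    """One voter's weighted, possibly partial, possibly tied ranking.

    ``ranking`` maps candidate transcript ids to dense ranks (1 = best;
    tied candidates share a rank; absent candidates receive no vote from
    this ballot at any level).
    """

    voter_id: str
    weight: float
    ranking: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"ballot {self.voter_id} has non-positive weight")
        if not self.ranking:
            raise ValueError(f"ballot {self.voter_id} ranks no candidates")
        levels = set(self.ranking.values())
        if levels != set(range(1, len(levels) + 1)):
            raise ValueError(
                f"ballot {self.voter_id} ranks are not dense: {sorted(levels)}"
            )

    @property
    def depth(self) -> int:
        return max(self.ranking.values())


@dataclass(frozen=True)
class TraceConfig:
    """Thresholds, voter weights and balancing parameters.

    max_aed
        ceiling on clipped AED for a sample to vote for a candidate.
    min_tpm
        minimum expression for an assembly to count as evidence.
    min_overlap
        minimum fraction of an assembly's exonic bases that must fall in
        the locus exon footprint.
    weight_domain / weight_protein / weight_transcript
        votes carried by the three length-criteria voters (defaults 9/6/3
        prioritize functional domain coverage over raw length).
    balance_factor
        total sample weight is capped at balance_factor x total length
        weight; with defaults each sample keeps weight 1 up to 18 samples.
    cds_includes_stop
        annotation dialect flag for protein-length computation.
    """

    max_aed: float = 0.5
    min_tpm: float = 0.5
    min_overlap: float = 0.5
    weight_domain: float = 9.0
    weight_protein: float = 6.0
    weight_transcript: float = 3.0
    balance_factor: float = 1.0
    tpm_attribute: str = "TPM"
    cds_includes_stop: bool = True
    tie_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("max_aed", "min_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be non-negative")
        for name in ("weight_domain", "weight_protein", "weight_transcript",
                     "balance_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_length_weight(self) -> float:
        return self.weight_domain + self.weight_protein + self.weight_transcript

    @classmethod
    def from_file(cls, path: str) -> "TraceConfig":
        """Load overrides from a YAML (or flat key: value) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must map keys to values")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def dense_ranks(
    scored: Sequence[tuple[str, float]], *, descending: bool, tolerance: float = 0.0
) -> dict[str, int]:
    """Assign dense ranks (1,1,2,...) to (id, score) pairs.

    Scores within ``tolerance`` of the first member of the current tie
    group share its rank.  Ids break ordering ties deterministically but
    never affect rank assignment.
    """
    if not scored:
        return {}
    sign = -1.0 if descending else 1.0
    ordered = sorted(scored, key=lambda kv: (sign * kv[1], kv[0]))
    ranks: dict[str, int] = {}
    rank = 1
    group_score = ordered[0][1]
    for ident, score in ordered:
        if abs(score - group_score) > tolerance:
            rank += 1
            group_score = score
        ranks[ident] = rank
    return ranks


def assign_assemblies(
    locus: GeneLocus,
    assemblies: Sequence[AssembledTranscript],
    cfg: TraceConfig,
) -> list[AssembledTranscript]:
    """Filter one sample's assemblies down to usable evidence for a locus.

    Keeps assemblies that are strand-compatible with the locus, expressed
    at >= cfg.min_tpm, and whose exonic bases overlap the locus exon
    footprint at fraction >= cfg.min_overlap (boundaries inclusive).
    """
    footprint = locus.exon_footprint
    kept = []
    for asm in assemblies:
        if asm.chrom != locus.chrom:
            continue
        if asm.strand not in (".", locus.strand):
            continue
        if asm.tpm < cfg.min_tpm:
            continue
        frac = intersection_length(list(asm.exons), footprint) / interval_union_length(
            list(asm.exons)
        )
        if frac >= cfg.min_overlap:
            kept.append(asm)
    return kept


def sample_ballot(
    locus: GeneLocus,
    sample_assemblies: Sequence[AssembledTranscript],
    sample_id: str,
    cfg: TraceConfig,
    candidates: Optional[Sequence[TranscriptModel]] = None,
) -> Optional[Ballot]:
    """Build one sample's ballot from its most highly expressed evidence.

    The top-TPM assembly scores every candidate by clipped AED; if
    several assemblies tie for top TPM each candidate takes its minimum
    score over the tied set.  Candidates above cfg.max_aed get no vote.
    Returns None (abstention) when no evidence or no candidate survives.
    """
    if candidates is None:
        candidates = [t for t in locus.transcripts if t.is_coding]
    if not sample_assemblies or not candidates:
        return None
    top_tpm = max(a.tpm for a in sample_assemblies)
    evidence = [
        a for a in sample_assemblies if abs(a.tpm - top_tpm) <= cfg.tie_tolerance
    ]
    scored = []
    for cand in candidates:
        score = min(clipped_aed(cand, ev).value for ev in evidence)
        if score <= cfg.max_aed:
            scored.append((cand.transcript_id, score))
    if not scored:
        return None
    ranking = dense_ranks(scored, descending=False, tolerance=cfg.tie_tolerance)
    return Ballot(voter_id=sample_id, weight=1.0, ranking=ranking)


def domain_coverage(t: TranscriptModel, hits: Sequence[DomainHit]) -> int:
    """Distinct residues of t's protein covered by at least one domain hit."""
    plen = t.protein_length
    if plen == 0:
        return 0
    covered = set()
    for h in hits:
        if h.end_aa > plen:
            warnings.warn(
                f"domain hit {h.accession or h.protein_id} ends at residue "
                f"{h.end_aa} beyond protein length {plen}; clamping",
                stacklevel=2,
            )
        start = h.start_aa
        end = min(h.end_aa, plen)
        if start <= end:
            covered.update(range(start, end + 1))
    return len(covered)


def length_ballots(
    locus: GeneLocus,
    hits: Mapping[str, Sequence[DomainHit]],
    cfg: TraceConfig,
    candidates: Optional[Sequence[TranscriptModel]] = None,
) -> list[Ballot]:
    """The three length-criteria ballots over all candidates.

    ``hits`` maps protein ids (taken equal to transcript ids) to their
    Pfam matches.
    """
    if candidates is None:
        candidates = [t for t in locus.transcripts if t.is_coding]
    if not candidates:
        return []
    specs = [
        (DOMAIN_VOTER, cfg.weight_domain,
         lambda t: float(domain_coverage(t, hits.get(t.transcript_id, ())))),
        (PROTEIN_VOTER, cfg.weight_protein, lambda t: float(t.protein_length)),
        (TRANSCRIPT_VOTER, cfg.weight_transcript, lambda t: float(t.spliced_length)),
    ]
    ballots = []
    for voter_id, weight, metric in specs:
        scored = [(t.transcript_id, metric(t)) for t in candidates]
        ranking = dense_ranks(scored, descending=True)
        ballots.append(Ballot(voter_id=voter_id, weight=weight, ranking=ranking))
    return ballots


def balance_weights(
    sample_ballots: Sequence[Ballot], cfg: TraceConfig
) -> list[Ballot]:
    """Scale sample ballot weights to balance the electorate.

    Each of the S non-abstaining samples gets weight
    min(1, balance_factor x total_length_weight / S): samples keep one
    vote each until their combined weight would exceed balance_factor
    times the length voters' combined weight, beyond which the total is
    capped.
    """
    s = len(sample_ballots)
    if s == 0:
        return []
    w = min(1.0, cfg.balance_factor * cfg.total_length_weight / s)
    return [replace(b, weight=w) for b in sample_ballots]
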