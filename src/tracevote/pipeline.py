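"""End-to-end orchestration: read inputs, hold per-gene elections, write outputs.

For every reference gene locus with two or more protein-coding
candidates, each RNA-seq sample contributes a ballot derived from its
most highly expressed overlapping assembly (clipped AED, filtered on
TPM, overlap fraction and an AED ceiling), the three length-criteria
voters are added, sample weights are balanced, and a multi-round
ranked-choice election orders the candidates.  Single-candidate loci
are trivially canonical; non-coding siblings are ranked last and
flagged.  Gene-by-gene processing is independent and output is ordered
by gene id, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .annotation_io import (
    read_interproscan_tsv,
    read_reference_gff3,
    read_sample_manifest,
    read_stringtie_gtf,
    write_canonical_gff3,
    write_rank_table,
)
from .balloting import (
    TraceConfig,
    assign_assemblies,
    balance_weights,
    domain_coverage,
    length_ballots,
    sample_ballot,
)
from .core_model import AssembledTranscript, DomainHit, GeneLocus
from .election import ElectionRecord, run_election

logger = logging.getLogger(__name__)

__all__ = ["RunSummary", "run_trace", "elect_locus"]


@dataclass(frozen=True)
class RunSummary:
    genes_total: int
    genes_multi_transcript: int
    genes_canonical_not_longest: int
    fraction_canonical_not_longest: float
    mean_samples_voting: float
    abstentions_by_sample: dict[str, int]

    def __post_init__(self) -> None:
        if not (
            self.genes_canonical_not_longest
            <= self.genes_multi_transcript
            <= self.genes_total
        ):
            raise ValueError("inconsistent summary counts")

    def to_dict(self) -> dict:
        return {
            "genes_total": self.genes_total,
            "genes_multi_transcript": self.genes_multi_transcript,
            "genes_canonical_not_longest": self.genes_canonical_not_longest,
            "fraction_canonical_not_longest": self.fraction_canonical_not_longest,
            "mean_samples_voting": self.mean_samples_voting,
            "abstentions_by_sample": self.abstentions_by_sample,
        }


def _tiebreak_key_for(locus: GeneLocus, hits: Mapping[str, Sequence[DomainHit]]):
    """Deterministic last-resort tie-break mirroring the voter priority:
    wider domain coverage, then longer protein, then longer transcript,
    then lexicographic id."""
    stats = {}
    for t in locus.transcripts:
        cov = domain_coverage(t, hits.get(t.transcript_id, ()))
        stats[t.transcript_id] = (-cov, -t.protein_length, -t.spliced_length)

    def key(tid: str) -> tuple:
        return stats[tid] + (tid,)

    return key


def elect_locus(
    locus: GeneLocus,
    assemblies_by_sample: Mapping[str, Sequence[AssembledTranscript]],
    hits: Mapping[str, Sequence[DomainHit]],
    cfg: TraceConfig,
) -> tuple[ElectionRecord, int, list[str]]:
    """Run one locus's election.

    Returns the record, the number of samples that voted, and the ids of
    abstaining samples.
    """
    coding = [t for t in locus.transcripts if t.is_coding]
    noncoding = sorted(
        (t for t in locus.transcripts if not t.is_coding),
        key=lambda t: (-t.spliced_length, t.transcript_id),
    )
    nc_ids = tuple(t.transcript_id for t in noncoding)

    if len(coding) < 2:
        order = tuple(t.transcript_id for t in coding) + nc_ids
        return (
            ElectionRecord(
                gene_id=locus.gene_id, order=order, rounds=(), trivial=True,
                noncoding=nc_ids,
            ),
            0,
            [],
        )

    ballots = []
    abstained = []
    for sid, sample_assemblies in assemblies_by_sample.items():
        kept = assign_assemblies(locus, sample_assemblies, cfg)
        b = sample_ballot(locus, kept, sid, cfg, candidates=coding)
        if b is None:
            abstained.append(sid)
        else:
            ballots.append(b)
    voted = len(ballots)
    ballots = balance_weights(ballots, cfg)
    ballots += length_ballots(locus, hits, cfg, candidates=coding)

    rec = run_election(
        ballots,
        [t.transcript_id for t in coding],
        tiebreak_key=_tiebreak_key_for(locus, hits),
        gene_id=locus.gene_id,
        tie_tolerance=cfg.tie_tolerance,
    )
    rec = ElectionRecord(
        gene_id=rec.gene_id,
        order=rec.order + nc_ids,
        rounds=rec.rounds,
        trivial=False,
        noncoding=nc_ids,
    )
    return rec, voted, abstained


def run_trace(
    cfg: TraceConfig,
    gff_path: str | Path,
    manifest_path: str | Path,
    iprscan_path: str | Path,
    out_prefix: str | Path,
) -> RunSummary:
    """Full run: elections for every locus plus rank/annotation/summary outputs.

    Writes ``<prefix>.ranks.tsv``, ``<prefix>.canonical.gff3`` and
    ``<prefix>.summary.json``.
    """
    loci = read_reference_gff3(gff_path, cds_includes_stop=cfg.cds_includes_stop)
    manifest = read_sample_manifest(manifest_path)
    assemblies_by_sample = {
        sid: read_stringtie_gtf(path, sid, cfg.tpm_attribute)
        for sid, path in manifest
    }

    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in read_interproscan_tsv(iprscan_path):
        hits_by_protein.setdefault(h.protein_id, []).append(h)

    records: list[ElectionRecord] = []
    votes_per_locus: list[int] = []
    abstentions: dict[str, int] = {sid: 0 for sid, _ in manifest}
    samples_with_votes: set[str] = set()

    for locus in sorted(loci, key=lambda l: l.gene_id):
        rec, voted, abstained = elect_locus(
            locus, assemblies_by_sample, hits_by_protein, cfg
        )
        records.append(rec)
        if not rec.trivial:
            votes_per_locus.append(voted)
            for sid in abstained:
                abstentions[sid] += 1
            voted_sids = set(assemblies_by_sample) - set(abstained)
            samples_with_votes |= voted_sids
            if abstained:
                logger.info(
                    "gene %s: %d/%d samples abstained",
                    locus.gene_id, len(abstained), len(assemblies_by_sample),
                )

    for sid in assemblies_by_sample:
        if sid not in samples_with_votes and votes_per_locus:
            logger.warning("sample %s cast no votes at any locus", sid)

    by_gene = {l.gene_id: l for l in loci}
    multi = [l for l in loci if l.is_multi_transcript]
    not_longest = 0
    for rec in records:
        locus = by_gene[rec.gene_id]
        if not locus.is_multi_transcript:
            continue
        longest = max(t.spliced_length for t in locus.transcripts)
        if locus.get(rec.order[0]).spliced_length < longest:
            not_longest += 1

    summary = RunSummary(
        genes_total=len(loci),
        genes_multi_transcript=len(multi),
        genes_canonical_not_longest=not_longest,
        fraction_canonical_not_longest=(not_longest / len(multi)) if multi else 0.0,
        mean_samples_voting=(
            sum(votes_per_locus) / len(votes_per_locus) if votes_per_locus else 0.0
        ),
        abstentions_by_sample=abstentions,
    )

    prefix = str(out_prefix)
    write_rank_table(records, f"{prefix}.ranks.tsv")
    write_canonical_gff3(loci, {r.gene_id: r for r in records}, f"{prefix}.canonical.gff3")
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
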