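"""Shared test utilities: independent brute-force oracles and random
input generators.

The oracles here deliberately avoid the package's interval-merge and
tally code paths: AED is recomputed by classifying every base in the
joint span, and elections are re-run with from-scratch cumulative
totals, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import random
from typing import Sequence

from tracevote.balloting import Ballot
from tracevote.core_model import AssembledTranscript, GenomicInterval, TranscriptModel

TIE_TOL = 1e-9


def make_transcript(
    pairs: Sequence[tuple[int, int]],
    tid: str = "t1",
    gid: str = "g1",
    chrom: str = "chr1",
    strand: str = "+",
    cds: Sequence[tuple[int, int]] = (),
    cds_includes_stop: bool = True,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in pairs],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds],
        cds_includes_stop=cds_includes_stop,
    )


def make_assembly(
    pairs: Sequence[tuple[int, int]],
    tid: str = "a1",
    sample: str = "s1",
    chrom: str = "chr1",
    strand: str = ".",
    tpm: float = 10.0,
) -> AssembledTranscript:
    return AssembledTranscript(
        sample_id=sample,
        transcript_id=tid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in pairs],
        tpm=tpm,
        strand=strand,
    )


def bases(pairs: Sequence[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in pairs:
        out.update(range(s, e))
    return out


def brute_force_aed(
    cand: Sequence[tuple[int, int]], ev: Sequence[tuple[int, int]]
) -> float:
    """Per-base AED: classify every base as shared/candidate-only/evidence-only."""
    cb, eb = bases(cand), bases(ev)
    if not cb or not eb:
        return 1.0
    shared = len(cb & eb)
    sn = shared / len(eb)
    sp = shared / len(cb)
    return 1.0 - (sn + sp) / 2.0


def brute_force_clipped_aed(
    cand: Sequence[tuple[int, int]], ev: Sequence[tuple[int, int]]
) -> float:
    """Per-base clipped AED: candidate bases restricted to the evidence span."""
    span_lo = min(s for s, _ in ev)
    span_hi = max(e for _, e in ev)
    cb = {b for b in bases(cand) if span_lo <= b < span_hi}
    eb = bases(ev)
    if not cb:
        return 1.0
    shared = len(cb & eb)
    return 1.0 - (shared / len(eb) + shared / len(cb)) / 2.0


def random_exon_chain(
    rng: random.Random, max_coord: int = 10_000, max_exons: int = 6
) -> list[tuple[int, int]]:
    """Sorted, strictly disjoint half-open intervals within [0, max_coord)."""
    n = rng.randint(1, max_exons)
    points = rng.sample(range(max_coord), 2 * n)
    points.sort()
    chain = []
    for i in range(0, 2 * n, 2):
        if points[i] < points[i + 1]:
            chain.append((points[i], points[i + 1]))
    if not chain:
        chain = [(points[0], points[0] + 1)]
    return chain


def oracle_election(
    ballots: Sequence[Ballot],
    candidates: Sequence[str],
    tiebreak_key=lambda c: (c,),
) -> list[str]:
    """Naive re-implementation of the multi-round tally rules.

    Cumulative totals are recomputed from scratch at every depth k as
    'sum of ballot weights whose original rank for c is <= k', rather
    than by incrementally adding levels.
    """
    max_depth = max((max(b.ranking.values()) for b in ballots), default=1)
    remaining = sorted(candidates)
    order = []
    while remaining:
        winner = None
        for k in range(1, max_depth + 1):
            totals = {
                c: sum(
                    b.weight
                    for b in ballots
                    if b.ranking.get(c) is not None and b.ranking[c] <= k
                )
                for c in remaining
            }
            top = max(totals.values())
            leaders = [c for c in remaining if totals[c] >= top - TIE_TOL]
            if len(leaders) == 1:
                winner = leaders[0]
                break
        if winner is None:
            winner = min(leaders, key=tiebreak_key)
        order.append(winner)
        remaining.remove(winner)
    return order


def random_election(
    rng: random.Random,
) -> tuple[list[str], list[Ballot]]:
    """Random small election: <=4 candidates, <=8 ballots, integer
    weights <=9, random ties and abstentions."""
    n_cand = rng.randint(1, 4)
    candidates = [f"c{i}" for i in range(n_cand)]
    ballots = []
    for b in range(rng.randint(0, 8)):
        subset = [c for c in candidates if rng.random() < 0.8]
        if not subset:
            continue
        rng.shuffle(subset)
        ranking = {}
        rank = 1
        for i, c in enumerate(subset):
            if i > 0 and rng.random() < 0.35:
                pass  # tie with previous
            elif i > 0:
                rank += 1
            ranking[c] = rank
        ballots.append(
            Ballot(voter_id=f"v{b}", weight=float(rng.randint(1, 9)), ranking=ranking)
        )
    return candidates, ballots
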