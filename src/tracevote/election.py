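"""Multi-round ranked-choice election with tie-escalation tallying.

Each round elects one winner from the remaining candidates.  The tally
starts with every ballot's weight at rank level 1; while two or more
candidates share the maximal cumulative tally, the next rank level's
votes are added.  Rank levels are the ORIGINAL ballot positions: when a
winner is removed from contention, the other candidates keep the ranks
they were given at ballot construction (no re-compaction, no vote
transfer).  Elected winners are removed and the rounds repeat until all
candidates are ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .balloting import Ballot

__all__ = ["RoundDetail", "ElectionRecord", "tally_at_level", "elect_one",
           "run_election", "lexicographic_tiebreak"]

TiebreakKey = Callable[[str], tuple]


def lexicographic_tiebreak(candidate_id: str) -> tuple:
    """Fallback tie-break: smallest transcript id wins."""
    return (candidate_id,)


@dataclass(frozen=True)
class RoundDetail:
    """Outcome of one election round.

    ``level_tallies[k]`` holds the weight each remaining candidate
    received at original rank level k+1; ``cumulative`` is their sum over
    all levels tallied before the round resolved.
    """

    winner: str
    cumulative: dict[str, float]
    level_tallies: tuple[dict[str, float], ...]
    level_reached: int
    tiebreak_used: bool

    def added_at_level(self, k: int) -> dict[str, float]:
        """Weights added at rank level k (1-based)."""
        return self.level_tallies[k - 1]


@dataclass(frozen=True)
class ElectionRecord:
    """Full per-gene outcome: winner order and per-round detail.

    ``order`` lists every transcript of the locus, coding candidates in
    election order followed by any non-coding siblings (in ``noncoding``,
    always ranked last).  ``trivial`` marks loci that needed no election
    (fewer than two coding candidates); such records carry no rounds.
    """

    gene_id: str
    order: tuple[str, ...]
    rounds: tuple[RoundDetail, ...]
    trivial: bool = False
    noncoding: tuple[str, ...] = ()

    @property
    def canonical(self) -> str:
        return self.order[0]

    @property
    def tiebreak_used(self) -> bool:
        return any(r.tiebreak_used for r in self.rounds)

    def rank_of(self, transcript_id: str) -> int:
        return self.order.index(transcript_id) + 1


def tally_at_level(
    ballots: Sequence[Ballot], remaining: Sequence[str] | set, k: int
) -> dict[str, float]:
    """Summed ballot weight assigning each remaining candidate original
    rank exactly k.  Ballots are never re-compacted after winner removal;
    tied candidates each receive the ballot's full weight."""
    if k < 1:
        raise ValueError("rank level must be >= 1")
    tally = {c: 0.0 for c in remaining}
    for b in ballots:
        for cand, rank in b.ranking.items():
            if rank == k and cand in tally:
                tally[cand] += b.weight
    return tally


def elect_one(
    ballots: Sequence[Ballot],
    remaining: Sequence[str],
    tiebreak_key: TiebreakKey = lexicographic_tiebreak,
    tie_tolerance: float = 1e-9,
) -> tuple[str, RoundDetail]:
    """Elect one winner from the remaining candidates.

    Starts from the level-1 tally and, while the maximal cumulative tally
    is shared (within tie_tolerance) and deeper ballot levels exist, adds
    the next level's votes.  A persistent tie is resolved by
    ``tiebreak_key`` (smaller key wins) with ``tiebreak_used`` set.
    """
    remaining = sorted(remaining)
    if not remaining:
        raise ValueError("no candidates remain")
    max_depth = max((b.depth for b in ballots), default=1)
    level_tallies = [tally_at_level(ballots, remaining, 1)]
    cumulative = dict(level_tallies[0])
    k = 1
    while True:
        top = max(cumulative.values())
        leaders = [c for c in remaining if abs(cumulative[c] - top) <= tie_tolerance]
        if len(leaders) == 1:
            return leaders[0], RoundDetail(
                winner=leaders[0],
                cumulative=cumulative,
                level_tallies=tuple(level_tallies),
                level_reached=k,
                tiebreak_used=False,
            )
        if k >= max_depth:
            winner = min(leaders, key=tiebreak_key)
            return winner, RoundDetail(
                winner=winner,
                cumulative=cumulative,
                level_tallies=tuple(level_tallies),
                level_reached=k,
                tiebreak_used=True,
            )
        k += 1
        nxt = tally_at_level(ballots, remaining, k)
        level_tallies.append(nxt)
        for c in remaining:
            cumulative[c] += nxt[c]


def run_election(
    ballots: Sequence[Ballot],
    candidates: Sequence[str],
    tiebreak_key: TiebreakKey = lexicographic_tiebreak,
    gene_id: str = "",
    tie_tolerance: float = 1e-9,
) -> ElectionRecord:
    """Order all candidates by repeated single-winner rounds.

    Winners are removed from the remaining set only; ballots are left
    untouched, so later rounds still tally original rank positions.
    Deterministic given inputs and tiebreak_key.
    """
    if not candidates:
        raise ValueError("election needs at least one candidate")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate ids")
    remaining = sorted(candidates)
    order: list[str] = []
    rounds: list[RoundDetail] = []
    while remaining:
        winner, detail = elect_one(ballots, remaining, tiebreak_key, tie_tolerance)
        order.append(winner)
        rounds.append(detail)
        remaining.remove(winner)
    return ElectionRecord(gene_id=gene_id, order=tuple(order), rounds=tuple(rounds))
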