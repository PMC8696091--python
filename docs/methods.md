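# Methods

## Model

`tracevote` treats canonical-transcript selection as a weighted
ranked-choice election held independently at every protein-coding gene
locus with at least two coding candidates. Voters are of two kinds:
RNA-seq samples, which express an empirical preference via annotation
edit distance to their own assembled transcripts, and three fixed
length-criteria voters encoding the prior that well-annotated isoforms
tend to have broad functional-domain coverage and, secondarily, long
translations and long mature transcripts.

### Annotation edit distance

For a candidate transcript *c* and an evidence transcript *e* on the
same chromosome and compatible strands, with exon chains treated as base
sets,

- SN = |c ∩ e| / |e| (sensitivity),
- SP = |c ∩ e| / |c| (specificity),
- AED(c, e) = 1 − (SN + SP)/2.

AED is 0 iff the exon chains are base-identical and 1 iff they share no
base. Distances are computed on exon intervals (UTRs included), not
CDS. Coordinates are 0-based half-open throughout; GFF3/GTF 1-based
closed coordinates are converted at the I/O boundary only.

**Clipping.** Samples in which a gene is weakly expressed often
assemble only part of a transcript. The sample-facing score therefore
clips the candidate's exons to the evidence's genomic span
[min start, max end) before scoring. Span-clipping (rather than
clipping to the evidence *exon union*) forgives missing terminal exons
while still penalizing internal disagreements such as retained introns
— clipping to the exon union would also forgive skipped internal exons
and make an intron-retaining candidate indistinguishable from the
correct one whenever the evidence is contained in it. Clipped AED is
deliberately asymmetric; the unclipped form is symmetric and both are
exposed.

### Ballot construction

Per sample and locus, assemblies are kept when (i) strand-compatible
with the locus (unstranded "." matches either strand, accommodating
unstranded libraries), (ii) TPM ≥ `min_tpm`, and (iii) the fraction of
the assembly's exonic bases inside the locus exon footprint is ≥
`min_overlap`. All threshold comparisons are inclusive at the boundary.
The single top-TPM survivor is the sample's evidence; if several tie
for top TPM (within `tie_tolerance`), each candidate takes its minimum
clipped AED over the tied set, keeping one ballot per sample.
Candidates with clipped AED > `max_aed` are omitted from the ballot; if
none remain, or no assembly survives filtering, the sample abstains.

Rankings are dense (1, 1, 2): tied items share a rank and the next
distinct item takes the next integer. Dense ranks are required for the
escalation tally to behave sensibly — with competition ranks (1, 1, 3)
a two-way tie at rank 1 would leave level 2 structurally empty.
Floating-point scores within `tie_tolerance` (default 1e-9) of the tie
group's first member are tied.

### Electorate balancing

With S non-abstaining samples, each sample ballot gets weight
min(1, `balance_factor` × W / S), where W is the summed length-voter
weight (18 by default). Small panels keep one vote per sample; beyond
S = W/`balance_factor` the total sample weight is capped at
`balance_factor` × W so an arbitrarily large expression atlas can
outvote the priors by at most that fixed factor. The cap formula is
this package's design choice for the stated balancing goal; the
behavioural contract (unit weights for small panels, bounded total) is
what the tests pin down.

### Tally and rounds

`tally_at_level(ballots, remaining, k)` sums the weight of ballots whose
*original* ranking assigns a remaining candidate rank exactly k. Each
round starts from the level-1 tally and, while the maximal cumulative
tally is shared by two or more candidates (within `tie_tolerance`) and
deeper ballot levels exist, adds the next level. The unique maximum
wins the round and is removed from the remaining set; ballots are never
re-compacted, so a candidate originally ranked 2 still arrives as
"rank-2 votes" in later rounds. This fixed-position semantics is forced
by the reference worked example: in its second round the winner gains
14 at level 2, which exceeds the 10 units of weight held by ballots that
put the third candidate first — impossible under re-compaction,
consistent under fixed positions. Winners' votes are not transferred
(no surplus redistribution); this is winner-election, not
loser-elimination instant-runoff.

If a tie survives all levels, a deterministic key decides — wider
domain coverage, then longer protein, then longer spliced length, then
lexicographic transcript id — mirroring the voter priority, and the
round is flagged `tiebreak_used`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `max_aed` | 0.5 | — | ceiling on clipped AED for a sample vote |
| `min_tpm` | 0.5 | TPM | minimum assembly expression |
| `min_overlap` | 0.5 | fraction | assembly exonic bases inside locus footprint |
| `weight_domain` | 9 | votes | Pfam-coverage voter |
| `weight_protein` | 6 | votes | protein-length voter |
| `weight_transcript` | 3 | votes | spliced-length voter |
| `balance_factor` | 1.0 | — | cap on sample/length weight ratio |
| `tpm_attribute` | `TPM` | — | GTF attribute carrying expression |
| `cds_includes_stop` | true | — | annotation dialect for protein length |
| `tie_tolerance` | 1e-9 | — | float comparison slack in ranks and tallies |

Protein length is ⌊ΣCDS/3⌋ residues, minus one (the stop codon) when
`cds_includes_stop` is set and the CDS length is a whole number of
codons. CDS phase is ignored. Pfam domain coverage is the count of
distinct residues covered by ≥1 hit, with hits clamped (with a warning)
to the protein length; InterProScan protein ids are matched to
candidates by identity with the transcript id.

Non-coding transcripts inside protein-coding loci are not election
candidates; they are appended after the elected order, flagged
`non-coding`, rather than silently dropped. Loci with fewer than two
coding candidates skip the election and are flagged `trivial`.

## Synthetic data

`fixtures.make_toy_dataset` emits a reference GFF3, per-sample
StringTie-style GTFs, a manifest and an InterProScan-format Pfam table,
all deterministic in the seed. Each gene's designed true isoform is a
three-exon form; siblings skip or truncate exons, and one designated
gene carries a retained-intron isoform that is simultaneously the
longest transcript and the longest translation — the classic failure
mode of length-based selection. Sample GTFs reproduce the true
isoform's exon chain at TPM drawn uniformly from 5–80, plus
sub-threshold (TPM 0.05–0.4) noise assemblies and an intergenic
assembly that the filters must discard. The generator emulates
structure and designed expression ranking, not realism: there is no
read-level noise, no partial assemblies, no expression-dependent
truncation and no inter-sample disagreement, so recovery of the
designed winners demonstrates the correctness of the filtering,
scoring and tally machinery — not expected accuracy on real RNA-seq
data. Default sizes (20 genes, 5 samples) keep the whole suite in
seconds while exercising 1–4 transcripts per gene.

`fixtures.worked_example_ballots` is a frozen 21-ballot electorate over three
candidates whose round-by-round tallies (24 at level 1; a 10–10 tie;
+14 at level 2) are the package's reference worked example; the ballot
multiplicities are a minimal construction consistent with all of those
tallies under the fixed-position tally rule and are shipped frozen, not
regenerated.

## Numerical and degenerate-input choices

- Interval arithmetic is exact integer sorted-merge; union and
  intersection lengths are cross-checked against per-base enumeration.
- Empty clip (evidence span disjoint from the candidate) scores AED 1;
  strand-incompatible pairs score exactly 1 with a `strand_mismatch`
  flag; different chromosomes are an error.
- An empty sample manifest is valid: the length voters alone decide.
- A header-only GFF3 yields zero loci; a gene with a transcript but no
  exons is a hard error; a CDS outside its exon footprint warns and the
  transcript is retained.
- End-to-end output is ordered by gene id and contains no randomness,
  so repeated runs are byte-identical.

## Known limitations

- The balancing formula and the span-clipping interpretation are
  documented package choices; other implementations of the same election
  scheme may differ in these two details.
- AED is computed on exon coordinates only; sequence-level validation
  (translations vs genome) is out of scope, as are running aligners,
  assemblers or InterProScan.
- One ballot per sample per locus: a sample expressing two isoforms at
  similar TPM contributes only its top assembly (or the tied set's
  minimum AED), not multiple ballots.
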