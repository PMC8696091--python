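# tracevote

Canonical transcript selection by weighted ranked-choice election.

Genome annotation projects release multiple transcript models per
protein-coding gene, but most downstream analyses (gene trees, ortholog
calling, variant effect prediction) operate on a single *canonical*
transcript per locus. The common default — the longest transcript with the
longest translation — is easily fooled: an in-frame retained intron inflates
both lengths and promotes a partially processed isoform. `tracevote`
instead holds an election per gene in which RNA-seq samples and
length-based criteria vote, and orders every transcript by relevance.

## The election

For a gene with candidate transcripts, the electorate is:

- **One ballot per RNA-seq sample.** Each sample's assembled
  transcripts (StringTie-style GTF with TPM) are filtered on expression
  (TPM ≥ 0.5), exonic overlap with the locus footprint (≥ 0.5) and
  strand; the most highly expressed survivor ranks the candidates by
  **annotation edit distance**,

  AED = 1 − (SN + SP)/2,

  where SN = shared exonic bases / evidence exonic bases and
  SP = shared exonic bases / candidate exonic bases, so AED ranges from
  0 (base-identical exon chains) to 1 (no overlap). Because shallow
  samples assemble partial transcripts, the candidate is first clipped
  to the evidence's genomic span. Candidates with AED > 0.5 receive no
  vote from that sample; a sample with no usable evidence abstains.
- **Three length-based voters** rank all candidates by Pfam domain
  coverage (weight 9), protein length (weight 6) and spliced transcript
  length (weight 3).
- With many samples, sample weights are scaled so their total cannot
  exceed the length voters' total (18 by default).

Rounds then elect winners until no candidates remain: each round tallies
every ballot's weight at rank 1, and while the lead is tied the next
rank level's votes are added to the tally (ballots keep their original
rank positions throughout; winners are removed from contention, never
redistributed). Equal AED or equal length yields dense tied ranks
(1, 1, 2), and a tied ballot counts fully for every tied candidate.

## Worked example

The package ships a deterministic toy-data generator with designed
answers, including a gene whose longest isoform carries a retained
intron:

```python
from tracevote.fixtures import make_toy_dataset
from tracevote.cli import cli_main

ds = make_toy_dataset("demo", n_genes=20, seed=1)
cli_main(["--gff", str(ds.gff3), "--samples", str(ds.manifest),
          "--domains", str(ds.domains), "--out", "demo/out"])
```

prints

```
20 genes (12 multi-transcript); canonical not longest in 1 (8.3%); mean samples voting 5.00
```

and writes `demo/out.ranks.tsv`, whose first rows are

```
gene_id	transcript_id	rank	tally	tally_level	tiebreak_used	flag
g001	g001.t1	1	14	1	0
g001	g001.t2	2	9	1	0
g001	g001.t3	3	0	1	0
g002	g002.t1	1	.	trivial	0	trivial
```

Gene `g001` is the retained-intron gene: `g001.t2` is its longest
transcript with the longest translation, yet the five sample voters plus
the domain-coverage voter elect `g001.t1` in round 1 with a tally of 14
against 9 — the designed correct answer. `demo/out.canonical.gff3`
re-emits the annotation with `canonical_transcript=1` on each winner and
`trace_rank=N` on every mRNA; `demo/out.summary.json` holds the run
summary. The same pipeline is available from the shell as `tracevote`.

All thresholds and weights above are defaults of `TraceConfig` and can
be overridden by CLI flags (`--max-aed`, `--min-tpm`, `--min-overlap`,
`--weights D,P,T`, `--balance-factor`, `--tpm-attr`) or a YAML config.

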