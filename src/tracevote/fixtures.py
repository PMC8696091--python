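"""Deterministic generators for test inputs with designed correct answers.

Two kinds of fixture live here: the frozen three-candidate ballot set
reproducing the worked blue/red/gray election (all reference tallies —
24 at level 1, the 10–10 tie, the 14 added at level 2 — follow from it
under the fixed-position tally rule), and a seeded toy-dataset writer
that emits a reference GFF3, per-sample StringTie-style GTFs and a Pfam
TSV in which every gene has a designed winner, including one gene whose
longest isoform harbours a retained intron and must lose.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .balloting import Ballot, DOMAIN_VOTER, PROTEIN_VOTER, TRANSCRIPT_VOTER

__all__ = ["worked_example_ballots", "make_toy_dataset", "make_minimal_gff3", "ToyDataset"]


def worked_example_ballots() -> tuple[tuple[str, str, str], list[Ballot]]:
    """The frozen blue/red/gray worked-example electorate.

    Three length voters (weights 9/6/3) plus 18 unit-weight sample
    ballots, eight of which rank blue and red tied first.  Total
    electorate weight is 36.
    """
    candidates = ("blue", "red", "gray")
    ballots = [
        Ballot(DOMAIN_VOTER, 9.0, {"blue": 1, "red": 2, "gray": 3}),
        Ballot(PROTEIN_VOTER, 6.0, {"gray": 1, "blue": 2, "red": 3}),
        Ballot(TRANSCRIPT_VOTER, 3.0, {"gray": 1, "blue": 2, "red": 3}),
    ]
    sample_rankings = (
        [{"blue": 1, "red": 1}] * 8
        + [{"blue": 1, "red": 2}] * 5
        + [{"blue": 1, "gray": 2, "red": 3}] * 2
        + [{"red": 1, "blue": 2, "gray": 3}] * 2
        + [{"gray": 1, "blue": 2, "red": 3}]
    )
    for i, ranking in enumerate(sample_rankings, 1):
        ballots.append(Ballot(f"sample{i:02d}", 1.0, dict(ranking)))
    return candidates, ballots


@dataclass(frozen=True)
class ToyDataset:
    """Paths to a generated dataset plus its designed answers."""

    gff3: Path
    manifest: Path
    domains: Path
    sample_gtfs: tuple[Path, ...]
    expected_canonical: dict[str, str]
    retained_intron_gene: str | None


# Exon architecture shared by the toy genes: three exons with a variable
# 3' extension; variants derive from it by dropping/merging exons.
_EXON1, _EXON2, _EXON3 = (0, 300), (500, 800), (1000, 1300)
_UTR = 60  # spliced bases trimmed from each end of the exon chain for CDS


def _cds_from_exons(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """CDS intervals: the exon chain minus a UTR trim at both ends."""
    total = sum(e - s for s, e in exons)
    lead, tail = _UTR, total - _UTR
    cds, pos = [], 0
    for s, e in exons:
        n = e - s
        lo, hi = max(lead, pos), min(tail, pos + n)
        if hi > lo:
            cds.append((s + lo - pos, s + hi - pos))
        pos += n
    return cds


def _gene_architectures(rng: random.Random, i: int, retained: bool, offset: int):
    """Return (true_tx_name, {tx_name: (exons, cds)}) for gene i."""

    def shift(pairs):
        return [(offset + s, offset + e) for s, e in pairs]

    ext = rng.randrange(0, 200, 10)
    e1, e2 = _EXON1, _EXON2
    e3 = (_EXON3[0], _EXON3[1] + ext)
    full = shift([e1, e2, e3])
    variants = {
        "skip": shift([e1, e3]),
        "short3": shift([e1, e2, (e3[0], e3[0] + 150)]),
        "short5": shift([e2, e3]),
    }
    if retained:
        # The longest spliced form keeps intron 1: it must NOT win.
        ri = shift([(e1[0], e2[1]), e3])
        txs = {"t1": full, "t2": ri, "t3": variants["skip"]}
        true_tx = "t1"
    else:
        n_tx = rng.choice([1, 2, 2, 3, 4])
        names = ["t1"] + [f"t{j + 2}" for j in range(n_tx - 1)]
        chosen = rng.sample(sorted(variants), n_tx - 1)
        txs = {"t1": full}
        for name, key in zip(names[1:], chosen):
            txs[name] = variants[key]
        true_tx = "t1"
    return true_tx, {name: (ex, _cds_from_exons(ex)) for name, ex in txs.items()}


def make_toy_dataset(
    out_dir: str | Path,
    n_genes: int = 20,
    seed: int = 1,
    n_samples: int = 5,
) -> ToyDataset:
    """Write a seeded toy dataset whose canonical winners are known.

    Every gene's designed true isoform is the full three-exon form: the
    samples' top-TPM assemblies reproduce its exon chain exactly and the
    Pfam table gives it the widest domain coverage.  When n_genes >= 2,
    gene g001 additionally carries a retained-intron isoform that is the
    longest transcript with the longest translation, so length criteria
    alone would pick the wrong winner there.  Each sample GTF also
    carries sub-threshold (TPM < 0.5) noise assemblies and one
    intergenic assembly, which the filters must remove.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    gff_lines = ["##gff-version 3"]
    expected: dict[str, str] = {}
    gene_info = []  # (gene_id, chrom, strand, true exons, other isoform exons)
    ri_gene = None

    for i in range(n_genes):
        gene_id = f"g{i + 1:03d}"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        strand = "+" if i % 3 else "-"
        offset = 5000 + (i // 2) * 10_000
        retained = n_genes >= 2 and i == 0
        if retained:
            ri_gene = gene_id
        true_tx, txs = _gene_architectures(rng, i, retained, offset)
        expected[gene_id] = f"{gene_id}.{true_tx}"

        g_start = min(s for ex, _ in txs.values() for s, _e in ex)
        g_end = max(e for ex, _ in txs.values() for _s, e in ex)
        gff_lines.append(
            f"{chrom}\ttoy\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={gene_id}"
        )
        for name, (exons, cds) in sorted(txs.items()):
            tid = f"{gene_id}.{name}"
            gff_lines.append(
                f"{chrom}\ttoy\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t"
                f"{strand}\t.\tID={tid};Parent={gene_id}"
            )
            for j, (s, e) in enumerate(exons, 1):
                gff_lines.append(
                    f"{chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tid}.exon{j};Parent={tid}"
                )
            for j, (s, e) in enumerate(cds, 1):
                gff_lines.append(
                    f"{chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                    f"ID={tid}.cds{j};Parent={tid}"
                )
        others = [
            (f"{gene_id}.{n}", ex) for n, (ex, _c) in txs.items() if n != true_tx
        ]
        gene_info.append((gene_id, chrom, strand, txs[true_tx][0], others))

    gff_path = out / "reference.gff3"
    gff_path.write_text("\n".join(gff_lines) + "\n")

    # Pfam table: the true isoform's protein is almost fully covered;
    # sibling isoforms get one short hit each.
    dom_lines = []
    for i in range(n_genes):
        gene_id = f"g{i + 1:03d}"
        _gid, _chrom, _strand, true_exons, others = gene_info[i]
        for tid, exons in [(expected[gene_id], true_exons)] + others:
            plen = sum(e - s for s, e in _cds_from_exons(exons)) // 3 - 1
            if tid == expected[gene_id]:
                s_aa, e_aa = 5, max(6, plen - 5)
            else:
                s_aa, e_aa = 5, min(40, plen)
            dom_lines.append(
                "\t".join(
                    [
                        tid, "md5", str(plen), "Pfam", "PF00001",
                        "toy domain", str(s_aa), str(e_aa), "1e-30", "T",
                        "2020-01-01", "IPR000001", "toy", "-", "-",
                    ]
                )
            )
            # rows from other analyses must be ignored by the reader
            dom_lines.append(
                "\t".join(
                    [
                        tid, "md5", str(plen), "PANTHER", "PTHR00001",
                        "toy family", "1", str(max(plen, 1)), "1e-10", "T",
                        "2020-01-01", "-", "-", "-", "-",
                    ]
                )
            )
    dom_path = out / "domains.tsv"
    dom_path.write_text("\n".join(dom_lines) + ("\n" if dom_lines else ""))

    # Per-sample GTFs: top-TPM assembly == true isoform exon chain.
    sample_dir = out / "samples"
    sample_dir.mkdir(exist_ok=True)
    gtf_paths = []
    manifest_lines = []
    for s in range(n_samples):
        sid = f"sample{s + 1}"
        lines = []
        asm = 0
        for gene_id, chrom, strand, true_exons, others in gene_info:
            asm += 1
            tid = f"{sid}.STRG.{asm}"
            tpm = round(rng.uniform(5.0, 80.0), 3)
            lines.extend(_gtf_record(chrom, strand, true_exons, tid, tpm))
            if others and rng.random() < 0.5:
                asm += 1
                noise_tid = f"{sid}.STRG.{asm}"
                noise_tpm = round(rng.uniform(0.05, 0.4), 3)
                lines.extend(
                    _gtf_record(chrom, strand, others[0][1], noise_tid, noise_tpm)
                )
        if n_genes:
            # an intergenic assembly: passes TPM but overlaps no locus
            asm += 1
            lines.extend(
                _gtf_record(
                    "chr1", "+",
                    [(1_000_000, 1_000_500)], f"{sid}.STRG.{asm}", 9.0,
                )
            )
        p = sample_dir / f"{sid}.gtf"
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        gtf_paths.append(p)
        manifest_lines.append(f"{sid}\tsamples/{sid}.gtf")
    manifest_path = out / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + ("\n" if manifest_lines else ""))

    return ToyDataset(
        gff3=gff_path,
        manifest=manifest_path,
        domains=dom_path,
        sample_gtfs=tuple(gtf_paths),
        expected_canonical=expected,
        retained_intron_gene=ri_gene,
    )


def _gtf_record(
    chrom: str, strand: str, exons: Sequence[tuple[int, int]], tid: str, tpm: float
) -> list[str]:
    gid = tid.rsplit(".", 1)[0]
    attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
    lines = [
        f"{chrom}\tStringTie\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}\t"
        f'1000\t{strand}\t.\t{attrs} TPM "{tpm:.6f}";'
    ]
    for j, (s, e) in enumerate(exons, 1):
        lines.append(
            f"{chrom}\tStringTie\texon\t{s + 1}\t{e}\t1000\t{strand}\t.\t"
            f'{attrs} exon_number "{j}";'
        )
    return lines


def make_minimal_gff3(path: str | Path) -> dict[str, int]:
    """A hand-written two-gene GFF3 (transcript counts 2 and 1)."""
    text = """##gff-version 3
chr1\ttoy\tgene\t1001\t3000\t.\t+\t.\tID=gA
chr1\ttoy\tmRNA\t1001\t3000\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\ttoy\texon\t1001\t1400\t.\t+\t.\tID=gA.t1.exon1;Parent=gA.t1
chr1\ttoy\texon\t2001\t3000\t.\t+\t.\tID=gA.t1.exon2;Parent=gA.t1
chr1\ttoy\tCDS\t1101\t1400\t.\t+\t0\tID=gA.t1.cds1;Parent=gA.t1
chr1\ttoy\tCDS\t2001\t2800\t.\t+\t0\tID=gA.t1.cds2;Parent=gA.t1
chr1\ttoy\tmRNA\t1001\t3000\t.\t+\t.\tID=gA.t2;Parent=gA
chr1\ttoy\texon\t1001\t3000\t.\t+\t.\tID=gA.t2.exon1;Parent=gA.t2
chr1\ttoy\tCDS\t1101\t2800\t.\t+\t0\tID=gA.t2.cds1;Parent=gA.t2
chr2\ttoy\tgene\t501\t1500\t.\t-\t.\tID=gB
chr2\ttoy\tmRNA\t501\t1500\t.\t-\t.\tID=gB.t1;Parent=gB
chr2\ttoy\texon\t501\t1500\t.\t-\t.\tID=gB.t1.exon1;Parent=gB.t1
chr2\ttoy\tCDS\t601\t1400\t.\t-\t0\tID=gB.t1.cds1;Parent=gB.t1
"""
    Path(path).write_text(text)
    return {"gA": 2, "gB": 1}
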