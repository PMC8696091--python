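"""Readers and writers for the standard annotation formats.

Reference annotations arrive as GFF3 (gene -> mRNA/transcript -> exon,
CDS linked by ID/Parent), sample assemblies as StringTie-style GTF with
per-transcript TPM attributes, and domain annotations as InterProScan
TSV restricted to Pfam rows.  Outputs are a per-transcript rank table
(TSV) and the input annotation re-emitted with canonical/rank tags.

All 1-based closed coordinates are converted to the internal 0-based
half-open convention here and nowhere else.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

from .core_model import (
    AssembledTranscript,
    DomainHit,
    GeneLocus,
    GenomicInterval,
    TranscriptModel,
)
from .election import ElectionRecord

__all__ = [
    "read_reference_gff3",
    "read_stringtie_gtf",
    "read_interproscan_tsv",
    "read_sample_manifest",
    "write_rank_table",
    "read_rank_table",
    "write_canonical_gff3",
    "RANK_TABLE_COLUMNS",
]

_TRANSCRIPT_TYPES = ("mRNA", "transcript")
RANK_TABLE_COLUMNS = (
    "gene_id",
    "transcript_id",
    "rank",
    "tally",
    "tally_level",
    "tiebreak_used",
    "flag",
)


def read_reference_gff3(
    path: str | Path, cds_includes_stop: bool = True
) -> list[GeneLocus]:
    """Parse a reference GFF3 into one GeneLocus per gene with >=1 transcript.

    Coordinates are converted to 0-based half-open.  A transcript feature
    without exon children is an error; a CDS interval outside the exon
    footprint raises a warning but the transcript is retained.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []  # header-only annotation: no loci
    # Validate parent links before assembling loci so errors name features.
    ids = {f.id for f in db.all_features()}
    for f in db.all_features():
        if f.featuretype in _TRANSCRIPT_TYPES + ("exon", "CDS"):
            parents = f.attributes.get("Parent")
            if not parents:
                raise ValueError(
                    f"feature {f.id or f.featuretype} at {f.seqid}:{f.start} "
                    "has no Parent attribute"
                )
            for p in parents:
                if p not in ids:
                    raise ValueError(
                        f"feature {f.id or f.featuretype} names unknown "
                        f"Parent {p!r}"
                    )

    loci = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for tf in db.children(gene, featuretype=_TRANSCRIPT_TYPES, level=1):
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(tf, featuretype="exon", level=1)
            ]
            if not exons:
                raise ValueError(
                    f"transcript {tf.id} of gene {gene.id} has no exon children"
                )
            cds = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                for c in db.children(tf, featuretype="CDS", level=1)
            ]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tf.id,
                    gene_id=gene.id,
                    exons=exons,
                    cds=cds,
                    cds_includes_stop=cds_includes_stop,
                )
            )
        if transcripts:
            loci.append(GeneLocus(gene_id=gene.id, transcripts=transcripts))
    return sorted(loci, key=lambda l: l.gene_id)


_GTF_ATTR = re.compile(r'\s*(\w+)\s+"([^"]*)"\s*;?')


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_GTF_ATTR.findall(text))
    if not attrs:
        raise ValueError(f"unparseable GTF attribute column at line {lineno}: {text!r}")
    return attrs


def read_stringtie_gtf(
    path: str | Path, sample_id: str, tpm_attribute: str = "TPM"
) -> list[AssembledTranscript]:
    """Parse a StringTie-style GTF into assembled transcripts with TPM.

    Transcript features lacking the TPM attribute get tpm = 0; no
    expression or overlap filtering happens here.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, float]] = {}  # tid -> (strand, tpm)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: expected 9 tab-separated columns at line {lineno}"
                )
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_text = fields
            if ftype not in ("transcript", "exon"):
                continue
            attrs = _parse_gtf_attributes(attr_text, lineno)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: missing transcript_id at line {lineno}")
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            if ftype == "transcript":
                tpm_text = attrs.get(tpm_attribute)
                try:
                    tpm = float(tpm_text) if tpm_text is not None else 0.0
                except ValueError:
                    raise ValueError(
                        f"{path}: bad {tpm_attribute} value {tpm_text!r} "
                        f"at line {lineno}"
                    ) from None
                meta[tid] = (strand, tpm)
            else:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
                prev = exons[tid]
                if prev and prev[0].strand != strand:
                    raise ValueError(
                        f"{path}: transcript {tid} has exons on both strands "
                        f"(line {lineno})"
                    )
                prev.append(iv)

    out = []
    for tid in order:
        if not exons[tid]:
            continue
        strand, tpm = meta.get(tid, (exons[tid][0].strand, 0.0))
        if exons[tid][0].strand not in (strand, "."):
            raise ValueError(
                f"{path}: transcript {tid} exon strand contradicts its "
                "transcript feature"
            )
        out.append(
            AssembledTranscript(
                sample_id=sample_id,
                transcript_id=tid,
                exons=exons[tid],
                tpm=tpm,
                strand=strand,
            )
        )
    return out


def read_interproscan_tsv(
    path: str | Path, db_filter: str = "Pfam"
) -> list[DomainHit]:
    """Parse InterProScan TSV, keeping only rows from one analysis source.

    Column layout (1-based): 1 protein id, 4 analysis, 5 signature
    accession, 7 start residue, 8 stop residue.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ValueError(
                    f"{path}: expected >=8 columns at line {lineno}, "
                    f"got {len(cols)}"
                )
            if cols[3] != db_filter:
                continue
            try:
                start_aa, end_aa = int(cols[6]), int(cols[7])
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer domain coordinates at line {lineno}"
                ) from None
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    start_aa=start_aa,
                    end_aa=end_aa,
                    db=cols[3],
                    accession=cols[4] if len(cols) > 4 else "",
                )
            )
    return hits


def read_sample_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Two-column TSV (sample_id, GTF path); relative paths resolve
    against the manifest's own directory."""
    base = Path(path).parent
    entries = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise ValueError(
                    f"{path}: expected 2 columns at line {lineno}"
                )
            sid, gtf = cols
            if sid in seen:
                raise ValueError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            p = Path(gtf)
            entries.append((sid, p if p.is_absolute() else base / p))
    return entries


def _rank_rows(record: ElectionRecord) -> Iterable[tuple]:
    noncoding = set(record.noncoding)
    for idx, tid in enumerate(record.order):
        rank = idx + 1
        if tid in noncoding:
            yield (record.gene_id, tid, rank, ".", ".", 0, "non-coding")
        elif record.trivial or idx >= len(record.rounds):
            yield (record.gene_id, tid, rank, ".", "trivial", 0, "trivial")
        else:
            rd = record.rounds[idx]
            yield (
                record.gene_id,
                tid,
                rank,
                f"{rd.cumulative[tid]:g}",
                rd.level_reached,
                int(rd.tiebreak_used),
                "",
            )


def write_rank_table(records: Sequence[ElectionRecord], path: str | Path) -> None:
    """TSV with one row per (gene, transcript), sorted by gene then rank."""
    with open(path, "w") as fh:
        fh.write("\t".join(RANK_TABLE_COLUMNS) + "\n")
        for record in sorted(records, key=lambda r: r.gene_id):
            for row in _rank_rows(record):
                fh.write("\t".join(str(v) for v in row) + "\n")


def read_rank_table(path: str | Path) -> list[dict]:
    """Inverse of write_rank_table (ranks as ints, tallies as str)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RANK_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected rank-table header {header}")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            row["rank"] = int(row["rank"])
            row["tiebreak_used"] = int(row["tiebreak_used"])
            rows.append(row)
    return rows


def _fmt_attrs(pairs: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def write_canonical_gff3(
    loci: Sequence[GeneLocus],
    records: Mapping[str, ElectionRecord],
    path: str | Path,
) -> None:
    """Re-emit the annotation with election results tagged on each mRNA.

    Every mRNA gets ``trace_rank=N``; each gene's rank-1 mRNA also gets
    ``canonical_transcript=1``.  Multi-transcript loci must have a record;
    a single-transcript locus without one is trivially canonical.
    """
    lines = ["##gff-version 3"]
    for locus in sorted(loci, key=lambda l: l.gene_id):
        record = records.get(locus.gene_id)
        if record is None:
            if locus.is_multi_transcript:
                raise ValueError(
                    f"multi-transcript locus {locus.gene_id} has no election record"
                )
            ranks = {locus.transcripts[0].transcript_id: 1}
        else:
            missing = {t.transcript_id for t in locus.transcripts} - set(record.order)
            if missing:
                raise ValueError(
                    f"record for {locus.gene_id} omits transcripts {sorted(missing)}"
                )
            ranks = {tid: i + 1 for i, tid in enumerate(record.order)}
        footprint = locus.exon_footprint
        g_start, g_end = footprint[0].start, footprint[-1].end
        lines.append(
            "\t".join(
                [
                    locus.chrom, "tracevote", "gene",
                    str(g_start + 1), str(g_end), ".", locus.strand, ".",
                    _fmt_attrs([("ID", locus.gene_id)]),
                ]
            )
        )
        for t in sorted(locus.transcripts, key=lambda t: ranks[t.transcript_id]):
            attrs = [("ID", t.transcript_id), ("Parent", locus.gene_id),
                     ("trace_rank", str(ranks[t.transcript_id]))]
            if ranks[t.transcript_id] == 1:
                attrs.append(("canonical_transcript", "1"))
            lines.append(
                "\t".join(
                    [
                        t.chrom, "tracevote", "mRNA",
                        str(t.exons[0].start + 1), str(t.exons[-1].end),
                        ".", t.strand, ".", _fmt_attrs(attrs),
                    ]
                )
            )
            for i, e in enumerate(t.exons, 1):
                lines.append(
                    "\t".join(
                        [
                            e.chrom, "tracevote", "exon",
                            str(e.start + 1), str(e.end), ".", e.strand, ".",
                            _fmt_attrs(
                                [("ID", f"{t.transcript_id}.exon{i}"),
                                 ("Parent", t.transcript_id)]
                            ),
                        ]
                    )
                )
            for i, c in enumerate(t.cds, 1):
                lines.append(
                    "\t".join(
                        [
                            c.chrom, "tracevote", "CDS",
                            str(c.start + 1), str(c.end), ".", c.strand, "0",
                            _fmt_attrs(
                                [("ID", f"{t.transcript_id}.cds{i}"),
                                 ("Parent", t.transcript_id)]
                            ),
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")
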