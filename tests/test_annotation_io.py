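"""Format readers and writers: GFF3, StringTie GTF, InterProScan TSV,
rank table, canonical-tagged GFF3."""

import random

import pytest

from tracevote.annotation_io import (
    read_interproscan_tsv,
    read_rank_table,
    read_reference_gff3,
    read_sample_manifest,
    read_stringtie_gtf,
    write_canonical_gff3,
    write_rank_table,
)
from tracevote.election import ElectionRecord, RoundDetail
from tracevote.fixtures import make_minimal_gff3


@pytest.fixture()
def minimal_gff(tmp_path):
    path = tmp_path / "two_genes.gff3"
    counts = make_minimal_gff3(path)
    return path, counts


class TestReadReferenceGff3:
    def test_two_gene_toy(self, minimal_gff):
        path, counts = minimal_gff
        loci = read_reference_gff3(path)
        assert {l.gene_id: len(l.transcripts) for l in loci} == counts

    def test_coordinates_converted_to_half_open(self, minimal_gff):
        path, _ = minimal_gff
        loci = read_reference_gff3(path)
        gA = next(l for l in loci if l.gene_id == "gA")
        t1 = gA.get("gA.t1")
        # GFF3 line "exon 1001 1400" becomes [1000,1400) internally
        assert (t1.exons[0].start, t1.exons[0].end) == (1000, 1400)
        assert t1.spliced_length == 400 + 1000

    def test_transcript_without_exons_is_error(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ttoy\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\ttoy\tmRNA\t1\t100\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        )
        with pytest.raises(ValueError, match="no exon"):
            read_reference_gff3(p)

    def test_missing_parent_is_error_naming_feature(self, tmp_path):
        p = tmp_path / "orphan.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ttoy\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\ttoy\tmRNA\t1\t100\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr1\ttoy\texon\t1\t100\t.\t+\t.\tID=e1;Parent=nonexistent\n"
        )
        with pytest.raises(ValueError, match="nonexistent"):
            read_reference_gff3(p)

    def test_cds_outside_exons_warns_but_keeps_transcript(self, tmp_path):
        p = tmp_path / "cds.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ttoy\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "chr1\ttoy\tmRNA\t1\t300\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr1\ttoy\texon\t1\t100\t.\t+\t.\tID=x1;Parent=g1.t1\n"
            "chr1\ttoy\tCDS\t50\t200\t.\t+\t0\tID=c1;Parent=g1.t1\n"
        )
        with pytest.warns(UserWarning):
            loci = read_reference_gff3(p)
        assert loci[0].get("g1.t1").is_coding

    def test_line_order_within_gene_is_irrelevant(self, minimal_gff, tmp_path):
        path, _ = minimal_gff
        ref = read_reference_gff3(path)
        lines = path.read_text().strip().split("\n")
        header, body = lines[0], lines[1:]
        rng = random.Random(0)
        for i in range(3):
            rng.shuffle(body)
            q = tmp_path / f"shuffled{i}.gff3"
            q.write_text("\n".join([header] + body) + "\n")
            assert read_reference_gff3(q) == ref


class TestReadStringtieGtf:
    def write(self, tmp_path, text):
        p = tmp_path / "sample.gtf"
        p.write_text(text)
        return p

    def test_tpm_parsed_and_missing_tpm_is_zero(self, tmp_path):
        p = self.write(
            tmp_path,
            'chr1\tStringTie\ttranscript\t1\t100\t1000\t+\t.\t'
            'gene_id "G"; transcript_id "T1"; TPM "12.300000";\n'
            'chr1\tStringTie\texon\t1\t100\t1000\t+\t.\t'
            'gene_id "G"; transcript_id "T1";\n'
            'chr1\tStringTie\ttranscript\t200\t300\t1000\t+\t.\t'
            'gene_id "G"; transcript_id "T2";\n'
            'chr1\tStringTie\texon\t200\t300\t1000\t+\t.\t'
            'gene_id "G"; transcript_id "T2";\n',
        )
        out = read_stringtie_gtf(p, "s1")
        assert [a.tpm for a in out] == [12.3, 0.0]
        assert out[0].sample_id == "s1"
        assert (out[0].exons[0].start, out[0].exons[0].end) == (0, 100)

    def test_reader_does_not_filter_low_tpm(self, tmp_path, toy_dataset):
        out = read_stringtie_gtf(toy_dataset.sample_gtfs[0], "s1")
        assert any(a.tpm < 0.5 for a in out)  # noise assemblies survive reading

    def test_exons_on_both_strands_is_error(self, tmp_path):
        p = self.write(
            tmp_path,
            'chr1\tStringTie\texon\t1\t100\t1000\t+\t.\ttranscript_id "T1";\n'
            'chr1\tStringTie\texon\t200\t300\t1000\t-\t.\ttranscript_id "T1";\n',
        )
        with pytest.raises(ValueError, match="both strands"):
            read_stringtie_gtf(p, "s1")

    def test_unparseable_attributes_error_names_line(self, tmp_path):
        p = self.write(
            tmp_path,
            'chr1\tStringTie\ttranscript\t1\t100\t1000\t+\t.\t???\n',
        )
        with pytest.raises(ValueError, match="line 1"):
            read_stringtie_gtf(p, "s1")

    def test_custom_tpm_attribute(self, tmp_path):
        p = self.write(
            tmp_path,
            'chr1\tq\ttranscript\t1\t100\t.\t+\t.\ttranscript_id "T"; FPKM "7.5";\n'
            'chr1\tq\texon\t1\t100\t.\t+\t.\ttranscript_id "T";\n',
        )
        assert read_stringtie_gtf(p, "s", tpm_attribute="FPKM")[0].tpm == 7.5


class TestReadInterproscanTsv:
    def test_pfam_rows_only(self, toy_dataset):
        hits = read_interproscan_tsv(toy_dataset.domains)
        assert hits and all(h.db == "Pfam" for h in hits)
        panther = read_interproscan_tsv(toy_dataset.domains, db_filter="PANTHER")
        assert panther and all(h.db == "PANTHER" for h in panther)

    def test_column_mapping(self, tmp_path):
        p = tmp_path / "ipr.tsv"
        p.write_text(
            "prot1\tmd5\t300\tPfam\tPF00042\tGlobin\t10\t50\t1e-20\tT\t"
            "2020-01-01\tIPR000971\tGlobin\t-\t-\n"
        )
        (hit,) = read_interproscan_tsv(p)
        assert (hit.protein_id, hit.start_aa, hit.end_aa) == ("prot1", 10, 50)
        assert hit.accession == "PF00042"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_interproscan_tsv(p) == []

    def test_non_integer_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("p\tm\t1\tPfam\tPF1\td\tten\t50\n")
        with pytest.raises(ValueError, match="line 1"):
            read_interproscan_tsv(p)


class TestManifest:
    def test_relative_paths_resolve_against_manifest_dir(self, toy_dataset):
        entries = read_sample_manifest(toy_dataset.manifest)
        assert [sid for sid, _ in entries] == [f"sample{i}" for i in range(1, 6)]
        assert all(p.exists() for _, p in entries)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\ta.gtf\ns1\tb.gtf\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_manifest(p)


def _record(gene_id="g1"):
    rounds = (
        RoundDetail("t1", {"t1": 14.0, "t2": 9.0}, ({"t1": 14.0, "t2": 9.0},), 1, False),
        RoundDetail("t2", {"t2": 9.0}, ({"t2": 9.0},), 1, False),
    )
    return ElectionRecord(gene_id, ("t1", "t2"), rounds)


class TestRankTable:
    def test_row_counts_and_round_trip(self, tmp_path):
        path = tmp_path / "out.tsv"
        trivial = ElectionRecord("g2", ("t9",), (), trivial=True)
        write_rank_table([_record(), trivial], path)
        rows = read_rank_table(path)
        assert len(rows) == 3
        assert [(r["gene_id"], r["transcript_id"], r["rank"]) for r in rows] == [
            ("g1", "t1", 1), ("g1", "t2", 2), ("g2", "t9", 1),
        ]
        assert rows[2]["tally_level"] == "trivial"
        # writing what was read reproduces the ranks byte-for-byte
        path2 = tmp_path / "again.tsv"
        write_rank_table([_record(), trivial], path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_noncoding_flagged_and_ranked_last(self, tmp_path):
        rec = _record()
        rec = ElectionRecord(
            rec.gene_id, rec.order + ("nc1",), rec.rounds, noncoding=("nc1",)
        )
        path = tmp_path / "out.tsv"
        write_rank_table([rec], path)
        rows = read_rank_table(path)
        assert rows[-1]["flag"] == "non-coding" and rows[-1]["rank"] == 3


class TestCanonicalGff3:
    def test_exactly_one_canonical_per_gene_and_reparses(self, tmp_path, minimal_gff):
        path, _ = minimal_gff
        loci = read_reference_gff3(path)
        rec = ElectionRecord(
            "gA",
            ("gA.t2", "gA.t1"),
            (
                RoundDetail("gA.t2", {"gA.t2": 9.0, "gA.t1": 5.0},
                            ({"gA.t2": 9.0, "gA.t1": 5.0},), 1, False),
                RoundDetail("gA.t1", {"gA.t1": 5.0}, ({"gA.t1": 5.0},), 1, False),
            ),
        )
        out = tmp_path / "canonical.gff3"
        write_canonical_gff3(loci, {"gA": rec}, out)
        text = out.read_text()
        assert text.count("canonical_transcript=1") == 2  # one per gene
        assert "ID=gA.t2;Parent=gA;trace_rank=1;canonical_transcript=1" in text
        assert "trace_rank=2" in text
        reparsed = read_reference_gff3(out)
        assert {l.gene_id for l in reparsed} == {"gA", "gB"}
        # coordinates and parentage survive the round trip
        orig = {t.transcript_id: t.exons for l in loci for t in l.transcripts}
        back = {t.transcript_id: t.exons for l in reparsed for t in l.transcripts}
        assert orig == back

    def test_multi_transcript_locus_without_record_is_error(self, tmp_path, minimal_gff):
        path, _ = minimal_gff
        loci = read_reference_gff3(path)
        with pytest.raises(ValueError, match="gA"):
            write_canonical_gff3(loci, {}, tmp_path / "x.gff3")
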