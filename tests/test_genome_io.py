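import random
import textwrap

import pytest

from lanminer.fixtures import FixtureSpec, make_genome
from lanminer.genome_io import (
    GeneFeature,
    GenomeRecord,
    extract_neighborhood,
    read_genbank,
    read_report_tsv,
    write_genbank,
    write_report,
)
from lanminer.report import MiningReport

MINIMAL_GBK = textwrap.dedent(
    """\
    LOCUS       TESTREC                   60 bp    DNA     linear   BCT 01-JAN-2000
    DEFINITION  test record.
    ACCESSION   TESTREC
    VERSION     TESTREC
    SOURCE      Examplea bacteria
      ORGANISM  Examplea bacteria
                Bacteria; Firmicutes; Bacillales.
    FEATURES             Location/Qualifiers
         CDS             10..18
                         /locus_tag="g1"
                         /protein_id="p1"
                         /translation="MK"
    ORIGIN
            1 atgaaataaa tgaaatgagc gcgcgcgcgc atgaaataaa tgaaatgagc gcgcgcgcgc
    //
    """
)


def test_read_genbank_basic(tmp_path):
    path = tmp_path / "one.gbk"
    path.write_text(MINIMAL_GBK)
    records = read_genbank(path)
    assert len(records) == 1
    rec = records[0]
    assert rec.record_id == "TESTREC"
    assert rec.length_nt == 60
    assert rec.organism == "Examplea bacteria"
    assert rec.lineage == ["Bacteria", "Firmicutes", "Bacillales"]
    assert not rec.circular


def test_coordinate_convention_one_based_inclusive_to_half_open(tmp_path):
    # GenBank span "10..18" on the plus strand -> start=9, end=18
    path = tmp_path / "one.gbk"
    path.write_text(MINIMAL_GBK)
    gene = read_genbank(path)[0].genes[0]
    assert (gene.start, gene.end, gene.strand) == (9, 18, 1)


def test_read_genbank_missing_file():
    with pytest.raises(OSError):
        read_genbank("/nonexistent/genome.gbk")


def test_fixture_roundtrip(tmp_path):
    record, _ = make_genome(FixtureSpec(seed=5, classes=("II",)))
    path = tmp_path / "fx.gbk"
    write_genbank([record], path)
    back = read_genbank(path)[0]
    assert back.record_id == record.record_id
    assert back.dna == record.dna
    assert back.organism == record.organism
    assert back.lineage == record.lineage
    assert back.circular == record.circular
    assert len(back.genes) == len(record.genes)
    for a, b in zip(record.genes, back.genes):
        assert (a.start, a.end, a.strand, a.locus_id, a.protein_seq) == (
            b.start,
            b.end,
            b.strand,
            b.locus_id,
            b.protein_seq,
        )


def test_genes_sorted_and_cds_count(tmp_path):
    record, _ = make_genome(FixtureSpec(seed=1, classes=("I",)))
    starts = [g.start for g in record.genes]
    assert starts == sorted(starts)


def _toy_record(n_genes: int = 30, gene_len: int = 900, spacer: int = 100, length: int | None = None):
    genes = []
    pos = 5000
    for i in range(n_genes):
        genes.append(
            GeneFeature(
                locus_id=f"g{i}",
                protein_id=f"p{i}",
                start=pos,
                end=pos + gene_len,
                strand=1,
                index=i,
            )
        )
        pos += gene_len + spacer
    total = length or pos + 5000
    return GenomeRecord(record_id="toy", dna="A" * total, genes=genes)


def test_neighborhood_window():
    rec = _toy_record()
    nbhd = extract_neighborhood(rec, 10, window=7)
    assert [g.index for g in nbhd.genes] == list(range(3, 18))
    assert len(nbhd.genes) == 15
    assert nbhd.anchor.index == 10
    assert nbhd.span_start == nbhd.genes[0].start
    assert nbhd.span_end == nbhd.genes[-1].end


def test_neighborhood_truncated_upstream():
    rec = _toy_record()
    nbhd = extract_neighborhood(rec, 2, window=7)
    assert [g.index for g in nbhd.genes] == list(range(0, 10))


def test_contig_edge_flag():
    # anchor gene starting at nt 1200 on a 50 kb linear contig
    genes = [
        GeneFeature(locus_id="a", protein_id="pa", start=1200, end=2100, strand=1, index=0),
        GeneFeature(locus_id="b", protein_id="pb", start=20000, end=20900, strand=1, index=1),
    ]
    rec = GenomeRecord(record_id="edge", dna="A" * 50000, genes=genes)
    assert extract_neighborhood(rec, 0).contig_edge is True
    # far from both ends: not flagged
    mid = GenomeRecord(
        record_id="mid",
        dna="A" * 50000,
        genes=[GeneFeature(locus_id="c", protein_id="pc", start=20000, end=20900, strand=1, index=0)],
    )
    assert extract_neighborhood(mid, 0).contig_edge is False


def test_circular_records_never_edge_flagged():
    genes = [GeneFeature(locus_id="a", protein_id="pa", start=100, end=400, strand=1, index=0)]
    rec = GenomeRecord(record_id="circ", dna="A" * 5000, genes=genes, circular=True)
    assert extract_neighborhood(rec, 0).contig_edge is False


def test_contig_edge_monotone_under_flank_shrink():
    # shrinking the flanks never turns the flag from true to false
    rng = random.Random(0)
    for _ in range(50):
        length = rng.randint(8000, 40000)
        start = rng.randint(0, length - 1000)
        genes = [GeneFeature(locus_id="a", protein_id="pa", start=start, end=start + 900, strand=1, index=0)]
        rec = GenomeRecord(record_id="r", dna="A" * length, genes=genes)
        flagged = extract_neighborhood(rec, 0).contig_edge
        shrunk = GenomeRecord(record_id="r", dna="A" * (start + 950), genes=genes)
        assert extract_neighborhood(shrunk, 0).contig_edge >= flagged


def test_neighborhood_size_bound():
    rec = _toy_record()
    for i in range(len(rec.genes)):
        nbhd = extract_neighborhood(rec, i, window=7)
        assert len(nbhd.genes) <= 15
        if 7 <= i < len(rec.genes) - 7:
            assert len(nbhd.genes) == 15


def test_coordinate_roundtrip_random_features(tmp_path):
    rng = random.Random(42)
    genes = []
    pos = 0
    for i in range(200):
        pos += rng.randint(10, 50)
        ln = 3 * rng.randint(3, 40)
        genes.append(
            GeneFeature(
                locus_id=f"g{i}",
                protein_id=f"p{i}",
                start=pos,
                end=pos + ln,
                strand=rng.choice((1, -1)),
                index=i,
            )
        )
        pos += ln
    dna = "".join(rng.choice("ACGT") for _ in range(pos + 100))
    rec = GenomeRecord(record_id="rt", dna=dna, genes=genes)
    path = tmp_path / "rt.gbk"
    write_genbank([rec], path)
    back = read_genbank(path)[0]
    assert [(g.start, g.end, g.strand) for g in back.genes] == [
        (g.start, g.end, g.strand) for g in rec.genes
    ]


def test_write_report_empty(tmp_path):
    report = MiningReport()
    files = write_report(report, tmp_path, formats=("tsv",))
    lines = files["tsv"].read_text().splitlines()
    assert len(lines) == 1
    assert lines[0].startswith("record_id\tbgc_id")


def _mined_report(pipeline_config, fixture_genome):
    from lanminer.pipeline import mine_records

    record, _ = fixture_genome
    return mine_records([record], pipeline_config)


def test_write_report_gff3_and_tsv_roundtrip(tmp_path, pipeline_config, fixture_genome):
    report = _mined_report(pipeline_config, fixture_genome)
    assert report.precursor_calls
    files = write_report(report, tmp_path)
    gff_lines = [l for l in files["gff3"].read_text().splitlines() if not l.startswith("#")]
    assert len(gff_lines) == len(report.precursor_calls)
    for line, (_, call) in zip(gff_lines, report.precursor_calls):
        cols = line.split("\t")
        assert int(cols[3]) == call.orf.start + 1  # 1-based inclusive
        assert int(cols[4]) == call.orf.end
    rows = read_report_tsv(files["tsv"])
    assert len(rows) == len(report.precursor_calls)
    # write-then-reparse is field-identical with a second write
    out2 = tmp_path / "again"
    files2 = write_report(report, out2)
    assert files["tsv"].read_bytes() == files2["tsv"].read_bytes()
    assert files["gff3"].read_bytes() == files2["gff3"].read_bytes()
    assert files["fasta"].read_bytes() == files2["fasta"].read_bytes()
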