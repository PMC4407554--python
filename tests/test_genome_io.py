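import os

import pytest

from spanprime.genome_io import (
    GeneModel,
    InputError,
    SequenceRecord,
    extract_gene,
    normalize_seq,
    read_fasta,
    read_gff3,
    revcomp,
    write_fasta,
    write_reports,
)

GFF = """##gff-version 3
chr1\ttest\tgene\t101\t160\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t101\t160\t.\t+\t.\tID=g1.1;Parent=g1
chr1\ttest\texon\t101\t160\t.\t+\t.\tID=g1.1.e1;Parent=g1.1
chr1\ttest\tCDS\t101\t160\t.\t+\t0\tID=g1.1.c1;Parent=g1.1
chr1\ttest\tgene\t301\t520\t.\t-\t.\tID=g2
chr1\ttest\tmRNA\t301\t520\t.\t-\t.\tID=g2.1;Parent=g2
chr1\ttest\texon\t301\t380\t.\t-\t.\tID=g2.1.e1;Parent=g2.1
chr1\ttest\texon\t461\t520\t.\t-\t.\tID=g2.1.e2;Parent=g2.1
chr1\ttest\tCDS\t301\t380\t.\t-\t0\tID=g2.1.c1;Parent=g2.1
chr1\ttest\tCDS\t461\t520\t.\t-\t0\tID=g2.1.c2;Parent=g2.1
"""


@pytest.fixture()
def toy_chrom(rnd):
    from conftest import random_dna

    return SequenceRecord(id="chr1", description="", seq=random_dna(rnd, 1000))


def test_fasta_normalization_and_round_trip(tmp_path):
    p = tmp_path / "in.fa"
    p.write_text(">g1 some gene\nacgu\nACGT\n")
    recs = read_fasta(str(p))
    assert recs[0].id == "g1"
    assert recs[0].seq == "ACGTACGT"  # case + U->T normalization
    out = tmp_path / "out.fa"
    write_fasta(recs, str(out))
    assert [r.seq for r in read_fasta(str(out))] == [r.seq for r in recs]


def test_fasta_errors(tmp_path):
    dup = tmp_path / "dup.fa"
    dup.write_text(">g1\nACGT\n>g1\nTTTT\n")
    with pytest.raises(InputError, match="duplicate"):
        read_fasta(str(dup))
    bad = tmp_path / "bad.fa"
    bad.write_text(">g1\nACXT\n")
    with pytest.raises(InputError, match="illegal"):
        read_fasta(str(bad))
    assert read_fasta(str(bad), strict=False)[0].seq == "ACNT"
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(InputError):
        read_fasta(str(empty))


def test_gff3_coordinate_and_strand_conventions(tmp_path, toy_chrom):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF)
    models = {m.gene_id: m for m in read_gff3(str(p), [toy_chrom])}
    g1 = models["g1.1"]
    assert g1.exons == ((100, 160),)  # 1-based inclusive -> 0-based half-open
    g2 = models["g2.1"]
    # minus strand: transcript order lists the rightmost genomic interval first
    assert g2.exons == ((460, 520), (300, 380))
    assert g2.strand == "-"


def test_gff3_feature_outside_chromosome(tmp_path, toy_chrom):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF.replace("461\t520", "461\t2000"))
    with pytest.raises(InputError, match="outside"):
        read_gff3(str(p), [toy_chrom])


def test_extract_plus_strand_single_exon(toy_chrom):
    model = GeneModel("g1", "chr1", "+", ((100, 160),), ((100, 160),))
    gs = extract_gene(model, [toy_chrom])
    assert gs.genomic == toy_chrom.seq[100:160]
    assert gs.cds == gs.genomic
    assert gs.exon_blocks.blocks == [(0, 60, 0, 60)]


def test_extract_minus_strand_is_reverse_complement(toy_chrom):
    model = GeneModel("g2", "chr1", "-", ((460, 520), (300, 380)), ((460, 520), (300, 380)))
    gs = extract_gene(model, [toy_chrom])
    assert gs.genomic == revcomp(toy_chrom.seq[300:520])
    # first CDS base is the rightmost genomic base of the rightmost exon
    assert gs.cds[0] == revcomp(toy_chrom.seq[519])
    assert gs.exon_blocks.splice(gs.genomic) == gs.cds


def test_extract_flank_clipped_at_chromosome_start(toy_chrom):
    # gene 150 bp from the chromosome start; a 200 bp flank clips to 150
    model = GeneModel("g3", "chr1", "+", ((150, 250),), ((150, 250),))
    gs = extract_gene(model, [toy_chrom], flank=200)
    assert gs.genomic == toy_chrom.seq[0:450]
    assert gs.exon_blocks.blocks == [(150, 250, 0, 100)]
    assert gs.exon_blocks.splice(gs.genomic) == gs.cds


def test_extract_missing_chromosome(toy_chrom):
    model = GeneModel("g1", "chrX", "+", ((0, 30),), ((0, 30),))
    with pytest.raises(InputError, match="chrX"):
        extract_gene(model, [toy_chrom])


def test_strand_mirror_property(toy_chrom):
    """Extracting from the genome and from its reverse complement (with
    mirrored annotation) yields identical gene sequences."""
    L = len(toy_chrom.seq)
    mirror = SequenceRecord(id="chr1", description="", seq=revcomp(toy_chrom.seq))
    fwd = GeneModel("g", "chr1", "+", ((300, 380), (460, 520)), ((300, 380), (460, 520)))
    rev = GeneModel(
        "g", "chr1", "-",
        ((L - 380, L - 300), (L - 520, L - 460)),
        ((L - 380, L - 300), (L - 520, L - 460)),
    )
    gs_f = extract_gene(fwd, [toy_chrom])
    gs_r = extract_gene(rev, [mirror])
    assert gs_f.genomic == gs_r.genomic
    assert gs_f.cds == gs_r.cds
    assert gs_f.exon_blocks.blocks == gs_r.exon_blocks.blocks


def test_reports_deterministic_and_well_formed(tmp_path, design_result):
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    results = {"gene_a": "gA", "gene_b": "gB", "pairs": design_result.pairs[:25]}
    write_reports(results, str(out1))
    write_reports(results, str(out2))
    t1 = (out1 / "primer_pairs.tsv").read_bytes()
    assert t1 == (out2 / "primer_pairs.tsv").read_bytes()
    lines = t1.decode().splitlines()
    assert lines[0].split("\t")[0] == "pair_id"
    assert len(lines) == 26
    # empty result set: header-only TSV, empty BED
    write_reports({"gene_a": "gA", "gene_b": "gB", "pairs": []}, str(tmp_path / "r0"))
    assert (tmp_path / "r0" / "primer_pairs.tsv").read_text().count("\n") == 1
    assert (tmp_path / "r0" / "amplicons.bed").read_text() == ""
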