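import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from conftest import random_dna
from spanprime.gene_structure import ExonBlocks
from spanprime.genome_io import revcomp
from spanprime.ortholog_align import PairwiseAlignment, build_pair_structure, conserved_blocks
from spanprime.primer_design import (
    PrimerParams,
    enumerate_primers,
    melting_temp,
    pair_primers,
    paginate,
    refine_pairs,
    score_pair,
)


def test_tm_matches_independent_nearest_neighbor(rnd):
    for _ in range(50):
        s = random_dna(rnd, rnd.randint(8, 50))
        ref = mt.Tm_NN(s, nn_table=mt.DNA_NN3, dnac1=250, dnac2=0, Na=50, saltcorr=5)
        assert melting_temp(s) == pytest.approx(ref, abs=0.01)


def test_tm_monotonic_in_gc():
    low = "ATATATATATATATATATAT"
    high = "ATATATATGCGCATATATAT"
    assert melting_temp(high) > melting_temp(low)


def test_tm_rejects_bad_input():
    with pytest.raises(ValueError):
        melting_temp("ACGTA")  # 5-mer
    with pytest.raises(ValueError):
        melting_temp("ACGTNACGTACGTACGT")


def _flat_structure(a_row, b_row, junctions_a=(), junctions_b=()):
    def eb(row, juncs):
        cds_len = len(row.replace("-", ""))
        blocks, g, prev = [], 0, 0
        for off in list(juncs) + [cds_len]:
            blocks.append((g, g + off - prev, prev, off))
            g += (off - prev) + 500
            prev = off
        return ExonBlocks(blocks)

    aln = PairwiseAlignment(a_row, b_row, score=0)
    return build_pair_structure(aln, eb(a_row, junctions_a), eb(b_row, junctions_b))


def test_enumeration_equals_window_oracle(rnd):
    """On an identical 30-column block, candidates = all windows of every
    allowed length and orientation that pass the Tm/GC filters."""
    row = random_dna(rnd, 30)
    ps = _flat_structure(row, row)
    blocks = conserved_blocks(ps, min_block_len=18)
    p = PrimerParams()
    got = enumerate_primers(ps, blocks, p)
    expected = 0
    for off in range(30):
        for length in range(p.len_min, p.len_max + 1):
            if off + length > 30:
                continue
            for orient in ("forward", "reverse"):
                w = row[off : off + length]
                seq = w if orient == "forward" else revcomp(w)
                gc = 100.0 * sum(c in "GC" for c in seq) / len(seq)
                if not (p.gc_min <= gc <= p.gc_max):
                    continue
                if not (p.tm_min <= melting_temp(seq) <= p.tm_max):
                    continue
                expected += 1
    assert len(got) == expected
    assert all(len(c.mismatch_cols) == 0 for c in got)


def test_short_block_yields_nothing(rnd):
    row = random_dna(rnd, 17)
    ps = _flat_structure(row, row)
    assert enumerate_primers(ps, conserved_blocks(ps, min_block_len=1)) == []


def test_3prime_terminal_mismatch_excluded():
    # 24-column block whose species-B allele differs at the last base:
    # every forward window ending there must be excluded
    a_row = "GCAGGTACGATCGGCATCGAGCAC"
    b_row = a_row[:-1] + ("A" if a_row[-1] != "A" else "C")
    ps = _flat_structure(a_row, b_row)
    got = enumerate_primers(ps, conserved_blocks(ps), PrimerParams())
    assert all(
        not (c.orientation == "forward" and c.col_end == 24) for c in got
    )
    # ... and reverse primers whose 3' end is the block start are unaffected
    # by that terminal column unless it falls in their own 3' window
    for c in got:
        assert not c.has_3prime_mismatch


def test_pair_product_arithmetic_two_exon_fixture(rnd):
    """Identical exon placement, intron 500 bp in A vs 300 bp in B: every
    pair's product sizes differ by exactly 200."""
    row = random_dna(rnd, 120)

    def eb(intron):
        return ExonBlocks([(0, 60, 0, 60), (60 + intron, 120 + intron, 60, 120)])

    aln = PairwiseAlignment(row, row, score=0)
    ps = build_pair_structure(aln, eb(500), eb(300))
    p = PrimerParams(product_min=100, product_max=2000)
    cands = enumerate_primers(ps, conserved_blocks(ps), p)
    pairs = pair_primers(cands, ps, p)
    assert pairs
    for pr in pairs:
        assert pr.product_size_a - pr.product_size_b == 200
        assert pr.introns_spanned_a == pr.introns_spanned_b == 1
    # same-exon combinations span no intron and must not appear
    assert all(not (pr.fw.col_end <= 60 and pr.rv.col_start < 60) for pr in pairs)


def test_product_size_out_of_range_in_one_species_rejects_pair(rnd):
    row = random_dna(rnd, 120)

    def eb(intron):
        return ExonBlocks([(0, 60, 0, 60), (60 + intron, 120 + intron, 60, 120)])

    aln = PairwiseAlignment(row, row, score=0)
    ps = build_pair_structure(aln, eb(500), eb(2500))  # B product always > 2000
    p = PrimerParams(product_min=100, product_max=2000)
    cands = enumerate_primers(ps, conserved_blocks(ps), p)
    assert pair_primers(cands, ps, p) == []


def test_score_formula():
    p = PrimerParams()
    assert score_pair(0, 0, 58.0, 58.0, 800, 800, p) == 100.0
    base = score_pair(0, 0, 58.0, 58.0, 800, 800, p)
    one_3p = score_pair(1, 1, 58.0, 58.0, 800, 800, p)
    assert base - one_3p == pytest.approx(p.w_mm + p.w_mm3)  # 11 by default
    # species-label symmetry of the size term
    assert score_pair(0, 0, 58.0, 58.0, 700, 900, p) == score_pair(
        0, 0, 58.0, 58.0, 900, 700, p
    )


def test_refine_is_pure_commutative_filter(design_result):
    pairs = design_result.pairs[:300]
    p = PrimerParams()
    assert refine_pairs(pairs, p, original=p) == pairs  # identity
    strict_mm = PrimerParams(max_mismatches_per_primer=0)
    only_clean = refine_pairs(pairs, strict_mm, original=p)
    assert only_clean and all(
        len(pr.fw.mismatch_cols) == 0 and len(pr.rv.mismatch_cols) == 0
        for pr in only_clean
    )
    x = PrimerParams(max_mismatches_per_primer=1)
    y = PrimerParams(tm_min=56.0)
    xy = refine_pairs(refine_pairs(pairs, x, original=p), y, original=p)
    yx = refine_pairs(refine_pairs(pairs, y, original=p), x, original=p)
    assert xy == yx
    ids = {pr.pair_id for pr in pairs}
    assert {pr.pair_id for pr in xy} <= ids  # never adds pairs


def test_refine_looser_criteria_warns_and_noops(design_result):
    pairs = design_result.pairs[:50]
    p = PrimerParams()
    looser = PrimerParams(max_mismatches_per_primer=5, product_max=9999)
    with pytest.warns(UserWarning, match="looser"):
        assert refine_pairs(pairs, looser, original=p) == pairs


def test_first_page_holds_top_scoring_pairs(design_result):
    pairs = design_result.pairs
    pages = paginate(pairs, page_size=60)
    first = pages[0]
    assert len(first) == min(60, len(pairs))
    top = sorted(pairs, key=lambda pr: -pr.score)[: len(first)]
    assert sorted(pr.score for pr in first) == sorted(pr.score for pr in top)
    assert [pr.rank for pr in first] == list(range(1, len(first) + 1))
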