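import random

import pytest
from Bio import Align

from conftest import random_dna
from oracles import affine_align
from spanprime.gene_structure import ExonBlocks
from spanprime.ortholog_align import (
    AlignParams,
    GAP_A,
    GAP_B,
    MISMATCH,
    build_pair_structure,
    conserved_blocks,
    global_align_cds,
)


def single_exon(n):
    return ExonBlocks([(0, n, 0, n)])


def multi_exon(cds_len, junction_offsets, intron=500):
    blocks, g, prev = [], 0, 0
    for off in list(junction_offsets) + [cds_len]:
        blocks.append((g, g + off - prev, prev, off))
        g += (off - prev) + intron
        prev = off
    return ExonBlocks(blocks)


def test_identical_sequences_score_2L(rnd):
    s = random_dna(rnd, 80)
    aln = global_align_cds(s, s)
    assert aln.score == 160 and aln.aligned_a == aln.aligned_b == s


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        global_align_cds("ACGT", "")


def test_gap_removal_recovers_inputs(rnd):
    for _ in range(10):
        a, b = random_dna(rnd, 120), random_dna(rnd, 100)
        aln = global_align_cds(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b
        assert not any(
            x == y == "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
        )


def test_alignment_matches_independent_dp_oracle(rnd):
    for _ in range(15):
        n, m = rnd.randint(10, 80), rnd.randint(10, 80)
        a, b = random_dna(rnd, n), random_dna(rnd, m)
        aln = global_align_cds(a, b)
        oa, ob, oscore = affine_align(a, b)
        assert aln.score == oscore
        assert (aln.aligned_a, aln.aligned_b) == (oa, ob)


def test_score_matches_biopython_global_aligner(rnd):
    """Score-only cross-check against a third, unrelated implementation."""
    p = AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open + p.gap_extend
    aligner.extend_gap_score = p.gap_extend
    for _ in range(10):
        a, b = random_dna(rnd, 150), random_dna(rnd, 140)
        assert global_align_cds(a, b).score == aligner.score(a, b)


def test_junction_projection_gapless_and_shifted(rnd):
    s = random_dna(rnd, 120)
    aln = global_align_cds(s, s)
    ps = build_pair_structure(aln, multi_exon(120, [90]), single_exon(120))
    assert ps.junctions_a == (90,) and ps.junctions_b == ()

    # hand-built 30-column alignment: three B-only columns (gap in the A row)
    # before A's junction at CDS offset 15 shift that junction column to 18
    b_row = "ACGTACGTACGTACGTACGTACGTACGTAC"
    a_row = b_row[:10] + "---" + b_row[13:]
    from spanprime.ortholog_align import PairwiseAlignment

    aln2 = PairwiseAlignment(a_row, b_row, score=0)
    ps2 = build_pair_structure(aln2, multi_exon(27, [15]), multi_exon(30, [20]))
    assert ps2.junctions_a == (18,)
    assert ps2.col_state[10] == GAP_A


def test_junction_out_of_range_rejected(rnd):
    s = random_dna(rnd, 50)
    aln = global_align_cds(s, s)
    with pytest.raises(ValueError, match="out of range"):
        build_pair_structure(aln, multi_exon(50, [50]), single_exon(50))


def block_oracle(state, junctions, min_len):
    """Brute-force scanner: maximal gapless runs split at junctions."""
    cuts = set(junctions)
    blocks, start = [], None
    for col in range(len(state) + 1):
        end_run = col == len(state) or state[col] in (GAP_A, GAP_B) or col in cuts
        if start is not None and end_run:
            if col - start >= min_len:
                blocks.append((start, col))
            start = None
        if col < len(state) and state[col] not in (GAP_A, GAP_B) and start is None:
            start = col
    return blocks


def test_conserved_blocks_match_enumeration_oracle(rnd):
    from spanprime.ortholog_align import PairwiseAlignment
    import numpy as np

    a_row = random_dna(rnd, 120)
    b_list = list(a_row)
    b_list[10] = "A" if a_row[10] != "A" else "C"
    b_list[60] = "A" if a_row[60] != "A" else "C"
    b_row = "".join(b_list)
    aln = PairwiseAlignment(a_row, b_row, score=0)
    ps = build_pair_structure(aln, multi_exon(120, [40]), multi_exon(120, [80]))
    got = conserved_blocks(ps, min_block_len=18, max_mismatches_per_block=3)
    want = block_oracle(ps.col_state, {40, 80}, 18)
    assert [(b.col_start, b.col_end) for b in got] == want
    assert got[0].mismatch_cols == (10,)
    # identical single-exon alignment: one block covering everything
    aln_id = PairwiseAlignment(a_row, a_row, score=0)
    ps_id = build_pair_structure(aln_id, single_exon(120), single_exon(120))
    blk = conserved_blocks(ps_id)
    assert [(b.col_start, b.col_end, b.mismatch_cols) for b in blk] == [(0, 120, ())]


def test_gap_column_splits_blocks(rnd):
    from spanprime.ortholog_align import PairwiseAlignment

    a_row = random_dna(rnd, 120)
    b_row = a_row[:50] + "-" + a_row[51:]
    aln = PairwiseAlignment(a_row, b_row, score=0)
    ps = build_pair_structure(aln, single_exon(120), single_exon(119))
    got = [(b.col_start, b.col_end) for b in conserved_blocks(ps)]
    assert got == [(0, 50), (51, 120)]


def test_mismatch_budget_monotonic_nesting(rnd):
    """Blocks from a stricter mismatch budget nest inside looser ones."""
    from spanprime.ortholog_align import PairwiseAlignment

    for trial in range(20):
        a_row = random_dna(rnd, 200)
        b_list = list(a_row)
        for pos in rnd.sample(range(200), 12):
            b_list[pos] = rnd.choice([c for c in "ACGT" if c != a_row[pos]])
        aln = PairwiseAlignment(a_row, "".join(b_list), score=0)
        ps = build_pair_structure(aln, single_exon(200), single_exon(200))
        by_budget = {
            k: conserved_blocks(ps, min_block_len=5, max_mismatches_per_block=k)
            for k in (0, 1, 2, 3)
        }
        for strict, loose in ((0, 1), (1, 2), (2, 3)):
            for sb in by_budget[strict]:
                assert any(
                    lb.col_start <= sb.col_start and sb.col_end <= lb.col_end
                    for lb in by_budget[loose]
                ), (trial, strict, loose, sb)
        for k, blocks in by_budget.items():
            for b in blocks:
                assert len(b.mismatch_cols) <= k
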