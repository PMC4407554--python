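"""Pairwise CDS alignment and the two-species gene structure.

The two orthologous coding sequences are aligned globally with affine gap
costs (Needleman–Wunsch / Gotoh).  Both species' exon–intron junctions are
then projected onto alignment columns, giving a *pair structure* from which
gapless, junction-free, well-conserved blocks are extracted as the only
territory where cross-species primers may sit.

Gap model: a gap of length ``k`` costs ``gap_open + k * gap_extend`` (both
negative).  The three-state DP allows direct insertion<->deletion
transitions, so the score is the true optimum of that model.  Traceback is
deterministic: on ties the match state is preferred, then a gap in sequence
B (consuming A), then a gap in sequence A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_structure import ExonBlocks

_NEG = np.int64(-(10**12))


@dataclass(frozen=True)
class AlignParams:
    """Scoring for coding DNA at roughly 70–95% identity."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -12
    gap_extend: int = -2


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: int
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)


def global_align_cds(
    cds_a: str, cds_b: str, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap costs.

    Raises ``ValueError`` on empty input.  Deterministic traceback (ties:
    diagonal, then up, then left) makes repeated runs byte-identical.
    """
    p = params or AlignParams()
    if not cds_a or not cds_b:
        raise ValueError("cannot align an empty sequence")
    a = np.frombuffer(cds_a.encode(), dtype=np.uint8)
    b = np.frombuffer(cds_b.encode(), dtype=np.uint8)
    n, m = len(a), len(b)
    go, ge = np.int64(p.gap_open), np.int64(p.gap_extend)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in B (consumes A)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in A (consumes B)
    M[0, 0] = 0
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    Iy[0, 1:] = go + ge * j_idx
    i_col = np.arange(1, n + 1, dtype=np.int64)
    Ix[1:, 0] = go + ge * i_col

    jj = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], p.match, p.mismatch).astype(np.int64)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub + prev_best[:-1]
        M[i, 0] = _NEG
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + go + ge,
            Ix[i - 1, 1:] + ge,
        )
        # Iy row is a prefix-max scan over the current row's M and Ix
        base = np.maximum(M[i], Ix[i]) + go - ge * jj
        run = np.maximum.accumulate(base)
        Iy[i, 1:] = run[:-1] + ge * jj[1:]
        Iy[i, 0] = _NEG

    # deterministic traceback on stored matrices; preference M > Ix > Iy
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    scores = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(scores))  # argmax returns first max: M > Ix > Iy
    score = int(scores[state])
    while i > 0 or j > 0:
        if state == 0:  # M: a[i-1] aligned to b[j-1]
            out_a.append(cds_a[i - 1])
            out_b.append(cds_b[j - 1])
            target = M[i, j] - (
                p.match if cds_a[i - 1] == cds_b[j - 1] else p.mismatch
            )
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            for nxt, mat in ((0, M), (1, Ix), (2, Iy)):
                if mat[i, j] == target:
                    state = nxt
                    break
        elif state == 1:  # Ix: a[i-1] against a gap
            out_a.append(cds_a[i - 1])
            out_b.append("-")
            val = Ix[i, j]
            i -= 1
            if M[i, j] + go + ge == val:
                state = 0
            elif Ix[i, j] + ge == val:
                state = 1
            else:
                state = 2
        else:  # Iy: b[j-1] against a gap
            out_a.append("-")
            out_b.append(cds_b[j - 1])
            val = Iy[i, j]
            j -= 1
            if M[i, j] + go + ge == val:
                state = 0
            elif Ix[i, j] + go + ge == val:
                state = 1
            else:
                state = 2
    return PairwiseAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=score,
        params=p,
    )


# ---------------------------------------------------------------------------
# Pair structure
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP_A, GAP_B = 0, 1, 2, 3


@dataclass
class PairStructure:
    """A two-species CDS alignment with both exon structures projected on it.

    ``junctions_a``/``junctions_b`` hold alignment-column indices ``j`` such
    that an intron of that species sits between columns ``j-1`` and ``j``.
    ``col_state`` codes each column as match / mismatch / gap_a / gap_b.
    """

    alignment: PairwiseAlignment
    exons_a: ExonBlocks
    exons_b: ExonBlocks
    junctions_a: tuple[int, ...]
    junctions_b: tuple[int, ...]
    col_state: np.ndarray
    col_to_cds_a: np.ndarray  # -1 on gap columns
    col_to_cds_b: np.ndarray
    cds_to_col_a: np.ndarray
    cds_to_col_b: np.ndarray

    def genomic_a(self, col: int) -> int:
        """Species-A local genomic coordinate of an alignment column."""
        c = int(self.col_to_cds_a[col])
        if c < 0:
            raise IndexError(f"column {col} is a gap in species A")
        return self.exons_a.cds_to_genomic(c)

    def genomic_b(self, col: int) -> int:
        c = int(self.col_to_cds_b[col])
        if c < 0:
            raise IndexError(f"column {col} is a gap in species B")
        return self.exons_b.cds_to_genomic(c)


def build_pair_structure(
    aln: PairwiseAlignment, exons_a: ExonBlocks, exons_b: ExonBlocks
) -> PairStructure:
    """Project both species' junction offsets onto alignment columns."""
    arr_a = np.frombuffer(aln.aligned_a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(aln.aligned_b.encode(), dtype=np.uint8)
    gap = ord("-")
    is_gap_a = arr_a == gap
    is_gap_b = arr_b == gap
    col_state = np.where(
        is_gap_a, GAP_A, np.where(is_gap_b, GAP_B, np.where(arr_a == arr_b, MATCH, MISMATCH))
    ).astype(np.uint8)

    def maps(is_gap: np.ndarray, cds_len: int):
        col_to_cds = np.cumsum(~is_gap) - 1
        col_to_cds[is_gap] = -1
        cds_to_col = np.flatnonzero(~is_gap)
        if len(cds_to_col) != cds_len:
            raise ValueError(
                f"alignment row holds {len(cds_to_col)} bases but CDS has {cds_len}"
            )
        return col_to_cds.astype(np.int64), cds_to_col.astype(np.int64)

    col_to_cds_a, cds_to_col_a = maps(is_gap_a, exons_a.cds_len)
    col_to_cds_b, cds_to_col_b = maps(is_gap_b, exons_b.cds_len)

    def project(offsets, cds_to_col, cds_len) -> tuple[int, ...]:
        cols = []
        for t in offsets:
            if not (0 < t < cds_len):
                raise ValueError(f"junction CDS offset {t} out of range")
            cols.append(int(cds_to_col[t]))
        return tuple(cols)

    return PairStructure(
        alignment=aln,
        exons_a=exons_a,
        exons_b=exons_b,
        junctions_a=project(exons_a.junction_cds_offsets(), cds_to_col_a, exons_a.cds_len),
        junctions_b=project(exons_b.junction_cds_offsets(), cds_to_col_b, exons_b.cds_len),
        col_state=col_state,
        col_to_cds_a=col_to_cds_a,
        col_to_cds_b=col_to_cds_b,
        cds_to_col_a=cds_to_col_a,
        cds_to_col_b=cds_to_col_b,
    )


@dataclass(frozen=True)
class ConservedBlock:
    """A gapless, junction-free alignment segment eligible for primers."""

    col_start: int
    col_end: int
    mismatch_cols: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


def _split_by_mismatch(
    col_start: int, col_end: int, mismatches: list[int], max_mm: int
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Recursively split at the median mismatch until each piece is within
    budget.  The split tree depends only on mismatch positions, so blocks
    from a stricter budget always nest inside blocks from a looser one."""
    if len(mismatches) <= max_mm:
        return [(col_start, col_end, tuple(mismatches))]
    mid = mismatches[len(mismatches) // 2]
    left = [m for m in mismatches if m < mid]
    right = [m for m in mismatches if m > mid]
    out = []
    if mid > col_start:
        out.extend(_split_by_mismatch(col_start, mid, left, max_mm))
    if mid + 1 < col_end:
        out.extend(_split_by_mismatch(mid + 1, col_end, right, max_mm))
    return out


def conserved_blocks(
    ps: PairStructure,
    min_block_len: int = 18,
    max_mismatches_per_block: int = 3,
) -> list[ConservedBlock]:
    """Maximal gapless alignment runs, split at every junction column of
    either species, then split further until each block carries at most
    ``max_mismatches_per_block`` mismatch columns; blocks shorter than
    ``min_block_len`` are dropped."""
    n = len(ps.alignment)
    boundaries = set(ps.junctions_a) | set(ps.junctions_b)
    blocks: list[ConservedBlock] = []
    start = None
    for col in range(n + 1):
        gap_here = col < n and ps.col_state[col] in (GAP_A, GAP_B)
        if start is not None and (col == n or gap_here or col in boundaries):
            if col > start:
                mism = [
                    c for c in range(start, col) if ps.col_state[c] == MISMATCH
                ]
                for s, e, mm in _split_by_mismatch(
                    start, col, mism, max_mismatches_per_block
                ):
                    if e - s >= min_block_len:
                        blocks.append(ConservedBlock(s, e, mm))
            start = None
        if col < n and not gap_here and (start is None):
            start = col
    blocks.sort(key=lambda b: b.col_start)
    return blocks
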