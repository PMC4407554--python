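"""Independent reference implementations used only to check the package.

Each oracle is deliberately written in the most transparent way possible
(plain Python, no vectorisation, no shared code with the implementation) so
that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def affine_align(a: str, b: str, match=2, mismatch=-3, gap_open=-12, gap_extend=-2):
    """Three-state affine-gap global alignment by straightforward DP.

    Gap of length k costs gap_open + k*gap_extend; insertion<->deletion
    transitions allowed.  Ties prefer the match state, then a gap in b
    (consuming a), then a gap in a — both in the final cell and at every
    traceback step.  Returns (aligned_a, aligned_b, score).
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )
    finals = (M[n][m], X[n][m], Y[n][m])
    best = max(finals)
    state = finals.index(best)  # index() returns the first: M > X > Y
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for nxt, mat in ((0, M), (1, X), (2, Y)):
                if mat[i][j] == target:
                    state = nxt
                    break
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i][j]
            i -= 1
            if M[i][j] + gap_open + gap_extend == val:
                state = 0
            elif X[i][j] + gap_extend == val:
                state = 1
            else:
                state = 2
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if M[i][j] + gap_open + gap_extend == val:
                state = 0
            elif X[i][j] + gap_extend == val:
                state = 1
            else:
                state = 2
    return "".join(reversed(out_a)), "".join(reversed(out_b)), best


def hamming_hits(primer: str, chrom: str, max_mm: int) -> set[tuple[int, str, int]]:
    """All (start, strand, mismatches) with Hamming distance <= max_mm,
    via numpy's sliding-window view (a different route than the
    per-offset accumulation used by the implementation)."""
    out: set[tuple[int, str, int]] = set()
    g = np.frombuffer(chrom.encode(), dtype=np.uint8)
    m = len(primer)
    if len(g) < m:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(g, m)
    for strand, seq in (("+", primer), ("-", rc(primer))):
        p = np.frombuffer(seq.encode(), dtype=np.uint8)
        mm = (windows != p).sum(axis=1)
        for start in np.flatnonzero(mm <= max_mm):
            out.add((int(start), strand, int(mm[start])))
    return out


def combo_amplicons(fw_hits, rv_hits, max_size: int) -> set[tuple[str, int, int]]:
    """Exhaustive (chrom, start, end) amplicon set from hit lists given as
    (chrom, start, strand, length) tuples."""
    out = set()
    for lh_pool, rh_pool in ((fw_hits, rv_hits), (rv_hits, fw_hits)):
        for c1, s1, st1, L1 in lh_pool:
            if st1 != "+":
                continue
            for c2, s2, st2, L2 in rh_pool:
                if st2 != "-" or c1 != c2:
                    continue
                size = (s2 + L2) - s1
                if L1 + L2 <= size <= max_size:
                    out.add((c1, s1, s2 + L2))
    return out
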