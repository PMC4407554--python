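"""Exon–intron structure of a gene, from annotation or by spliced alignment.

A gene's coding sequence (CDS) is a concatenation of exon segments of its
genomic sequence.  :class:`ExonBlocks` records that correspondence as a chain
of colinear blocks, each mapping a genomic interval onto a CDS interval of the
same length (no indels within a block).  Blocks can either be computed
arithmetically from a GFF3 annotation (:func:`junctions_from_annotation`) or
recovered de novo by aligning a CDS against the genomic sequence it was
spliced from (:func:`map_junctions`).

``map_junctions`` does the work a spliced aligner performs when the cDNA and
the genomic locus are (nearly) the same allele: seed maximal exact matches of
length >= ``anchor_k``, chain them colinearly by dynamic programming to
maximise matched CDS coverage, and then slide each exon/intron boundary
within a small window to prefer canonical GT..AG (then GC..AG) intron ends.
Because a CDS aligned to its own locus is near-identical, exact anchoring is
sufficient and the result is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .genome_io import GeneModel


class StructureError(ValueError):
    """Raised when exon blocks violate their invariants."""


class CoverageError(StructureError):
    """Raised when a CDS cannot be located on the genomic sequence."""


@dataclass(frozen=True)
class JunctionParams:
    """Tunables for CDS-to-genomic junction mapping.

    anchor_k: minimum exact-match seed length (bp).
    refine_window: how far (bp) a junction may slide during GT–AG refinement.
    min_coverage: minimum fraction of CDS bases matching the genomic
        sequence under the final block tiling.
    min_intron: introns shorter than this are treated as alignment noise.
    min_exon_anchor: minimum CDS length accepted at all.
    """

    anchor_k: int = 16
    refine_window: int = 10
    min_coverage: float = 0.95
    min_intron: int = 20
    min_exon_anchor: int = 20


@dataclass
class ExonBlocks:
    """Colinear exon blocks mapping genomic onto CDS coordinates.

    ``blocks`` is an ordered list of ``(g_start, g_end, c_start, c_end)``
    tuples, 0-based half-open in both coordinate systems.  CDS segments tile
    ``[0, cds_len)`` exactly and each block has equal genomic and CDS length.
    """

    blocks: list[tuple[int, int, int, int]]
    provenance: str = "annotation"

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive blocks."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]

    @property
    def cds_len(self) -> int:
        return self.blocks[-1][3] if self.blocks else 0

    @property
    def n_introns(self) -> int:
        return len(self.blocks) - 1

    def junction_cds_offsets(self) -> list[int]:
        """CDS offsets at which an intron interrupts the coding sequence.

        The junction before CDS base ``t`` is reported as ``t`` (the first
        base of the downstream exon).
        """
        return [b[3] for b in self.blocks[:-1]]

    def cds_to_genomic(self, c: int) -> int:
        """Map a CDS coordinate to its genomic coordinate."""
        for g_start, g_end, c_start, c_end in self.blocks:
            if c_start <= c < c_end:
                return g_start + (c - c_start)
        raise IndexError(f"CDS position {c} outside [0, {self.cds_len})")

    def splice(self, genomic: str) -> str:
        """Concatenate the genomic substrings of all blocks."""
        return "".join(genomic[g0:g1] for g0, g1, _, _ in self.blocks)

    def validate(self, min_intron: int = 20) -> None:
        if not self.blocks:
            raise StructureError("ExonBlocks requires at least one block")
        prev_g = prev_c = None
        for i, (g0, g1, c0, c1) in enumerate(self.blocks):
            if not (g0 < g1 and c0 < c1):
                raise StructureError(f"empty or inverted block {i}")
            if (g1 - g0) != (c1 - c0):
                raise StructureError(f"block {i} genomic/CDS length mismatch")
            if i == 0:
                if c0 != 0:
                    raise StructureError("CDS does not start at offset 0")
            else:
                if c0 != prev_c:
                    raise StructureError("CDS segments do not tile contiguously")
                if g0 <= prev_g:
                    raise StructureError("blocks overlap or are unsorted in genomic coordinates")
                if g0 - prev_g < min_intron:
                    raise StructureError(
                        f"intron {i - 1} shorter than min_intron={min_intron}"
                    )
            prev_g, prev_c = g1, c1


def blocks_from_intervals(
    intervals: Sequence[tuple[int, int]],
    strand: str,
    window_start: int,
    window_end: int,
) -> ExonBlocks:
    """Convert genomic feature intervals into local-coordinate exon blocks.

    ``intervals`` are genomic (chromosome-level, 0-based half-open) and must
    be given in transcript order.  The result is expressed in coordinates of
    the coding-strand window ``[window_start, window_end)``: for minus-strand
    genes the window is reverse complemented, so local position 0 is the
    window's rightmost genomic base.
    """
    if not intervals:
        raise StructureError("gene has no intervals")
    blocks: list[tuple[int, int, int, int]] = []
    c = 0
    for s, e in intervals:
        if not (window_start <= s < e <= window_end):
            raise StructureError(
                f"interval [{s},{e}) outside window [{window_start},{window_end})"
            )
        if strand == "+":
            ls, le = s - window_start, e - window_start
        elif strand == "-":
            ls, le = window_end - e, window_end - s
        else:
            raise StructureError(f"unknown strand {strand!r}")
        blocks.append((ls, le, c, c + (le - ls)))
        c += le - ls
    blocks.sort(key=lambda b: b[2])
    return ExonBlocks(blocks=blocks, provenance="annotation")


def junctions_from_annotation(model: "GeneModel", cds_only: bool = True) -> ExonBlocks:
    """Exon blocks of a gene model, local to its own (flankless) gene span.

    Same contract as :func:`map_junctions`, but computed arithmetically from
    the annotation.  Raises :class:`StructureError` if the annotation violates
    the block invariants (overlapping exons, negative introns, ...).
    """
    intervals = model.cds_intervals if cds_only else model.exons
    span_start = min(s for s, _ in model.exons)
    span_end = max(e for _, e in model.exons)
    eb = blocks_from_intervals(intervals, model.strand, span_start, span_end)
    eb.validate(min_intron=1)
    return eb


# ---------------------------------------------------------------------------
# CDS-to-genomic spliced mapping
# ---------------------------------------------------------------------------


def _maximal_anchors(cds: str, genomic: str, k: int) -> list[tuple[int, int, int, int]]:
    """All maximal exact matches of length >= k, as (c0, c1, g0, g1)."""
    index: dict[str, list[int]] = {}
    for g in range(len(genomic) - k + 1):
        index.setdefault(genomic[g : g + k], []).append(g)
    seen: set[tuple[int, int]] = set()  # (diagonal, c_start) of recorded maximal matches
    anchors: list[tuple[int, int, int, int]] = []
    for i in range(len(cds) - k + 1):
        for g in index.get(cds[i : i + k], ()):
            d = g - i
            # extend left
            ci, gi = i, g
            while ci > 0 and gi > 0 and cds[ci - 1] == genomic[gi - 1]:
                ci -= 1
                gi -= 1
            if (d, ci) in seen:
                continue
            seen.add((d, ci))
            # extend right
            cj, gj = i + k, g + k
            while cj < len(cds) and gj < len(genomic) and cds[cj] == genomic[gj]:
                cj += 1
                gj += 1
            anchors.append((ci, cj, gi, gj))
    anchors.sort(key=lambda a: (a[0], a[2]))
    return anchors


def _chain_anchors(
    anchors: list[tuple[int, int, int, int]], min_intron: int
) -> list[tuple[int, int, int, int]]:
    """Colinear chain maximising covered CDS length; ties broken leftmost.

    A transition a -> b trims b's head if it overlaps a in CDS coordinates,
    and is allowed only if the implied genomic gap is 0 (same diagonal, later
    merged) or at least ``min_intron``.
    """
    n = len(anchors)
    best = [a[1] - a[0] for a in anchors]
    pred = [-1] * n
    for j in range(n):
        cj0, cj1, gj0, gj1 = anchors[j]
        for i in range(j):
            ci0, ci1, gi0, gi1 = anchors[i]
            trim = max(0, ci1 - cj0)
            eff_c0 = cj0 + trim
            eff_g0 = gj0 + trim
            if eff_c0 >= cj1 or eff_g0 < gi1:
                continue
            diag_gap = (gj0 - cj0) - (gi0 - ci0)
            if diag_gap != 0 and diag_gap < min_intron:
                continue
            cand = best[i] + (cj1 - eff_c0)
            if cand > best[j]:
                best[j] = cand
                pred[j] = i
    end = max(range(n), key=lambda j: (best[j], -anchors[j][0], -anchors[j][2]))
    chain: list[tuple[int, int, int, int]] = []
    j = end
    while j != -1:
        chain.append(anchors[j])
        j = pred[j]
    chain.reverse()
    # apply head trims along the chain and merge same-diagonal neighbours
    merged: list[list[int]] = []
    for c0, c1, g0, g1 in chain:
        if merged:
            trim = max(0, merged[-1][1] - c0)
            c0 += trim
            g0 += trim
        if merged and (g0 - c0) == (merged[-1][2] - merged[-1][0]):
            merged[-1][1] = c1
            merged[-1][3] = g1
        else:
            merged.append([c0, c1, g0, g1])
    return [tuple(m) for m in merged]  # type: ignore[misc]


def _refine_boundary(
    cds: str,
    genomic: str,
    a: list[int],
    b: list[int],
    window: int,
) -> int:
    """Pick the CDS split point between two chained blocks.

    Candidate split points ``p`` extend block ``a`` to CDS ``[a0, p)`` and
    shrink/extend ``b`` to ``[p, b1)``; the intron length is fixed by the two
    diagonals.  Score = splice-site bonus (GT..AG +4, GC..AG +2) minus the
    number of CDS/genomic mismatches the assignment introduces; ties prefer
    the leftmost (smallest) ``p``.
    """
    a0, a1, ga0, _ = a
    b0, b1, gb0, _ = b
    diag_a = ga0 - a0
    diag_b = gb0 - b0
    lo = max(a0 + 1, min(a1, b0) - window)
    hi = min(b1 - 1, max(a1, b0) + window)
    best_p, best_score = None, None
    for p in range(lo, hi + 1):
        g_left = diag_a + p
        g_right = diag_b + p
        if g_left < 0 or g_right > len(genomic) or g_left >= g_right:
            continue
        mism = 0
        for x in range(lo, hi + 1):
            if x >= len(cds):
                break
            diag = diag_a if x < p else diag_b
            gpos = diag + x
            if gpos < 0 or gpos >= len(genomic) or cds[x] != genomic[gpos]:
                mism += 1
        intron = genomic[g_left:g_right]
        bonus = 0
        if intron[:2] == "GT" and intron[-2:] == "AG":
            bonus = 4
        elif intron[:2] == "GC" and intron[-2:] == "AG":
            bonus = 2
        score = bonus - mism
        if best_score is None or score > best_score:
            best_p, best_score = p, score
    if best_p is None:
        raise CoverageError("no feasible junction placement between chained blocks")
    return best_p


def map_junctions(
    cds: str, genomic: str, params: JunctionParams | None = None
) -> ExonBlocks:
    """Locate exon–intron junctions by aligning a CDS to its genomic locus.

    Returns :class:`ExonBlocks` with ``provenance='spliced_alignment'``.
    Raises :class:`CoverageError` when less than ``min_coverage`` of the CDS
    can be matched (e.g. an unrelated sequence).
    """
    p = params or JunctionParams()
    if len(cds) < p.min_exon_anchor:
        raise CoverageError(
            f"CDS shorter than min_exon_anchor={p.min_exon_anchor}"
        )
    if len(genomic) < len(cds):
        raise CoverageError("genomic sequence shorter than CDS")
    anchors = _maximal_anchors(cds, genomic, p.anchor_k)
    if not anchors:
        raise CoverageError("no anchor matches between CDS and genomic sequence")
    chain = [list(t) for t in _chain_anchors(anchors, p.min_intron)]
    # extend outermost blocks to cover the CDS ends
    head = chain[0]
    if head[0] > 0:
        shift = head[0]
        if head[2] - shift < 0:
            raise CoverageError("CDS head extends past genomic start")
        head[0] = 0
        head[2] -= shift
    tail = chain[-1]
    if tail[1] < len(cds):
        grow = len(cds) - tail[1]
        if tail[3] + grow > len(genomic):
            raise CoverageError("CDS tail extends past genomic end")
        tail[1] = len(cds)
        tail[3] += grow
    # refine interior boundaries towards canonical splice sites
    for a, b in zip(chain[:-1], chain[1:]):
        split = _refine_boundary(cds, genomic, a, b, p.refine_window)
        a[1] = split
        a[3] = (a[2] - a[0]) + split
        delta = split - b[0]
        b[0] = split
        b[2] += delta
    matched = 0
    for c0, c1, g0, _ in chain:
        for x in range(c0, c1):
            if cds[x] == genomic[g0 + (x - c0)]:
                matched += 1
    coverage = matched / len(cds)
    if coverage < p.min_coverage:
        raise CoverageError(
            f"matched CDS coverage {coverage:.3f} below min_coverage={p.min_coverage}"
        )
    eb = ExonBlocks(
        blocks=[(c[2], c[3], c[0], c[1]) for c in chain],
        provenance="spliced_alignment",
    )
    eb.validate(min_intron=p.min_intron)
    return eb
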