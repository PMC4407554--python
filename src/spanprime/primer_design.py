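"""Cross-species primer enumeration, pairing, scoring and refinement.

Primers are enumerated only inside conserved alignment blocks (gapless,
junction-free, low-mismatch; see :mod:`spanprime.ortholog_align`), so by
construction no primer crosses an exon–intron junction of either species.
The *template* species (default A) supplies the primer sequence; the other
species' allele may differ at up to ``max_mismatches_per_primer`` positions.
Mismatches near a primer's 3' end, consecutive mismatches and AT-rich 3'
ends are annotated and (configurably) filtered, since each depresses PCR
performance.

A primer pair must span at least ``min_introns_spanned`` introns in *both*
species and yield an intron-inclusive product within the allowed size range
in both genomes.  Pairs are scored by a transparent linear penalty (see
:func:`score_pair`) and ranked; higher scores are better.

Melting temperatures come from unified nearest-neighbor thermodynamics
(two-state model) with a monovalent-salt entropy correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .genome_io import revcomp
from .ortholog_align import MISMATCH, ConservedBlock, PairStructure

# Unified nearest-neighbor enthalpy (kcal/mol) and entropy (cal/mol/K) for
# DNA/DNA duplex propagation, keyed by the top-strand dinucleotide.  Values
# for a dinucleotide and its reverse complement are identical.
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM = (0.0, -1.4)
_R = 1.987  # cal/(mol*K)


def melting_temp(
    seq: str,
    primer_nm: float = 250.0,
    template_nm: float = 0.0,
    na_mm: float = 50.0,
) -> float:
    """Two-state nearest-neighbor melting temperature in degrees Celsius.

    ``primer_nm``/``template_nm`` are strand concentrations in nM (primer in
    excess); ``na_mm`` is the monovalent cation concentration in mM, applied
    as an entropy correction of ``0.368 (N-1) ln[Na+]``.
    """
    if not (8 <= len(seq) <= 50):
        raise ValueError(f"primer length {len(seq)} outside [8, 50]")
    if any(c not in "ACGT" for c in seq):
        raise ValueError("ambiguous base in primer")
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = _INIT_AT if end in "AT" else _INIT_GC
        dh += h
        ds += s
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
        ct = primer_nm * 1e-9
    else:
        ct = (primer_nm - template_nm / 2.0) * 1e-9
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm * 1e-3)
    return (1000.0 * dh) / (ds + _R * math.log(ct)) - 273.15


def gc_fraction(seq: str) -> float:
    return sum(c in "GC" for c in seq) / len(seq)


@dataclass(frozen=True)
class PrimerParams:
    """All tunable primer-design constraints (units in docs/methods.md)."""

    len_min: int = 18
    len_max: int = 24
    tm_min: float = 55.0
    tm_max: float = 62.0
    tm_opt: float = 58.0
    max_pair_tm_diff: float = 3.0
    gc_min: float = 35.0
    gc_max: float = 65.0
    max_mismatches_per_primer: int = 3
    forbid_3prime_mismatch_window: int = 5
    forbid_consecutive_mismatches: bool = True
    at_rich_3prime_filter: bool = False  # flag-only by default
    product_min: int = 300
    product_max: int = 2000
    min_introns_spanned: int = 1
    # score weights
    w_mm: float = 3.0
    w_mm3: float = 8.0
    w_tm: float = 1.0
    w_dtm: float = 2.0
    w_len: float = 1.0
    preferred_size: int = 800

    def __post_init__(self) -> None:
        if not (0 < self.len_min <= self.len_max):
            raise ValueError("invalid primer length range")
        if self.tm_min > self.tm_max or self.gc_min > self.gc_max:
            raise ValueError("invalid Tm/GC range")
        if self.product_min > self.product_max:
            raise ValueError("invalid product size range")


@dataclass(frozen=True)
class PrimerCandidate:
    """One oriented primer window inside a conserved block.

    ``template_seq`` is the primer 5'->3' as synthesised (for reverse
    primers this is the antisense strand of the alignment window).
    ``start_a``/``start_b`` are species-local genomic coordinates of the
    window's leftmost base on the coding strand.
    """

    orientation: str  # 'forward' | 'reverse'
    template_seq: str
    col_start: int
    col_end: int
    start_a: int
    start_b: int
    tm_a: float
    tm_b: float
    gc: float
    mismatch_cols: tuple[int, ...]
    has_3prime_mismatch: bool
    has_consecutive_mismatch: bool
    at_rich_3prime: bool

    def __len__(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    fw: PrimerCandidate
    rv: PrimerCandidate
    product_size_a: int
    product_size_b: int
    introns_spanned_a: int
    introns_spanned_b: int
    score: float
    rank: int


def _window_seqs(ps: PairStructure, cs: int, ce: int) -> tuple[str, str]:
    return ps.alignment.aligned_a[cs:ce], ps.alignment.aligned_b[cs:ce]


def enumerate_primers(
    ps: PairStructure,
    blocks: list[ConservedBlock],
    params: PrimerParams | None = None,
    template: str = "A",
) -> list[PrimerCandidate]:
    """All primer windows in all blocks passing the per-primer filters.

    Candidates come in deterministic order (block, offset, length,
    orientation).  An empty list is a legitimate result.
    """
    p = params or PrimerParams()
    if template not in ("A", "B"):
        raise ValueError("template must be 'A' or 'B'")
    out: list[PrimerCandidate] = []
    for blk in blocks:
        for off in range(blk.col_start, blk.col_end):
            for length in range(p.len_min, p.len_max + 1):
                cs, ce = off, off + length
                if ce > blk.col_end:
                    break
                for orientation in ("forward", "reverse"):
                    cand = _make_candidate(ps, cs, ce, orientation, p, template)
                    if cand is not None:
                        out.append(cand)
    return out


def _make_candidate(
    ps: PairStructure,
    cs: int,
    ce: int,
    orientation: str,
    p: PrimerParams,
    template: str,
) -> PrimerCandidate | None:
    win_a, win_b = _window_seqs(ps, cs, ce)
    if "N" in win_a or "N" in win_b:
        return None
    tpl_win, other_win = (win_a, win_b) if template == "A" else (win_b, win_a)
    mism = tuple(c for c in range(cs, ce) if ps.col_state[c] == MISMATCH)
    if len(mism) > p.max_mismatches_per_primer:
        return None
    # 3' end of a forward primer is the window's right edge; of a reverse
    # primer (antisense strand) the window's left edge.
    if orientation == "forward":
        three_prime_cols = range(max(cs, ce - p.forbid_3prime_mismatch_window), ce)
        primer_seq = tpl_win
    else:
        three_prime_cols = range(cs, min(ce, cs + p.forbid_3prime_mismatch_window))
        primer_seq = revcomp(tpl_win)
    has_3p = any(c in three_prime_cols for c in mism)
    if p.forbid_3prime_mismatch_window and has_3p:
        return None
    consecutive = any(b - a == 1 for a, b in zip(mism, mism[1:]))
    if p.forbid_consecutive_mismatches and consecutive:
        return None
    gc = 100.0 * gc_fraction(primer_seq)
    if not (p.gc_min <= gc <= p.gc_max):
        return None
    tm_a = melting_temp(win_a if orientation == "forward" else revcomp(win_a))
    tm_b = melting_temp(win_b if orientation == "forward" else revcomp(win_b))
    tm_tpl = tm_a if template == "A" else tm_b
    if not (p.tm_min <= tm_tpl <= p.tm_max):
        return None
    at_rich = all(c in "AT" for c in primer_seq[-5:])
    if p.at_rich_3prime_filter and at_rich:
        return None
    return PrimerCandidate(
        orientation=orientation,
        template_seq=primer_seq,
        col_start=cs,
        col_end=ce,
        start_a=ps.genomic_a(cs),
        start_b=ps.genomic_b(cs),
        tm_a=tm_a,
        tm_b=tm_b,
        gc=gc,
        mismatch_cols=mism,
        has_3prime_mismatch=has_3p,
        has_consecutive_mismatch=consecutive,
        at_rich_3prime=at_rich,
    )


def _introns_between(junctions: tuple[int, ...], fw_end: int, rv_start: int) -> int:
    """Junction columns j with fw_end <= j <= rv_start are spanned."""
    return sum(1 for j in junctions if fw_end <= j <= rv_start)


def score_pair(
    total_mismatches: int,
    mismatches_3prime: int,
    tm_fw: float,
    tm_rv: float,
    product_size_a: int,
    product_size_b: int,
    params: PrimerParams,
) -> float:
    """Linear penalty score; 100 is a perfect pair.

    score = 100 - [w_mm * mm + w_mm3 * mm_3' + w_tm * (|Tm_fw - Tm_opt| +
    |Tm_rv - Tm_opt|) + w_dtm * |Tm_fw - Tm_rv| +
    w_len * |mean(product sizes) - preferred| / 100]
    """
    mean_size = (product_size_a + product_size_b) / 2.0
    penalty = (
        params.w_mm * total_mismatches
        + params.w_mm3 * mismatches_3prime
        + params.w_tm * (abs(tm_fw - params.tm_opt) + abs(tm_rv - params.tm_opt))
        + params.w_dtm * abs(tm_fw - tm_rv)
        + params.w_len * abs(mean_size - params.preferred_size) / 100.0
    )
    return 100.0 - penalty


def pair_primers(
    cands: list[PrimerCandidate],
    ps: PairStructure,
    params: PrimerParams | None = None,
    template: str = "A",
) -> list[PrimerPair]:
    """All forward x reverse combinations passing the pair-level filters.

    Product size per species is the intron-inclusive genomic distance from
    the forward primer's 5' start to the reverse primer's 5' end.
    """
    p = params or PrimerParams()
    fwd = [c for c in cands if c.orientation == "forward"]
    rev = [c for c in cands if c.orientation == "reverse"]
    scored = []
    for fw in fwd:
        for rv in rev:
            if rv.col_start < fw.col_end:
                continue
            ia = _introns_between(ps.junctions_a, fw.col_end, rv.col_start)
            ib = _introns_between(ps.junctions_b, fw.col_end, rv.col_start)
            if ia < p.min_introns_spanned or ib < p.min_introns_spanned:
                continue
            end_a = ps.genomic_a(rv.col_end - 1) + 1
            end_b = ps.genomic_b(rv.col_end - 1) + 1
            size_a = end_a - fw.start_a
            size_b = end_b - fw.start_b
            if not (p.product_min <= size_a <= p.product_max):
                continue
            if not (p.product_min <= size_b <= p.product_max):
                continue
            tm_fw = fw.tm_a if template == "A" else fw.tm_b
            tm_rv = rv.tm_a if template == "A" else rv.tm_b
            if abs(tm_fw - tm_rv) > p.max_pair_tm_diff:
                continue
            mism = len(fw.mismatch_cols) + len(rv.mismatch_cols)
            mm3 = _count_3prime_mismatches(fw, p) + _count_3prime_mismatches(rv, p)
            score = score_pair(mism, mm3, tm_fw, tm_rv, size_a, size_b, p)
            scored.append((fw, rv, ia, ib, size_a, size_b, mism, score))
    scored.sort(
        key=lambda t: (-t[7], t[6], abs(t[4] - t[5]), t[0].col_start, t[1].col_start)
    )
    pairs = []
    for rank, (fw, rv, ia, ib, sa, sb, _, score) in enumerate(scored, start=1):
        pairs.append(
            PrimerPair(
                pair_id=f"P{rank:05d}",
                fw=fw,
                rv=rv,
                product_size_a=sa,
                product_size_b=sb,
                introns_spanned_a=ia,
                introns_spanned_b=ib,
                score=score,
                rank=rank,
            )
        )
    return pairs


def _count_3prime_mismatches(c: PrimerCandidate, p: PrimerParams) -> int:
    w = p.forbid_3prime_mismatch_window
    if c.orientation == "forward":
        zone = range(max(c.col_start, c.col_end - w), c.col_end)
    else:
        zone = range(c.col_start, min(c.col_end, c.col_start + w))
    return sum(1 for m in c.mismatch_cols if m in zone)


def refine_pairs(
    pairs: list[PrimerPair],
    criteria: PrimerParams,
    original: PrimerParams | None = None,
    pair_ids: list[str] | None = None,
) -> list[PrimerPair]:
    """Pure search-within-result filter: never adds pairs, re-ranks survivors.

    ``criteria`` fields looser than ``original`` trigger a warning and are
    clamped to the original bound (a no-op).
    """
    eff = criteria
    if original is not None:
        clamps = {}
        for name, tighter in (
            ("len_min", max),
            ("len_max", min),
            ("tm_min", max),
            ("tm_max", min),
            ("gc_min", max),
            ("gc_max", min),
            ("max_mismatches_per_primer", min),
            ("max_pair_tm_diff", min),
            ("product_min", max),
            ("product_max", min),
        ):
            c, o = getattr(criteria, name), getattr(original, name)
            if tighter(c, o) != c:
                clamps[name] = o
        if clamps:
            warnings.warn(
                f"refinement criteria looser than original for {sorted(clamps)}; "
                "clamped to original bounds",
                stacklevel=2,
            )
            eff = replace(criteria, **clamps)
    wanted = set(pair_ids) if pair_ids is not None else None
    survivors = [
        pr
        for pr in pairs
        if (wanted is None or pr.pair_id in wanted) and _pair_passes(pr, eff)
    ]
    return [replace(pr, rank=i) for i, pr in enumerate(survivors, start=1)]


def _pair_passes(pr: PrimerPair, p: PrimerParams) -> bool:
    for c in (pr.fw, pr.rv):
        if not (p.len_min <= len(c) <= p.len_max):
            return False
        if len(c.mismatch_cols) > p.max_mismatches_per_primer:
            return False
        if not (p.gc_min <= c.gc <= p.gc_max):
            return False
        if not (p.tm_min <= c.tm_a <= p.tm_max):
            return False
        if p.forbid_3prime_mismatch_window and c.has_3prime_mismatch:
            return False
        if p.forbid_consecutive_mismatches and c.has_consecutive_mismatch:
            return False
        if p.at_rich_3prime_filter and c.at_rich_3prime:
            return False
    if abs(c_tm(pr.fw) - c_tm(pr.rv)) > p.max_pair_tm_diff:
        return False
    for size in (pr.product_size_a, pr.product_size_b):
        if not (p.product_min <= size <= p.product_max):
            return False
    if pr.introns_spanned_a < p.min_introns_spanned:
        return False
    if pr.introns_spanned_b < p.min_introns_spanned:
        return False
    return True


def c_tm(c: PrimerCandidate) -> float:
    """Template-species melting temperature of a candidate."""
    return c.tm_a


def paginate(pairs: list[PrimerPair], page_size: int = 60) -> list[list[PrimerPair]]:
    """Chunk ranked pairs into report pages; the first page holds the
    top-scoring ``min(page_size, n)`` pairs."""
    ordered = sorted(pairs, key=lambda p: p.rank)
    return [ordered[i : i + page_size] for i in range(0, len(ordered), page_size)]
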