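"""Electronic high-throughput PCR: genome-wide virtual amplification.

Given designed primer pairs and one or more whole genomes, this module
(i) reduces the primer pool to unique oriented sequences, (ii) locates every
genomic site each primer could anneal to within a bounded number of
mismatches (Hamming distance on both strands; indels are not modelled — a
primer annealing over an indel essentially never amplifies), (iii) combines
forward/reverse hits into virtual amplicons bounded by a maximum product
size, and (iv) classifies each (pair, genome) as *specific* (exactly one
locus), *non_specific* (two or more loci) or *no_amplification*.

The site search is an exhaustive scan vectorised over the genome: for a
primer of length m the mismatch count of every window is accumulated in m
shifted comparisons, so the contract is literally "every window within
Hamming distance <= max_mismatches", with no heuristic seeding loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import SequenceRecord, revcomp


@dataclass(frozen=True)
class EHTPCRParams:
    """Parameters of the genome-wide annealing-site model.

    ``max_mismatches`` (default 5) is the overall mismatch ceiling used for
    cross-species primer mapping.  ``seed_mismatches``/``seed_length``
    additionally cap mismatches within the primer's first (5') 32 bases,
    mirroring how short-read mappers seed their search; for primer-length
    queries the seed spans the whole sequence, so the effective tolerance is
    ``min(max_mismatches, seed_mismatches)``.  Without this cap an 18-mer has
    a ~3e-5 per-window chance of a 5-mismatch match, so an exhaustive scan
    would predict annealing at thousands of random genomic sites.  The
    default seed cap of 2 reproduces the classic ``bwa aln -k 2 -l 32``
    parameterisation used for primer mapping.  Note the consequence: a
    primer that carries 3 designed mismatches against the partner genome is
    not detected there and reports no_amplification — raise the cap (or set
    ``seed_mismatches=None`` for the raw exhaustive scan) to trade chance
    3-mismatch background predictions for detection of such sites.
    ``anchor_3prime`` optionally requires the last m bases of a hit to match
    exactly (annealing is most sensitive at the 3' end); off by default.
    """

    max_mismatches: int = 5
    max_product_size: int = 5000
    seed_mismatches: int | None = 2
    seed_length: int = 32
    anchor_3prime: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_product_size <= 0:
            raise ValueError("max_product_size must be positive")


@dataclass(frozen=True)
class PrimerHit:
    primer_id: str
    genome_id: str
    chrom: str
    start: int  # 0-based forward-strand coordinate of the window
    strand: str
    length: int
    mismatch_count: int
    mismatch_offsets: tuple[int, ...]  # primer 5'->3'

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Amplicon:
    genome_id: str
    chrom: str
    start: int
    end: int  # half-open
    fw_hit: PrimerHit
    rv_hit: PrimerHit
    pair_ids: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpecificityEntry:
    status: str  # 'specific' | 'non_specific' | 'no_amplification'
    locus_count: int
    loci: tuple[Amplicon, ...]


@dataclass
class SpecificityReport:
    """Per (pair_id, genome_id) amplification specificity."""

    entries: dict[tuple[str, str], SpecificityEntry] = field(default_factory=dict)

    def status(self, pair_id: str, genome_id: str) -> str:
        return self.entries[(pair_id, genome_id)].status

    def to_rows(self) -> list[dict]:
        rows = []
        for (pair_id, genome_id), e in sorted(self.entries.items()):
            loci_repr = (
                ";".join(f"{a.chrom}:{a.start}-{a.end}" for a in e.loci)
                if e.status == "specific"
                else str(e.locus_count)
            )
            rows.append(
                {
                    "pair_id": pair_id,
                    "genome_id": genome_id,
                    "status": e.status,
                    "locus_count": e.locus_count,
                    "loci": loci_repr,
                }
            )
        return rows


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan_strand(
    garr: np.ndarray, primer: str
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch count of ``primer`` against every window of ``garr``."""
    m = len(primer)
    n = len(garr)
    parr = _encode(primer)
    nwin = n - m + 1
    mm = np.zeros(nwin, dtype=np.int32)
    for j in range(m):
        mm += garr[j : j + nwin] != parr[j]
    return mm, parr


def find_sites(
    primer: str,
    genome: list[SequenceRecord],
    max_mismatches: int,
    genome_id: str = "",
    primer_id: str = "",
    anchor_3prime: int = 0,
    seed_mismatches: int | None = None,
    seed_length: int = 32,
) -> list[PrimerHit]:
    """Every genomic window on either strand within the mismatch budget.

    With the default ``seed_mismatches=None`` this is the exhaustive scan:
    every window with Hamming distance <= ``max_mismatches``.  A ``+`` hit
    means the primer sequence matches the forward strand (it would prime
    rightward); a ``-`` hit means it matches the reverse complement (priming
    leftward).  ``mismatch_offsets`` are primer 5'->3'.
    """
    if len(primer) < 15:
        raise ValueError("primer shorter than 15 nt")
    if "N" in primer:
        raise ValueError("primer contains N")
    m = len(primer)
    hits: list[PrimerHit] = []
    for rec in genome:
        if len(rec.seq) < m:
            continue
        garr = _encode(rec.seq)
        for strand, pseq in (("+", primer), ("-", revcomp(primer))):
            mm, parr = _scan_strand(garr, pseq)
            for start in np.flatnonzero(mm <= max_mismatches):
                start = int(start)
                window = garr[start : start + m]
                offs = np.flatnonzero(window != parr)
                if strand == "-":
                    offs = (m - 1) - offs[::-1]
                offs_t = tuple(int(o) for o in offs)
                if anchor_3prime and any(o >= m - anchor_3prime for o in offs_t):
                    continue
                if seed_mismatches is not None:
                    if sum(1 for o in offs_t if o < seed_length) > seed_mismatches:
                        continue
                hits.append(
                    PrimerHit(
                        primer_id=primer_id,
                        genome_id=genome_id,
                        chrom=rec.id,
                        start=start,
                        strand=strand,
                        length=m,
                        mismatch_count=len(offs_t),
                        mismatch_offsets=offs_t,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def enumerate_amplicons(
    fw_hits: list[PrimerHit],
    rv_hits: list[PrimerHit],
    params: EHTPCRParams | None = None,
    pair_id: str = "",
) -> list[Amplicon]:
    """Virtual products from opposing forward/reverse primer hits.

    The canonical case pairs a forward-primer ``+`` hit with a downstream
    reverse-primer ``-`` hit; the mirrored case (forward on ``-``, reverse on
    ``+`` upstream) covers amplification off the other strand and is reported
    in forward-strand coordinates.  Products are bounded by
    ``max_product_size`` below and by the summed primer lengths above zero.
    """
    p = params or EHTPCRParams()
    out: list[Amplicon] = []
    pair_ids = (pair_id,) if pair_id else ()
    cases = (
        # (left hits, right hits, left role is forward primer?)
        ([h for h in fw_hits if h.strand == "+"], [h for h in rv_hits if h.strand == "-"], True),
        ([h for h in rv_hits if h.strand == "+"], [h for h in fw_hits if h.strand == "-"], False),
    )
    for left_hits, right_hits, left_is_fw in cases:
        for lh in left_hits:
            for rh in right_hits:
                if lh.chrom != rh.chrom:
                    continue
                start, end = lh.start, rh.end
                size = end - start
                if size < lh.length + rh.length or size > p.max_product_size:
                    continue
                fw_hit, rv_hit = (lh, rh) if left_is_fw else (rh, lh)
                out.append(
                    Amplicon(
                        genome_id=lh.genome_id,
                        chrom=lh.chrom,
                        start=start,
                        end=end,
                        fw_hit=fw_hit,
                        rv_hit=rv_hit,
                        pair_ids=pair_ids,
                    )
                )
    out.sort(key=lambda a: (a.chrom, a.start, a.end))
    return out


def dedupe_primers(pairs) -> tuple[list[tuple[str, str]], dict[str, list[tuple[str, str]]]]:
    """Reduce primer pairs to unique oriented sequences.

    Returns ``(unique, back_map)`` where ``unique`` is a deterministic list
    of ``(orientation, sequence)`` and ``back_map`` maps a sequence to every
    ``(pair_id, role)`` it serves, losslessly reconstructing the pool.
    """
    if not pairs:
        raise ValueError("no primer pairs to dedupe")
    back: dict[str, list[tuple[str, str]]] = {}
    unique: list[tuple[str, str]] = []
    for pr in pairs:
        for role, cand in (("fw", pr.fw), ("rv", pr.rv)):
            seq = cand.template_seq
            if seq not in back:
                back[seq] = []
                unique.append((role, seq))
            back[seq].append((pr.pair_id, role))
    return unique, back


def run_ehtpcr(
    pairs,
    genomes: dict[str, list[SequenceRecord]],
    params: EHTPCRParams | None = None,
    dedupe: bool = True,
) -> SpecificityReport:
    """Full in-silico PCR of every pair against every genome.

    ``genomes`` maps genome id -> FASTA records.  With ``dedupe`` the site
    search runs once per unique primer sequence; the report is identical
    either way.
    """
    p = params or EHTPCRParams()
    report = SpecificityReport()
    for genome_id, records in genomes.items():
        site_cache: dict[str, list[PrimerHit]] = {}

        def sites(seq: str) -> list[PrimerHit]:
            if dedupe and seq in site_cache:
                return site_cache[seq]
            hits = find_sites(
                seq,
                records,
                p.max_mismatches,
                genome_id=genome_id,
                anchor_3prime=p.anchor_3prime,
                seed_mismatches=p.seed_mismatches,
                seed_length=p.seed_length,
            )
            if dedupe:
                site_cache[seq] = hits
            return hits

        for pr in pairs:
            amps = enumerate_amplicons(
                sites(pr.fw.template_seq),
                sites(pr.rv.template_seq),
                p,
                pair_id=pr.pair_id,
            )
            loci = sorted(
                {(a.chrom, a.start, a.end): a for a in amps}.values(),
                key=lambda a: (a.chrom, a.start, a.end),
            )
            n = len(loci)
            status = (
                "no_amplification" if n == 0 else "specific" if n == 1 else "non_specific"
            )
            report.entries[(pr.pair_id, genome_id)] = SpecificityEntry(
                status=status, locus_count=n, loci=tuple(loci)
            )
    return report
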