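"""SNP calling between parental amplicons and CAPS marker design.

A CAPS (cleaved amplified polymorphic sequence) marker scores a SNP by a
restriction digest whose fragment pattern differs between the two alleles,
because the polymorphism creates or destroys a recognition site.  Given the
two Sanger-derived amplicon sequences of a mapping-parent pair, this module
aligns them (reusing the affine-gap global aligner), calls substitution SNPs
and indels, predicts the digestion pattern of each allele for a table of
restriction enzymes, and reports every enzyme whose patterns differ.

The digestion model is deliberately simple: a cut at every occurrence of the
recognition site on either strand, at the enzyme's top-strand cut offset
(bottom-strand matches cut at the mirrored offset); partial digestion and
methylation sensitivity are not modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .genome_io import InputError
from .ortholog_align import AlignParams, global_align_cds

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(site: str) -> str:
    return site.translate(_IUPAC_COMPLEMENT)[::-1]


def _site_regex(site: str) -> re.Pattern:
    try:
        body = "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in site
        )
    except KeyError as exc:
        raise InputError(f"unknown IUPAC code {exc.args[0]!r} in site {site!r}")
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition_site: str  # IUPAC, top strand
    cut_offset: int  # cut position within the site, top strand

    def __post_init__(self) -> None:
        if len(self.recognition_site) < 4:
            raise InputError(f"{self.name}: recognition site shorter than 4")
        if not (0 <= self.cut_offset <= len(self.recognition_site)):
            raise InputError(f"{self.name}: cut offset outside site")
        _site_regex(self.recognition_site)  # validates the alphabet

    @property
    def palindromic(self) -> bool:
        return iupac_revcomp(self.recognition_site) == self.recognition_site


def load_enzymes(path: str | None = None) -> list[Enzyme]:
    """Load the enzyme table (name, IUPAC site, cut offset) from TSV.

    Defaults to the ~20 common six-cutters shipped with the package.
    """
    if path is None:
        text = (
            resources.files("spanprime").joinpath("data/enzymes.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    enzymes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site, offset = line.split("\t")
        enzymes.append(Enzyme(name, site.upper(), int(offset)))
    if not enzymes:
        raise InputError("empty enzyme table")
    return enzymes


def site_match_intervals(seq: str, enzyme: Enzyme) -> list[tuple[int, int]]:
    """Recognition-site occurrences on either strand, as forward-strand
    intervals (palindromic sites counted once)."""
    L = len(enzyme.recognition_site)
    intervals = {m.start(1): (m.start(1), m.start(1) + L)
                 for m in _site_regex(enzyme.recognition_site).finditer(seq)}
    if not enzyme.palindromic:
        rc = iupac_revcomp(enzyme.recognition_site)
        for m in _site_regex(rc).finditer(seq):
            intervals.setdefault(m.start(1), (m.start(1), m.start(1) + L))
    return sorted(intervals.values())


def cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates of every digestible site."""
    L = len(enzyme.recognition_site)
    cuts = set()
    for m in _site_regex(enzyme.recognition_site).finditer(seq):
        cuts.add(m.start(1) + enzyme.cut_offset)
    if not enzyme.palindromic:
        rc = iupac_revcomp(enzyme.recognition_site)
        for m in _site_regex(rc).finditer(seq):
            cuts.add(m.start(1) + (L - enzyme.cut_offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest_pattern(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths (5'->3') after complete digestion; sums to len(seq)."""
    cuts = cut_positions(seq, enzyme)
    edges = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(edges, edges[1:])]


@dataclass(frozen=True)
class SNP:
    alignment_column: int
    pos_a: int
    pos_b: int
    allele_a: str
    allele_b: str
    flanks: str  # allele-A context, SNP bracketed

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("SNP with identical alleles")
        if "-" in (self.allele_a, self.allele_b):
            raise ValueError("SNP allele may not be a gap")


@dataclass
class SNPCallResult:
    alignment: "object"
    snps: list[SNP]
    indels: list[tuple[int, int, str]]  # (col_start, col_end, 'a'|'b' gapped row)


def call_snps(
    seq_a: str, seq_b: str, params: AlignParams | None = None, flank: int = 10
) -> SNPCallResult:
    """Align two amplicon alleles and score substitution SNPs.

    Indel columns are excluded from the SNP list but recorded separately as
    maximal gap runs.
    """
    if not seq_a or not seq_b:
        raise InputError("empty amplicon sequence")
    aln = global_align_cds(seq_a, seq_b, params)
    snps: list[SNP] = []
    indels: list[tuple[int, int, str]] = []
    pos_a = pos_b = 0
    run_start, run_row = None, None
    for col, (ca, cb) in enumerate(zip(aln.aligned_a, aln.aligned_b)):
        row = "a" if ca == "-" else "b" if cb == "-" else None
        if run_row is not None and row != run_row:
            indels.append((run_start, col, run_row))
            run_start = run_row = None
        if row is not None and run_row is None:
            run_start, run_row = col, row
        if row is None and ca != cb:
            ctx = seq_a[max(0, pos_a - flank) : pos_a] + f"[{ca}/{cb}]" + seq_a[
                pos_a + 1 : pos_a + 1 + flank
            ]
            snps.append(
                SNP(
                    alignment_column=col,
                    pos_a=pos_a,
                    pos_b=pos_b,
                    allele_a=ca,
                    allele_b=cb,
                    flanks=ctx,
                )
            )
        pos_a += ca != "-"
        pos_b += cb != "-"
    if run_row is not None:
        indels.append((run_start, len(aln.aligned_a), run_row))
    return SNPCallResult(alignment=aln, snps=snps, indels=indels)


@dataclass(frozen=True)
class CAPSCandidate:
    snps: tuple[SNP, ...]  # called SNPs overlapping a differential site
    enzyme: Enzyme
    fragments_a: tuple[int, ...]
    fragments_b: tuple[int, ...]
    diagnostic: bool


def find_caps(
    seq_a: str,
    seq_b: str,
    enzymes: list[Enzyme] | None = None,
    snp_result: SNPCallResult | None = None,
) -> list[CAPSCandidate]:
    """Enzymes whose digestion patterns distinguish the two alleles.

    For each enzyme both alleles are digested; a candidate is emitted when
    the fragment-length multisets differ, annotated with the called SNPs that
    sit inside a recognition site present in exactly one allele.  Enzyme
    order (hence output order) is deterministic.
    """
    if enzymes is None:
        enzymes = load_enzymes()
    if not enzymes:
        raise InputError("empty enzyme table")
    res = snp_result or call_snps(seq_a, seq_b)
    out: list[CAPSCandidate] = []
    for enz in enzymes:
        fr_a = digest_pattern(seq_a, enz)
        fr_b = digest_pattern(seq_b, enz)
        if sorted(fr_a) == sorted(fr_b):
            continue
        iv_a = site_match_intervals(seq_a, enz)
        iv_b = site_match_intervals(seq_b, enz)
        linked = tuple(
            s
            for s in res.snps
            if any(a0 <= s.pos_a < a1 for a0, a1 in iv_a)
            != any(b0 <= s.pos_b < b1 for b0, b1 in iv_b)
        )
        out.append(
            CAPSCandidate(
                snps=linked,
                enzyme=enz,
                fragments_a=tuple(fr_a),
                fragments_b=tuple(fr_b),
                diagnostic=True,
            )
        )
    return out
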