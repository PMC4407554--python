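"""Genome FASTA / GFF3 input, per-gene sequence extraction, report output.

Conventions used throughout the package:

* internal coordinates are 0-based half-open; GFF3's 1-based inclusive
  coordinates are converted on input and only reappear in human-readable
  reports (BED output stays 0-based);
* per-gene sequences are always stored on the coding strand, so primer
  design never has to think about strand; genome-scale operations
  (:mod:`spanprime.eht_pcr`) work on the genome's forward strand with
  explicit strand flags.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .gene_structure import ExonBlocks, StructureError, blocks_from_intervals

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(raw: str, strict: bool = True) -> str:
    """Uppercase, map U->T, and restrict to {A,C,G,T,N}.

    In strict mode any other character raises :class:`InputError`; otherwise
    it is converted to N.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        if strict:
            raise InputError(f"illegal characters in sequence: {sorted(bad)}")
        seq = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        if not self.seq:
            raise InputError(f"sequence record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: exons and CDS intervals in genomic coordinates.

    ``exons`` and ``cds_intervals`` are 0-based half-open genomic intervals
    listed in transcript order (5'->3' of the mRNA), i.e. descending genomic
    start for minus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise InputError(f"gene {self.gene_id}: no exons")
        genomic_order = sorted(self.exons)
        if self.strand == "-":
            genomic_order = genomic_order[::-1]
        if tuple(genomic_order) != self.exons:
            raise InputError(f"gene {self.gene_id}: exons not in transcript order")
        for (s0, e0), (s1, e1) in zip(sorted(self.exons), sorted(self.exons)[1:]):
            if e0 > s1:
                raise InputError(f"gene {self.gene_id}: overlapping exons")
        for s, e in self.cds_intervals:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise InputError(
                    f"gene {self.gene_id}: CDS interval [{s},{e}) outside exons"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class GeneSequences:
    """Coding-strand sequences of one gene plus its exon-block structure.

    ``genomic`` is the gene span plus ``flank`` on both sides, clipped to the
    chromosome and given on the coding strand; ``exon_blocks`` is expressed in
    local coordinates of that string.
    """

    gene_id: str
    genomic: str
    cds: str
    exon_blocks: ExonBlocks
    provenance: str = "annotation"


def read_fasta(path: str, strict: bool = True) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized records."""
    if not os.path.exists(path):
        raise InputError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen and strict:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                seq=normalize_seq(str(rec.seq), strict=strict),
            )
        )
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gff3(path: str, genome: list[SequenceRecord]) -> list[GeneModel]:
    """Parse GFF3 gene models (one :class:`GeneModel` per mRNA/transcript).

    Coordinates are converted from 1-based inclusive to 0-based half-open,
    and exon/CDS lists are ordered 5'->3' of the transcript.
    """
    chrom_len = {r.id: len(r.seq) for r in genome}
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        if mrna.seqid not in chrom_len:
            raise InputError(f"mRNA {mrna.id}: unknown chromosome {mrna.seqid!r}")
        if mrna.strand not in "+-":
            raise InputError(f"mRNA {mrna.id}: unknown strand {mrna.strand!r}")
        L = chrom_len[mrna.seqid]
        exons = []
        cds = []
        for child in db.children(mrna, featuretype=("exon", "CDS"), order_by="start"):
            iv = (child.start - 1, child.end)
            if iv[0] < 0 or iv[1] > L:
                raise InputError(
                    f"mRNA {mrna.id}: feature [{child.start},{child.end}] outside "
                    f"chromosome {mrna.seqid} (length {L})"
                )
            (exons if child.featuretype == "exon" else cds).append(iv)
        if not exons:  # CDS-only annotations: treat CDS intervals as exons
            exons = list(cds)
        if mrna.strand == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds_intervals=tuple(cds),
            )
        )
    if not models:
        raise InputError(f"no mRNA/transcript features in {path}")
    return models


def extract_gene(
    model: GeneModel,
    genome: list[SequenceRecord],
    flank: int = 0,
    cds_only: bool = True,
) -> GeneSequences:
    """Extract a gene's coding-strand genomic window and spliced CDS.

    The window is ``[span_start - flank, span_end + flank)`` clipped to the
    chromosome; ``exon_blocks`` bookkeeping shifts by the actual clip so the
    blocks always index into the returned ``genomic`` string.
    """
    if flank < 0:
        raise InputError("flank must be non-negative")
    by_id = {r.id: r for r in genome}
    if model.chrom not in by_id:
        raise InputError(f"chromosome {model.chrom!r} not present in genome")
    chrom = by_id[model.chrom].seq
    span_start, span_end = model.span
    ws = max(0, span_start - flank)
    we = min(len(chrom), span_end + flank)
    window = chrom[ws:we]
    if model.strand == "-":
        window = revcomp(window)
    intervals = model.cds_intervals if cds_only else model.exons
    eb = blocks_from_intervals(intervals, model.strand, ws, we)
    try:
        eb.validate(min_intron=1)
    except StructureError as exc:
        raise InputError(f"gene {model.gene_id}: {exc}") from exc
    cds = eb.splice(window)
    return GeneSequences(
        gene_id=model.gene_id,
        genomic=window,
        cds=cds,
        exon_blocks=eb,
        provenance="annotation",
    )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

PRIMER_TSV_COLUMNS = [
    "pair_id",
    "gene_a",
    "gene_b",
    "fw_seq",
    "rv_seq",
    "fw_tm",
    "rv_tm",
    "fw_mismatches",
    "rv_mismatches",
    "product_size_a",
    "product_size_b",
    "introns_spanned_a",
    "introns_spanned_b",
    "score",
    "rank",
]


def write_primer_tsv(pairs, gene_a: str, gene_b: str, path: str) -> None:
    """Primer-pair table with fixed columns, ordered by (rank, pair_id)."""
    rows = sorted(pairs, key=lambda p: (p.rank, p.pair_id))
    with open(path, "w") as fh:
        fh.write("\t".join(PRIMER_TSV_COLUMNS) + "\n")
        for p in rows:
            fh.write(
                "\t".join(
                    [
                        p.pair_id,
                        gene_a,
                        gene_b,
                        p.fw.template_seq,
                        p.rv.template_seq,
                        f"{p.fw.tm_a:.2f}",
                        f"{p.rv.tm_a:.2f}",
                        str(len(p.fw.mismatch_cols)),
                        str(len(p.rv.mismatch_cols)),
                        str(p.product_size_a),
                        str(p.product_size_b),
                        str(p.introns_spanned_a),
                        str(p.introns_spanned_b),
                        f"{p.score:.3f}",
                        str(p.rank),
                    ]
                )
                + "\n"
            )


def write_amplicons_bed(amplicons, path: str) -> None:
    """BED6, one line per amplicon: name = pair id(s), score = mismatches."""
    rows = sorted(
        amplicons, key=lambda a: (a.genome_id, a.chrom, a.start, a.end, a.pair_ids)
    )
    with open(path, "w") as fh:
        for a in rows:
            total_mm = a.fw_hit.mismatch_count + a.rv_hit.mismatch_count
            name = ",".join(a.pair_ids)
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{name}\t{total_mm}\t+\n"
            )


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_reports(results: dict, out_dir: str) -> dict[str, str]:
    """Write all report files for a design / in-silico PCR run.

    ``results`` keys: ``gene_a``, ``gene_b``, ``pairs`` (required);
    ``amplicons``, ``json`` (optional).  Returns {kind: path}.  Re-running on
    identical input yields byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise InputError(f"output directory not writable: {out_dir}")
    paths: dict[str, str] = {}
    tsv = os.path.join(out_dir, "primer_pairs.tsv")
    write_primer_tsv(results["pairs"], results["gene_a"], results["gene_b"], tsv)
    paths["primer_tsv"] = tsv
    bed = os.path.join(out_dir, "amplicons.bed")
    write_amplicons_bed(results.get("amplicons", []), bed)
    paths["amplicon_bed"] = bed
    if "json" in results:
        jp = os.path.join(out_dir, "result.json")
        write_json(results["json"], jp)
        paths["json"] = jp
    return paths
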