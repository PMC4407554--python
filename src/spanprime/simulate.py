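"""Seeded simulation of ortholog gene pairs, genomes and paralog copies.

The generator emulates the evolutionary premise behind intron-spanning
genic markers: coding exons are under stronger purifying selection than
introns, so an ancestral gene is mutated into two descendant "species"
alleles with a high per-site exon identity (default 0.97 to the ancestor)
and a much lower intron identity (default 0.60), with short indels in
introns only.  Intron boundaries keep the canonical GT..AG dinucleotides.
Each descendant gene is embedded in random genomic background with a
GFF3-consistent annotation, and a truth record retains junctions and
mutated positions for recovery tests.

All randomness flows from a single explicitly seeded generator per call;
identical parameters reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_structure import ExonBlocks
from .genome_io import GeneModel, GeneSequences, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic ortholog test bed.

    Ranges are inclusive.  Identities are the per-site probability that a
    descendant base equals the ancestral base, per region class.
    """

    seed: int = 0
    n_exons: tuple[int, int] = (2, 10)
    exon_len: tuple[int, int] = (60, 400)
    intron_len: tuple[int, int] = (80, 2000)
    exon_identity: float = 0.97
    intron_identity: float = 0.60
    indel_rate_intron: float = 0.02
    genome_padding: int = 2000
    paralog_identity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("exon_identity", "intron_identity", "paralog_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("n_exons", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {name} range")
        if self.intron_len[0] < 20:
            raise ValueError("introns shorter than 20 bp are not simulated")


@dataclass
class SimulatedSpecies:
    genome: list[SequenceRecord]
    model: GeneModel
    gene: GeneSequences
    truth: dict


@dataclass
class SimulatedPair:
    params: SimParams
    species_a: SimulatedSpecies
    species_b: SimulatedSpecies


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _substitute(
    rng: np.random.Generator, arr: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site substitution at ``rate``, uniform over the 3 other bases."""
    out = arr.copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out, hit


def _mutate_intron(rng: np.random.Generator, intron: np.ndarray, p: SimParams) -> np.ndarray:
    """Substitutions plus short geometric indels, splice dinucleotides kept."""
    interior, _ = _substitute(rng, intron[2:-2], 1.0 - p.intron_identity)
    pieces: list[np.ndarray] = []
    i = 0
    while i < len(interior):
        if rng.random() < p.indel_rate_intron:
            length = min(int(rng.geometric(1 / 3.0)), len(interior) - i)
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            pieces.append(_random_seq(rng, length))  # insertion
        pieces.append(interior[i : i + 1])
        i += 1
    body = np.concatenate(pieces) if pieces else interior[:0]
    return np.concatenate([intron[:2], body, intron[-2:]])


def _assemble_species(
    rng: np.random.Generator,
    exons: list[np.ndarray],
    introns: list[np.ndarray],
    p: SimParams,
    label: str,
) -> SimulatedSpecies:
    mut_exons = []
    mut_positions_cds = []
    c = 0
    for ex in exons:
        mut, hit = _substitute(rng, ex, 1.0 - p.exon_identity)
        mut_exons.append(mut)
        mut_positions_cds.extend(int(c + h) for h in hit)
        c += len(ex)
    mut_introns = [_mutate_intron(rng, iv, p) for iv in introns]

    left = _random_seq(rng, p.genome_padding)
    right = _random_seq(rng, p.genome_padding)
    parts = [left]
    blocks: list[tuple[int, int, int, int]] = []
    pos = len(left)
    c = 0
    for i, ex in enumerate(mut_exons):
        blocks.append((pos, pos + len(ex), c, c + len(ex)))
        parts.append(ex)
        pos += len(ex)
        c += len(ex)
        if i < len(mut_introns):
            parts.append(mut_introns[i])
            pos += len(mut_introns[i])
    parts.append(right)
    chrom_arr = np.concatenate(parts)
    chrom = SequenceRecord(
        id=f"chr_{label}", description=f"simulated chromosome ({label})", seq=_to_str(chrom_arr)
    )
    exon_ivs = tuple((g0, g1) for g0, g1, _, _ in blocks)
    model = GeneModel(
        gene_id=f"gene_{label}",
        chrom=chrom.id,
        strand="+",
        exons=exon_ivs,
        cds_intervals=exon_ivs,
    )
    span_start = blocks[0][0]
    local_blocks = [(g0 - span_start, g1 - span_start, c0, c1) for g0, g1, c0, c1 in blocks]
    eb = ExonBlocks(blocks=local_blocks, provenance="annotation")
    genomic = _to_str(chrom_arr[span_start : blocks[-1][1]])
    gene = GeneSequences(
        gene_id=model.gene_id,
        genomic=genomic,
        cds="".join(_to_str(e) for e in mut_exons),
        exon_blocks=eb,
        provenance="annotation",
    )
    truth = {
        "junction_cds_offsets": eb.junction_cds_offsets(),
        "exon_blocks_local": local_blocks,
        "gene_span": (span_start, blocks[-1][1]),
        "mutated_cds_positions": mut_positions_cds,
        "intron_lengths": [len(iv) for iv in mut_introns],
    }
    return SimulatedSpecies(genome=[chrom], model=model, gene=gene, truth=truth)


def simulate_ortholog_pair(params: SimParams | None = None) -> SimulatedPair:
    """Generate an ancestral gene and two descendant species alleles.

    Exon count and lengths are shared (substitutions only in exons), so the
    two descendants have identical CDS lengths and junction offsets; intron
    lengths drift through indels.
    """
    p = params or SimParams()
    rng = np.random.default_rng(p.seed)
    n_exons = int(rng.integers(p.n_exons[0], p.n_exons[1] + 1))
    exons = [
        _random_seq(rng, int(rng.integers(p.exon_len[0], p.exon_len[1] + 1)))
        for _ in range(n_exons)
    ]
    introns = []
    for _ in range(n_exons - 1):
        L = int(rng.integers(p.intron_len[0], p.intron_len[1] + 1))
        iv = _random_seq(rng, L)
        iv[0:2] = _BASES[[2, 3]]  # GT
        iv[-2:] = _BASES[[0, 2]]  # AG
        introns.append(iv)
    a = _assemble_species(rng, exons, introns, p, "A")
    b = _assemble_species(rng, exons, introns, p, "B")
    return SimulatedPair(params=p, species_a=a, species_b=b)


def plant_paralog(
    genome: list[SequenceRecord],
    model: GeneModel,
    paralog_identity: float,
    seed: int,
) -> tuple[list[SequenceRecord], dict]:
    """Insert a mutated copy of the gene's genomic span into the genome.

    The copy is substituted at ``1 - paralog_identity`` per site and inserted
    at a random position downstream of the gene (keeping the existing
    annotation's coordinates valid).  Returns the new genome and a truth
    record with the insertion point.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in genome}
    chrom = by_id[model.chrom]
    s, e = model.span
    arr = np.frombuffer(chrom.seq.encode(), dtype=np.uint8).copy()
    copy, hit = _substitute(rng, arr[s:e], 1.0 - paralog_identity)
    lo, hi = e, len(arr)
    if hi <= lo:
        raise ValueError("genome too small to accept a paralog insertion")
    ins = int(rng.integers(lo, hi + 1))
    new_arr = np.concatenate([arr[:ins], copy, arr[ins:]])
    new_chrom = SequenceRecord(id=chrom.id, description=chrom.description, seq=_to_str(new_arr))
    new_genome = [new_chrom if r.id == chrom.id else r for r in genome]
    truth = {
        "insertion_point": ins,
        "copy_span": (ins, ins + (e - s)),
        "mutated_offsets": [int(h) for h in hit],
    }
    return new_genome, truth


def write_gff3(model: GeneModel, genome: list[SequenceRecord], path: str) -> None:
    """Minimal GFF3 (gene/mRNA/exon/CDS) for a simulated gene."""
    s, e = model.span
    gid = model.gene_id
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in genome:
            fh.write(f"##sequence-region {rec.id} 1 {len(rec.seq)}\n")
        fh.write(
            f"{model.chrom}\tspanprime\tgene\t{s + 1}\t{e}\t.\t{model.strand}\t.\tID={gid}\n"
        )
        fh.write(
            f"{model.chrom}\tspanprime\tmRNA\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={gid}.1;Parent={gid}\n"
        )
        for kind, ivs in (("exon", model.exons), ("CDS", model.cds_intervals)):
            for i, (a, b) in enumerate(sorted(ivs), start=1):
                phase = "0" if kind == "CDS" else "."
                fh.write(
                    f"{model.chrom}\tspanprime\t{kind}\t{a + 1}\t{b}\t.\t{model.strand}\t{phase}\t"
                    f"ID={gid}.1.{kind}{i};Parent={gid}.1\n"
                )
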