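"""End-to-end marker design: gene structures -> alignment -> primer pairs."""

from __future__ import annotations

from dataclasses import dataclass

from .gene_structure import JunctionParams, map_junctions
from .genome_io import GeneSequences
from .ortholog_align import (
    AlignParams,
    ConservedBlock,
    PairStructure,
    build_pair_structure,
    conserved_blocks,
    global_align_cds,
)
from .primer_design import PrimerCandidate, PrimerPair, PrimerParams, enumerate_primers, pair_primers


@dataclass
class DesignResult:
    structure: PairStructure
    blocks: list[ConservedBlock]
    candidates: list[PrimerCandidate]
    pairs: list[PrimerPair]


def gene_from_sequences(
    gene_id: str, genomic: str, cds: str, params: JunctionParams | None = None
) -> GeneSequences:
    """Build a :class:`GeneSequences` from bare genomic + CDS FASTA input by
    spliced alignment (used when no GFF3 annotation is available)."""
    eb = map_junctions(cds, genomic, params)
    return GeneSequences(
        gene_id=gene_id,
        genomic=genomic,
        cds=cds,
        exon_blocks=eb,
        provenance="spliced_alignment",
    )


def design_markers(
    gene_a: GeneSequences,
    gene_b: GeneSequences,
    primer_params: PrimerParams | None = None,
    align_params: AlignParams | None = None,
    max_mismatches_per_block: int = 3,
    template: str = "A",
) -> DesignResult:
    """Design intron-spanning cross-species primer pairs for one ortholog pair."""
    pp = primer_params or PrimerParams()
    aln = global_align_cds(gene_a.cds, gene_b.cds, align_params)
    ps = build_pair_structure(aln, gene_a.exon_blocks, gene_b.exon_blocks)
    blocks = conserved_blocks(
        ps,
        min_block_len=pp.len_min,
        max_mismatches_per_block=max_mismatches_per_block,
    )
    cands = enumerate_primers(ps, blocks, pp, template=template)
    pairs = pair_primers(cands, ps, pp, template=template)
    return DesignResult(structure=ps, blocks=blocks, candidates=cands, pairs=pairs)
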