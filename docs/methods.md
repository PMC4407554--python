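# Methods

This note documents the models and procedures implemented in `spanprime`,
the defaults chosen where the design space was genuinely open, and what the
synthetic test bed does and does not demonstrate about real data.

## Coordinate and strand conventions

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
inclusive coordinates are converted on input, and BED output stays 0-based.
Per-gene sequences are always stored on the coding strand (minus-strand
genes are reverse complemented at extraction), so primer design is
strand-free; genome-scale mapping works on the forward strand with explicit
strand flags.  Gene extraction defaults to CDS-only exon blocks (UTR exons
can be included with `cds_only=False`); a `flank` parameter exists for
context display only — primers are exonic and never fall in flanks.

## Spliced junction mapping (`gene_structure.map_junctions`)

When no annotation is supplied, exon–intron junctions are recovered by
aligning the CDS to its own genomic locus.  Because the two sequences are
(nearly) the same allele, a full spliced-alignment DP is unnecessary:

1. all maximal exact matches of length ≥ `anchor_k` (default 16) are found
   by k-mer indexing and bidirectional extension;
2. anchors are chained colinearly by dynamic programming maximising matched
   CDS coverage, with overlaps trimmed; a chain transition must imply a
   genomic gap of 0 (merged) or ≥ `min_intron` (default 20 bp — shorter
   gaps are treated as alignment noise);
3. each exon/intron boundary then slides within ± `refine_window`
   (default 10 bp) to the split maximising a splice-site bonus
   (GT..AG +4, GC..AG +2, otherwise 0) minus the substitution cost of the
   bases reassigned between the two exon diagonals; ties resolve to the
   leftmost genomic junction, making the result deterministic;
4. the mapping fails (`CoverageError`) if under the final tiling fewer than
   `min_coverage` (default 0.95) of CDS bases match the genome.

The boundary-slide scoring resolves the classical ambiguity where the bases
flanking an intron are repeated on both sides and several splits give the
same exon sequence: the canonical-dinucleotide bonus picks the GT–AG
placement.  Non-canonical junctions are allowed but only chosen when no
canonical placement exists within the window.

## CDS–CDS alignment and the pair structure

The two orthologous CDSs are aligned globally with affine gap costs
(match +2, mismatch −3, gap of length k costs −12 − 2k), parameters chosen
for coding DNA at roughly 70–95 % identity.  The three-state Gotoh DP
includes insertion↔deletion transitions, so the score is the true optimum
of the stated model; rows are computed vectorised (the horizontal-gap state
is a prefix-max scan), and traceback is deterministic with ties preferring
match, then a gap in the second sequence, then a gap in the first.

Both species' junction CDS offsets are projected onto alignment columns
(the junction before CDS base *t* maps to the column carrying base *t*).
Conserved blocks are maximal runs of non-gap columns, split at every
junction column of either species — this enforces "no primer across a
junction" structurally rather than by post-filtering — and then split
further until each block carries at most `max_mismatches_per_block`
(default 3) mismatch columns.  The mismatch split recurses at the *median*
mismatch column rather than greedily left-to-right: the split tree then
depends only on mismatch positions, so blocks obtained under a stricter
budget always nest inside blocks from a looser one (a monotonicity property
the greedy rule violates).  Blocks shorter than the minimum primer length
are dropped.

## Primer model

Melting temperatures use unified nearest-neighbor thermodynamics (two-state
model): ΔH/ΔS summed over dinucleotide stacks with terminal A·T/G·C
initiation terms and a symmetry correction for self-complementary
sequences, a monovalent-salt entropy correction of 0.368 (N−1) ln[Na⁺], and
Tm = 1000·ΔH / (ΔS + R ln C_T) − 273.15 with primer 250 nM (in excess) and
Na⁺ 50 mM.  Tm is computed separately against each species' own allele —
the primer physically anneals to each genome on its own — while range and
pair-difference constraints are evaluated on the template species
(default A).

Defaults: length 18–24 nt, Tm 55–62 °C (optimum 58), GC 35–65 %, pair
ΔTm ≤ 3 °C, product 300–2000 bp in *both* species, ≥1 intron spanned in
both species, ≤3 cross-species mismatches per primer.  Mismatches within
the 5 terminal 3' bases and consecutive (adjacent) mismatches are hard
filters by default; an AT-rich 3' end (no G/C in the last 5 nt) is flagged
but not filtered.  Positions containing N are never eligible.

Each pair is scored by a transparent linear penalty

    score = 100 − [ 3·mm + 8·mm3' + (|Tm_fw−58| + |Tm_rv−58|)
                    + 2·|Tm_fw−Tm_rv| + |mean(product) − 800|/100 ]

with ties broken by fewer mismatches, smaller inter-species product-size
difference, then leftmost forward primer.  The weights are design choices
(no published formula exists for this ranking); they are exposed in the
configuration.  Reports are paginated with the top-scoring 60 pairs on the
first page.  `refine_pairs` is a pure search-within-result filter: it never
adds pairs, warns and clamps when given criteria looser than the original
run, and re-ranks survivors; filters commute.

## In-silico PCR (eHT-PCR)

`find_sites` is an exhaustive bounded-mismatch scanner: for a primer of
length m it accumulates per-window Hamming distance in m vectorised shifted
comparisons over each chromosome and both strands, so its contract is
literally "every window within `max_mismatches`" with no seeding loss.
`run_ehtpcr` additionally applies, by default, a seed constraint of at most
2 mismatches within the primer's first 32 bases, reproducing the classic
`bwa aln -k 2 -l 32 -n 5` parameterisation used for mapping primer pools.
This cap matters statistically: an 18-mer lies within 5 mismatches of a
random window with probability ≈3·10⁻⁵, so without it even a small genome
yields chance annealing predictions for every short primer, and single-locus
classification becomes meaningless.  The documented blind spot is the
converse: a primer carrying 3 designed mismatches against the partner
genome is not detected there and reports `no_amplification`; raise
`ehtpcr.seed_mismatches` (or set it to `None` for the raw exhaustive scan)
to trade background predictions for detection of such sites.  An optional
3'-anchor (exact match required over the last m bases) is off by default.

Amplicons combine a forward-primer hit on the plus strand with a downstream
reverse-primer hit on the minus strand (and the strand-mirrored case,
reported in forward-strand coordinates), bounded by
`max_product_size` (default 5000 bp — a deliberately generous ceiling for a
2-minute extension protocol) and below by the summed primer lengths.
Indels are not modelled in primer annealing: a primer bound across an indel
essentially never amplifies, and the Hamming-only contract keeps the scanner
oracle-testable.  Per (pair, genome), distinct amplicon coordinates are the
loci: 1 → specific, ≥2 → non-specific, 0 → no amplification.  Primer
deduplication before mapping is a pure optimisation; reports are identical
with it on or off.

## CAPS marker design

Parental amplicon alleles are aligned with the same affine-gap engine;
substitution SNPs are mismatch columns with bases in both rows, and gap
runs are recorded separately as indels.  Digestion uses a simple complete-
digest model: every occurrence of the enzyme's IUPAC site on either strand
cuts at the top-strand offset (bottom-strand occurrences at the mirrored
offset; palindromic sites counted once), and fragment lengths always sum to
the sequence length.  An enzyme is reported when the fragment-length
multisets of the two alleles differ, annotated with the called SNPs lying
inside a recognition site present in exactly one allele.  The shipped table
of ~20 common six-cutters is a self-contained editable TSV; partial
digestion, star activity and methylation sensitivity are not modelled, and
dCAPS (mismatch-primer-introduced sites) is out of scope.

## Synthetic test bed

`simulate_ortholog_pair` draws an ancestral gene (exon count 2–10, exon
lengths 60–400 bp, intron lengths 80–2000 bp, canonical GT..AG) and mutates
it into two descendant species alleles: per-site substitutions at
1 − identity (exons 0.97, introns 0.60 by default; uniform over the three
alternative bases, no transition bias), plus intron-only indels (per-site
rate 0.02, geometric lengths with mean 3 bp, splice dinucleotides never
touched).  Genes are embedded in random background (2 kb padding per side)
with GFF3-consistent annotation, and a truth record keeps junctions and
mutated positions.  `plant_paralog` inserts a substituted copy of the gene
span at a random position downstream of the gene — downstream only, so the
existing annotation's coordinates remain valid.  All randomness flows from
one explicitly seeded generator per call.

What the simulator does *not* emulate — codon structure, transition bias,
repeat landscapes, segmental duplication, sequencing error — bounds what
passing tests show: they validate the algorithmic contracts (junction
recovery, block extraction, specificity classification, CAPS recovery) on
idealised neutral-drift data, not wet-lab amplification rates on real
germplasm.

## Problem sizes in the test suite

The suite exercises the oracles at desk scale: the mapping oracle on a
50 kb genome × 30 primers × mismatch levels 0–5; the alignment oracle on
100 random pairs ≤200 nt; junction recovery on 100 simulated genes; the
end-to-end planted design on a fixed-seed 3-intron pair (~300 k emitted
pairs screened in both genomes); CAPS recovery on 50 planted fixtures.
`scripts/acceptance.py` repeats the pipeline at the same conditions under a
caller-supplied seed.
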