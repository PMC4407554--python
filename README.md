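# spanprime

Cross-species **intron-spanning genic PCR marker** design, with genome-wide
in-silico PCR and CAPS marker discovery.

## The problem

Breeding programmes for under-characterised crop species often lack genome
sequence, so markers must be carried over from related, well-sequenced
reference species via orthologous genes.  The trick that makes such markers
both *transferable* and *polymorphic* is structural: place both PCR primers
in coding exons — where purifying selection keeps sequence conserved enough
for cross-species annealing — but force the amplicon to cross at least one
intron, where relaxed constraint supplies the polymorphism needed for
genotyping.  Two hazards must be engineered around: primers that straddle an
exon–intron junction cannot anneal to genomic DNA, and close paralogs within
a genome produce multi-locus amplification.

`spanprime` automates the whole workflow for a pair of orthologous genes
from two species:

1. **Gene structure** — exon–intron junctions located either from GFF3
   annotation or de novo, by spliced alignment of the CDS onto its genomic
   locus (exact-anchor chaining + GT–AG boundary refinement).
2. **Ortholog alignment** — global CDS-to-CDS alignment (Needleman–Wunsch
   with affine gaps, score `s(gap of length k) = g_open + k·g_ext`), both
   species' junctions projected onto alignment columns, and extraction of
   gapless, junction-free, low-mismatch *conserved blocks*.
3. **Primer design** — exhaustive enumeration of oriented primer windows in
   conserved blocks, with nearest-neighbor melting temperatures
   (unified NN parameter set, `Tm = ΔH / (ΔS + R ln C_T) − 273.15` with
   monovalent-salt entropy correction), cross-species mismatch annotation
   (3'-window, consecutive, AT-rich-3' rules), pairing under intron-spanning
   and product-size constraints in **both** genomes, linear-penalty scoring
   and ranking.
4. **eHT-PCR** — electronic high-throughput PCR: every primer mapped to
   whole genomes by bounded-mismatch search (both strands), virtual
   amplicons enumerated, and each (pair, genome) classified *specific*
   (single locus), *non-specific* (≥2 loci) or *no amplification*.
5. **CAPS markers** — SNPs called between parental amplicon alleles and
   restriction enzymes reported whose digestion patterns distinguish them.

A seeded simulator (`spanprime.simulate`) generates ortholog gene pairs
with controlled exon/intron divergence, genomic background and planted
paralogs, and is the test bed for every module.

## Worked example

Simulate a 3-exon ortholog pair, design markers, and screen them genome-wide:

```sh
spanprime simulate --seed 5 --out sim \
    --set sim.n_exons=3,3 --set sim.exon_len=80,200 \
    --set sim.intron_len=80,200 --set sim.genome_padding=500
spanprime design --genomic-a sim/genome_A.fasta --cds-a sim/cds_A.fasta \
    --genomic-b sim/genome_B.fasta --cds-b sim/cds_B.fasta --out design
spanprime ehtpcr --pairs design/primer_pairs.tsv \
    --genome A=sim/genome_A.fasta --genome B=sim/genome_B.fasta --out eht
```

prints `30323 primer pair(s) -> design`, and the top of the ranked report is

```
pair_id  gene_a  gene_b  fw_seq                    rv_seq                  fw_tm  rv_tm  fw_mismatches  rv_mismatches  product_size_a  product_size_b  introns_spanned_a  introns_spanned_b  score   rank
P00001   gene_A  gene_B  GGCTACCGCAAAAATAGTACCCTA  ATTGGGAGTAACCATTACGCGT  57.99  58.00  0              0              547             542             2                  2                  97.425  1
```

i.e. the best pair has both primer melting temperatures at the 58 °C
optimum, no cross-species mismatches, and amplifies a ~545 bp product
crossing both introns in each species (product sizes differ between species
because the introns drifted).  The in-silico PCR report confirms single-locus
amplification in both genomes:

```
pair_id  genome_id  status    locus_count  loci
P00001   A          specific  1            chr_A:504-1051
P00001   B          specific  1            chr_B:504-1046
```

`spanprime caps --amplicons-a parentA.fa --amplicons-b parentB.fa --out caps`
then tabulates SNPs between sequenced parental amplicons and every
restriction enzyme whose fragment pattern separates the two alleles on a gel.

All parameters (primer length/Tm/GC windows, mismatch rules, product-size
range, mapping tolerance, simulator divergences) live in dataclasses exposed
via `--config` YAML or dotted `--set` overrides, and every run writes a
`manifest.json` sufficient to reproduce its outputs byte-identically.

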