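# mitomarkers

Taxon-diagnostic SNP discovery and CAPS marker design from annotated plant
organelle genomes.

## The problem

Verifying the declared genus of wood — particularly in composite products
such as particle board — requires molecular markers that identify a taxon
with certainty from small amounts of degraded DNA. Plant mitochondrial
genomes are a good substrate: they are present in many copies per cell and
their genes mutate slowly, so a nucleotide variant shared by every member of
a genus, family or order and absent everywhere else ("golden marker") can
carry real diagnostic weight at those ranks.

`mitomarkers` implements the full marker-development workflow for this
setting, aimed at researchers in forest genetics, timber-trade verification
and plant organelle genomics:

1. **Diagnostic SNP calling.** Gene sequences (taxonomic lineage included)
   are extracted from annotated GenBank records of related and outgroup
   species, each shared gene is aligned across all genomes, and every
   alignment column is scanned: a column is diagnostic for a taxon *T* when
   all members of *T* carry one base `X`, no non-member carries `X`, and the
   column is gap-free and unambiguous in every genome. Only SNPs inside
   conserved regions are retained, so that universal primers can amplify the
   locus across the whole validation panel.
2. **CAPS marker design.** A diagnostic SNP becomes a CAPS (cleaved
   amplified polymorphic site) marker when (i) it lies inside a restriction
   enzyme's recognition site, (ii) only the target allele completes the site
   — the target taxon's amplicon is cut, every other allele leaves it uncut —
   and (iii) it sits far enough from the gene ends that both primers fit
   inside the gene. Amplicons are capped at 200 bp because DNA from processed
   wood is highly fragmented. Digestion is simulated with full IUPAC
   recognition codes and Type IIS cut geometry, so the predicted gel
   patterns (fragment sizes) come out directly.
3. **Genome characterization.** Interspersed direct/inverted repeats
   (genome self-comparison), chloroplast-derived insertions (high-identity
   local alignment against the plastid genome), shared gene-order clusters
   between genomes, and an ORF scanner.
4. **Synthetic studies.** A seeded generator emits a toy clade of annotated
   genomes with planted diagnostic SNPs, CAPS sites, repeats and a
   plastid-like insertion, together with a truth manifest — every pipeline
   stage is testable offline against known ground truth.

## Worked example

Generate the default 13-species synthetic study (three species inside the
target order, ten outgroup species) and design markers for three nested
taxa:

```bash
mitomarkers simulate --seed 1 -o demo
mitomarkers caps --taxon Fagus --taxon Fagaceae --taxon Fagales -o out demo/*.gb
# INFO mitomarkers: 6 SNPs, 4 CAPS markers -> out/markers.tsv
```

`out/markers.tsv` (abridged):

| marker | taxon | gene | pos | alleles | enzyme | fragments (target/others) |
|---|---|---|---|---|---|---|
| Fagus_matr | Fagus | matr | 301 | G/A,C,T | BstXI | 40,40 / 80 |
| Fagus_ccmfc | Fagus | ccmfc | 501 | T/C | BsmBI | 40,40 / 80 |
| Fagaceae_nad7 | Fagaceae | nad7 | 701 | A/G | SfcI | 40,40 / 80 |
| Fagales_matr | Fagales | matr | 901 | G/A | NciI | 40,40 / 80 |

Each row is one validated design: the SNP position in the gene, the target
allele versus the alternatives, the enzyme whose site the target allele
completes, and the predicted gel bands — the target taxon's 80-bp amplicon
is cut into 40+40, everyone else's stays at 80. The `nad7` marker sits in
intron 2 of a cis-spliced gene: genes are extracted as genomic spans, so
intronic diagnostic sites are fair game.

The same genome's repeat scan:

```bash
mitomarkers repeats mito.fasta -o out
# copy_a          copy_b            orientation  length  identity
# 466..1384       11466..12384      inverted     918     100.0
# 50..366         11050..11366      direct       316     100.0
```

The library mirrors the CLI one-to-one; the equivalent Python entry points
are `mitomarkers.pipeline.design_markers`, `find_interspersed_repeats`,
`find_plastid_like_regions`, `insilico_pcr`, `digest_linear`, etc.

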