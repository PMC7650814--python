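# Methods

## Diagnostic SNP model

A SNP is diagnostic for a taxon *T* over a set of genomes when, at one
column of a per-gene multiple alignment, (a) every genome shows a plain
A/C/G/T base (columns containing a gap or an ambiguity code in *any* row are
ineligible — a diagnostic allele must be unambiguous in every taxon, and
down-weighting was deliberately rejected in favour of exclusion), (b) all
members of *T* share one base, and (c) no non-member carries that base. The
alternative-allele set reported with a SNP is exactly the set of bases
observed among non-members. Membership is resolved by matching the taxon
name against any rank of each record's lineage (order → family → genus, as
annotated in the GenBank ORGANISM block) or against the organism binomial.

A single-member taxon is allowed — a genus represented by one genome is the
realistic starting point for many marker studies — but triggers a warning,
because genus-level specificity is then extrapolated from one sequence and
only validation against more congeners can substantiate it.

**Conserved-region filter.** Markers must be amplifiable with near-universal
primers, so a diagnostic column only survives filtering when both flanks of
`flank_width` alignment columns (default 20; the SNP column excluded) exist
in full — a flank truncated by the alignment end fails, it is not shortened —
are gap-free in every row, and each contain at least `min_monomorphic`
percent (default 90%) monomorphic columns. The defaults are a deliberate
operationalization of "conserved region"; no published quantification
exists for this step, so both knobs are exposed. Note one consequence of a
percentage threshold: widening the flank can dilute a polymorphic column and
rescue a SNP, so the conserved count is monotone in `min_monomorphic` but
monotone in `flank_width` only at the 100% setting.

## Gene extraction

Internally all intervals are 0-based half-open; conversion to and from
GenBank's 1-based inclusive `join()`/`complement()` locations happens only
at the I/O boundary (via Biopython). Genes are extracted as their genomic
span by default, introns included, because intronic diagnostic sites are
legitimate marker targets (the family-level marker in the worked example
sits in an intron); exon-joined extraction is available as a mode switch.
Trans-spliced genes have no single contiguous genomic sequence and are
excluded from extraction; a gene is treated as trans-spliced when it carries
a `trans_splicing` qualifier or when the same gene name occurs in more than
one disjoint feature. Gene names are normalized case-insensitively through
an explicit, user-extensible alias table (`ccmFC`/`ccmFc`, `cytb`/`cob`, …),
since unreconciled synonyms silently shrink shared-gene sets. Any gene
sequence containing N drops that gene from alignment input.

## Multiple alignment

The built-in aligner is progressive: pairwise distances are one minus the
shared 6-mer fraction, a UPGMA tree (scipy average linkage) orders the
merges, and profiles are merged by global affine-gap dynamic programming on
expected column scores (match +2, mismatch −3, gap open −6, gap extend −1;
N scores 0 against everything). Ties are broken by lexicographic genome id,
making the output deterministic for given inputs. The DP is exact per merge
(verified against a brute-force affine recursion), but progressive alignment
is a heuristic overall — it does not guarantee sum-of-pairs optimality for
three or more sequences. Output of an external aligner can be substituted
via `import_alignment` (aligned FASTA); on import, every ungapped row is
checked against its source sequence. The scores above were chosen for
offline determinism and are not tuned to mimic any particular external tool.

## Local alignment engine

Repeat comparison and plastid-insertion detection share one ungapped
seed-and-extend engine: exact shared k-mers (k clamped to 12–20, or the
minimum repeat length when seeding the repeat finder) are grouped per
diagonal, merged into runs, and extended with an x-drop score (match +1,
mismatch −3, drop 20), trimming each hit to its best-scoring span. Identity
is matches over alignment columns, reported to 0.1% — with no gaps the
denominator equals the hit length. Hits below the length or identity
thresholds are dropped; overlapping hits on one diagonal are merged. The
engine is plus-strand only; callers provide orientation (the repeat finder
scans the genome against its own reverse complement, the plastid-region
detector scans both plastid strands and merges hits on mitochondrial
intervals).

Because extension is trimmed by score, a hit can absorb a boundary mismatch
when enough chance matches follow it (roughly a 0.4% event per boundary);
an exact-substring oracle and the finder therefore only agree exactly when
planted features are pinned by several mismatching flank bases. The
synthetic generator pins 8 — more than the x-drop tolerates — which makes
planted-coordinate recovery exact for every seed, not just most.

## CAPS design

Restriction enzymes are specified REBASE-style: caret notation for
within-site cutters (`G^AATTC`; the bottom-strand cut is taken as the
symmetric position, correct for these palindromic sites) or `(t/b)` offsets
for Type IIS enzymes cutting past the 3′ end (`CGTCTC(1/5)`). Digestion is
modeled by top-strand cut coordinates only — overhangs do not change gel
fragment sizes, which are the experimental readout. A plus-strand site at
*p* cuts at *p* + `cut_top`; a minus-strand site at *p* cuts at
*p* + site length − `cut_bottom`. Cut coordinates falling outside the open
interval of the molecule do not cut — a Type IIS site near an amplicon end
whose cut would land beyond the fragment leaves it intact, matching the
physics of short amplicons.

For each SNP × enzyme, every placement of the recognition window over the
SNP is tested on the member reference sequence, both strands: the site must
match with the target allele and fail for every alternative allele. An
amplicon is then chosen in alignment-column space: both primer windows
(default 18 columns) must be gap-free in all rows, identical to the member
consensus within the clade (mismatch budget 0), and within 2 mismatches of
every other genome; candidates are ranked by amplicon length, then leftmost
forward window, and the first candidate whose predicted fragments all reach
`min_fragment` (default 40 bp, a practical gel-resolution floor) and whose
alternative-allele amplicons stay uncut wins. Any additional constitutive
site of the same enzyme inside the amplicon disqualifies the candidate —
it would cut every taxon and blur the diagnostic pattern. Criterion (iii),
"not close to the gene ends", is operationalized exactly as "both primer
windows fit inside the gene alignment"; no extra distance parameter is
added. At most one marker is emitted per SNP-enzyme pair.

In-silico PCR matches the forward primer on the plus strand and the reverse
primer's reverse complement downstream, each within a mismatch budget but
with the 3′-terminal base required to pair exactly (polymerase extension is
intolerant of 3′ mismatches); zero or multiple predicted products are
distinct error conditions.

## Repeat finder

Interspersed (nontandem) repeats are found by self-comparison: the genome
against itself (trivial self-diagonal discarded) for direct repeats and
against its reverse complement for inverted ones, with exact seeds of the
minimum repeat length (default 50 bp, requiring at least one exact 50-mer
per copy pair — guaranteed for any repeat of a few hundred bases at the
default 99% identity floor). Pairs contained in a longer pair of the same
orientation are collapsed; a repeat present more than twice yields one entry
per unordered copy pair; output is longest-first. The minimum seed length is
capped below at 20 because shorter exact seeds stop being reliable anchors.
Counting rules differ between repeat tools (copy pairs versus unique repeat
sequences, merging heuristics), so absolute repeat counts are
parameter-sensitive across implementations; this package documents its own
rule rather than emulating any specific tool's.

## Plastid-like regions and gene order

Chloroplast-like regions are local-alignment hits (default ≥90% identity,
≥100 bp) of the mitochondrial genome against the plastid genome, both
plastid strands scanned, with overlapping mitochondrial intervals merged
before the genome fraction is computed (merged length over genome length,
to 0.01%); each merged region reports a length-weighted identity.

Gene-order clusters are maximal runs of genes present in both genomes and
adjacent in both annotated orders — any intervening annotated gene, shared
or not, breaks a run in the genome that carries it — in the same or exactly
reversed relative order, with a flag recording strand consistency.
Singletons are not reported. tRNA genes are excluded by default (the
comparison considers protein-coding genes) but can be switched on;
trans-spliced genes are excluded upstream. Genomes are treated as linear
sequences: a cluster spanning the origin of a circular map would be missed,
a conservative simplification.

## ORF scan

ATG-initiated open reading frames under the standard genetic code, stop
codon included in both the reported interval and the codon count, both
strands by default, minimum length 100 codons by default; within a reading
frame only the longest ORF per stop is reported, and fully nested same-strand
calls are removed on request. Verified against an independent six-frame
enumeration.

## Synthetic data generator

The generator emulates the data a taxon-marker study consumes: one annotated
mitochondrial genome per species over a four-rank taxonomy, with a gene
roster including a cis-spliced (intron-bearing), a minus-strand and a
trans-spliced gene. The default model has 13 species — one genome in the
target genus, a second family member, a third order member, ten outgroup
species — seven genes totalling ~5.8 kb of genic sequence in a 15 kb genome,
four planted CAPS-compatible SNPs (genus ×2, family, order; the genus-level
one carries a 153-bp planted primer pair whose digestion yields 108 + 45),
two plain diagnostic SNPs, a 316-bp direct and a 918-bp inverted repeat, and
one 668-bp plastid-derived insertion with 8 substitutions (98.8% identity).

Neutral divergence uses an equal-rate (Jukes–Cantor-like) choice among the
three non-ancestral bases, 15 substitutions per internal branch and 30 per
leaf by default, with no indels — alignments stay unambiguous, isolating
SNP-calling correctness from aligner behaviour (an explicit limitation: the
generator does not exercise gap handling in real alignments, nor
recombination, repeat-mediated isomerization, or annotation errors, so
passing tests certify algorithmic correctness, not robustness to dirty
annotation). Randomness comes from a single integer seed (default 42)
through one `numpy` generator; identical seeds give byte-identical output.

Three constructions make the planted truth *provably* the complete truth:

* clade-branch substitutions are placed in intergenic DNA only, leaf
  substitutions are globally distinct across species, and a leaf that is the
  sole member of a queried taxon receives intergenic substitutions only —
  otherwise any private genic substitution of that leaf would itself be a
  diagnostic SNP;
* each planted SNP's neighbourhood is scrubbed of accidental enzyme sites
  until, for every enzyme in the panel, the only discriminating placement
  over the SNP is the planted one (and none for plain SNPs), no constitutive
  site of the marker enzyme lies within amplicon reach, and no alternative
  allele creates a site; scrubbing mutates bases conservatively (never the
  SNP, and inside the planted site only at degenerate positions) and fails
  loudly if planted features collide;
* repeat copies and the plastid insertion get 8 forced-mismatch flank bases
  (beyond the x-drop), pinning recovered coordinates exactly.

The manifest's expected amplicon and fragment sizes for planted markers are
computed from first principles by replaying the designer's documented
deterministic choice rule (smallest amplicon, leftmost window, fragment
floor) on the known SNP and cut coordinates — not by calling the designer.
SNP positions in the manifest and reports are 1-based gene positions on the
sense strand; substitutions avoid a 220-bp protected radius around each
planted SNP so that flanks and primer windows stay monomorphic.

## Problem sizes

The default test and acceptance runs use the 13-genome, 15-kb model above
(full pipeline in seconds), brute-force oracle comparisons on 100 random
alignments, 1,000 random digestions, repeat oracles on 1.5-kb genomes and
six-frame ORF enumeration up to 4 kb — sizes chosen so the complete offline
evidence chain (planted-truth recovery plus oracle equivalence) runs on a
laptop in well under a minute while still exercising every code path,
including multi-exon, minus-strand and trans-spliced features.

## Known limitations

* Progressive alignment is heuristic; badly diverged or heavily indel-laden
  genes should be aligned externally and imported.
* The local-alignment engine is ungapped: an insertion inside a repeat copy
  or plastid insertion splits it into two hits (merged only if on one
  diagonal). Identity is computed without gap columns.
* Primer design checks sequence identity windows only — no melting
  temperature, secondary structure or dimer screening; designs should go
  through standard primer QC before ordering.
* Digestion assumes complete digestion of unmethylated DNA; star activity
  and partial digestion are out of scope.
* Circular genome topology is not modeled (repeats or clusters spanning the
  origin of a circular map are missed).
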