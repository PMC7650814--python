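"""End-to-end workflow: genomes -> per-gene alignments -> diagnostic SNPs -> markers.

Thin orchestration over the library modules, shared by the CLI and the
acceptance script.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

from . import alignment as aln_mod
from .alignment import GeneAlignment, build_msa
from .caps import CapsMarker, DesignConstraints, RestrictionEnzyme, design_caps_markers
from .genbank_io import AnnotatedGenome, extract_gene_sequences, shared_genes
from .snps import CandidateSNP, ConservationFilter, TaxonQuery, find_taxon_specific_snps


def full_lineage(genome: AnnotatedGenome) -> list[str]:
    """Lineage extended with the organism binomial (genus + species match)."""
    return [*genome.lineage, genome.organism]


def build_gene_alignments(
    genomes: Sequence[AnnotatedGenome],
    genes: Iterable[str] | None = None,
    mode: Literal["span", "exons"] = "span",
    exclude_trans_spliced: bool = True,
) -> dict[str, GeneAlignment]:
    """Align every shared gene across genomes with the built-in aligner.

    Only genes annotated in all genomes enter alignment; trans-spliced genes
    are excluded by default, and any gene sequence containing N drops that
    gene from the run (diagnostic alleles must be unambiguous everywhere).
    """
    if not genomes:
        raise ValueError("no genomes given")
    per_genome = {
        g.id: extract_gene_sequences(g, exclude_trans_spliced, mode) for g in genomes
    }
    lineages = {g.id: full_lineage(g) for g in genomes}
    wanted = set(genes) if genes is not None else None
    common = set.intersection(*(set(seqs) for seqs in per_genome.values()))
    alignments: dict[str, GeneAlignment] = {}
    for gene in sorted(common):
        if wanted is not None and gene not in wanted:
            continue
        seqs = {gid: per_genome[gid][gene] for gid in per_genome}
        if any("N" in s for s in seqs.values()):
            continue
        alignments[gene] = build_msa(seqs, gene_name=gene, lineages=lineages)
    return alignments


def discover_snps(
    alignments: Mapping[str, GeneAlignment],
    taxa: Iterable[str],
    filter: ConservationFilter | None = None,
    conserved_only: bool = True,
) -> list[CandidateSNP]:
    """Diagnostic SNPs for each queried taxon over a set of gene alignments.

    Only SNPs in conserved regions are kept by default — markers must be
    amplifiable with universal primers across the whole validation panel.
    """
    out: list[CandidateSNP] = []
    alns = list(alignments.values())
    if not alns:
        return out
    lineages = alns[0].lineages
    for taxon in taxa:
        query = TaxonQuery.from_lineages(taxon, lineages)
        out.extend(
            find_taxon_specific_snps(alns, query, filter, conserved_only=conserved_only)
        )
    return out


def design_markers(
    genomes: Sequence[AnnotatedGenome],
    taxa: Iterable[str],
    enzymes: Sequence[RestrictionEnzyme] | None = None,
    constraints: DesignConstraints | None = None,
    filter: ConservationFilter | None = None,
) -> tuple[list[CapsMarker], list[CandidateSNP], dict[str, GeneAlignment]]:
    """The full marker-development workflow for a set of annotated genomes."""
    alignments = build_gene_alignments(genomes)
    snps = discover_snps(alignments, taxa, filter)
    markers = design_caps_markers(snps, alignments, enzymes, constraints)
    return markers, snps, alignments


__all__ = [
    "build_gene_alignments",
    "discover_snps",
    "design_markers",
    "full_lineage",
    "shared_genes",
    "aln_mod",
]
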