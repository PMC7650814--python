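"""Plastid-derived insertions and shared gene-order clusters.

Mitochondrial genomes of seed plants routinely carry segments of chloroplast
origin (MTPTs), detected here as high-identity local alignments against the
plastid genome of the same individual.  Gene-order comparison looks for runs
of shared genes that stay adjacent in two genomes — synteny is essentially
absent in plant mitochondria, so surviving clusters are phylogenetically
informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .alignment import local_align
from .genbank_io import AnnotatedGenome, normalize_gene_name, reverse_complement


@dataclass(frozen=True)
class PlastidLikeRegion:
    """A mitochondrial interval with high identity to the plastid genome."""

    mito_interval: tuple[int, int]
    plastid_interval: tuple[int, int]
    identity: float


@dataclass(frozen=True)
class GeneOrderCluster:
    """Genes adjacent in both genomes, in the same or exactly reversed order."""

    genes: tuple[str, ...]
    orientation_consistent: bool


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def find_plastid_like_regions(
    mito: str,
    plastid: str,
    min_identity: float = 90.0,
    min_len: int = 100,
) -> tuple[list[PlastidLikeRegion], float]:
    """Chloroplast-like regions of a mitochondrial genome and their fraction.

    Both plastid strands are scanned; hits whose mitochondrial intervals
    overlap are merged (each merged region reports its best hit's plastid
    interval and length-weighted identity).  The fraction is merged length
    over mitochondrial genome length, as a percentage to 0.01%.
    """
    if not mito or not plastid:
        raise ValueError("both sequences must be non-empty")
    Lp = len(plastid)
    hits: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    hits.extend(local_align(mito, plastid, min_identity, min_len))
    for (m0, m1), (p0, p1), ident in local_align(
        mito, reverse_complement(plastid), min_identity, min_len
    ):
        hits.append(((m0, m1), (Lp - p1, Lp - p0), ident))

    merged = _merge_intervals([m for m, _, _ in hits])
    regions: list[PlastidLikeRegion] = []
    for interval in merged:
        covered = [h for h in hits if h[0][0] < interval[1] and h[0][1] > interval[0]]
        total = sum(h[0][1] - h[0][0] for h in covered)
        identity = round(
            sum(h[2] * (h[0][1] - h[0][0]) for h in covered) / total, 1
        )
        best = max(covered, key=lambda h: h[0][1] - h[0][0])
        regions.append(PlastidLikeRegion(interval, best[1], identity))
    fraction = round(sum(e - s for s, e in merged) / len(mito) * 100, 2)
    return regions, fraction


def _protein_gene_order(
    genome: AnnotatedGenome, include_trna: bool = False
) -> list[tuple[str, str]]:
    kinds = {"protein_coding"} | ({"tRNA"} if include_trna else set())
    feats = [f for f in genome.features if f.kind in kinds and not f.trans_spliced]
    feats.sort(key=lambda f: f.span[0])
    return [(normalize_gene_name(f.gene_name), f.strand) for f in feats]


def shared_gene_clusters(
    order_a: Sequence[tuple[str, str]],
    order_b: Sequence[tuple[str, str]],
) -> list[GeneOrderCluster]:
    """Maximal runs of shared genes adjacent in both gene orders.

    Orders are ``(gene, strand)`` lists.  Cluster members must occur in both
    genomes, and adjacency is evaluated on the full annotated order: any
    intervening gene — shared or not — breaks a run in the genome that
    carries it.  A run may appear in B in the same relative order or exactly
    reversed; the orientation flag records whether strands agree (after the
    flip, for reversed runs).  Singletons are not reported; clusters come out
    in order of first occurrence in A.
    """
    a = list(order_a)
    b = list(order_b)
    pos_b = {g: i for i, (g, _) in enumerate(b)}

    clusters: list[GeneOrderCluster] = []
    used: set[tuple[str, ...]] = set()
    i = 0
    n = len(a)
    while i < n:
        gene, _ = a[i]
        if gene not in pos_b:
            i += 1
            continue
        j = pos_b[gene]
        best_len = 1
        best_dir = 1
        for direction in (1, -1):
            k = 1
            while (
                i + k < n
                and 0 <= j + direction * k < len(b)
                and a[i + k][0] == b[j + direction * k][0]
            ):
                k += 1
            if k > best_len:
                best_len, best_dir = k, direction
        if best_len >= 2:
            run_a = a[i : i + best_len]
            if best_dir == 1:
                run_b = b[j : j + best_len]
                consistent = all(
                    sa == sb for (_, sa), (_, sb) in zip(run_a, run_b)
                )
            else:
                run_b = b[j - best_len + 1 : j + 1][::-1]
                consistent = all(
                    sa != sb for (_, sa), (_, sb) in zip(run_a, run_b)
                )
            genes = tuple(g for g, _ in run_a)
            if genes not in used and genes[::-1] not in used:
                used.add(genes)
                clusters.append(GeneOrderCluster(genes, consistent))
            i += best_len
        else:
            i += 1
    return clusters


def gene_order_clusters(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    include_trna: bool = False,
) -> list[GeneOrderCluster]:
    """Shared-gene-order clusters between two annotated genomes.

    tRNA genes are excluded by default (gene-order comparison considers
    protein-coding genes); switch them on to probe tRNA-anchored
    neighbourhoods.  Trans-spliced genes are excluded upstream.
    """
    return shared_gene_clusters(
        _protein_gene_order(genome_a, include_trna),
        _protein_gene_order(genome_b, include_trna),
    )


def write_region_report(
    regions: Sequence[PlastidLikeRegion], fraction: float, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("mito_start\tmito_end\tplastid_start\tplastid_end\tidentity\n")
        for r in regions:
            handle.write(
                f"{r.mito_interval[0]}\t{r.mito_interval[1]}\t"
                f"{r.plastid_interval[0]}\t{r.plastid_interval[1]}\t{r.identity}\n"
            )
        handle.write(f"# genome_fraction_percent\t{fraction:.2f}\n")
    return path


def write_cluster_report(clusters: Sequence[GeneOrderCluster], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("genes\torientation_consistent\n")
        for c in clusters:
            handle.write(f"{'/'.join(c.genes)}\t{c.orientation_consistent}\n")
    return path
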