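"""Taxon-diagnostic SNP calling from per-gene multiple alignments.

A column is diagnostic for a taxon when every member genome carries one base
there, no non-member genome carries that base, and the column is clean
(gap-free, unambiguous) across all rows.  Diagnostic columns are further
required to sit inside a conserved neighbourhood so that universal primers
can be designed around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import GAP, GeneAlignment, map_position

_BASES = frozenset("ACGT")


@dataclass
class TaxonQuery:
    """Membership split of genome ids for one named taxon.

    Membership is derived from lineages: a genome is a member when the taxon
    name matches any rank of its lineage (or its organism/genus name).
    """

    taxon_name: str
    members: set[str]
    non_members: set[str]

    def __post_init__(self) -> None:
        if not self.members or not self.non_members:
            raise ValueError(
                f"taxon {self.taxon_name!r}: member and non-member sets must both be non-empty"
            )
        if self.members & self.non_members:
            raise ValueError(f"taxon {self.taxon_name!r}: member sets overlap")
        if len(self.members) == 1:
            warnings.warn(
                f"taxon {self.taxon_name!r} has a single member genome; "
                "taxon-level specificity is extrapolated from one sequence",
                stacklevel=2,
            )

    @classmethod
    def from_lineages(
        cls, taxon_name: str, lineages: Mapping[str, Sequence[str]]
    ) -> "TaxonQuery":
        members = {
            rid
            for rid, lineage in lineages.items()
            if taxon_name in lineage or any(taxon_name in part.split() for part in lineage)
        }
        return cls(taxon_name, members, set(lineages) - members)


@dataclass
class ConservationFilter:
    """Conserved-flank requirement around a candidate SNP column.

    Both flanks of ``flank_width`` columns (the SNP column excluded) must
    exist in full — a flank truncated by the alignment end fails — be
    gap-free in every row, and each have at least ``min_monomorphic`` percent
    monomorphic columns.
    """

    flank_width: int = 20
    min_monomorphic: float = 90.0

    def __post_init__(self) -> None:
        if self.flank_width < 1:
            raise ValueError("flank_width must be >= 1")


@dataclass
class CandidateSNP:
    """One alignment column diagnostic for a target taxon."""

    gene_name: str
    column: int
    target_taxon: str
    target_allele: str
    alt_alleles: set[str]
    positions: dict[str, int] = field(default_factory=dict)
    conserved: bool = False


def conserved_flank_filter(
    aln: GeneAlignment,
    column: int,
    flank_width: int = 20,
    min_monomorphic: float = 90.0,
) -> bool:
    """True iff both flanks of the column are full-width, gap-free, and conserved."""
    if flank_width < 1:
        raise ValueError("flank_width must be >= 1")
    if not 0 <= column < aln.n_columns:
        raise IndexError(f"column {column} out of range")
    rows = list(aln.rows.values())
    for flank in (range(column - flank_width, column), range(column + 1, column + 1 + flank_width)):
        cols = list(flank)
        if cols[0] < 0 or cols[-1] >= aln.n_columns:
            return False
        monomorphic = 0
        for col in cols:
            chars = {row[col] for row in rows}
            if GAP in chars:
                return False
            if len(chars) == 1 and chars <= _BASES:
                monomorphic += 1
        if monomorphic / len(cols) * 100 < min_monomorphic:
            return False
    return True


def find_taxon_specific_snps(
    alignments: Iterable[GeneAlignment],
    query: TaxonQuery,
    filter: ConservationFilter | None = None,
    conserved_only: bool = False,
) -> list[CandidateSNP]:
    """Scan every alignment column for bases diagnostic of the query taxon.

    A column qualifies when (a) no row has a gap or non-ACGT base, (b) all
    member rows share one base, and (c) no non-member row carries that base.
    The conservation filter sets the ``conserved`` flag (and gates the output
    when ``conserved_only`` is set).  Output is sorted by gene then column.
    """
    filter = filter or ConservationFilter()
    out: list[CandidateSNP] = []
    for aln in alignments:
        ids = set(aln.ids)
        members = sorted(query.members & ids)
        non_members = sorted(query.non_members & ids)
        unresolved = ids - query.members - query.non_members
        if unresolved:
            raise ValueError(
                f"{aln.gene_name}: rows not resolvable to member/non-member: {sorted(unresolved)}"
            )
        if not members or not non_members:
            continue
        member_rows = [aln.rows[r] for r in members]
        non_member_rows = [(r, aln.rows[r]) for r in non_members]
        all_rows = list(aln.rows.values())
        for col in range(aln.n_columns):
            chars = {row[col] for row in all_rows}
            if not chars <= _BASES:
                continue
            member_alleles = {row[col] for row in member_rows}
            if len(member_alleles) != 1:
                continue
            target = next(iter(member_alleles))
            alts = {row[col] for _, row in non_member_rows}
            if target in alts:
                continue
            conserved = conserved_flank_filter(
                aln, col, filter.flank_width, filter.min_monomorphic
            )
            if conserved_only and not conserved:
                continue
            positions = {
                rid: map_position(aln, rid, col, "col2pos") for rid in aln.rows
            }
            out.append(
                CandidateSNP(
                    gene_name=aln.gene_name,
                    column=col,
                    target_taxon=query.taxon_name,
                    target_allele=target,
                    alt_alleles=alts,
                    positions={k: int(v) for k, v in positions.items()},
                    conserved=conserved,
                )
            )
    return sorted(out, key=lambda s: (s.gene_name, s.column))


def summarize_snps(snps: Iterable[CandidateSNP]) -> pd.DataFrame:
    """Per-taxon totals: SNP count and number of distinct genes."""
    records = [(s.target_taxon, s.gene_name) for s in snps]
    if not records:
        return pd.DataFrame(columns=["taxon", "n_snps", "n_genes"])
    df = pd.DataFrame(records, columns=["taxon", "gene"])
    summary = (
        df.groupby("taxon")
        .agg(n_snps=("gene", "size"), n_genes=("gene", "nunique"))
        .reset_index()
    )
    return summary


def snp_report(
    snps: Iterable[CandidateSNP], reference_id: str | None = None
) -> pd.DataFrame:
    """Tabular SNP report (the machine-readable twin of a marker appendix table)."""
    rows = []
    for s in snps:
        ref_pos = s.positions.get(reference_id) if reference_id else None
        rows.append(
            {
                "gene": s.gene_name,
                "column": s.column,
                "reference_position": ref_pos,
                "target_taxon": s.target_taxon,
                "target_allele": s.target_allele,
                "alt_alleles": ",".join(sorted(s.alt_alleles)),
                "conserved": s.conserved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "column",
            "reference_position",
            "target_taxon",
            "target_allele",
            "alt_alleles",
            "conserved",
        ],
    )


def write_snp_report(
    snps: Iterable[CandidateSNP], path: str | Path, reference_id: str | None = None
) -> Path:
    path = Path(path)
    snp_report(snps, reference_id).to_csv(path, sep="\t", index=False)
    return path
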