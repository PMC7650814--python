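"""CAPS marker design: enzyme geometry, digestion, in-silico PCR.

A CAPS (cleaved amplified polymorphic site) marker is a short PCR amplicon
whose restriction digestion pattern separates a target taxon from everything
else: the target allele completes an enzyme recognition site, every
alternative allele breaks it, and the readout is fragment sizes on a gel.

Design criteria implemented here:
(i) the diagnostic SNP lies inside a recognition site, (ii) only the target
allele completes the site (both strands checked, and every alternative
allele must leave the amplicon uncut), and (iii) the SNP is far enough from
the gene ends that both primer windows fit inside the gene alignment.
Amplicons are capped (default 200 bp) because DNA from processed wood is
highly degraded; primers must match the target clade perfectly and every
other genome with at most a small mismatch budget.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import GAP, GeneAlignment, map_position
from .genbank_io import reverse_complement
from .snps import CandidateSNP, TaxonQuery

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class PcrError(Exception):
    """Base class for in-silico PCR failures."""


class NoProductError(PcrError):
    pass


class MultipleProductsError(PcrError):
    pass


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition pattern plus cut geometry.

    ``cut_top`` is the offset of the top-strand cut from the recognition
    start; ``cut_bottom`` is the top-strand coordinate offset of the
    bottom-strand cut.  For outside cutters (Type IIS) both lie beyond the
    recognition length.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    @property
    def site_length(self) -> int:
        return len(self.recognition)


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    return re.compile("".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in pattern))


def iupac_match(pattern: str, text: str) -> bool:
    """Exact-length IUPAC match of ``pattern`` against a plain DNA ``text``."""
    return len(pattern) == len(text) and all(
        t in IUPAC[p] for p, t in zip(pattern, text)
    )


_TB_RE = re.compile(r"^([ACGTRYSWKMBDHVN]+)\((-?\d+)/(-?\d+)\)$")


def parse_enzyme_spec(name: str, site: str) -> RestrictionEnzyme:
    """Parse one recognition string in caret or REBASE ``(t/b)`` notation.

    ``G^AATTC`` puts the top cut after the caret; the bottom cut is taken as
    the symmetric position (these within-site patterns are palindromic).
    ``CGTCTC(1/5)`` cuts 1 (top) and 5 (bottom) bases past the 3' end of the
    site.  Mixing both notations is an error.
    """
    site = site.strip().upper()
    if "^" in site and "(" in site:
        raise ValueError(f"{name}: caret and (t/b) notation cannot be combined")
    if "^" in site:
        if site.count("^") != 1:
            raise ValueError(f"{name}: exactly one caret expected")
        cut = site.index("^")
        recognition = site.replace("^", "")
        return RestrictionEnzyme(name, recognition, cut, len(recognition) - cut)
    m = _TB_RE.match(site)
    if m:
        recognition, top, bottom = m.group(1), int(m.group(2)), int(m.group(3))
        return RestrictionEnzyme(
            name, recognition, len(recognition) + top, len(recognition) + bottom
        )
    raise ValueError(f"{name}: unparseable recognition spec {site!r}")


def parse_enzyme_table(path: str | Path) -> list[RestrictionEnzyme]:
    """Read a TSV of ``name<TAB>recognition`` rows (header optional)."""
    enzymes: list[RestrictionEnzyme] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>site")
            name, site = parts[0].strip(), parts[1].strip()
            if lineno == 1 and name.lower() == "name":
                continue
            enzymes.append(parse_enzyme_spec(name, site))
    return enzymes


def default_enzymes() -> list[RestrictionEnzyme]:
    """The bundled enzyme table (common 4-6 bp cutters plus Type IIS)."""
    with resources.as_file(
        resources.files("mitomarkers").joinpath("data/enzymes.tsv")
    ) as path:
        return parse_enzyme_table(path)


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All recognition-site matches on a plain-DNA sequence.

    Plus-strand hits match the recognition itself; minus-strand hits are
    matches of its reverse complement, reported at their plus-strand start.
    Palindromic sites are reported once (plus strand).
    """
    sequence = sequence.upper()
    sites: list[tuple[int, str]] = []
    fwd = _iupac_regex(enzyme.recognition)
    for m in re.finditer(f"(?={fwd.pattern})", sequence):
        sites.append((m.start(), "+"))
    if not enzyme.palindromic:
        rev = _iupac_regex(reverse_complement(enzyme.recognition))
        for m in re.finditer(f"(?={rev.pattern})", sequence):
            sites.append((m.start(), "-"))
    return sorted(sites)


def cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut coordinates on a linear molecule, unique and sorted.

    A plus-strand site at p cuts at ``p + cut_top``; a minus-strand site at p
    cuts at ``p + site_length - cut_bottom`` (the enzyme reads the bottom
    strand there).  Cuts that would fall outside ``[1, L-1]`` — e.g. an
    outside cutter whose cut coordinate lies beyond the molecule — do not cut.
    """
    L = len(sequence)
    cuts: set[int] = set()
    for pos, strand in find_sites(sequence, enzyme):
        if strand == "+":
            cut = pos + enzyme.cut_top
        else:
            cut = pos + enzyme.site_length - enzyme.cut_bottom
        if 1 <= cut <= L - 1:
            cuts.add(cut)
    return sorted(cuts)


def digest_linear(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths after complete digestion of a linear molecule.

    Fragments always sum to the sequence length; reported largest-first
    (gel-band order).
    """
    L = len(sequence)
    cuts = cut_positions(sequence, enzyme)
    bounds = [0] + cuts + [L]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(fragments, reverse=True)


def _primer_matches(template: str, primer: str, max_mismatches: int) -> list[int]:
    """Start positions where the primer anneals (3'-terminal base exact)."""
    hits = []
    plen = len(primer)
    for i in range(len(template) - plen + 1):
        window = template[i : i + plen]
        if window[-1] not in IUPAC[primer[-1]]:
            continue
        mismatches = sum(1 for p, t in zip(primer, window) if t not in IUPAC[p])
        if mismatches <= max_mismatches:
            hits.append(i)
    return hits


def insilico_pcr(
    template: str, fwd: str, rev: str, max_mismatches: int = 0
) -> str:
    """Predict the single PCR product of a primer pair on a linear template.

    The forward primer anneals to the plus strand; the reverse primer's
    reverse complement must occur downstream.  Each primer tolerates at most
    ``max_mismatches`` but its 3'-terminal base must pair exactly.  The
    amplicon runs from the forward-primer start through the end of the
    reverse-primer binding site.  Zero or multiple products raise distinct
    errors.
    """
    if len(fwd) < 12 or len(rev) < 12:
        raise ValueError("primers must be at least 12 bases")
    template = template.upper()
    fwd = fwd.upper()
    rev_rc = reverse_complement(rev.upper())
    fwd_hits = _primer_matches(template, fwd, max_mismatches)
    # On the plus strand the reverse primer's 3' end is the *leftmost* base
    # of its reverse-complement match, so check that end exactly.
    rev_hits = []
    plen = len(rev_rc)
    for i in range(len(template) - plen + 1):
        window = template[i : i + plen]
        if window[0] not in IUPAC[rev_rc[0]]:
            continue
        mismatches = sum(1 for p, t in zip(rev_rc, window) if t not in IUPAC[p])
        if mismatches <= max_mismatches:
            rev_hits.append(i)
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            if r >= f + len(fwd):
                products.append(template[f : r + plen])
    if not products:
        raise NoProductError("no product: primer pair does not amplify this template")
    if len(products) > 1:
        raise MultipleProductsError(f"{len(products)} products predicted")
    return products[0]


@dataclass
class DesignConstraints:
    """Amplicon, primer and fragment constraints for CAPS design."""

    max_amplicon: int = 200
    primer_len_min: int = 18
    primer_len_max: int = 25
    mismatch_budget_target: int = 0
    mismatch_budget_other: int = 2
    min_fragment: int = 40

    def __post_init__(self) -> None:
        if min(
            self.max_amplicon,
            self.primer_len_min,
            self.primer_len_max,
            self.min_fragment,
        ) < 1 or self.mismatch_budget_target < 0:
            raise ValueError("constraints must be positive")
        if self.mismatch_budget_other < self.mismatch_budget_target:
            raise ValueError("non-target mismatch budget must be >= target budget")


@dataclass
class CapsMarker:
    """A validated SNP-enzyme-amplicon design with predicted fragments."""

    snp: CandidateSNP
    enzyme: RestrictionEnzyme
    fwd_primer: str
    rev_primer: str
    fwd_window: tuple[int, int]  # alignment columns
    rev_window: tuple[int, int]
    amplicon_intervals: dict[str, tuple[int, int]]  # per genome, 0-based gene coords
    fragments_target: list[int]
    fragments_alt: dict[str, list[int]] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.snp.target_taxon}_{self.snp.gene_name}"

    @property
    def amplicon_length(self) -> int:
        return sum(self.fragments_target)


def _site_discriminates(
    enzyme: RestrictionEnzyme, context: str, offset: int, target: str, alts: set[str]
) -> bool:
    """Does a site window (SNP at ``offset``) match only with the target allele?"""
    rc = reverse_complement(enzyme.recognition)

    def matches(window: str) -> bool:
        return iupac_match(enzyme.recognition, window) or iupac_match(rc, window)

    window = context[:offset] + target + context[offset + 1 :]
    if not matches(window):
        return False
    for alt in alts:
        if matches(context[:offset] + alt + context[offset + 1 :]):
            return False
    return True


def _window_ok(
    aln: GeneAlignment,
    cols: tuple[int, int],
    reference: str,
    members: Sequence[str],
    constraints: DesignConstraints,
) -> bool:
    """Gap-free primer window satisfying per-clade mismatch budgets."""
    start, end = cols
    if start < 0 or end > aln.n_columns:
        return False
    ref_window = aln.rows[reference][start:end]
    if GAP in ref_window:
        return False
    for rid in aln.rows:
        row_window = aln.rows[rid][start:end]
        if GAP in row_window:
            return False
        mism = sum(1 for a, b in zip(ref_window, row_window) if a != b)
        budget = (
            constraints.mismatch_budget_target
            if rid in members
            else constraints.mismatch_budget_other
        )
        if mism > budget:
            return False
    return True


def design_caps_markers(
    snps: Iterable[CandidateSNP],
    alignments: Mapping[str, GeneAlignment],
    enzymes: Sequence[RestrictionEnzyme] | None = None,
    constraints: DesignConstraints | None = None,
) -> list[CapsMarker]:
    """Screen diagnostic SNPs against an enzyme panel and design amplicons.

    For every SNP x enzyme, every placement of the recognition window over
    the SNP is tested on the member reference sequence (both strands): the
    site must exist with the target allele and vanish for every alternative
    allele.  An amplicon of at most ``max_amplicon`` bases is then chosen
    around the SNP whose primer windows are gap-free alignment blocks meeting
    the mismatch budgets; the smallest feasible amplicon wins (ties: leftmost
    forward window).  Predicted target fragments must all reach
    ``min_fragment`` and every alternative-allele amplicon must stay uncut.
    At most one marker per SNP-enzyme pair is emitted.
    """
    enzymes = list(enzymes) if enzymes is not None else default_enzymes()
    if not enzymes:
        raise ValueError("enzyme list must be non-empty")
    constraints = constraints or DesignConstraints()
    markers: list[CapsMarker] = []
    for snp in snps:
        aln = alignments.get(snp.gene_name)
        if aln is None:
            raise KeyError(f"no alignment for gene {snp.gene_name}")
        query = TaxonQuery.from_lineages(snp.target_taxon, aln.lineages)
        members = sorted(query.members & set(aln.ids))
        reference = members[0]
        refseq = aln.ungapped(reference)
        ref_pos = snp.positions[reference] - 1  # 0-based position in refseq
        plen = constraints.primer_len_min
        col = snp.column

        for enzyme in enzymes:
            L = enzyme.site_length
            placement = None
            for offset in range(L):
                start = ref_pos - offset
                if start < 0 or start + L > len(refseq):
                    continue
                context = refseq[start : start + L]
                if _site_discriminates(
                    enzyme, context, offset, snp.target_allele, snp.alt_alleles
                ):
                    placement = start
                    break
            if placement is None:
                continue

            # candidate primer windows in alignment-column space
            fwd_starts = [
                f
                for f in range(max(0, col - constraints.max_amplicon + 1), col - plen + 1)
                if _window_ok(aln, (f, f + plen), reference, members, constraints)
            ]
            rev_ends = [
                r
                for r in range(col + 1 + plen, min(aln.n_columns, col + constraints.max_amplicon) + 1)
                if _window_ok(aln, (r - plen, r), reference, members, constraints)
            ]
            candidates = []
            for f in fwd_starts:
                a_start = int(map_position(aln, reference, f, "col2pos")) - 1
                for r in rev_ends:
                    a_end = int(map_position(aln, reference, r - 1, "col2pos"))
                    length = a_end - a_start
                    if length > constraints.max_amplicon:
                        continue
                    candidates.append((length, f, -r, r, a_start, a_end))
            chosen = None
            for length, f, _, r, a_start, a_end in sorted(candidates):
                amplicon = refseq[a_start:a_end]
                snp_off = ref_pos - a_start
                frags_target = digest_linear(amplicon, enzyme)
                if len(frags_target) < 2 or min(frags_target) < constraints.min_fragment:
                    continue
                frags_alt: dict[str, list[int]] = {}
                ok = True
                for alt in sorted(snp.alt_alleles):
                    amp_alt = amplicon[:snp_off] + alt + amplicon[snp_off + 1 :]
                    frags = digest_linear(amp_alt, enzyme)
                    if frags != [len(amp_alt)]:
                        ok = False
                        break
                    frags_alt[alt] = frags
                if ok:
                    chosen = (f, r, a_start, a_end, frags_target, frags_alt)
                    break
            if chosen is None:
                continue
            f, r, a_start, a_end, frags_target, frags_alt = chosen
            intervals = {}
            for rid in aln.rows:
                s = int(map_position(aln, rid, f, "col2pos")) - 1
                e = int(map_position(aln, rid, r - 1, "col2pos"))
                intervals[rid] = (s, e)
            markers.append(
                CapsMarker(
                    snp=snp,
                    enzyme=enzyme,
                    fwd_primer=refseq[a_start : a_start + plen],
                    rev_primer=reverse_complement(refseq[a_end - plen : a_end]),
                    fwd_window=(f, f + plen),
                    rev_window=(r - plen, r),
                    amplicon_intervals=intervals,
                    fragments_target=frags_target,
                    fragments_alt=frags_alt,
                )
            )
    return markers


def marker_report(markers: Iterable[CapsMarker], reference_id: str | None = None) -> pd.DataFrame:
    """Marker table in gel-readout layout (one row per validated design)."""
    rows = []
    for m in markers:
        alt_pattern = "/".join(
            ",".join(str(x) for x in m.fragments_alt[a]) for a in sorted(m.fragments_alt)
        )
        rows.append(
            {
                "marker": m.name,
                "taxon": m.snp.target_taxon,
                "gene": m.snp.gene_name,
                "reference_position": m.snp.positions.get(reference_id)
                if reference_id
                else m.snp.positions.get(min(m.snp.positions)),
                "target_allele": m.snp.target_allele,
                "alt_alleles": ",".join(sorted(m.snp.alt_alleles)),
                "enzyme": m.enzyme.name,
                "fragments_target": ",".join(str(x) for x in m.fragments_target),
                "fragments_others": alt_pattern,
                "amplicon_length": m.amplicon_length,
                "fwd_primer": m.fwd_primer,
                "rev_primer": m.rev_primer,
            }
        )
    return pd.DataFrame(rows)


def write_marker_report(
    markers: Iterable[CapsMarker], path: str | Path, reference_id: str | None = None
) -> Path:
    path = Path(path)
    marker_report(markers, reference_id).to_csv(path, sep="\t", index=False)
    return path
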