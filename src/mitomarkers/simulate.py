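"""Seeded synthetic datasets with planted, provable ground truth.

The generator emits a miniature clade of annotated organelle genomes — a
taxonomy of order/family/genus/species, a small gene roster, neutral
divergence — with planted features whose expected pipeline output is written
to a truth manifest: taxon-diagnostic SNPs (some completing a restriction
site, i.e. CAPS-compatible), interspersed repeats, and a plastid-derived
insertion.  Every pipeline stage is thereby testable offline against known
truth.

Guarantees engineered into the construction (and verified before returning):

* planted diagnostic SNPs are the *only* diagnostic columns for the queried
  taxa: clade-branch substitutions are placed in intergenic DNA, leaf
  substitutions use globally distinct positions, and leaves that are sole
  members of a queried taxon receive intergenic substitutions only;
* planted CAPS sites are discriminative by construction — the target allele
  completes the recognition site, every alternative breaks it — and the SNP
  neighbourhood is scrubbed of accidental sites so each planted SNP pairs
  with exactly one enzyme of the panel;
* planted repeats and the plastid insertion have mismatching flanks, so
  seed-and-extend recovery reproduces their exact coordinates.

Substitutions follow an equal-rate (Jukes-Cantor-like) choice among the three
non-ancestral bases; there are no indels by default, so alignments are
unambiguous and SNP-calling correctness is isolated from aligner behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .caps import DesignConstraints, RestrictionEnzyme, default_enzymes, iupac_match, IUPAC
from .genbank_io import AnnotatedGenome, GeneFeature, reverse_complement, write_genbank

_BASES = "ACGT"

# planted-feature flanks are forced to mismatch over this many bases: longer
# than the local aligner's x-drop tolerance, so extension can never run past
# a planted boundary and recovered coordinates are exact for any seed
_PIN = 8


@dataclass
class Species:
    id: str
    organism: str
    lineage: list[str]  # order, family, genus


@dataclass
class GeneSpec:
    name: str
    length: int
    strand: str = "+"
    exons: list[tuple[int, int]] | None = None  # gene-local; None = single exon
    trans_spliced: bool = False


@dataclass
class PlantedSnp:
    """A diagnostic SNP: members of ``taxon`` carry ``target_allele``."""

    gene: str
    position: int  # 0-based on the gene's sense strand (genomic-span coords)
    taxon: str
    target_allele: str
    alt_default: str
    alt_overrides: dict[str, str] = field(default_factory=dict)  # genus -> allele

    def alt_for(self, species: Species) -> str:
        return self.alt_overrides.get(species.lineage[-1], self.alt_default)

    @property
    def alt_alleles(self) -> set[str]:
        return {self.alt_default, *self.alt_overrides.values()}


@dataclass
class PlantedCaps(PlantedSnp):
    """A CAPS-compatible SNP: the target allele completes an enzyme site."""

    enzyme: str = ""
    site_offset: int = 0  # SNP offset within the recognition site
    pcr_fragments: tuple[int, int] | None = None  # planted-primer digestion plan


@dataclass
class PlantedRepeat:
    length: int
    orientation: str = "direct"  # or "inverted"


@dataclass
class PlantedInsertion:
    length: int = 668
    n_substitutions: int = 8


@dataclass
class CladeModel:
    """Full description of one synthetic study: taxonomy, genes, planted truth."""

    species: list[Species]
    genes: list[GeneSpec]
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    planted_insertions: list[PlantedInsertion] = field(default_factory=list)
    clade_substitutions: int = 15
    leaf_substitutions: int = 30
    spacer: int = 300
    bay_length: int = 2500
    insertion_bay: int = 1500
    plastid_length: int = 6000
    protect_radius: int = 220
    seed: int = 42
    enzyme_panel: list[RestrictionEnzyme] = field(default_factory=default_enzymes)
    constraints: DesignConstraints = field(default_factory=DesignConstraints)


@dataclass
class SimulatedDataset:
    genomes: list[AnnotatedGenome]
    plastid: str
    manifest: list[dict]
    model: CladeModel


def default_model(seed: int = 42) -> CladeModel:
    """The default study design: a 13-species tree (3 in-order, 10 outgroup).

    Mirrors the shape of a genus/family/order marker study — one genome in
    the target genus, a second family member, a third order member, and ten
    outgroup species — with four planted CAPS-compatible SNPs at the
    genus/family/family/order levels and two plain diagnostic SNPs.
    """
    species = [
        Species("SIM001", "Fagus sylvatica", ["Fagales", "Fagaceae", "Fagus"]),
        Species("SIM002", "Quercus variabilis", ["Fagales", "Fagaceae", "Quercus"]),
        Species("SIM003", "Betula pendula", ["Fagales", "Betulaceae", "Betula"]),
        Species("SIM004", "Bombax ceiba", ["Malvales", "Malvaceae", "Bombax"]),
        Species("SIM005", "Eucalyptus grandis", ["Myrtales", "Myrtaceae", "Eucalyptus"]),
        Species("SIM006", "Lagerstroemia indica", ["Myrtales", "Lythraceae", "Lagerstroemia"]),
        Species("SIM007", "Populus alba", ["Malpighiales", "Salicaceae", "Populus"]),
        Species("SIM008", "Populus davidiana", ["Malpighiales", "Salicaceae", "Populus"]),
        Species("SIM009", "Populus tremula", ["Malpighiales", "Salicaceae", "Populus"]),
        Species("SIM010", "Liriodendron tulipifera", ["Magnoliales", "Magnoliaceae", "Liriodendron"]),
        Species("SIM011", "Malus domestica", ["Rosales", "Rosaceae", "Malus"]),
        Species("SIM012", "Ginkgo biloba", ["Ginkgoales", "Ginkgoaceae", "Ginkgo"]),
        Species("SIM013", "Pinus taeda", ["Pinales", "Pinaceae", "Pinus"]),
    ]
    genes = [
        GeneSpec("matR", 1200),
        GeneSpec("ccmFc", 1000),
        GeneSpec("nad7", 1200, exons=[(0, 600), (800, 1200)]),
        GeneSpec("cox1", 700),
        GeneSpec("cob", 600, strand="-"),
        GeneSpec("nad9", 500),
        GeneSpec("nad1", 600, trans_spliced=True),
    ]
    planted: list[PlantedSnp] = [
        PlantedCaps(
            "matR", 300, "Fagus", "G", "C",
            alt_overrides={"Betula": "T", "Populus": "A"},
            enzyme="BstXI", site_offset=10,
        ),
        PlantedCaps(
            "ccmFc", 500, "Fagus", "T", "C",
            enzyme="BsmBI", site_offset=4, pcr_fragments=(108, 45),
        ),
        PlantedCaps("nad7", 700, "Fagaceae", "A", "G", enzyme="SfcI", site_offset=4),
        PlantedCaps("matR", 900, "Fagales", "G", "A", enzyme="NciI", site_offset=2),
        PlantedSnp("cox1", 350, "Fagaceae", "T", "C"),
        PlantedSnp("cob", 300, "Fagales", "A", "G"),
    ]
    return CladeModel(
        species=species,
        genes=genes,
        planted_snps=planted,
        planted_repeats=[PlantedRepeat(316, "direct"), PlantedRepeat(918, "inverted")],
        planted_insertions=[PlantedInsertion(668, 8)],
        seed=seed,
    )


# --------------------------------------------------------------------------
# construction helpers


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, n)]


@dataclass
class _Layout:
    total: int
    gene_start: dict[str, int]
    features: dict[str, list[GeneFeature]]  # per gene name
    bay_a: tuple[int, int]
    bay_b: tuple[int, int]
    bay_c: tuple[int, int]
    gene_positions: set[int]


def _build_layout(model: CladeModel) -> _Layout:
    cursor = 0
    bay_a = (cursor, cursor + model.bay_length)
    cursor += model.bay_length
    gene_start: dict[str, int] = {}
    features: dict[str, list[GeneFeature]] = {}
    gene_positions: set[int] = set()
    trans_pending: list[GeneSpec] = []
    for spec in model.genes:
        cursor += model.spacer
        if spec.trans_spliced:
            trans_pending.append(spec)
            half = spec.length // 2
            start = cursor
            features[spec.name] = [
                GeneFeature(
                    spec.name, "protein_coding", [(start, start + half)], spec.strand, True
                )
            ]
            gene_positions.update(range(start, start + half))
            cursor += half
            # second transcription unit placed after another spacer
            cursor += model.spacer
            start2 = cursor
            features[spec.name].append(
                GeneFeature(
                    spec.name, "protein_coding", [(start2, start2 + half)], spec.strand, True
                )
            )
            gene_positions.update(range(start2, start2 + half))
            cursor += half
            gene_start[spec.name] = start
            continue
        start = cursor
        gene_start[spec.name] = start
        exons = spec.exons or [(0, spec.length)]
        segments = [(start + s, start + e) for s, e in exons]
        features[spec.name] = [
            GeneFeature(spec.name, "protein_coding", segments, spec.strand)
        ]
        gene_positions.update(range(start, start + spec.length))
        cursor += spec.length
    cursor += model.spacer
    bay_b = (cursor, cursor + model.bay_length)
    cursor += model.bay_length
    bay_c = (cursor, cursor + model.insertion_bay)
    cursor += model.insertion_bay
    return _Layout(cursor, gene_start, features, bay_a, bay_b, bay_c, gene_positions)


def _genome_pos(model: CladeModel, layout: _Layout, snp: PlantedSnp) -> tuple[int, bool]:
    """(genome position, gene_is_minus) of a planted SNP."""
    spec = next(g for g in model.genes if g.name == snp.gene)
    if spec.trans_spliced:
        raise ValueError("cannot plant SNPs in trans-spliced genes")
    start = layout.gene_start[snp.gene]
    if spec.strand == "+":
        return start + snp.position, False
    return start + spec.length - 1 - snp.position, True


def _discriminating_placements(
    seq: Sequence[str],
    gp: int,
    target: str,
    alts: set[str],
    enzyme: RestrictionEnzyme,
) -> list[int]:
    """Starts of recognition windows overlapping gp that cut target-only."""
    L = enzyme.site_length
    rc = reverse_complement(enzyme.recognition)
    found = []
    for start in range(gp - L + 1, gp + 1):
        if start < 0 or start + L > len(seq):
            continue
        window = list(seq[start : start + L])
        off = gp - start
        window[off] = target
        w = "".join(window)
        if not (iupac_match(enzyme.recognition, w) or iupac_match(rc, w)):
            continue
        ok = True
        for alt in sorted(alts):
            window[off] = alt
            w_alt = "".join(window)
            if iupac_match(enzyme.recognition, w_alt) or iupac_match(rc, w_alt):
                ok = False
                break
        if ok:
            found.append(start)
    return found


def _matches_overlapping(
    seq: Sequence[str], start: int, end: int, enzyme: RestrictionEnzyme
) -> list[int]:
    """Starts of enzyme matches (either strand) within [start, end)."""
    L = enzyme.site_length
    rc = reverse_complement(enzyme.recognition)
    out = []
    for s in range(max(0, start), min(len(seq) - L, end) + 1):
        w = "".join(seq[s : s + L])
        if iupac_match(enzyme.recognition, w) or iupac_match(rc, w):
            out.append(s)
    return out


def _scrub_snp_neighbourhood(
    seq: list[str],
    rng: np.random.Generator,
    gp: int,
    target: str,
    alts: set[str],
    panel: Sequence[RestrictionEnzyme],
    allowed: tuple[RestrictionEnzyme, int] | None,
    radius: int,
) -> None:
    """Remove accidental enzyme sites around a planted SNP.

    After scrubbing, the only discriminating placement over the SNP (for any
    panel enzyme) is the planted one; the planted enzyme has no constitutive
    site within ``radius``; and no alternative allele creates a site.  Bases
    are mutated conservatively: never the SNP itself, and inside the planted
    site only at degenerate pattern positions, to a base the pattern allows.
    """
    planted_site: tuple[int, int] | None = None
    planted_pattern = ""
    if allowed is not None:
        enzyme, start = allowed
        planted_site = (start, start + enzyme.site_length)
        planted_pattern = enzyme.recognition

    def offenders() -> list[tuple[RestrictionEnzyme, int]]:
        out: list[tuple[RestrictionEnzyme, int]] = []
        for enz in panel:
            for s in _discriminating_placements(seq, gp, target, alts, enz):
                if allowed is None or (enz.name, s) != (allowed[0].name, allowed[1]):
                    out.append((enz, s))
        if allowed is not None:
            enz, planted_start = allowed
            # constitutive sites of the marker enzyme near the SNP (any site
            # not overlapping the SNP would cut every allele's amplicon)
            for s in _matches_overlapping(seq, gp - radius, gp + radius, enz):
                if not (s <= gp < s + enz.site_length):
                    out.append((enz, s))
            # placements where an alternative allele creates a site
            for alt in sorted(alts):
                saved = seq[gp]
                seq[gp] = alt
                for s in _matches_overlapping(
                    seq, gp - enz.site_length + 1, gp, enz
                ):
                    if s <= gp < s + enz.site_length:
                        out.append((enz, s))
                seq[gp] = saved
        return out

    for _ in range(300):
        bad = offenders()
        if not bad:
            return
        enz, s = bad[0]
        mutated = False
        for q in rng.permutation(np.arange(s, s + enz.site_length)):
            q = int(q)
            if q == gp or q < 0 or q >= len(seq):
                continue
            if planted_site and planted_site[0] <= q < planted_site[1]:
                letter = planted_pattern[q - planted_site[0]]
                options = [b for b in IUPAC[letter] if b != seq[q]]
            else:
                options = [b for b in _BASES if b != seq[q]]
            if not options:
                continue
            seq[q] = options[int(rng.integers(len(options)))]
            mutated = True
            break
        if not mutated:
            raise ValueError("planted features collide: cannot scrub enzyme site")
    raise ValueError("planted features collide: scrubbing did not converge")


def _mirror_design(
    p: int, cut: int, gene_len: int, constraints: DesignConstraints
) -> tuple[int, int, list[int]]:
    """Expected amplicon and fragments under the designer's deterministic rule.

    The marker designer picks the smallest amplicon (ties: leftmost forward
    window) whose fragments all reach ``min_fragment``; with a fully
    conserved, gap-free neighbourhood that choice depends only on the SNP
    position, the cut coordinate and the constraints, reproduced here from
    first principles for the manifest.
    """
    plen = constraints.primer_len_min
    mf = constraints.min_fragment
    for ell in range(2 * plen + 1, constraints.max_amplicon + 1):
        f_lo = max(0, p + 1 + plen - ell)
        f_hi = min(p - plen, gene_len - ell)
        for f in range(f_lo, f_hi + 1):
            r = f + ell
            left, right = cut - f, r - cut
            if left >= mf and right >= mf:
                return f, r, sorted([left, right], reverse=True)
    raise ValueError("no feasible amplicon for planted marker")


class _PositionPool:
    """Deterministic allocator of distinct substitution positions."""

    def __init__(self, rng: np.random.Generator, positions: list[int], genic: set[int]):
        self.queue = [int(q) for q in rng.permutation(positions)]
        self.genic = genic
        self.stash: list[int] = []

    def take(self, n: int, intergenic_only: bool) -> list[int]:
        out: list[int] = []
        if not intergenic_only:
            while self.stash and len(out) < n:
                out.append(self.stash.pop())
        while len(out) < n and self.queue:
            q = self.queue.pop()
            if intergenic_only and q in self.genic:
                self.stash.append(q)
                continue
            out.append(q)
        if len(out) < n:
            raise ValueError("not enough free positions for requested substitutions")
        return out


def simulate_clade_dataset(model: CladeModel) -> SimulatedDataset:
    """Generate the genomes and truth manifest for a clade model.

    Identical seeds give byte-identical output.  Raises on colliding planted
    features.
    """
    rng = np.random.default_rng(model.seed)
    layout = _build_layout(model)
    anc = _random_seq(rng, layout.total)
    plastid = _random_seq(rng, model.plastid_length)
    manifest: list[dict] = []

    # ---- repeats: source copies in bay A, second copies in bay B
    cursor_a, cursor_b = layout.bay_a[0] + 50, layout.bay_b[0] + 50
    for rep in model.planted_repeats:
        a0, a1 = cursor_a, cursor_a + rep.length
        b0, b1 = cursor_b, cursor_b + rep.length
        if a1 + 100 > layout.bay_a[1] or b1 + 100 > layout.bay_b[1]:
            raise ValueError("planted repeats do not fit in their bays")
        block = anc[a0:a1]
        copy = list(reverse_complement("".join(block))) if rep.orientation == "inverted" else list(block)
        anc[b0:b1] = copy
        # a run of mismatching flank bases longer than the extension x-drop
        # tolerates pins the recovered coordinates exactly, for any seed
        flank_pairs = []
        for k in range(_PIN):
            if rep.orientation == "direct":
                flank_pairs += [(b0 - 1 - k, anc[a0 - 1 - k]), (b1 + k, anc[a1 + k])]
            else:
                flank_pairs += [
                    (b0 - 1 - k, reverse_complement(anc[a1 + k])),
                    (b1 + k, reverse_complement(anc[a0 - 1 - k])),
                ]
        for q, forbidden in flank_pairs:
            if anc[q] == forbidden:
                anc[q] = [b for b in _BASES if b != forbidden][int(rng.integers(3))]
        manifest.append(
            {
                "type": "repeat",
                "orientation": rep.orientation,
                "length": rep.length,
                "identity": 100.0,
                "copy_a": [a0, a1],
                "copy_b": [b0, b1],
            }
        )
        cursor_a = a1 + 100
        cursor_b = b1 + 100

    # ---- plastid-like insertion into bay C
    cursor_c = layout.bay_c[0] + 50
    for ins in model.planted_insertions:
        src0 = model.plastid_length // 3
        src1 = src0 + ins.length
        if src1 > model.plastid_length or cursor_c + ins.length + 50 > layout.bay_c[1]:
            raise ValueError("planted insertion does not fit")
        fragment = list(plastid[src0:src1])
        if ins.n_substitutions:
            subs = rng.choice(
                np.arange(25, ins.length - 25), size=ins.n_substitutions, replace=False
            )
            for q in sorted(int(x) for x in subs):
                fragment[q] = [b for b in _BASES if b != fragment[q]][int(rng.integers(3))]
        m0 = cursor_c
        anc[m0 : m0 + ins.length] = fragment
        for k in range(_PIN):
            for q, forbidden in (
                (m0 - 1 - k, plastid[src0 - 1 - k]),
                (m0 + ins.length + k, plastid[src1 + k]),
            ):
                if anc[q] == forbidden:
                    anc[q] = [b for b in _BASES if b != forbidden][int(rng.integers(3))]
        identity = round((ins.length - ins.n_substitutions) / ins.length * 100, 1)
        manifest.append(
            {
                "type": "plastid_region",
                "mito_interval": [m0, m0 + ins.length],
                "plastid_interval": [src0, src1],
                "length": ins.length,
                "identity": identity,
            }
        )
        cursor_c = m0 + ins.length + 100

    # ---- planted SNPs and CAPS sites
    panel_by_name = {e.name: e for e in model.enzyme_panel}
    snp_truth: list[tuple[PlantedSnp, int, bool]] = []
    placements: dict[int, tuple[RestrictionEnzyme, int]] = {}
    for snp in model.planted_snps:
        gp, minus = _genome_pos(model, layout, snp)
        for other, other_gp, _ in snp_truth:
            if abs(gp - other_gp) < 2 * model.protect_radius + 60:
                raise ValueError(
                    f"planted features collide: SNPs at {gp} and {other_gp}"
                )
        snp_truth.append((snp, gp, minus))
        if isinstance(snp, PlantedCaps):
            if minus:
                raise ValueError("plant CAPS SNPs in plus-strand genes")
            enzyme = panel_by_name[snp.enzyme]
            site_start = gp - snp.site_offset
            pattern = enzyme.recognition
            if snp.target_allele not in IUPAC[pattern[snp.site_offset]]:
                raise ValueError(
                    f"{snp.gene}: target allele does not complete the {enzyme.name} site"
                )
            for alt in snp.alt_alleles:
                if alt in IUPAC[pattern[snp.site_offset]]:
                    raise ValueError(
                        f"{snp.gene}: alternative allele {alt} does not break the site"
                    )
            for off, letter in enumerate(pattern):
                q = site_start + off
                anc[q] = (
                    snp.target_allele
                    if off == snp.site_offset
                    else IUPAC[letter][int(rng.integers(len(IUPAC[letter])))]
                )
            placements[gp] = (enzyme, site_start)
        else:
            # sense-strand allele; minus-strand genes store the complement
            anc[gp] = (
                reverse_complement(snp.target_allele) if minus else snp.target_allele
            )

    for snp, gp, minus in snp_truth:
        target = reverse_complement(snp.target_allele) if minus else snp.target_allele
        alts = (
            {reverse_complement(a) for a in snp.alt_alleles} if minus else snp.alt_alleles
        )
        _scrub_snp_neighbourhood(
            anc,
            rng,
            gp,
            target,
            alts,
            model.enzyme_panel,
            placements.get(gp),
            model.protect_radius,
        )

    # manifest entries need the scrubbed ancestral sequence (primer sequences)
    for snp, gp, minus in snp_truth:
        spec = next(g for g in model.genes if g.name == snp.gene)
        gs = layout.gene_start[snp.gene]
        gene_seq = "".join(anc[gs : gs + spec.length])
        if minus:
            gene_seq = reverse_complement(gene_seq)
        assert gene_seq[snp.position] == snp.target_allele
        entry: dict = {
            "type": "caps_marker" if isinstance(snp, PlantedCaps) else "snp",
            "gene": snp.gene.lower(),
            "position": snp.position + 1,  # 1-based, reported convention
            "taxon": snp.taxon,
            "target_allele": snp.target_allele,
            "alt_alleles": sorted(snp.alt_alleles),
        }
        if isinstance(snp, PlantedCaps):
            enzyme, site_start = placements[gp]
            cut = (site_start - gs) + enzyme.cut_top  # plus-strand site
            f, r, fragments = _mirror_design(
                snp.position, cut, spec.length, model.constraints
            )
            entry.update(
                enzyme=enzyme.name,
                fragments_target=fragments,
                amplicon_length=r - f,
                fragments_alt={a: [r - f] for a in sorted(snp.alt_alleles)},
            )
            if snp.pcr_fragments is not None:
                up, down = snp.pcr_fragments
                a0, a1 = cut - up, cut + down
                if a0 < 0 or a1 > spec.length:
                    raise ValueError("planted PCR amplicon falls outside its gene")
                entry.update(
                    pcr_fwd=gene_seq[a0 : a0 + 20],
                    pcr_rev=reverse_complement(gene_seq[a1 - 20 : a1]),
                    pcr_product_length=up + down,
                    pcr_fragments=sorted([up, down], reverse=True),
                )
        manifest.append(entry)

    # ---- substitution plan
    protected: set[int] = set()
    for _, gp, _ in snp_truth:
        protected.update(range(gp - model.protect_radius, gp + model.protect_radius + 1))
    for rec in manifest:
        if rec["type"] == "repeat":
            protected.update(range(rec["copy_a"][0] - _PIN, rec["copy_a"][1] + _PIN))
            protected.update(range(rec["copy_b"][0] - _PIN, rec["copy_b"][1] + _PIN))
        elif rec["type"] == "plastid_region":
            protected.update(
                range(rec["mito_interval"][0] - _PIN, rec["mito_interval"][1] + _PIN)
            )
    free = [q for q in range(layout.total) if q not in protected]
    pool = _PositionPool(rng, free, layout.gene_positions)

    # sole members of queried taxa receive intergenic substitutions only:
    # any genic substitution private to such a leaf would itself be a
    # diagnostic SNP and break planted-truth exactness
    queried = {snp.taxon for snp in model.planted_snps}
    restricted_leaves: set[str] = set()
    for taxon in sorted(queried):
        members = [
            sp.id
            for sp in model.species
            if taxon in sp.lineage or taxon in sp.organism.split()
        ]
        if len(members) == 1:
            restricted_leaves.add(members[0])

    substitutions: dict[str, list[tuple[int, str]]] = {sp.id: [] for sp in model.species}
    if model.clade_substitutions:
        branches: list[tuple[str, list[str]]] = []
        for rank in range(3):
            for taxon in sorted({sp.lineage[rank] for sp in model.species}):
                members = [sp.id for sp in model.species if sp.lineage[rank] == taxon]
                branches.append((taxon, members))
        for taxon, members in branches:
            for q in pool.take(model.clade_substitutions, intergenic_only=True):
                base = [b for b in _BASES if b != anc[q]][int(rng.integers(3))]
                for sid in members:
                    substitutions[sid].append((q, base))
    if model.leaf_substitutions:
        for sp in model.species:
            intergenic_only = sp.id in restricted_leaves
            for q in pool.take(model.leaf_substitutions, intergenic_only):
                base = [b for b in _BASES if b != anc[q]][int(rng.integers(3))]
                substitutions[sp.id].append((q, base))

    # ---- per-species genomes
    genomes: list[AnnotatedGenome] = []
    features = [f for specs in layout.features.values() for f in specs]
    features.sort(key=lambda f: f.span[0])
    for sp in model.species:
        seq = list(anc)
        for snp, gp, minus in snp_truth:
            member = snp.taxon in sp.lineage or snp.taxon in sp.organism.split()
            allele = snp.target_allele if member else snp.alt_for(sp)
            seq[gp] = reverse_complement(allele) if minus else allele
        for q, base in substitutions[sp.id]:
            seq[q] = base
        genomes.append(
            AnnotatedGenome(
                id=sp.id,
                organism=sp.organism,
                lineage=list(sp.lineage),
                sequence="".join(seq),
                features=[
                    GeneFeature(f.gene_name, f.kind, list(f.segments), f.strand, f.trans_spliced)
                    for f in features
                ],
            )
        )
    return SimulatedDataset(genomes, "".join(plastid), manifest, model)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write GenBank files, the plastid FASTA, and the JSON-lines manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for genome in dataset.genomes:
        write_genbank(genome, out_dir / f"{genome.id}.gb")
    with open(out_dir / "plastid.fasta", "w") as handle:
        handle.write(">plastid synthetic chloroplast genome\n")
        for i in range(0, len(dataset.plastid), 70):
            handle.write(dataset.plastid[i : i + 70] + "\n")
    with open(out_dir / "manifest.jsonl", "w") as handle:
        for record in dataset.manifest:
            handle.write(json.dumps(record) + "\n")
    return out_dir
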