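"""Reading, writing and interrogating annotated organelle genomes.

GenBank flat files are the interchange format; internally every interval is
0-based half-open and minus-strand features keep their segments in plus-strand
coordinates (annotation order preserved).  Conversion to and from GenBank's
1-based inclusive ``join()``/``complement()`` locations happens only at the
I/O boundary, through Biopython.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FeatureKind = Literal["protein_coding", "tRNA", "rRNA", "ORF", "pseudogene"]

_KIND_TO_GB = {
    "protein_coding": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ORF": "CDS",
    "pseudogene": "gene",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: Known spelling variants of organelle gene names, all mapped to a canonical
#: lower-case key.  User code can extend this mapping via ``normalize_gene_name``.
GENE_ALIASES: dict[str, str] = {
    "ccmfc": "ccmfc",
    "ccmf-c": "ccmfc",
    "ccmfn": "ccmfn",
    "ccmf-n": "ccmfn",
    "cob": "cob",
    "cytb": "cob",
    "matr": "matr",
    "mttb": "mttb",
    "tatc": "mttb",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Case-insensitive canonical form of a gene name.

    Organelle annotations disagree on capitalisation (``ccmFC`` vs ``ccmFc``)
    and occasionally on spelling; unreconciled synonyms silently shrink
    shared-gene sets, so normalization is explicit and extensible.
    """
    key = name.strip().lower()
    table = dict(GENE_ALIASES)
    if aliases:
        table.update({k.lower(): v.lower() for k, v in aliases.items()})
    return table.get(key, key)


@dataclass
class GeneFeature:
    """One annotated gene: ordered exon segments on one strand."""

    gene_name: str
    kind: FeatureKind
    segments: list[tuple[int, int]]
    strand: Literal["+", "-"]
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.gene_name}: feature needs at least one segment")
        for start, end in self.segments:
            if start < 0 or end <= start:
                raise ValueError(f"{self.gene_name}: bad segment [{start}, {end})")

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.segments), max(e for _, e in self.segments)


@dataclass
class OrfCall:
    """An open reading frame: ATG through stop codon (stop included)."""

    start: int
    end: int
    strand: Literal["+", "-"]
    length_codons: int


@dataclass
class AnnotatedGenome:
    """Sequence + features + taxonomy of one GenBank record."""

    id: str
    organism: str
    lineage: list[str]
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN characters in sequence: {sorted(bad)}")
        for feat in self.features:
            if feat.span[1] > len(self.sequence):
                raise ValueError(
                    f"{self.id}: feature {feat.gene_name} extends past genome end"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_names(self, kind: FeatureKind | None = None) -> set[str]:
        return {
            normalize_gene_name(f.gene_name)
            for f in self.features
            if kind is None or f.kind == kind
        }


def _feature_kind(gb_feature: SeqFeature) -> FeatureKind | None:
    if "pseudo" in gb_feature.qualifiers or "pseudogene" in gb_feature.qualifiers:
        return "pseudogene"
    if gb_feature.type == "CDS":
        name = _feature_name(gb_feature) or ""
        return "ORF" if re.fullmatch(r"orf\w*", name, re.IGNORECASE) else "protein_coding"
    if gb_feature.type in ("tRNA", "rRNA"):
        return gb_feature.type  # type: ignore[return-value]
    return None


def _feature_name(gb_feature: SeqFeature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in gb_feature.qualifiers:
            return str(gb_feature.qualifiers[key][0])
    return None


def read_genbank(path: str | Path) -> list[AnnotatedGenome]:
    """Parse a GenBank flat file into one :class:`AnnotatedGenome` per record.

    Coordinates are converted from GenBank's 1-based inclusive convention to
    the internal 0-based half-open one; ``join()``/``complement()`` locations
    become segment lists plus a strand.  A gene is flagged trans-spliced when
    it carries a ``trans_splicing`` qualifier or when the same gene name
    occurs in more than one disjoint feature of the same kind.
    """
    path = Path(path)
    genomes: list[AnnotatedGenome] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    for record in records:
        sequence = str(record.seq).upper()
        features: list[GeneFeature] = []
        explicit_trans: set[str] = set()
        for gbf in record.features:
            kind = _feature_kind(gbf)
            if kind is None:
                continue
            name = _feature_name(gbf)
            if name is None:
                continue
            segments = [(int(part.start), int(part.end)) for part in gbf.location.parts]
            strand = "-" if gbf.location.strand == -1 else "+"
            if strand == "-":
                # Biopython reports complement(join(...)) parts in plus-strand
                # order already; keep plus-strand sorted segments internally.
                segments = sorted(segments)
            for start, end in segments:
                if start < 0 or end > len(sequence):
                    raise ValueError(
                        f"{record.id}: feature {name} coordinates out of range"
                    )
            trans = "trans_splicing" in gbf.qualifiers
            if trans:
                explicit_trans.add(normalize_gene_name(name))
            features.append(GeneFeature(name, kind, segments, strand, trans))
        # Same gene name in >1 disjoint feature of one kind => trans-spliced.
        by_name: dict[tuple[str, str], int] = {}
        for feat in features:
            key = (normalize_gene_name(feat.gene_name), feat.kind)
            by_name[key] = by_name.get(key, 0) + 1
        for feat in features:
            key = (normalize_gene_name(feat.gene_name), feat.kind)
            if by_name[key] > 1 or normalize_gene_name(feat.gene_name) in explicit_trans:
                feat.trans_spliced = True
        lineage = [t for t in record.annotations.get("taxonomy", [])]
        organism = record.annotations.get("organism", record.description or record.id)
        genomes.append(
            AnnotatedGenome(
                id=record.id or record.name,
                organism=organism,
                lineage=lineage,
                sequence=sequence,
                features=features,
            )
        )
    return genomes


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> Path:
    """Serialize a genome as a GenBank flat file.

    Multi-exon minus-strand genes come out as ``complement(join(...))`` with
    1-based inclusive coordinates.  Refuses to write features that fall
    outside the sequence.
    """
    for feat in genome.features:
        if feat.span[1] > genome.length:
            raise ValueError(f"feature {feat.gene_name} outside sequence; refusing to write")
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16],
        description=f"{genome.organism} mitochondrion",
        annotations={
            "molecule_type": "DNA",
            "organism": genome.organism,
            "source": genome.organism,
            "taxonomy": list(genome.lineage),
        },
    )
    for feat in genome.features:
        strand = -1 if feat.strand == "-" else 1
        segments = feat.segments if strand == 1 else list(reversed(feat.segments))
        # minus-strand compound parts go in biological order; Biopython then
        # renders the conventional ascending complement(join(...)) text
        parts = [SimpleLocation(s, e, strand=strand) for s, e in segments]
        location = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        qualifiers: dict[str, list[str]] = {"gene": [feat.gene_name]}
        if feat.trans_spliced:
            qualifiers["trans_splicing"] = [""]
        if feat.kind == "pseudogene":
            qualifiers["pseudo"] = [""]
        record.features.append(
            SeqFeature(location, type=_KIND_TO_GB[feat.kind], qualifiers=qualifiers)
        )
    path = Path(path)
    with open(path, "w") as handle:
        SeqIO.write([record], handle, "genbank")
    return path


def extract_gene_sequences(
    genome: AnnotatedGenome,
    exclude_trans_spliced: bool = True,
    mode: Literal["span", "exons"] = "span",
    kinds: tuple[FeatureKind, ...] = ("protein_coding",),
) -> dict[str, str]:
    """Extract per-gene DNA sequences from one genome.

    ``mode="span"`` (default) returns the genomic span including introns —
    intronic diagnostic sites are real marker targets, so introns are kept;
    ``mode="exons"`` concatenates exon segments in annotation order.  Either
    way the result is reverse-complemented for minus-strand genes.
    Trans-spliced genes have no single contiguous genomic sequence and are
    omitted when ``exclude_trans_spliced`` is on.
    """
    out: dict[str, str] = {}
    for feat in genome.features:
        if feat.kind not in kinds:
            continue
        if exclude_trans_spliced and feat.trans_spliced:
            continue
        if mode == "span":
            start, end = feat.span
            seq = genome.sequence[start:end]
        else:
            seq = "".join(genome.sequence[s:e] for s, e in feat.segments)
        if feat.strand == "-":
            seq = reverse_complement(seq)
        out[normalize_gene_name(feat.gene_name)] = seq
    return out


def shared_genes(
    genomes: Iterable[AnnotatedGenome], kind: FeatureKind = "protein_coding"
) -> set[str]:
    """Gene names of the given kind annotated in every genome (normalized)."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("shared_genes needs at least one genome")
    shared = genomes[0].gene_names(kind)
    for genome in genomes[1:]:
        shared &= genome.gene_names(kind)
    return shared


def export_gene_fastas(
    genomes: Iterable[AnnotatedGenome],
    out_dir: str | Path,
    genes: Iterable[str] | None = None,
    exclude_trans_spliced: bool = True,
    mode: Literal["span", "exons"] = "span",
) -> dict[str, Path]:
    """Write one FASTA per gene with records named ``accession|organism``.

    Gene sequences containing N are excluded from the export (they cannot
    enter alignments) and noted in the returned report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes = list(genomes)
    wanted = {normalize_gene_name(g) for g in genes} if genes is not None else None
    per_gene: dict[str, list[tuple[str, str, str]]] = {}
    for genome in genomes:
        seqs = extract_gene_sequences(genome, exclude_trans_spliced, mode)
        for name, seq in seqs.items():
            if wanted is not None and name not in wanted:
                continue
            if "N" in seq:
                continue
            per_gene.setdefault(name, []).append((genome.id, genome.organism, seq))
    written: dict[str, Path] = {}
    for name, records in sorted(per_gene.items()):
        fasta = out_dir / f"{name}.fasta"
        with open(fasta, "w") as handle:
            for acc, organism, seq in records:
                handle.write(f">{acc}|{organism}\n{seq}\n")
        written[name] = fasta
    return written


_STOPS = {"TAA", "TAG", "TGA"}


def orf_scan(
    sequence: str,
    min_codons: int = 100,
    both_strands: bool = True,
    exclude_nested: bool = True,
) -> list[OrfCall]:
    """Find ATG-initiated open reading frames of at least ``min_codons`` codons.

    Codon count and the reported interval both include the stop codon, the
    standard genetic code is used, and fully nested calls on the same strand
    are removed on request.  Within one reading frame only the longest ORF
    per stop (first ATG after the previous stop) is reported.  Results are
    sorted by start coordinate.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    sequence = sequence.upper()
    length = len(sequence)
    calls: list[OrfCall] = []

    def scan_strand(seq: str, strand: str) -> None:
        for frame in range(3):
            prev_stop_end = frame
            pos = frame
            while pos + 3 <= len(seq):
                codon = seq[pos : pos + 3]
                if codon in _STOPS:
                    # first ATG in-frame since the previous stop
                    atg = prev_stop_end
                    while atg < pos and seq[atg : atg + 3] != "ATG":
                        atg += 3
                    if atg < pos:
                        n_codons = (pos + 3 - atg) // 3
                        if n_codons >= min_codons:
                            if strand == "+":
                                calls.append(OrfCall(atg, pos + 3, "+", n_codons))
                            else:
                                calls.append(
                                    OrfCall(length - (pos + 3), length - atg, "-", n_codons)
                                )
                    prev_stop_end = pos + 3
                pos += 3

    scan_strand(sequence, "+")
    if both_strands:
        scan_strand(reverse_complement(sequence), "-")

    if exclude_nested:
        kept: list[OrfCall] = []
        for orf in calls:
            nested = any(
                other is not orf
                and other.strand == orf.strand
                and other.start <= orf.start
                and orf.end <= other.end
                and (other.start, other.end) != (orf.start, orf.end)
                for other in calls
            )
            if not nested:
                kept.append(orf)
        calls = kept
    return sorted(calls, key=lambda o: (o.start, o.end, o.strand))
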