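"""Interspersed (nontandem) repeat detection by genome self-comparison.

Plant mitochondrial genomes carry pairs of direct and inverted repeats that
drive isomerization by recombination.  The finder seeds on exact shared
k-mers between the genome and itself (and its reverse complement), extends
each seed run ungapped along its diagonal, and reports maximal copy pairs
above length and identity thresholds, longest-first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .alignment import local_align
from .genbank_io import reverse_complement


@dataclass(frozen=True)
class RepeatPair:
    """Two similar copies at separated loci, direct or inverted."""

    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    orientation: str  # "direct" | "inverted"
    length: int
    identity: float


def find_interspersed_repeats(
    sequence: str, min_len: int = 50, min_identity: float = 99.0
) -> list[RepeatPair]:
    """Self-comparison repeat scan.

    Direct repeats come from aligning the sequence against itself (the trivial
    self-diagonal discarded); inverted repeats from aligning it against its
    reverse complement.  Seeds are exact matches of length ``min_len`` so a
    copy pair is only found if it contains one exact ``min_len``-mer — at 99%
    identity every repeat of a few hundred bases does.  Contained/duplicate
    pairs are collapsed; a repeat present more than twice yields one entry per
    unordered copy pair.
    """
    if min_len < 20:
        raise ValueError("min_len < 20: exact seeding becomes unreliable")
    if len(sequence) < 2 * min_len:
        raise ValueError("sequence shorter than twice min_len")
    sequence = sequence.upper()
    L = len(sequence)
    pairs: dict[tuple[tuple[int, int], tuple[int, int], str], float] = {}

    # direct: self vs self, keep hits off the identity diagonal
    for (a0, a1), (b0, b1), ident in local_align(
        sequence, sequence, min_identity, min_len, seed_k=min_len
    ):
        if a0 == b0:
            continue
        if a0 > b0:
            (a0, a1), (b0, b1) = (b0, b1), (a0, a1)
        pairs.setdefault(((a0, a1), (b0, b1), "direct"), ident)

    # inverted: self vs reverse complement; a hit at rc positions [p, q)
    # corresponds to genome interval [L-q, L-p)
    for (a0, a1), (p0, p1), ident in local_align(
        sequence, reverse_complement(sequence), min_identity, min_len, seed_k=min_len
    ):
        b0, b1 = L - p1, L - p0
        if (a0, a1) == (b0, b1):
            continue  # perfect palindrome maps onto itself
        if a0 > b0:
            (a0, a1), (b0, b1) = (b0, b1), (a0, a1)
        pairs.setdefault(((a0, a1), (b0, b1), "inverted"), ident)

    # collapse pairs contained in a longer pair of the same orientation
    items = [
        RepeatPair(a, b, orient, a[1] - a[0], ident)
        for (a, b, orient), ident in pairs.items()
    ]

    def contains(outer: RepeatPair, inner: RepeatPair) -> bool:
        return (
            outer.orientation == inner.orientation
            and outer is not inner
            and outer.copy_a[0] <= inner.copy_a[0]
            and inner.copy_a[1] <= outer.copy_a[1]
            and outer.copy_b[0] <= inner.copy_b[0]
            and inner.copy_b[1] <= outer.copy_b[1]
        )

    kept = [r for r in items if not any(contains(o, r) for o in items)]
    return sorted(kept, key=lambda r: (-r.length, r.copy_a, r.copy_b))


def repeat_sequence(genome: str, repeat: RepeatPair, copy: str = "a") -> str:
    start, end = repeat.copy_a if copy == "a" else repeat.copy_b
    seq = genome[start:end]
    if copy == "b" and repeat.orientation == "inverted":
        seq = reverse_complement(seq)
    return seq


def compare_repeat_sets(
    repeats_a: Iterable[RepeatPair],
    genome_a: str,
    repeats_b: Iterable[RepeatPair],
    genome_b: str,
    min_identity: float = 90.0,
    min_len: int = 30,
) -> list[dict]:
    """Cross-genome repeat comparison via local alignment of repeat copies.

    Every repeat sequence from genome A is aligned against every repeat
    sequence from B (both orientations); hits at or above ``min_identity``
    are reported with identity and coverage of the shorter repeat.
    """
    results = []
    for i, ra in enumerate(repeats_a):
        seq_a = repeat_sequence(genome_a, ra)
        for j, rb in enumerate(repeats_b):
            seq_b = repeat_sequence(genome_b, rb)
            best = None
            for query in (seq_b, reverse_complement(seq_b)):
                k = min(min_len, len(seq_a), len(seq_b))
                if k < 8:
                    continue
                for (a0, a1), _, ident in local_align(
                    seq_a, query, min_identity, min(min_len, k), seed_k=k
                ):
                    coverage = round((a1 - a0) / min(len(seq_a), len(seq_b)) * 100, 1)
                    if best is None or (a1 - a0, ident) > (best["aligned_length"], best["identity"]):
                        best = {
                            "repeat_a": i,
                            "repeat_b": j,
                            "aligned_length": a1 - a0,
                            "identity": ident,
                            "coverage": coverage,
                        }
            if best is not None:
                results.append(best)
    return results


def write_repeat_report(
    repeats: Iterable[RepeatPair], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("copy_a_start\tcopy_a_end\tcopy_b_start\tcopy_b_end\torientation\tlength\tidentity\n")
        for r in repeats:
            handle.write(
                f"{r.copy_a[0]}\t{r.copy_a[1]}\t{r.copy_b[0]}\t{r.copy_b[1]}\t"
                f"{r.orientation}\t{r.length}\t{r.identity}\n"
            )
    return path


def write_repeat_bed(repeats: Iterable[RepeatPair], path: str | Path, chrom: str) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for i, r in enumerate(repeats):
            for copy, (start, end) in (("a", r.copy_a), ("b", r.copy_b)):
                strand = "+" if copy == "a" or r.orientation == "direct" else "-"
                handle.write(f"{chrom}\t{start}\t{end}\trepeat_{i}_{copy}\t0\t{strand}\n")
    return path
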