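"""Per-gene multiple alignments and alignment-coordinate bookkeeping.

The built-in aligner is a deterministic progressive profile aligner:
pairwise k-mer distances feed a UPGMA guide tree (scipy), and profiles are
merged by affine-gap Needleman-Wunsch on expected column scores.  External
aligner output can be imported from aligned FASTA instead.

``local_align`` is the shared ungapped seed-and-extend engine used for
repeat comparison and plastid-insertion detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

GAP = "-"
_ALPHABET = "ACGTN-"
_IDX = {c: i for i, c in enumerate(_ALPHABET)}

# Built-in aligner defaults: chosen for offline determinism, documented here
# rather than inherited from any external tool.
MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -6.0
GAP_EXTEND = -1.0
KMER = 6

# Substitution matrix over A,C,G,T,N,-: N scores 0 against everything, and a
# gap column in a profile contributes the extension penalty.
_SUBST = np.full((6, 6), MISMATCH)
np.fill_diagonal(_SUBST, MATCH)
_SUBST[4, :] = _SUBST[:, 4] = 0.0
_SUBST[5, :] = _SUBST[:, 5] = GAP_EXTEND
_SUBST[5, 5] = 0.0


@dataclass
class GeneAlignment:
    """A gapped multiple alignment of one gene across genomes."""

    gene_name: str
    rows: dict[str, str]
    lineages: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_name}: rows have unequal lengths {lengths}")
        for rid in self.rows:
            if self.lineages and rid not in self.lineages:
                raise ValueError(f"{self.gene_name}: row {rid} has no lineage")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, col: int) -> dict[str, str]:
        if not 0 <= col < self.n_columns:
            raise IndexError(f"column {col} out of range")
        return {rid: seq[col] for rid, seq in self.rows.items()}

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as handle:
            for rid, seq in self.rows.items():
                handle.write(f">{rid}\n{seq}\n")
        return path


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column frequency matrix (n_columns x 6)."""
    arr = np.array([[_IDX.get(c, 4) for c in row] for row in rows])
    prof = np.zeros((arr.shape[1], 6))
    for a in range(6):
        prof[:, a] = (arr == a).mean(axis=0)
    return prof


def _align_profiles(
    rows_a: list[str], rows_b: list[str]
) -> tuple[list[str], list[str]]:
    """Affine-gap Needleman-Wunsch between two profiles; returns gapped rows."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    n, m = pa.shape[0], pb.shape[0]
    score = pa @ _SUBST @ pb.T

    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), neg)  # gap in A (consume B)
    M[0, 0] = 0.0
    X[1:, 0] = GAP_OPEN + GAP_EXTEND * np.arange(n)
    Y[0, 1:] = GAP_OPEN + GAP_EXTEND * np.arange(m)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + score[i - 1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] + GAP_OPEN, X[i - 1, 1:] + GAP_EXTEND)
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        # Y[i, j] = max(M[i, j-1] + open, Y[i, j-1] + ext).  Unrolled this is a
        # running maximum over M[i, k] + open + ext*(j-1-k) (and the boundary
        # Y[i, 0]), so one prefix-max pass replaces the sequential scan.
        base = M[i] + GAP_OPEN - GAP_EXTEND  # M[i, 0] is -inf, as is Y[i, 0]
        cand = np.maximum.accumulate(base - GAP_EXTEND * np.arange(m + 1))
        Y[i, 1:] = cand[:-1] + GAP_EXTEND * np.arange(1, m + 1)

    # traceback
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    eps = 1e-9
    path: list[tuple[int, int]] = []  # (consume_a, consume_b)
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0 or j == 0:
                state = 1 if j == 0 else 2
                continue
            path.append((1, 1))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - score[i - 1, j - 1]
            state = int(np.argmax(np.abs(np.array(prev) - target) < eps))
            if abs(prev[state] - target) > eps:
                state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # X: gap in B
            path.append((1, 0))
            if i > 1 and abs(X[i, j] - (X[i - 1, j] + GAP_EXTEND)) < eps:
                state = 1
            else:
                state = 0
            i -= 1
        else:  # Y: gap in A
            path.append((0, 1))
            if j > 1 and abs(Y[i, j] - (Y[i, j - 1] + GAP_EXTEND)) < eps:
                state = 2
            else:
                state = 0
            j -= 1
    path.reverse()

    res_a = ["" for _ in rows_a]
    res_b = ["" for _ in rows_b]
    ia = ib = 0
    for ca, cb in path:
        for r, row in enumerate(rows_a):
            res_a[r] += row[ia] if ca else GAP
        for r, row in enumerate(rows_b):
            res_b[r] += row[ib] if cb else GAP
        ia += ca
        ib += cb
    return res_a, res_b


def build_msa(
    sequences: Mapping[str, str],
    gene_name: str = "",
    lineages: Mapping[str, Sequence[str]] | None = None,
) -> GeneAlignment:
    """Progressive multiple alignment of gene sequences.

    Pairwise distances are 1 minus the shared-k-mer fraction (k=6); a UPGMA
    guide tree orders profile-profile merges.  Ties are broken by
    lexicographic id, so the result is deterministic for given inputs.
    """
    if len(sequences) < 2:
        raise ValueError("build_msa needs at least 2 sequences")
    if any(not s for s in sequences.values()):
        raise ValueError("empty sequence passed to build_msa")
    ids = sorted(sequences)
    seqs = [sequences[i].upper() for i in ids]
    n = len(ids)

    kmers = [_kmer_set(s, KMER) for s in seqs]
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            denom = min(len(kmers[a]), len(kmers[b])) or 1
            shared = len(kmers[a] & kmers[b])
            dist[a, b] = dist[b, a] = 1.0 - shared / denom
    if n == 2:
        merges: list[tuple[int, int]] = [(0, 1)]
        tree = None
    else:
        tree = linkage(squareform(dist, checks=False), method="average")

    # clusters[idx] -> (row ids, gapped rows)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(n)
    }
    if n == 2:
        steps = [(0, 1, n)]
    else:
        steps = [(int(a), int(b), n + k) for k, (a, b, *_rest) in enumerate(tree)]
    for a, b, new in steps:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        aligned_a, aligned_b = _align_profiles(rows_a, rows_b)
        clusters[new] = (ids_a + ids_b, aligned_a + aligned_b)

    (final_ids, final_rows), = clusters.values()
    rows = {rid: row for rid, row in sorted(zip(final_ids, final_rows))}
    lin = {rid: list(lineages[rid]) for rid in rows} if lineages else {}
    aln = GeneAlignment(gene_name, rows, lin)
    for rid in rows:
        if aln.ungapped(rid) != sequences[rid].upper():
            raise AssertionError(f"aligner corrupted row {rid}")
    return aln


def import_alignment(
    path: str | Path,
    lineages: Mapping[str, Sequence[str]],
    gene_name: str = "",
) -> GeneAlignment:
    """Load an aligned FASTA (e.g. from an external aligner) as a GeneAlignment."""
    rows: dict[str, str] = {}
    rid = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip()
            if line.startswith(">"):
                if rid is not None:
                    rows[rid] = "".join(chunks).upper()
                rid = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if rid is not None:
        rows[rid] = "".join(chunks).upper()
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: aligned FASTA records have unequal lengths {lengths}")
    missing = [r for r in rows if r not in lineages]
    if missing:
        raise ValueError(f"no lineage for record(s): {missing}")
    return GeneAlignment(gene_name, rows, {r: list(lineages[r]) for r in rows})


def map_position(
    aln: GeneAlignment, rid: str, index: int, direction: str = "col2pos"
) -> int | str:
    """Map between alignment columns (0-based) and ungapped positions (1-based).

    ``col2pos`` returns the 1-based ungapped position of row ``rid`` at the
    column, or ``"gap"``; ``pos2col`` returns the unique column holding that
    position.  The two directions are mutually inverse away from gaps.
    """
    row = aln.rows[rid]
    if direction == "col2pos":
        if not 0 <= index < len(row):
            raise IndexError(f"column {index} out of range")
        if row[index] == GAP:
            return "gap"
        return len(row[: index + 1].replace(GAP, ""))
    if direction == "pos2col":
        if index < 1:
            raise IndexError("positions are 1-based")
        count = 0
        for col, char in enumerate(row):
            if char != GAP:
                count += 1
                if count == index:
                    return col
        raise IndexError(f"position {index} beyond end of {rid}")
    raise ValueError(f"unknown direction {direction!r}")


def local_align(
    a: str,
    b: str,
    min_identity: float = 90.0,
    min_length: int = 100,
    seed_k: int | None = None,
) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Ungapped local alignments between two sequences.

    Exact shared k-mers seed extensions along their diagonal; extension uses
    an x-drop score (match +1, mismatch -3) and the hit is trimmed to its
    best-scoring span.  Hits shorter than ``min_length`` or below
    ``min_identity`` percent (matches / alignment columns, reported to 0.1%)
    are dropped; overlapping hits on one diagonal are merged.
    """
    if not a or not b:
        raise ValueError("local_align needs non-empty sequences")
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    k = seed_k or max(12, min(20, min_length))
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)

    # seed positions grouped by diagonal d = i - j
    diagonals: dict[int, list[int]] = {}
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            diagonals.setdefault(i - j, []).append(i)

    hits: list[tuple[int, int, int]] = []  # (a_start, b_start, length)
    xdrop = 20.0
    for d, starts in diagonals.items():
        starts.sort()
        merged: list[tuple[int, int]] = []  # runs of seed coverage [i_start, i_end)
        for i in starts:
            if merged and i <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], i + k))
            else:
                merged.append((i, i + k))
        for run_start, run_end in merged:
            lo, hi = run_start, run_end
            # extend right
            score = best = 0.0
            best_hi = hi
            i = hi
            while i < len(a) and i - d < len(b):
                score += 1.0 if a[i] == b[i - d] else -3.0
                if score > best:
                    best, best_hi = score, i + 1
                if best - score > xdrop:
                    break
                i += 1
            hi = best_hi
            # extend left
            score = best = 0.0
            best_lo = lo
            i = lo - 1
            while i >= 0 and i - d >= 0:
                score += 1.0 if a[i] == b[i - d] else -3.0
                if score > best:
                    best, best_lo = score, i
                if best - score > xdrop:
                    break
                i -= 1
            lo = best_lo
            hits.append((lo, lo - d, hi - lo))

    # merge overlapping hits on the same diagonal, dedup
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for a0, b0, ln in hits:
        by_diag.setdefault(a0 - b0, []).append((a0, a0 + ln))
    results = []
    for d, spans in by_diag.items():
        spans.sort()
        merged = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            length = e - s
            if length < min_length:
                continue
            matches = sum(1 for i in range(s, e) if a[i] == b[i - d])
            identity = round(matches / length * 100, 1)
            if identity >= min_identity:
                results.append(((s, e), (s - d, e - d), identity))
    results.sort(key=lambda h: (h[0], h[1]))
    return results
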