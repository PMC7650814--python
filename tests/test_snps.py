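"""Taxon-diagnostic SNP calling and the conserved-flank filter."""

import random
import warnings

import pytest

from mitomarkers.alignment import GeneAlignment
from mitomarkers.snps import (
    CandidateSNP,
    ConservationFilter,
    TaxonQuery,
    conserved_flank_filter,
    find_taxon_specific_snps,
    summarize_snps,
)

BASES = "ACGT"


def _aln(rows, gene="g", lineages=None):
    return GeneAlignment(gene, rows, lineages or {})


def _query(members, non_members):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TaxonQuery("T", set(members), set(non_members))


def _snp_oracle(aln, query, flank_width=20, min_monomorphic=90.0):
    """Independent per-column scan with its own flank check."""
    rows = aln.rows
    members = sorted(query.members & set(rows))
    non_members = sorted(query.non_members & set(rows))
    out = []
    for col in range(aln.n_columns):
        chars = [rows[r][col] for r in rows]
        if any(c not in BASES for c in chars):
            continue
        member_alleles = {rows[r][col] for r in members}
        if len(member_alleles) != 1:
            continue
        target = member_alleles.pop()
        alts = {rows[r][col] for r in non_members}
        if target in alts:
            continue
        conserved = True
        for flank in (
            range(col - flank_width, col),
            range(col + 1, col + 1 + flank_width),
        ):
            cols = list(flank)
            if cols[0] < 0 or cols[-1] >= aln.n_columns:
                conserved = False
                break
            mono = 0
            for c in cols:
                vals = {rows[r][c] for r in rows}
                if "-" in vals:
                    conserved = False
                    break
                if len(vals) == 1 and vals <= set(BASES):
                    mono += 1
            if not conserved or mono * 100 < min_monomorphic * len(cols):
                conserved = False
                break
        out.append((col, target, frozenset(alts), conserved))
    return out


class TestConservedFlankFilter:
    def _monomorphic(self, n_cols, rows=4):
        return _aln({f"r{i}": "A" * n_cols for i in range(rows)})

    def test_fully_monomorphic_flanks_pass(self):
        aln = self._monomorphic(41)
        assert conserved_flank_filter(aln, 20, flank_width=20) is True

    def test_truncated_flank_fails(self):
        aln = self._monomorphic(41)
        assert conserved_flank_filter(aln, 5, flank_width=20) is False
        assert conserved_flank_filter(aln, 40, flank_width=20) is False

    def test_gap_in_flank_fails(self):
        rows = {"r0": "A" * 41, "r1": "A" * 10 + "-" + "A" * 30}
        assert conserved_flank_filter(_aln(rows), 20, flank_width=20) is False

    def test_monomorphic_percentage_threshold(self):
        # 3 polymorphic columns in the left flank: 17/20 = 85% < 90% fails
        row_a = "A" * 41
        row_b = list(row_a)
        for c in (2, 7, 12):
            row_b[c] = "C"
        aln = _aln({"r0": row_a, "r1": "".join(row_b)})
        assert conserved_flank_filter(aln, 20, 20, 90.0) is False
        # 2 polymorphic columns: 18/20 = 90% passes
        row_c = list(row_a)
        for c in (2, 7):
            row_c[c] = "C"
        aln = _aln({"r0": row_a, "r1": "".join(row_c)})
        assert conserved_flank_filter(aln, 20, 20, 90.0) is True

    def test_flank_width_validation(self):
        with pytest.raises(ValueError):
            conserved_flank_filter(self._monomorphic(41), 20, flank_width=0)


class TestTaxonQuery:
    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            TaxonQuery("T", set(), {"a"})
        with pytest.raises(ValueError):
            TaxonQuery("T", {"a"}, set())

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            TaxonQuery("T", {"a", "b"}, {"b", "c"})

    def test_single_member_warns(self):
        with pytest.warns(UserWarning, match="single member"):
            TaxonQuery("T", {"a"}, {"b", "c"})

    def test_membership_from_lineage_ranks_and_binomial(self):
        lineages = {
            "A": ["Fagales", "Fagaceae", "Fagus", "Fagus sylvatica"],
            "B": ["Fagales", "Fagaceae", "Quercus", "Quercus robur"],
            "C": ["Pinales", "Pinaceae", "Pinus", "Pinus taeda"],
        }
        assert TaxonQuery.from_lineages("Fagaceae", lineages).members == {"A", "B"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert TaxonQuery.from_lineages("Fagus", lineages).members == {"A"}
            assert TaxonQuery.from_lineages("Pinus taeda", lineages).members == {"C"}


class TestFindTaxonSpecificSnps:
    def test_all_identical_alignment_yields_nothing(self):
        aln = _aln({f"r{i}": "ACGT" * 20 for i in range(6)})
        query = _query({"r0", "r1"}, {f"r{i}" for i in range(2, 6)})
        assert find_taxon_specific_snps([aln], query) == []

    def test_single_diagnostic_column(self):
        base = "A" * 101
        rows = {}
        for i in range(6):
            row = list(base)
            row[50] = "T" if i < 2 else "C"
            rows[f"r{i}"] = "".join(row)
        aln = _aln(rows)
        query = _query({"r0", "r1"}, {f"r{i}" for i in range(2, 6)})
        snps = find_taxon_specific_snps([aln], query)
        assert len(snps) == 1
        snp = snps[0]
        assert (snp.column, snp.target_allele, snp.alt_alleles) == (50, "T", {"C"})
        assert snp.conserved is True
        assert snp.positions["r0"] == 51
        oracle = _snp_oracle(aln, query)
        assert [(s.column, s.target_allele, frozenset(s.alt_alleles), s.conserved) for s in snps] == oracle

    def test_gap_and_ambiguity_columns_ineligible(self):
        rows = {
            "m": "AAAAT" + "A" * 20,
            "n1": "AAA-C" + "A" * 20,
            "n2": "AANAC" + "A" * 20,
        }
        query = _query({"m"}, {"n1", "n2"})
        snps = find_taxon_specific_snps([_aln(rows)], query)
        assert [s.column for s in snps if s.column in (3, 2)] == []

    def test_unresolvable_row_raises(self):
        aln = _aln({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        query = _query({"a"}, {"b"})
        with pytest.raises(ValueError):
            find_taxon_specific_snps([aln], query)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scanner_on_random_alignments(self, seed):
        rng = random.Random(seed)
        n_rows = rng.randint(4, 9)
        n_cols = rng.randint(50, 120)
        ancestor = [rng.choice(BASES) for _ in range(n_cols)]
        rows = {}
        for i in range(n_rows):
            row = list(ancestor)
            for _ in range(rng.randint(0, 12)):
                c = rng.randrange(n_cols)
                row[c] = rng.choice(BASES + ("-" if rng.random() < 0.3 else "N"))
            rows[f"r{i}"] = "".join(row)
        ids = sorted(rows)
        k = rng.randint(1, n_rows - 1)
        query = _query(set(ids[:k]), set(ids[k:]))
        got = [
            (s.column, s.target_allele, frozenset(s.alt_alleles), s.conserved)
            for s in find_taxon_specific_snps([_aln(rows)], query, ConservationFilter(5, 80.0))
        ]
        assert got == _snp_oracle(_aln(rows), query, 5, 80.0)

    def test_soundness_of_emitted_snps(self, alignments):
        """Re-check every emitted SNP against the raw alignment rows."""
        lineages = next(iter(alignments.values())).lineages
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            query = TaxonQuery.from_lineages("Fagales", lineages)
        snps = find_taxon_specific_snps(list(alignments.values()), query)
        assert snps, "expected at least one Fagales-diagnostic SNP in the fixture"
        by_gene = {a.gene_name: a for a in alignments.values()}
        for snp in snps:
            aln = by_gene[snp.gene_name]
            col = aln.column(snp.column)
            assert all(col[r] == snp.target_allele for r in query.members)
            observed_alts = {col[r] for r in query.non_members}
            assert snp.target_allele not in observed_alts
            assert observed_alts == snp.alt_alleles

    def test_conservation_monotonicity(self):
        rng = random.Random(99)
        ancestor = [rng.choice(BASES) for _ in range(120)]
        rows = {}
        for i in range(6):
            row = list(ancestor)
            for _ in range(10):
                row[rng.randrange(120)] = rng.choice(BASES)
            rows[f"r{i}"] = "".join(row)
        # plant one clean diagnostic column
        for i, rid in enumerate(sorted(rows)):
            row = list(rows[rid])
            row[60] = "G" if i < 3 else "T"
            rows[rid] = "".join(row)
        query = _query({"r0", "r1", "r2"}, {"r3", "r4", "r5"})
        aln = _aln(rows)

        def conserved_count(width, mono):
            snps = find_taxon_specific_snps([aln], query, ConservationFilter(width, mono))
            return sum(s.conserved for s in snps)

        for width in (2, 5, 10, 20):
            for lo, hi in [(50.0, 80.0), (80.0, 95.0)]:
                assert conserved_count(width, hi) <= conserved_count(width, lo)
        # with a percentage threshold a wider flank can dilute a polymorphic
        # column, so width-monotonicity only holds at 100% monomorphic
        counts = [conserved_count(w, 100.0) for w in (2, 8, 20)]
        assert counts == sorted(counts, reverse=True)


def test_summary_counts_snps_and_genes():
    snps = [
        CandidateSNP("g1", 5, "Fagus", "A", {"C"}),
        CandidateSNP("g1", 9, "Fagus", "G", {"T"}),
        CandidateSNP("g2", 3, "Fagus", "T", {"A"}),
        CandidateSNP("g2", 4, "Fagales", "C", {"G"}),
    ]
    summary = summarize_snps(snps).set_index("taxon")
    assert summary.loc["Fagus", "n_snps"] == 3
    assert summary.loc["Fagus", "n_genes"] == 2
    assert summary.loc["Fagales", "n_snps"] == 1
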