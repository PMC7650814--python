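"""Enzyme geometry, digestion, in-silico PCR and CAPS marker design."""

import random
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomarkers.alignment import GeneAlignment
from mitomarkers.caps import (
    IUPAC,
    DesignConstraints,
    MultipleProductsError,
    NoProductError,
    default_enzymes,
    design_caps_markers,
    digest_linear,
    find_sites,
    insilico_pcr,
    parse_enzyme_spec,
    parse_enzyme_table,
)
from mitomarkers.genbank_io import reverse_complement
from mitomarkers.snps import CandidateSNP


@pytest.fixture(scope="module")
def enzymes():
    return {e.name: e for e in default_enzymes()}


class TestEnzymeParsing:
    def test_caret_notation(self):
        enz = parse_enzyme_spec("EcoRI", "G^AATTC")
        assert enz.recognition == "GAATTC"
        assert enz.cut_top == 1
        assert enz.cut_bottom == 5
        assert enz.palindromic

    def test_type_iis_offset_notation(self):
        enz = parse_enzyme_spec("BsmBI", "CGTCTC(1/5)")
        assert enz.recognition == "CGTCTC"
        assert enz.site_length == 6
        assert enz.cut_top == 7  # one base past the site's 3' end
        assert enz.cut_bottom == 11
        assert not enz.palindromic

    def test_mixed_notation_rejected(self):
        with pytest.raises(ValueError):
            parse_enzyme_spec("Bad", "G^AATTC(1/5)")

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            parse_enzyme_spec("Bad", "GAAXTC")

    def test_bundled_table_has_the_marker_enzymes(self, enzymes):
        assert enzymes["NciI"].recognition == "CCSGG"
        assert enzymes["BstXI"].recognition == "CCANNNNNNTGG"
        assert enzymes["SfcI"].recognition == "CTRYAG"
        assert enzymes["BsmBI"].recognition == "CGTCTC"

    def test_table_parse_errors(self, tmp_path):
        bad = tmp_path / "enzymes.tsv"
        bad.write_text("OnlyOneColumn\n")
        with pytest.raises(ValueError):
            parse_enzyme_table(bad)


def _site_oracle(sequence, enzyme):
    """Brute-force sliding-window IUPAC matcher (both strands)."""
    hits = []
    rc = reverse_complement(enzyme.recognition)
    L = enzyme.site_length
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        if all(c in IUPAC[p] for p, c in zip(enzyme.recognition, window)):
            hits.append((i, "+"))
        elif all(c in IUPAC[p] for p, c in zip(rc, window)):
            hits.append((i, "-"))
    return hits


class TestFindSites:
    def test_no_match_empty(self, enzymes):
        assert find_sites("ATATATATAT", enzymes["EcoRI"]) == []

    def test_iupac_degenerate_site(self, enzymes):
        # CCSGG with S = C/G: hits at CCCGG (2) and CCGGG (9)
        assert find_sites("AACCCGGTTCCGGGAA", enzymes["NciI"]) == [(2, "+"), (9, "+")]

    def test_reverse_strand_site(self, enzymes):
        seq = "TTTTGAGACGTTTT"  # GAGACG = revcomp of BsmBI's CGTCTC
        assert find_sites(seq, enzymes["BsmBI"]) == [(4, "-")]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sliding_window_oracle(self, seed, enzymes):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        for enzyme in enzymes.values():
            assert find_sites(seq, enzyme) == _site_oracle(seq, enzyme)


class TestDigestLinear:
    def test_no_sites_single_fragment(self, enzymes):
        assert digest_linear("A" * 137, enzymes["EcoRI"]) == [137]

    def test_within_site_cut_arithmetic(self, enzymes):
        # BamHI G^GATCC starting at index 4 of a 14-mer: cut after index 5
        seq = "AAAA" + "GGATCC" + "TTTT"
        assert digest_linear(seq, enzymes["BamHI"]) == [9, 5]

    def test_type_iis_cut_downstream_of_site(self, enzymes):
        # BsmBI site at 2, cut at 2 + 7 = 9
        seq = "AA" + "CGTCTC" + "TTTTTTTT"
        assert digest_linear(seq, enzymes["BsmBI"]) == [9, 7]

    def test_type_iis_cut_beyond_molecule_does_not_cut(self, enzymes):
        seq = "AA" + "CGTCTC"  # cut coordinate would be 9 > len 8
        assert digest_linear(seq, enzymes["BsmBI"]) == [8]

    def test_minus_strand_type_iis_cut(self, enzymes):
        # GAGACG at 8: bottom-strand recognition, top cut at 8 + 6 - 11 = 3
        seq = "AAAAAAAA" + "GAGACG" + "TT"
        assert digest_linear(seq, enzymes["BsmBI"]) == [13, 3]

    @pytest.mark.parametrize("seed", range(10))
    def test_fragments_always_sum_to_length(self, seed, enzymes):
        rng = random.Random(seed)
        table = list(enzymes.values())
        for _ in range(100):
            n = rng.randint(1, 400)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            enzyme = rng.choice(table)
            fragments = digest_linear(seq, enzyme)
            assert sum(fragments) == n
            assert fragments == sorted(fragments, reverse=True)
            assert all(f > 0 for f in fragments)


class TestInsilicoPcr:
    def test_full_template_amplification(self):
        rng = random.Random(5)
        template = "".join(rng.choice("ACGT") for _ in range(200))
        product = insilico_pcr(
            template, template[:20], reverse_complement(template[-20:]), 0
        )
        assert product == template

    def test_amplicon_coordinates(self):
        rng = random.Random(6)
        template = "".join(rng.choice("ACGT") for _ in range(120))
        fwd = template[10:30]
        rev = reverse_complement(template[80:100])
        product = insilico_pcr(template, fwd, rev, 0)
        assert len(product) == 90
        assert product == template[10:100]

    def test_no_product_raises(self):
        with pytest.raises(NoProductError):
            insilico_pcr("ACGT" * 30, "TTTTTTTTTTTT", "AAAAAAAAAAAA", 0)

    def test_multiple_products_raise(self):
        rng = random.Random(7)
        unit = "".join(rng.choice("ACGT") for _ in range(60))
        template = unit + unit  # two identical priming sites each
        with pytest.raises(MultipleProductsError):
            insilico_pcr(template, unit[:15], reverse_complement(unit[-15:]), 0)

    def test_three_prime_mismatch_blocks_annealing(self):
        rng = random.Random(8)
        template = "".join(rng.choice("ACGT") for _ in range(150))
        fwd = template[:20]
        bad_fwd = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        rev = reverse_complement(template[-20:])
        with pytest.raises(NoProductError):
            insilico_pcr(template, bad_fwd, rev, 2)

    def test_mismatch_budget(self):
        rng = random.Random(9)
        template = "".join(rng.choice("ACGT") for _ in range(150))
        fwd = list(template[:20])
        fwd[3] = "A" if fwd[3] != "A" else "C"
        fwd[8] = "A" if fwd[8] != "A" else "C"
        fwd = "".join(fwd)
        rev = reverse_complement(template[-20:])
        with pytest.raises(NoProductError):
            insilico_pcr(template, fwd, rev, 1)
        assert insilico_pcr(template, fwd, rev, 2) == template

    def test_short_primers_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT" * 30, "ACGTACGT", "ACGTACGTACGT", 0)


class TestDesign:
    def _toy_alignment(self, member_seq, alt_allele, snp_pos, n_others=3):
        rows = {"M1": member_seq, "M2": member_seq}
        lineages = {"M1": ["Ord", "Fam"], "M2": ["Ord", "Fam"]}
        for i in range(n_others):
            row = list(member_seq)
            row[snp_pos] = alt_allele
            rows[f"O{i}"] = "".join(row)
            lineages[f"O{i}"] = ["OtherOrd", f"OtherFam{i}"]
        return GeneAlignment("toy", rows, lineages)

    def _snp(self, aln, snp_pos, target, alts):
        return CandidateSNP(
            gene_name="toy",
            column=snp_pos,
            target_taxon="Fam",
            target_allele=target,
            alt_alleles=set(alts),
            positions={rid: snp_pos + 1 for rid in aln.rows},
            conserved=True,
        )

    def test_planted_discriminative_site_recovered(self, enzymes):
        rng = random.Random(11)
        seq = [rng.choice("ACGT") for _ in range(300)]
        seq[150:156] = list("CGTCTC")  # BsmBI; SNP is the T at offset 4
        member_seq = "".join(seq)
        aln = self._toy_alignment(member_seq, "C", 154)
        snp = self._snp(aln, 154, "T", {"C"})
        markers = design_caps_markers([snp], {"toy": aln}, [enzymes["BsmBI"]])
        assert len(markers) == 1
        marker = markers[0]
        assert marker.enzyme.name == "BsmBI"
        assert sum(marker.fragments_target) == marker.amplicon_length
        assert len(marker.fragments_target) == 2
        assert min(marker.fragments_target) >= 40
        assert marker.fragments_alt == {"C": [marker.amplicon_length]}

    def test_snp_without_discriminative_enzyme_yields_nothing(self, enzymes):
        member_seq = "AT" * 150  # no site of any bundled enzyme overlaps
        aln = self._toy_alignment(member_seq, "C", 150)
        snp = self._snp(aln, 150, "A", {"C"})
        assert design_caps_markers([snp], {"toy": aln}, [enzymes["EcoRI"]]) == []

    def test_additional_constitutive_site_disqualifies(self, enzymes):
        rng = random.Random(12)
        seq = [rng.choice("ACGT") for _ in range(300)]
        seq[150:156] = list("CGTCTC")
        seq[170:176] = list("CGTCTC")  # constitutive second site in any amplicon
        member_seq = "".join(seq)
        aln = self._toy_alignment(member_seq, "C", 154)
        snp = self._snp(aln, 154, "T", {"C"})
        markers = design_caps_markers([snp], {"toy": aln}, [enzymes["BsmBI"]])
        for m in markers:
            # if a design exists its amplicon must exclude the second site
            interval = m.amplicon_intervals["M1"]
            assert not (interval[0] <= 170 and 176 <= interval[1])

    def test_primer_mismatch_budget_blocks_design(self, enzymes):
        rng = random.Random(13)
        seq = [rng.choice("ACGT") for _ in range(300)]
        seq[150:156] = list("CGTCTC")
        member_seq = "".join(seq)
        aln = self._toy_alignment(member_seq, "C", 154)
        # give one outgroup row 3 mismatches in every possible primer window
        row = list(aln.rows["O0"])
        for c in range(0, 300, 5):
            if abs(c - 154) > 2:
                row[c] = "A" if row[c] != "A" else "G"
        aln.rows["O0"] = "".join(row)
        snp = self._snp(aln, 154, "T", {"C"})
        constraints = DesignConstraints(mismatch_budget_other=2)
        assert design_caps_markers([snp], {"toy": aln}, [enzymes["BsmBI"]], constraints) == []

    def test_planted_dataset_recovery_matches_manifest(self, dataset, alignments):
        from mitomarkers.pipeline import discover_snps

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            snps = discover_snps(alignments, ["Fagus", "Fagaceae", "Fagales"])
        markers = design_caps_markers(snps, alignments)
        truth = {
            (r["gene"], r["position"], r["taxon"]): r
            for r in dataset.manifest
            if r["type"] == "caps_marker"
        }
        assert len(markers) == len(truth) == 4
        for marker in markers:
            key = (
                marker.snp.gene_name,
                marker.snp.positions["SIM001"],
                marker.snp.target_taxon,
            )
            expected = truth[key]
            assert marker.enzyme.name == expected["enzyme"]
            assert marker.snp.target_allele == expected["target_allele"]
            assert sorted(marker.snp.alt_alleles) == expected["alt_alleles"]
            assert marker.fragments_target == expected["fragments_target"]
            assert marker.amplicon_length == expected["amplicon_length"]

    def test_discrimination_soundness(self, dataset, alignments):
        """Substituting any alternative allele leaves the amplicon uncut."""
        from mitomarkers.pipeline import discover_snps

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            snps = discover_snps(alignments, ["Fagus", "Fagaceae", "Fagales"])
        markers = design_caps_markers(snps, alignments)
        assert markers
        for marker in markers:
            aln = alignments[marker.snp.gene_name]
            rid = sorted(marker.amplicon_intervals)[0]
            ref_members = [
                r for r in aln.rows if aln.rows[r][marker.snp.column] == marker.snp.target_allele
            ]
            ref = ref_members[0]
            start, end = marker.amplicon_intervals[ref]
            gene_seq = aln.ungapped(ref)
            amplicon = gene_seq[start:end]
            assert digest_linear(amplicon, marker.enzyme) == marker.fragments_target
            snp_off = marker.snp.positions[ref] - 1 - start
            for alt in marker.snp.alt_alleles:
                mutated = amplicon[:snp_off] + alt + amplicon[snp_off + 1 :]
                assert digest_linear(mutated, marker.enzyme) == [len(mutated)]


_ENZYMES = default_enzymes()


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=300),
    st.sampled_from(range(len(_ENZYMES))),
)
def test_digest_fragment_sum_property(seq, enzyme_idx):
    """Digestion partitions any linear molecule: fragments sum to its length."""
    fragments = digest_linear(seq, _ENZYMES[enzyme_idx])
    assert sum(fragments) == len(seq)
    assert all(f > 0 for f in fragments)


def test_constraints_validation():
    with pytest.raises(ValueError):
        DesignConstraints(max_amplicon=0)
    with pytest.raises(ValueError):
        DesignConstraints(mismatch_budget_target=2, mismatch_budget_other=1)
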