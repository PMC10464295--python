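"""Coordinate mapping: HGVS parsing, residue/column arithmetic, and the
variant projection with its exclusion statuses."""

import pytest
from hypothesis import given, settings, strategies as st

from kinspot.errors import MappingError, ProteinChangeError
from kinspot.mapping import (
    column_to_reference_residue,
    map_variants,
    parse_protein_change,
    residue_to_column,
)
from kinspot.model import MappingStatus, MsaRow, Substitution

from conftest import (
    brute_force_reference_map,
    brute_force_row_map,
    make_msa,
    make_variant,
)


class TestParseProteinChange:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("p.Val600Glu", ("V", 600, "E")),
            ("p.V600E", ("V", 600, "E")),
            ("V600E", ("V", 600, "E")),
            ("D835Y", ("D", 835, "Y")),
            ("p.val600glu", ("V", 600, "E")),  # case-insensitive
            ("p.(Leu858Arg)", ("L", 858, "R")),
            ("p.His280Tyr", ("H", 280, "Y")),
        ],
    )
    def test_accepted_dialects(self, text, expected):
        sub = parse_protein_change(text)
        assert (sub.ref_aa, sub.position, sub.alt_aa) == expected

    @pytest.mark.parametrize(
        "text,reason",
        [
            ("p.Val600fs", "frameshift"),
            ("p.Val600Ter", "nonsense"),
            ("p.V600*", "nonsense"),
            ("p.Val600del", "indel"),
            ("p.Val600_Lys601insGly", "indel"),
            ("p.Val600dup", "indel"),
            ("p.Val600=", "synonymous"),
            ("p.Val600Val", "synonymous"),
            ("p.V600V", "synonymous"),
            ("p.Met1ext-5", "extension"),
            ("c.1799T>A", "unparsable"),
            ("", "unparsable"),
            ("p.Xyz600Glu", "unparsable"),
        ],
    )
    def test_rejections_carry_reason_codes(self, text, reason):
        with pytest.raises(ProteinChangeError) as err:
            parse_protein_change(text)
        assert err.value.reason == reason


class TestResidueToColumn:
    row = MsaRow(gene="G", protein_id="P", offset=1, sequence="AC-DE")

    def test_counts_past_gaps(self):
        assert residue_to_column(self.row, 3) == 4

    def test_offset_arithmetic(self):
        row = MsaRow(gene="G", protein_id="P", offset=10, sequence="AC-DE")
        assert residue_to_column(row, 10) == 1

    @pytest.mark.parametrize("residue", [5, 0, 99])
    def test_out_of_domain(self, residue):
        assert residue_to_column(self.row, residue) is None

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_strictly_increasing_in_residue_number(self, data):
        seq = data.draw(
            st.text(alphabet="ACDEF-", min_size=1, max_size=30).filter(
                lambda s: s.replace("-", "")
            )
        )
        offset = data.draw(st.integers(min_value=1, max_value=400))
        row = MsaRow(gene="G", protein_id="P", offset=offset, sequence=seq)
        cols = [
            residue_to_column(row, offset + i)
            for i in range(row.ungapped_length)
        ]
        assert all(a < b for a, b in zip(cols, cols[1:]))
        assert cols == sorted(brute_force_row_map(row).values())


class TestColumnToReference:
    def msa_and_structure(self):
        from kinspot.synthetic import generate_reference_structure

        msa = make_msa(["A-CD", "DEFG"], offsets=[122, 1])
        return msa, generate_reference_structure(msa)

    def test_reference_gap_signals_none(self):
        msa, structure = self.msa_and_structure()
        assert column_to_reference_residue(msa, structure, 2) is None

    def test_counts_non_gap_reference_chars(self):
        msa, structure = self.msa_and_structure()
        assert column_to_reference_residue(msa, structure, 3) == 123

    def test_first_column_is_first_residue(self):
        msa, structure = self.msa_and_structure()
        assert column_to_reference_residue(msa, structure, 1) == 122

    def test_inverse_consistency(self, tiny_msa, tiny_structure):
        # for every non-gap reference column, going back through the
        # reference row recovers the same column
        ref = tiny_msa.reference_row
        for column in range(1, tiny_msa.n_columns + 1):
            residue = column_to_reference_residue(tiny_msa, tiny_structure, column)
            if residue is not None:
                assert residue_to_column(ref, residue) == column


class TestMapVariants:
    def test_reference_gap_excluded(self, tiny_msa, tiny_structure):
        # BRAF W3 sits in column 3 where the reference is gapped
        v = make_variant(gene="BRAF", change="W3A")
        mapped, exclusions = map_variants([v], tiny_msa, tiny_structure)
        assert mapped[0].status is MappingStatus.REFERENCE_GAP
        assert exclusions[0].reason == "excluded_reference_gap"

    def test_mapped_variant_lands_on_reference_numbering(self, tiny_msa, tiny_structure):
        v = make_variant(gene="BRAF", change="D4A")  # column 4 -> 3rd ref residue
        mapped, _ = map_variants([v], tiny_msa, tiny_structure)
        assert mapped[0].status is MappingStatus.MAPPED
        assert mapped[0].alignment_column == 4
        assert mapped[0].reference_residue_number == 102

    def test_ref_mismatch_excluded_when_verify_on(self, tiny_msa, tiny_structure):
        v = make_variant(gene="BRAF", change="K4A")  # MSA has D at that cell
        mapped, _ = map_variants([v], tiny_msa, tiny_structure)
        assert mapped[0].status is MappingStatus.REF_MISMATCH
        mapped_off, _ = map_variants([v], tiny_msa, tiny_structure, verify_ref_aa=False)
        assert mapped_off[0].status is MappingStatus.MAPPED

    def test_unmatched_gene_and_out_of_domain(self, tiny_msa, tiny_structure):
        variants = [
            make_variant(gene="NOPE", change="A1C", record_id="a"),
            make_variant(gene="BRAF", change="A99C", record_id="b"),
        ]
        mapped, exclusions = map_variants(variants, tiny_msa, tiny_structure)
        assert mapped[0].status is MappingStatus.UNMATCHED_GENE
        assert mapped[1].status is MappingStatus.OUT_OF_DOMAIN
        assert len(exclusions) == 2

    def test_conservation_one_output_per_input(self, tiny_msa, tiny_structure):
        variants = [
            make_variant(gene=g, change=c, record_id=str(i))
            for i, (g, c) in enumerate(
                [("BRAF", "A1C"), ("BRAF", "W3A"), ("EGFR", "C31A"),
                 ("NOPE", "A1C"), ("REF", "A100C")]
            )
        ]
        mapped, exclusions = map_variants(variants, tiny_msa, tiny_structure)
        assert len(mapped) == len(variants)
        n_ok = sum(1 for m in mapped if m.status is MappingStatus.MAPPED)
        assert n_ok + len(exclusions) == len(variants)

    def test_ambiguous_multi_domain_gene_is_an_error(self):
        from kinspot.synthetic import generate_reference_structure

        msa = make_msa(
            ["ACDE", "EFGH", "IKLM"],
            offsets=[1, 10, 10],
            genes=["REF", "DUAL", "DUAL"],
        )
        structure = generate_reference_structure(msa)
        v = make_variant(gene="DUAL", change="F11A")
        with pytest.raises(MappingError):
            map_variants([v], msa, structure, verify_ref_aa=False)

    def test_multi_domain_gene_resolved_by_domain_membership(self):
        from kinspot.synthetic import generate_reference_structure

        msa = make_msa(
            ["ACDE", "EFGH", "IKLM"],
            offsets=[1, 10, 100],
            genes=["REF", "DUAL", "DUAL"],
        )
        structure = generate_reference_structure(msa)
        mapped, _ = map_variants(
            [make_variant(gene="DUAL", change="K101A")], msa, structure
        )
        assert mapped[0].status is MappingStatus.MAPPED
        assert mapped[0].alignment_column == 2
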