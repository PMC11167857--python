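"""Parsing of bracket-annotated peptides, mass classification, localization."""

import pytest
from hypothesis import given, strategies as st

from histodiff import (
    ClassificationError,
    MassTable,
    ModificationDef,
    PeptideParseError,
    PTMSite,
    dump_mass_table,
    load_mass_table,
    localize_peptide,
    parse_modified_sequence,
)


class TestParsing:
    @pytest.mark.parametrize(
        "raw, stripped, annotations",
        [
            ("K[+112]STGGK[+42]APR", "KSTGGKAPR", ((1, 112), (6, 42))),
            ("K[+ 112]STGGK[+ 42]APR", "KSTGGKAPR", ((1, 112), (6, 42))),
            ("SEEAPAPAPAPAKAAK[+114]KKTTASKPKKVGPSVGE",
             "SEEAPAPAPAPAKAAKKKTTASKPKKVGPSVGE", ((16, 114),)),
            ("PEPTIDE", "PEPTIDE", ()),
            ("PEPK[-18]R", "PEPKR", ((4, -18),)),
        ],
    )
    def test_examples(self, raw, stripped, annotations):
        form = parse_modified_sequence(raw)
        assert form.stripped_sequence == stripped
        assert form.annotations == annotations

    def test_fig3_peptide_length(self):
        form = parse_modified_sequence("SEEAPAPAPAPAKAAK[+ 114]KKTTASKPKKVGPSVGE")
        assert len(form.stripped_sequence) == 33
        assert form.annotations == ((16, 114),)

    def test_leading_bracket_is_nterm_on_position_one(self):
        form = parse_modified_sequence("[+42]PEPK")
        assert form.nterm
        assert form.annotations == ((1, 42),)
        assert form.serialize() == "[+42]PEPK"

    def test_multiple_shifts_on_one_residue_are_summed(self):
        form = parse_modified_sequence("K[+56][+56]APR")
        assert form.annotations == ((1, 112),)

    @pytest.mark.parametrize("raw", ["PEP[+42", "PEP]X", "[+42]", "", "PE[+4.2]P", "pep"])
    def test_malformed_inputs_raise(self, raw):
        with pytest.raises(PeptideParseError):
            parse_modified_sequence(raw)

    def test_error_names_offset(self):
        with pytest.raises(PeptideParseError, match="offset 3"):
            parse_modified_sequence("PEP[+42")

    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        data=st.data(),
    )
    def test_round_trip_is_identity(self, seq, data):
        n_ann = data.draw(st.integers(0, min(3, len(seq))))
        positions = data.draw(
            st.lists(st.integers(1, len(seq)), min_size=n_ann, max_size=n_ann, unique=True)
        )
        ann = {p: data.draw(st.integers(-200, 200).filter(lambda m: m != 0))
               for p in positions}
        raw = "".join(
            aa + (f"[{ann[i]:+d}]" if i in ann else "")
            for i, aa in enumerate(seq, start=1)
        )
        form = parse_modified_sequence(raw)
        assert form.serialize() == raw
        assert parse_modified_sequence(form.serialize()) == form


class TestClassification:
    def test_composite_nterm_shift_decomposes(self, mass_table):
        form = parse_modified_sequence("K[+112]STGGK[+42]APR")
        assigned, unresolved = form.classify(mass_table)
        names = [(pos, d.name) for pos, d in assigned]
        assert names == [(1, "propionyl"), (1, "propionyl"), (6, "acetyl")]
        assert not unresolved
        assert all(d.lab_introduced for pos, d in assigned if pos == 1)

    def test_gg_remnant_maps_to_ubiquityl(self, mass_table):
        form = parse_modified_sequence("SEEAPAPAPAPAKAAK[+114]KKTTASKPKKVGPSVGE")
        assigned, _ = form.classify(mass_table)
        assert assigned == [(16, mass_table.get("gg"))]

    def test_nterm_serine_acetyl_resolves_directly(self, mass_table):
        form = parse_modified_sequence("S[+42]EEAPAPAPAPAK")
        assigned, _ = form.classify(mass_table)
        assert assigned == [(1, mass_table.get("acetyl"))]

    def test_unknown_mass_raises_with_candidates(self, mass_table):
        form = parse_modified_sequence("PK[+57]R")
        with pytest.raises(ClassificationError, match=r"\+57 on K2"):
            form.classify(mass_table)

    def test_unknown_mass_flag_mode_reports_not_drops(self, mass_table):
        form = parse_modified_sequence("S[+42]EEAPAPAPAPAK[+57]AAKKKTTASKPKKVGPSVGE")
        assigned, unresolved = form.classify(mass_table, on_unresolved="flag")
        assert (1, mass_table.get("acetyl")) in assigned
        assert [(pos, mass) for pos, mass, _ in unresolved] == [(13, 57)]

    def test_ambiguous_table_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="ambiguous"):
            MassTable([
                ModificationDef("acetyl", 1, 42, frozenset({"K"})),
                ModificationDef("trimethyl", 37, 42, frozenset({"K"})),
            ])

    def test_override_table_maps_42_to_trimethyl(self):
        table = MassTable([ModificationDef("trimethyl", 37, 42, frozenset({"K"}))])
        form = parse_modified_sequence("AK[+42]R")
        assigned, _ = form.classify(table)
        assert assigned[0][1].name == "trimethyl"

    def test_mass_table_round_trips_through_yaml(self, mass_table, tmp_path):
        path = tmp_path / "masses.yaml"
        dump_mass_table(mass_table, path)
        loaded = load_mass_table(path)
        assert [d for d in loaded] == [d for d in mass_table]


class TestLocalization:
    H3_TAIL = {"H3": "ARTKQTARKSTGGKAPRKQLATKAARKSAPAT"}

    def test_k14_peptide(self):
        form = localize_peptide(parse_modified_sequence("KSTGGKAPR"), self.H3_TAIL)
        assert (form.status, form.protein_start) == ("localized", 9)
        assert form.protein_position(6) == 14

    def test_k18_peptide(self):
        form = localize_peptide(parse_modified_sequence("KQLATKAAR"), self.H3_TAIL)
        assert form.protein_start == 18
        assert form.protein_position(1) == 18

    def test_absent_peptide_is_unlocalized(self):
        form = localize_peptide(parse_modified_sequence("WWWW"), self.H3_TAIL)
        assert form.status == "unlocalized"
        assert form.protein_start is None

    def test_multiple_hits_flag_ambiguous(self):
        proteins = {"a": "ARTKQTARKS", "b": "ARTKQTARKS"}
        form = localize_peptide(parse_modified_sequence("ARTKQ"), proteins)
        assert form.status == "ambiguous"
        assert len(form.all_hits) == 2

    def test_localized_subsequence_matches(self, reference_proteins):
        for raw in ("KSTGGKAPR", "KQLATKAAR", "SEEAPAPAPAPAKAAK[+114]KKTTASKPKKVGPSVGE"):
            form = localize_peptide(parse_modified_sequence(raw), reference_proteins)
            assert form.status == "localized"
            seq = reference_proteins[form.source_protein]
            assert seq[form.protein_start - 1: form.protein_end] == form.stripped_sequence


class TestPTMSite:
    def test_lab_introduced_cannot_define_site(self, mass_table):
        with pytest.raises(ValueError, match="lab-introduced"):
            PTMSite("H3", "H3", 14, "K", mass_table.get("propionyl"), "H3K14pr")

    def test_chemically_incompatible_residue_rejected(self, mass_table):
        with pytest.raises(ValueError, match="not chemically"):
            PTMSite("H3", "H3", 2, "R", mass_table.get("gg"), "H3R2ub")

    def test_nominal_mass_must_be_nonzero_integer(self):
        with pytest.raises(ValueError):
            ModificationDef("null", 0, 0, frozenset({"K"}))
        with pytest.raises(ValueError):
            ModificationDef("empty", 1, 42, frozenset())
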