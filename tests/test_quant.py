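"""Site-occupancy arithmetic: covering forms, relative abundance, beta/M."""

import numpy as np
import pandas as pd
import pytest

from histodiff import (
    PTMSite,
    QuantTable,
    SampleDesign,
    build_ptm_matrix,
    covering_forms,
    localize_peptide,
    mean_relative_abundance,
    parse_modified_sequence,
    read_quant_table,
    relative_abundance_per_digest,
)
from histodiff.synthetic_reference import worked_panel

from conftest import make_quant_table


def _forms(raws, proteins, digest="trypsin_propionyl"):
    return [
        localize_peptide(parse_modified_sequence(r, digest=digest), proteins)
        for r in raws
    ]


@pytest.fixture(scope="module")
def h1k16ub(mass_table):
    return next(s for s in worked_panel(mass_table) if s.abbreviated_name == "H1K16ub")


@pytest.fixture(scope="module")
def h3k14ac(mass_table):
    return next(s for s in worked_panel(mass_table) if s.abbreviated_name == "H3K14ac")


class TestCoveringForms:
    def test_gg_at_site_is_modified_other_marks_are_not(
        self, h1k16ub, mass_table, reference_proteins
    ):
        forms = _forms(
            [
                "SEEAPAPAPAPAKAAK[+114]KKTTASKPKKVGPSVGE",   # GG at K16: modified
                "S[+42]EEAPAPAPAPAK[+57]AAKKKTTASKPKKVGPSVGE",  # other marks: unmodified
            ],
            reference_proteins,
        )
        modified, unmodified = covering_forms(h1k16ub, forms, mass_table)
        assert [f.serialize() for f in modified] == ["SEEAPAPAPAPAKAAK[+114]KKTTASKPKKVGPSVGE"]
        assert len(unmodified) == 1

    def test_same_mark_at_other_residue_counts_unmodified(
        self, h3k14ac, mass_table, reference_proteins
    ):
        # acetyl on K18, not K14: covers K14 but is unmodified for H3K14ac
        forms = _forms(["KSTGGKAPRK[+42]QLATKAAR"], reference_proteins)
        assert forms[0].status == "localized"
        modified, unmodified = covering_forms(h3k14ac, forms, mass_table)
        assert not modified and len(unmodified) == 1

    def test_no_coverage_yields_empty_partitions(self, h3k14ac, mass_table, reference_proteins):
        forms = _forms(["KQLATKAAR"], reference_proteins)  # starts at 18, misses K14
        assert covering_forms(h3k14ac, forms, mass_table) == ([], [])


class TestRelativeAbundance:
    def test_hand_arithmetic(self, h3k14ac, mass_table, reference_proteins, h3_two_form_table):
        ra = relative_abundance_per_digest(
            h3k14ac, h3_two_form_table, "s1", "trypsin_propionyl",
            reference_proteins, mass_table,
        )
        assert ra == pytest.approx(20.0)

    def test_zero_modified_signal_is_zero_percent(self, h3k14ac, mass_table, reference_proteins):
        table = make_quant_table([("K[+112]STGGK[+56]APR", "trypsin_propionyl", "s1", 500.0)])
        ra = relative_abundance_per_digest(
            h3k14ac, table, "s1", "trypsin_propionyl", reference_proteins, mass_table
        )
        assert ra == 0.0

    def test_no_covering_forms_is_missing(self, h3k14ac, mass_table, reference_proteins):
        table = make_quant_table([("KQLATKAAR", "trypsin_propionyl", "s1", 500.0)])
        assert relative_abundance_per_digest(
            h3k14ac, table, "s1", "trypsin_propionyl", reference_proteins, mass_table
        ) is None


class TestMeanRelativeAbundance:
    def _three_digest_table(self, ras):
        """Build a table whose per-digest RA for H3K14ac equals the given values."""
        rows = []
        digests = ["trypsin_propionyl", "v8_ambic", "v8_naphos"]
        for digest, ra in zip(digests, ras):
            if ra is None:
                continue
            rows.append(("K[+112]STGGK[+42]APR", digest, "s1", float(ra)))
            rows.append(("K[+112]STGGK[+56]APR", digest, "s1", float(100 - ra)))
        return make_quant_table(rows)

    def test_mean_beta_and_m(self, h3k14ac, mass_table, reference_proteins):
        table = self._three_digest_table([20, 30, 10])
        prof = mean_relative_abundance(h3k14ac, table, "s1", reference_proteins, mass_table)
        assert prof.relative_abundance == pytest.approx(20.0)
        assert prof.beta == pytest.approx(0.20)
        assert prof.m_value == pytest.approx(-2.0)  # log2(0.25)

    def test_missing_digest_averages_over_available(self, h3k14ac, mass_table, reference_proteins):
        table = self._three_digest_table([20, None, 10])
        prof = mean_relative_abundance(h3k14ac, table, "s1", reference_proteins, mass_table)
        assert prof.relative_abundance == pytest.approx(15.0)
        assert set(prof.per_digest_ra) == {"trypsin_propionyl", "v8_naphos"}

    def test_beta_half_gives_m_zero(self, h3k14ac, mass_table, reference_proteins):
        prof = mean_relative_abundance(
            h3k14ac, self._three_digest_table([50, 50, 50]), "s1",
            reference_proteins, mass_table,
        )
        assert prof.m_value == pytest.approx(0.0)

    def test_all_digests_missing_returns_none(self, h3k14ac, mass_table, reference_proteins):
        table = make_quant_table([("KQLATKAAR", "trypsin_propionyl", "s1", 5.0)])
        assert mean_relative_abundance(
            h3k14ac, table, "s1", reference_proteins, mass_table
        ) is None

    def test_extreme_occupancy_clamped_to_finite_m(self, h3k14ac, mass_table, reference_proteins):
        prof = mean_relative_abundance(
            h3k14ac, self._three_digest_table([0, 0, 0]), "s1",
            reference_proteins, mass_table,
        )
        assert prof.relative_abundance == 0.0
        assert np.isfinite(prof.m_value)


class TestMatrix:
    def _table(self, scale_s1=1.0):
        rows = []
        for sample in ("s1", "s2", "s3"):
            c = scale_s1 if sample == "s1" else 1.0
            rows += [
                ("K[+112]STGGK[+42]APR", "trypsin_propionyl", sample, 200.0 * c),
                ("K[+112]STGGK[+56]APR", "trypsin_propionyl", sample, 800.0 * c),
                ("K[+114]QLATK[+42]AAR", "trypsin_propionyl", sample, 100.0 * c),
                ("K[+56]QLATK[+42]AAR", "trypsin_propionyl", sample, 900.0 * c),
            ]
        return make_quant_table(rows)

    def test_full_coverage_counts(self, mass_table, reference_proteins):
        panel = [s for s in worked_panel(mass_table)
                 if s.abbreviated_name in ("H3K14ac", "H3K18ub")]
        matrix = build_ptm_matrix(panel, self._table(), reference_proteins, mass_table)
        assert matrix.ra.shape == (2, 3)
        assert matrix.n_missing == 0
        assert matrix.ra.loc["H3K14ac"].tolist() == pytest.approx([20.0] * 3)
        assert matrix.ra.loc["H3K18ub"].tolist() == pytest.approx([10.0] * 3)

    def test_scale_invariance_per_sample(self, mass_table, reference_proteins):
        panel = [s for s in worked_panel(mass_table)
                 if s.abbreviated_name in ("H3K14ac", "H3K18ub")]
        base = build_ptm_matrix(panel, self._table(), reference_proteins, mass_table)
        scaled = build_ptm_matrix(panel, self._table(scale_s1=7.3), reference_proteins,
                                  mass_table)
        pd.testing.assert_frame_equal(base.ra, scaled.ra)

    def test_uncovered_site_is_missing_and_logged(self, mass_table, reference_proteins):
        panel = worked_panel(mass_table)  # includes H1 sites with no signal here
        matrix = build_ptm_matrix(panel, self._table(), reference_proteins, mass_table)
        assert matrix.n_missing == 6  # 2 H1 sites x 3 samples
        assert matrix.profile("H1K16ub", "s1") is None
        prof = matrix.profile("H3K14ac", "s1")
        assert prof.relative_abundance == pytest.approx(20.0)

    def test_monotonicity_in_modified_area(self, mass_table, reference_proteins):
        panel = [s for s in worked_panel(mass_table) if s.abbreviated_name == "H3K14ac"]
        ras = []
        for mod_area in (100.0, 200.0, 400.0):
            table = make_quant_table([
                ("K[+112]STGGK[+42]APR", "trypsin_propionyl", "s1", mod_area),
                ("K[+112]STGGK[+56]APR", "trypsin_propionyl", "s1", 800.0),
            ])
            m = build_ptm_matrix(panel, table, reference_proteins, mass_table)
            ras.append(m.ra.at["H3K14ac", "s1"])
        assert ras == sorted(ras)

    def test_two_state_residue_complementarity(self, mass_table, reference_proteins):
        """Acetyl and GG states of K14 sum to 100% when they partition the forms."""
        acetyl = next(s for s in worked_panel(mass_table) if s.abbreviated_name == "H3K14ac")
        gg = PTMSite("H3_syn", "H3", 14, "K", mass_table.get("gg"), "H3K14ub")
        table = make_quant_table([
            ("K[+112]STGGK[+42]APR", "trypsin_propionyl", "s1", 321.0),
            ("K[+112]STGGK[+114]APR", "trypsin_propionyl", "s1", 679.0),
        ])
        m = build_ptm_matrix([acetyl, gg], table, reference_proteins, mass_table)
        total = m.ra.at["H3K14ac", "s1"] + m.ra.at["H3K14ub", "s1"]
        assert total == pytest.approx(100.0)

    def test_long_frame_round_trip(self, mass_table, reference_proteins, tmp_path):
        panel = [s for s in worked_panel(mass_table)
                 if s.abbreviated_name in ("H3K14ac", "H3K18ub")]
        matrix = build_ptm_matrix(panel, self._table(), reference_proteins, mass_table)
        out = tmp_path / "matrix.csv"
        matrix.write(out)
        frame = pd.read_csv(out)
        assert set(frame.columns) == {"ptm", "sample_id", "relative_abundance", "beta", "m_value"}
        assert len(frame) == 6


class TestTableValidation:
    def test_duplicate_record_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_quant_table([
                ("PEPK", "v8_ambic", "s1", 1.0),
                ("PEPK", "v8_ambic", "s1", 2.0),
            ])

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            make_quant_table([("PEPK", "v8_ambic", "s1", -1.0)])

    def test_unknown_digest_rejected(self):
        with pytest.raises(ValueError, match="digest"):
            make_quant_table([("PEPK", "lysC", "s1", 1.0)])

    @pytest.mark.parametrize("sep,name", [(",", "t.csv"), ("\t", "t.tsv")])
    def test_reader_sniffs_delimiter(self, tmp_path, sep, name):
        path = tmp_path / name
        pd.DataFrame(
            [("PEPK", "v8_ambic", "s1", 1.0)],
            columns=["modified_sequence", "digest", "sample_id", "normalized_area"],
        ).to_csv(path, sep=sep, index=False)
        assert len(read_quant_table(path).records) == 1

    def test_design_group_experiment_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SampleDesign(pd.DataFrame([
                {"sample_id": "a", "fish_id": "f", "tissue": "gills",
                 "experiment": "short_term", "group": "S1"},
            ]))
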