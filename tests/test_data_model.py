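"""Validation, normalization and join semantics of the input tables."""

import numpy as np
import pandas as pd
import pytest

from marinvef.data_model import (
    AssessmentTable,
    ConfigurationError,
    EcoregionTable,
    OccurrenceTable,
    SchemaError,
    ThreatTaxonomy,
    ValidationError,
    build_dataset,
    normalize_name,
    parse_threat_codes,
    read_assessments,
    read_ecoregions,
    read_occurrences,
)

ECO_CSV = """ecoregion_id,name,area_km2,centroid_latitude
ER1,North shelf,1200.5,55.0
ER2,Mid gyre,800.0,10.0
ER3,South basin,450.25,-42.5
"""


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestEcoregions:
    def test_well_formed_csv_is_read_verbatim(self, tmp_path):
        table = read_ecoregions(_write(tmp_path, "eco.csv", ECO_CSV))
        assert table.ids == ["ER1", "ER2", "ER3"]
        assert table.area_map()["ER3"] == 450.25

    def test_zero_area_rejected_with_row_index(self, tmp_path):
        bad = ECO_CSV.replace("800.0", "0")
        with pytest.raises(ValidationError, match="area_km2.*1"):
            read_ecoregions(_write(tmp_path, "eco.csv", bad))

    def test_duplicate_id_rejected(self, tmp_path):
        bad = ECO_CSV.replace("ER2", "ER1")
        with pytest.raises(ValidationError, match="duplicate.*ER1"):
            read_ecoregions(_write(tmp_path, "eco.csv", bad))

    def test_missing_column_names_the_column(self, tmp_path):
        bad = ECO_CSV.replace("area_km2", "surface")
        with pytest.raises(SchemaError, match="area_km2"):
            read_ecoregions(_write(tmp_path, "eco.csv", bad))

    def test_latitude_out_of_bounds_rejected(self):
        frame = pd.DataFrame(
            [("ER1", "x", 1.0, 95.0)],
            columns=["ecoregion_id", "name", "area_km2", "centroid_latitude"],
        )
        with pytest.raises(ValidationError, match="centroid_latitude"):
            EcoregionTable.from_frame(frame)


OCC_CSV = """species_name,ecoregion_id,is_alien,alien_provenance
Abra alba,ER1,false,
Abra alba,ER2,true,sighted
Caulerpa taxa,ER1,true,total_only
"""


class TestOccurrences:
    def test_native_blank_provenance_normalized(self, tmp_path):
        table = read_occurrences(_write(tmp_path, "occ.csv", OCC_CSV))
        native = table.frame.iloc[0]
        assert not native["is_alien"]
        assert native["alien_provenance"] == "not_applicable"

    def test_alien_provenances_kept(self, tmp_path):
        table = read_occurrences(_write(tmp_path, "occ.csv", OCC_CSV))
        assert list(table.frame["alien_provenance"][1:]) == ["sighted", "total_only"]

    def test_alien_with_bad_provenance_rejected(self, tmp_path):
        bad = OCC_CSV.replace("total_only", "guessed")
        with pytest.raises(ValidationError, match="provenance"):
            read_occurrences(_write(tmp_path, "occ.csv", bad))

    def test_duplicate_species_region_pair_rejected(self, tmp_path):
        bad = OCC_CSV + "Abra alba,ER1,false,\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_occurrences(_write(tmp_path, "occ.csv", bad))


ASSESS_CSV = """species_name,threat_level,threat_codes,dd_threat_probability
Abra alba,VU,8.1|9.1,
Caulerpa taxa,DD,,0.8
Mya lata,LC,,
"""


class TestAssessments:
    def test_codes_parsed_to_set_and_dd_probability_kept(self, tmp_path):
        table = read_assessments(_write(tmp_path, "a.csv", ASSESS_CSV))
        frame = table.frame.set_index("species_name")
        assert frame.loc["Abra alba", "threat_codes"] == frozenset({"8.1", "9.1"})
        assert frame.loc["Caulerpa taxa", "dd_threat_probability"] == 0.8
        assert frame.loc["Mya lata", "threat_codes"] == frozenset()

    def test_probability_out_of_range_rejected(self, tmp_path):
        bad = ASSESS_CSV.replace("0.8", "1.3")
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            read_assessments(_write(tmp_path, "a.csv", bad))

    def test_probability_on_non_dd_strict_vs_lenient(self, tmp_path):
        bad = ASSESS_CSV.replace("8.1|9.1,", "8.1|9.1,0.5")
        path = _write(tmp_path, "a.csv", bad)
        with pytest.raises(ValidationError, match="non-DD"):
            read_assessments(path)
        table = read_assessments(path, strict=False)
        frame = table.frame.set_index("species_name")
        assert np.isnan(frame.loc["Abra alba", "dd_threat_probability"])

    def test_unknown_threat_level_rejected(self, tmp_path):
        bad = ASSESS_CSV.replace("VU", "XX")
        with pytest.raises(ValidationError, match="XX"):
            read_assessments(_write(tmp_path, "a.csv", bad))

    def test_dd_without_probability_gets_default(self, tmp_path):
        text = ASSESS_CSV.replace("0.8", "")
        table = read_assessments(_write(tmp_path, "a.csv", text), dd_default=0.0)
        frame = table.frame.set_index("species_name")
        assert frame.loc["Caulerpa taxa", "dd_threat_probability"] == 0.0


def test_scientific_name_matching_is_whitespace_normalized():
    assert normalize_name("  Abra   alba ") == "Abra alba"
    assert normalize_name("Abra alba") != normalize_name("abra alba")  # case kept


def test_threat_code_cell_parsing_roundtrips():
    assert parse_threat_codes("8.1| 9.1 |") == frozenset({"8.1", "9.1"})
    assert parse_threat_codes("") == frozenset()
    assert parse_threat_codes(float("nan")) == frozenset()


class TestTaxonomy:
    def test_top_level_collapse_keeps_invasion_subcategory(self):
        tax = ThreatTaxonomy.iucn_top_level()
        assert tax.canonical("8.1.2") == "8.1"
        assert tax.canonical("8.1") == "8.1"
        assert tax.canonical("9.3.1") == "9"
        assert tax.contains("8.1") and tax.contains("12")
        assert not tax.contains("invasion")

    def test_identity_taxonomy_passes_codes_through(self):
        tax = ThreatTaxonomy.identity(["invasion", "pollution"])
        assert tax.canonical("pollution") == "pollution"
        assert not tax.contains("fishing")


class TestBuildDataset:
    def _tables(self, tmp_path):
        eco = read_ecoregions(_write(tmp_path, "eco.csv", ECO_CSV))
        occ = read_occurrences(_write(tmp_path, "occ.csv", OCC_CSV))
        assess = read_assessments(_write(tmp_path, "a.csv", ASSESS_CSV))
        return eco, occ, assess

    def test_unassessed_species_flagged_not_dropped(self, tmp_path):
        eco, occ, _ = self._tables(tmp_path)
        assess = AssessmentTable.from_frame(
            pd.DataFrame(
                [("Abra alba", "VU", "8.1", np.nan)],
                columns=["species_name", "threat_level", "threat_codes",
                         "dd_threat_probability"],
            )
        )
        ds = build_dataset(eco, occ, assess)
        assert ds.unassessed == {"Caulerpa taxa"}
        log = ds.join_log
        assert (
            log["occurrence_rows_in"]
            == log["occurrence_rows_kept"] + log["occurrence_rows_flagged_unassessed"]
        )

    def test_fully_matching_tables_have_zero_flags(self, tmp_path):
        eco, occ, assess = self._tables(tmp_path)
        ds = build_dataset(eco, occ, assess)
        assert ds.unassessed == frozenset()
        assert ds.join_log["occurrence_rows_flagged_unassessed"] == 0

    def test_unknown_ecoregion_reference_rejected(self, tmp_path):
        eco, _, assess = self._tables(tmp_path)
        occ = OccurrenceTable.from_frame(
            pd.DataFrame(
                [("Abra alba", "ER9", False, "not_applicable")],
                columns=["species_name", "ecoregion_id", "is_alien",
                         "alien_provenance"],
            )
        )
        with pytest.raises(ValidationError, match="ER9"):
            build_dataset(eco, occ, assess)

    def test_empty_join_rejected(self, tmp_path):
        eco, occ, _ = self._tables(tmp_path)
        assess = AssessmentTable.from_frame(
            pd.DataFrame(
                [("Nemo nullius", "LC", "", np.nan)],
                columns=["species_name", "threat_level", "threat_codes",
                         "dd_threat_probability"],
            )
        )
        with pytest.raises(ValidationError, match="empty join"):
            build_dataset(eco, occ, assess)

    def test_invasion_code_outside_taxonomy_rejected(self, tmp_path):
        eco, occ, assess = self._tables(tmp_path)
        with pytest.raises(ConfigurationError):
            build_dataset(eco, occ, assess, invasion_threat_code="not-a-code")

    def test_join_is_independent_of_row_order(self, tmp_path):
        eco, occ, assess = self._tables(tmp_path)
        ds1 = build_dataset(eco, occ, assess)
        occ_rev = OccurrenceTable.from_frame(occ.frame.iloc[::-1].reset_index(drop=True))
        assess_rev = AssessmentTable.from_frame(
            assess.frame.iloc[::-1].reset_index(drop=True).assign(
                threat_codes=lambda df: df["threat_codes"].map(
                    lambda s: "|".join(sorted(s))
                )
            )
        )
        ds2 = build_dataset(eco, occ_rev, assess_rev)
        assert ds1.unassessed == ds2.unassessed
        from marinvef.threat_frequency import compute_threat_frequencies

        r1 = compute_threat_frequencies(ds1)
        r2 = compute_threat_frequencies(ds2)
        pd.testing.assert_series_equal(r1.phi_inv, r2.phi_inv)


class TestRoundTrip:
    def test_tables_written_then_read_are_identical(self, tmp_path, random_studies):
        _, dataset, _ = random_studies[0]
        eco_p, occ_p, ass_p = (tmp_path / n for n in ("e.csv", "o.csv", "a.csv"))
        dataset.ecoregions.to_csv(eco_p)
        dataset.occurrences.to_csv(occ_p)
        dataset.assessments.to_csv(ass_p)
        eco2 = read_ecoregions(eco_p)
        occ2 = read_occurrences(occ_p)
        ass2 = read_assessments(ass_p)
        pd.testing.assert_frame_equal(dataset.ecoregions.frame, eco2.frame)
        pd.testing.assert_frame_equal(dataset.occurrences.frame, occ2.frame)
        pd.testing.assert_frame_equal(dataset.assessments.frame, ass2.frame)
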