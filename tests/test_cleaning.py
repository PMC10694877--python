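"""Deduplication, drug normalization, class assignment and exposure maps."""

from __future__ import annotations

import pandas as pd
import pytest

from aadsignal.cleaning import (ANTIBIOTIC_CLASSES, DrugDictionary,
                                assign_class, clean_table_set,
                                deduplicate_cases, normalize_drugs,
                                primary_suspect_exposures)
from aadsignal.errors import ConfigurationError
from aadsignal.faers_io import parse_demo
from conftest import make_demo


def parsed(rows):
    frame, _ = parse_demo(make_demo(rows))
    return frame


class TestDeduplicate:
    def test_keeps_greatest_primaryid(self):
        frame = parsed([
            {"primaryid": "1111", "caseid": "111"},
            {"primaryid": "1113", "caseid": "111"},
        ])
        kept, removed = deduplicate_cases(frame)
        assert removed == 1
        assert kept["primaryid"].tolist() == ["1113"]

    def test_distinct_caseids_untouched(self):
        frame = parsed([
            {"primaryid": "1", "caseid": "1"},
            {"primaryid": "2", "caseid": "2"},
        ])
        kept, removed = deduplicate_cases(frame)
        assert removed == 0
        assert sorted(kept["caseid"]) == ["1", "2"]

    def test_numeric_not_lexicographic_comparison(self):
        frame = parsed([
            {"primaryid": "9", "caseid": "7"},
            {"primaryid": "10", "caseid": "7"},
        ])
        kept, _ = deduplicate_cases(frame)
        assert kept["primaryid"].tolist() == ["10"]

    def test_tiebreak_latest_event_date(self):
        # equal numeric primaryids can only happen with non-numeric ids;
        # force the tie with unparseable ids and distinct event dates
        frame = parsed([
            {"primaryid": "A", "caseid": "5", "event_dt": "20190101"},
            {"primaryid": "B", "caseid": "5", "event_dt": "20200101"},
        ])
        kept, _ = deduplicate_cases(frame)
        assert kept["primaryid"].tolist() == ["B"]

    def test_idempotent(self, small_synthetic):
        _, ts, _ = small_synthetic
        frame, _ = parse_demo(ts.demo)
        once, removed1 = deduplicate_cases(frame)
        twice, removed2 = deduplicate_cases(once)
        assert removed2 == 0
        pd.testing.assert_frame_equal(once, twice)
        assert once["caseid"].is_unique

    def test_removed_matches_generator_bookkeeping(self, small_synthetic):
        cfg, ts, gt = small_synthetic
        frame, _ = parse_demo(ts.demo)
        kept, removed = deduplicate_cases(frame)
        assert removed == gt.n_duplicates == round(0.10 * cfg.n_reports)
        # the retained version is always the generator's current one
        assert set(kept["primaryid"]) == set(gt.report["primaryid"])

    def test_empty_input(self):
        kept, removed = deduplicate_cases(parsed([]))
        assert removed == 0 and len(kept) == 0


@pytest.fixture
def dictionary():
    return DrugDictionary(
        name_to_ingredient={
            "AMOXICILLIN AND CLAVULANATE POTASSIUM": "amoxicillin-clavulanate"},
        ingredient_to_class={
            "amoxicillin-clavulanate": "beta-lactamase inhibitors",
            "amoxicillin": "penicillins",
            "ceftriaxone": "third-generation cephalosporins"})


class TestNormalizeDrugs:
    def drug_frame(self, names, roles=None):
        roles = roles or ["PS"] * len(names)
        return pd.DataFrame({
            "primaryid": [str(i) for i in range(len(names))],
            "drug_seq": ["1"] * len(names),
            "drugname": names, "role_cod": roles}, dtype=object)

    def test_combination_product_lookup(self, dictionary):
        out, unmapped = normalize_drugs(
            self.drug_frame(["AMOXICILLIN AND CLAVULANATE POTASSIUM"]),
            dictionary)
        assert out["ingredient"].tolist() == ["amoxicillin-clavulanate"]
        assert len(unmapped) == 0

    def test_case_and_whitespace_insensitive(self, dictionary):
        out, _ = normalize_drugs(
            self.drug_frame([" amoxicillin ", "AMOXICILLIN"]), dictionary)
        assert out["ingredient"].tolist() == ["amoxicillin", "amoxicillin"]

    def test_unmapped_reported_with_frequency(self, dictionary):
        out, unmapped = normalize_drugs(
            self.drug_frame(["WIDGETOL", "WIDGETOL", "CEFTRIAXONE"]),
            dictionary)
        assert out["ingredient"].tolist() == [None, None, "ceftriaxone"]
        assert unmapped.to_dict() == {"WIDGETOL": 2}
        assert len(out) == 3  # row count never changes

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_drugs(self.drug_frame(["X"]), DrugDictionary())


class TestExposures:
    def test_role_filter_and_set_semantics(self, dictionary):
        drug = pd.DataFrame({
            "primaryid": ["1", "1", "2", "2", "3"],
            "drug_seq": ["1", "2", "1", "2", "1"],
            "drugname": ["CEFTRIAXONE", "OMEPRAZOLE", "CEFTRIAXONE",
                         "CEFTRIAXONE", "AMOXICILLIN"],
            "role_cod": ["PS", "C", "PS", "PS", "SS"]}, dtype=object)
        out, _ = normalize_drugs(drug, dictionary)
        exposures = primary_suspect_exposures(out)
        assert exposures == {"1": {"ceftriaxone"}, "2": {"ceftriaxone"}}
        assert "3" not in exposures  # SS-only report is not exposed

    def test_matches_generator_assignments(self, noise_free_synthetic):
        cfg, ts, gt = noise_free_synthetic
        clean = clean_table_set(ts, gt.dictionary())
        exposures = primary_suspect_exposures(clean.drugs)
        for spec in cfg.drugs:
            expected = set(
                gt.report.loc[gt.report[f"exposed_{spec.ingredient}"],
                              "primaryid"])
            got = {pid for pid, ings in exposures.items()
                   if spec.ingredient in ings}
            assert got == expected


class TestAssignClass:
    @pytest.mark.parametrize("ingredient, cls", [
        ("lincomycin", "lincomycins"),
        ("ceftriaxone", "third-generation cephalosporins"),
        ("cefazolin", "first/second-generation cephalosporins"),
        ("amoxicillin-clavulanate", "beta-lactamase inhibitors"),
        ("fluconazole", "antifungal drugs"),
        ("ibuprofen", None),
    ])
    def test_packaged_default_taxonomy(self, ingredient, cls):
        assert assign_class(ingredient, DrugDictionary.default()) == cls

    def test_default_dictionary_uses_only_the_fourteen_groups(self):
        d = DrugDictionary.default()
        assert set(d.ingredient_to_class.values()) <= set(ANTIBIOTIC_CLASSES)

    def test_duplicate_class_rows_rejected(self, tmp_path):
        p = tmp_path / "classes.csv"
        p.write_text("ingredient,class\nfoo,penicillins\nFOO,carbapenems\n")
        with pytest.raises(ConfigurationError):
            DrugDictionary.from_files(None, p)


class TestCleanTableSet:
    def test_children_restricted_and_attrition_consistent(self, small_synthetic):
        cfg, ts, gt = small_synthetic
        clean = clean_table_set(ts, gt.dictionary())
        a = clean.attrition
        assert a["demo_rows_in"] == a["reports_kept"] + a["duplicates_removed"]
        kept = set(clean.reports["primaryid"])
        for frame in (clean.drugs, clean.reactions, clean.outcomes,
                      clean.therapies):
            assert set(frame["primaryid"].astype(str)) <= kept
        for t in ("drug", "reac", "outc", "ther"):
            assert a[f"{t}_rows_kept"] + a[f"{t}_rows_dropped"] == len(ts.table(t))
        assert clean.reports["caseid"].is_unique

    def test_year_range_filter(self, small_synthetic):
        _, ts, gt = small_synthetic
        clean = clean_table_set(ts, gt.dictionary(), year_range=(2010, 2015))
        years = clean.reports["year"].dropna().astype(int)
        assert years.between(2010, 2015).all()
        with pytest.raises(ConfigurationError):
            clean_table_set(ts, gt.dictionary(), year_range=(2020, 2010))
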