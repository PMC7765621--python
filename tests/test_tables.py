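"""Ingestion, deduplication, merging and BMI cleaning of report tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jaderpv import (clean_bmi, deduplicate, filter_suspected, generate,
                     merge_cases, read_jader_table, recode_weight,
                     write_jader_table)
from jaderpv.errors import ConfigurationError, DataIntegrityError, SchemaError
from jaderpv.simulate import SynthConfig
from jaderpv.tables import parse_age, read_cases_csv, write_cases_csv

from conftest import make_cases


def write_csv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadJaderTable:
    def test_parses_one_row_per_involvement_category(self, tmp_path):
        p = write_csv(tmp_path, "drug.csv",
                      "case_id,drug_name,involvement\n"
                      "C1,alendronate,suspected\n"
                      "C1,omeprazole,concomitant\n"
                      "C2,warfarin,interaction\n")
        df = read_jader_table(p, "DRUG")
        assert len(df) == 3
        assert list(df["involvement"]) == ["suspected", "concomitant", "interaction"]

    def test_blank_numeric_fields_become_missing_after_merge(self, tmp_path):
        p = write_csv(tmp_path, "demo.csv",
                      "case_id,sex,age,height,weight\nC1,female,70s,,52\n")
        demo = read_jader_table(p, "DEMO")
        cases = merge_cases(pd.DataFrame(columns=["case_id", "drug_name", "involvement"]),
                            pd.DataFrame(columns=["case_id", "pt_name"]), demo)
        assert np.isnan(cases.loc[0, "height_cm"])
        assert cases.loc[0, "weight_kg"] == 52.0
        assert cases.loc[0, "age_years"] == 75.0

    def test_header_mismatch_names_missing_column(self, tmp_path):
        p = write_csv(tmp_path, "drug.csv", "case_id,drug,involvement\nC1,x,suspected\n")
        with pytest.raises(SchemaError, match="drug_name"):
            read_jader_table(p, "DRUG")

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_jader_table(tmp_path / "nope.csv", "REAC")

    def test_column_map_translates_foreign_headers(self, tmp_path):
        p = write_csv(tmp_path, "reac.csv", "ID,PT\nC1,bone pain\n")
        df = read_jader_table(p, "REAC",
                              column_map={"REAC": {"ID": "case_id", "PT": "pt_name"}})
        assert list(df.columns) == ["case_id", "pt_name"]

    def test_generator_tables_round_trip(self, tmp_path):
        cfg = SynthConfig(n_cases=400, drugs={"a": 0.5, "b": 0.3},
                          events=["e1", "e2"], baseline_event_logit=-1.0,
                          duplicate_rate=0.1, concomitant_rate=0.2, seed=4)
        drug, reac, demo, _ = generate(cfg)
        for df, kind, name in [(drug, "DRUG", "d.csv"), (reac, "REAC", "r.csv"),
                               (demo, "DEMO", "m.csv")]:
            path = tmp_path / name
            write_jader_table(df, path, kind)
            back = read_jader_table(path, kind)
            pd.testing.assert_frame_equal(back, df.astype(str).where(df.notna(), ""),
                                          check_dtype=False)


class TestFilterAndDedup:
    def test_keeps_only_suspected_rows(self):
        df = pd.DataFrame({
            "case_id": ["C1"] * 3,
            "drug_name": ["a", "b", "c"],
            "involvement": ["suspected", "concomitant", "interaction"],
        })
        out = filter_suspected(df)
        assert list(out["drug_name"]) == ["a"]

    def test_empty_input_gives_empty_output(self):
        df = pd.DataFrame(columns=["case_id", "drug_name", "involvement"])
        assert len(filter_suspected(df)) == 0

    def test_filter_count_matches_direct_scan(self):
        rng = np.random.default_rng(0)
        inv = rng.choice(["suspected", "concomitant", "interaction"], size=100)
        df = pd.DataFrame({"case_id": [f"C{i}" for i in range(100)],
                           "drug_name": "x", "involvement": inv})
        assert len(filter_suspected(df)) == int((inv == "suspected").sum())

    def test_exact_duplicates_collapse(self):
        df = pd.DataFrame({"case_id": ["C1", "C1"], "drug_name": ["a", "a"],
                           "involvement": ["suspected", "suspected"]})
        assert len(deduplicate(df, "DRUG")) == 1

    def test_within_case_repeated_term_collapses(self):
        df = pd.DataFrame({"case_id": ["C1", "C1"], "pt_name": ["bone pain", "bone pain"]})
        assert len(deduplicate(df, "REAC")) == 1

    @given(st.lists(st.tuples(st.sampled_from(["C1", "C2", "C3"]),
                              st.sampled_from(["a", "b", "c"])), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_deduplicate_is_idempotent_and_subset(self, pairs):
        df = pd.DataFrame(pairs, columns=["case_id", "pt_name"])
        once = deduplicate(df, "REAC")
        twice = deduplicate(once, "REAC")
        pd.testing.assert_frame_equal(once, twice)
        merged = once.merge(df.drop_duplicates(), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestMergeCases:
    def test_aggregates_drugs_and_events_into_sets(self):
        drug = pd.DataFrame({"case_id": ["C1", "C1"], "drug_name": ["a", "b"],
                             "involvement": ["suspected"] * 2})
        reac = pd.DataFrame({"case_id": ["C1"] * 3, "pt_name": ["e1", "e2", "e3"]})
        demo = pd.DataFrame({"case_id": ["C1"], "sex": ["female"], "age": ["70s"],
                             "height": ["150"], "weight": ["50"]})
        cases = merge_cases(drug, reac, demo)
        assert len(cases) == 1
        assert cases.loc[0, "suspected_drugs"] == frozenset({"a", "b"})
        assert cases.loc[0, "events"] == frozenset({"e1", "e2", "e3"})
        assert cases.loc[0, "bmi"] == pytest.approx(50 / 1.5 ** 2)

    def test_case_only_in_demo_gets_empty_sets(self):
        demo = pd.DataFrame({"case_id": ["C9"], "sex": ["male"], "age": ["40"],
                             "height": [""], "weight": [""]})
        cases = merge_cases(pd.DataFrame(columns=["case_id", "drug_name", "involvement"]),
                            pd.DataFrame(columns=["case_id", "pt_name"]), demo)
        assert cases.loc[0, "suspected_drugs"] == frozenset()
        assert cases.loc[0, "events"] == frozenset()

    def test_duplicate_case_id_in_demo_is_integrity_error(self):
        demo = pd.DataFrame({"case_id": ["C1", "C1"], "sex": ["male"] * 2,
                             "age": ["40"] * 2, "height": [""] * 2, "weight": [""] * 2})
        with pytest.raises(DataIntegrityError):
            merge_cases(pd.DataFrame(columns=["case_id", "drug_name", "involvement"]),
                        pd.DataFrame(columns=["case_id", "pt_name"]), demo)

    def test_set_sizes_match_generator_ground_truth(self):
        cfg = SynthConfig(n_cases=500, drugs={"a": 0.4, "b": 0.2},
                          events=["e1", "e2"], baseline_event_logit=0.0, seed=9)
        drug, reac, demo, truth = generate(cfg)
        cases = merge_cases(deduplicate(filter_suspected(drug), "DRUG"),
                            deduplicate(reac, "REAC"), demo)
        cases = cases.set_index("case_id")
        n_drugs = truth.exposure.sum(axis=1)
        n_events = truth.event_ind.sum(axis=1)
        for cid in cases.index:
            assert len(cases.loc[cid, "suspected_drugs"]) == n_drugs[cid]
            assert len(cases.loc[cid, "events"]) == n_events[cid]


@pytest.mark.parametrize("raw,expected", [
    (">60 kg", 65.0), ("<10 kg", 5.0), (">60", 65.0), ("<10", 5.0),
    ("52", 52.0), (52, 52.0), ("52.5", 52.5),
    ("unknown", np.nan), ("", np.nan), (None, np.nan),
])
def test_recode_weight(raw, expected):
    got = recode_weight(raw)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == expected


@pytest.mark.parametrize("raw,expected", [
    ("70s", 75.0), ("10s", 15.0), ("75", 75.0), ("0", 0.0),
    ("", np.nan), ("adult", np.nan), (None, np.nan),
])
def test_parse_age(raw, expected):
    got = parse_age(raw)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == expected


class TestCleanBmi:
    def bmi_cases(self, bmis):
        n = len(bmis)
        df = make_cases([((), ())] * n)
        df["bmi"] = bmis
        return df

    def test_boundaries(self):
        cases = self.bmi_cases([4.9, 5.0, 99.9, 100.0, np.nan])
        kept, rep = clean_bmi(cases)
        assert rep.n_removed_low_bmi == 1      # 4.9 < 5
        assert rep.n_removed_high_bmi == 1     # 100.0 is removed (>= bound)
        assert rep.n_output == 3               # missing BMI is kept
        assert set(kept["bmi"].dropna()) == {5.0, 99.9}

    def test_study_scale_removal_counts(self):
        cases = self.bmi_cases([3.0] * 8 + [120.0] * 1164 + [22.0] * 10)
        _, rep = clean_bmi(cases)
        assert rep.n_removed_low_bmi + rep.n_removed_high_bmi == 1172
        assert rep.n_output == 10

    @given(st.lists(st.one_of(st.floats(0.1, 200), st.none()), max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, bmis):
        cases = self.bmi_cases([np.nan if b is None else b for b in bmis])
        _, rep = clean_bmi(cases)
        assert rep.n_input == rep.n_output + rep.n_removed_low_bmi + rep.n_removed_high_bmi

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError):
            clean_bmi(self.bmi_cases([20.0]), low=50, high=50)


def test_cases_csv_round_trip(tmp_path, study_cases):
    sample = study_cases.head(200)
    write_cases_csv(sample, tmp_path / "cases.csv")
    back = read_cases_csv(tmp_path / "cases.csv")
    assert list(back["suspected_drugs"]) == list(sample["suspected_drugs"])
    assert list(back["events"]) == list(sample["events"])
    np.testing.assert_allclose(back["bmi"], sample["bmi"])
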