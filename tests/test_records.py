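"""Record ingest, consolidation and inclusion filters."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equamu.records import (apply_inclusion_filters, compute_age,
                            consolidate_consultations, read_horses,
                            read_records)

from conftest import make_records


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadRecords:
    def test_empty_file_with_header(self, tmp_path):
        p = _write(tmp_path, "r.csv",
                   "practice_id,horse_id,date,item_kind,anamnesis_text,"
                   "diagnosis_text,description_text,product_id,quantity\n")
        recs, rep = read_records(p)
        assert len(recs) == 0 and rep.n_errors == 0

    def test_well_formed_rows_preserved(self, tmp_path):
        p = _write(tmp_path, "r.csv", "\n".join([
            "practice_id,horse_id,date,item_kind,anamnesis_text,"
            "diagnosis_text,description_text,product_id,quantity",
            "P1,H1,2020-01-02,procedure,husten,,,,",
            "P1,H1,2020-01-02,pharmaceutical,,,,EQ001,2",
            "P2,H9,2021-06-30,other,kontrolle,,,,",
        ]) + "\n")
        recs, rep = read_records(p)
        assert rep.n_errors == 0 and len(recs) == 3
        assert recs.loc[0, "anamnesis_text"] == "husten"
        assert recs.loc[1, "product_id"] == "EQ001"
        assert recs.loc[1, "quantity"] == 2.0
        assert recs.loc[2, "date"] == date(2021, 6, 30)

    def test_malformed_date_is_counted_not_dropped_silently(self, tmp_path):
        p = _write(tmp_path, "r.csv", "\n".join([
            "practice_id,horse_id,date,item_kind,anamnesis_text,"
            "diagnosis_text,description_text,product_id,quantity",
            "P1,H1,2018-13-40,procedure,,,,,",
        ]) + "\n")
        recs, rep = read_records(p)
        assert len(recs) == 0
        assert rep.n_errors == 1 and "date" in rep.errors[0][1]

    def test_missing_horse_id_rejected_with_count(self, tmp_path):
        p = _write(tmp_path, "r.csv", "\n".join([
            "practice_id,horse_id,date,item_kind,anamnesis_text,"
            "diagnosis_text,description_text,product_id,quantity",
            "P1,,2020-01-02,procedure,,,,,",
            "P1,H1,2020-01-02,pharmaceutical,,,,,",  # pharma without product
        ]) + "\n")
        recs, rep = read_records(p)
        assert len(recs) == 0 and rep.n_errors == 2

    def test_column_mapping_adapts_foreign_headers(self, tmp_path):
        p = _write(tmp_path, "r.csv", "\n".join([
            "Praxis;Pferd;Datum;Art;Text",
            "P1;H1;2020-01-02;procedure;lahmheit",
        ]) + "\n")
        recs, rep = read_records(p, column_map={
            "practice_id": "Praxis", "horse_id": "Pferd", "date": "Datum",
            "item_kind": "Art", "anamnesis_text": "Text"}, sep=";")
        assert rep.n_errors == 0 and len(recs) == 1
        assert recs.loc[0, "anamnesis_text"] == "lahmheit"

    def test_horses_reader_rejects_birth_after_death(self, tmp_path):
        p = _write(tmp_path, "h.csv", "\n".join([
            "practice_id,horse_id,birth_date,death_date",
            "P1,H1,2020-01-01,2010-01-01",
        ]) + "\n")
        with pytest.raises(ValueError):
            read_horses(p)


class TestConsolidation:
    def test_empty_input(self):
        out = consolidate_consultations(make_records([]))
        assert len(out) == 0

    def test_same_day_records_merge(self):
        recs = make_records([
            ("P1", "H1", "2020-01-02", "procedure", "husten", None),
            ("P1", "H1", "2020-01-02", "pharmaceutical", "", "EQ001"),
        ])
        out = consolidate_consultations(recs)
        assert len(out) == 1
        assert out.loc[0, "n_records"] == 2
        assert out.loc[0, "combined_text"] == "husten"

    def test_grouping_matches_brute_force(self):
        recs = make_records([
            ("P1", "A", "2020-01-01", "procedure", "a", None),
            ("P1", "A", "2020-01-01", "other", "b", None),
            ("P1", "A", "2020-01-02", "procedure", "c", None),
            ("P1", "B", "2020-01-01", "procedure", "d", None),
            ("P1", "B", "2020-01-01", "other", "e", None),
        ])
        out = consolidate_consultations(recs)
        sizes = dict(zip(zip(out["horse_id"], out["date"].astype(str)),
                         out["n_records"]))
        assert sizes == {("A", "2020-01-01"): 2, ("A", "2020-01-02"): 1,
                         ("B", "2020-01-01"): 2}

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(
        st.sampled_from(["P1", "P2"]),
        st.sampled_from(["H1", "H2", "H3"]),
        st.sampled_from(["2020-01-01", "2020-01-02", "2020-02-01"]),
        st.sampled_from(["a", "b", ""])), max_size=30))
    def test_partition_property(self, rows):
        recs = make_records([(p, h, d, "procedure", t, None)
                             for p, h, d, t in rows])
        out = consolidate_consultations(recs)
        assert out["n_records"].sum() == len(recs)
        assert not out.duplicated(
            subset=["practice_id", "horse_id", "date"]).any()
        # idempotence on singleton re-consolidation of the consultation keys
        again = consolidate_consultations(make_records(
            [(r.practice_id, r.horse_id, str(r.date), "procedure",
              r.combined_text, None) for r in out.itertuples()]))
        assert len(again) == len(out)


class TestInclusionFilters:
    def _one_practice(self, n_horses):
        return pd.DataFrame({
            "practice_id": "P1",
            "horse_id": [f"H{i}" for i in range(n_horses)],
            "date": date(2020, 5, 1), "n_records": 1, "combined_text": "",
        })

    def test_practice_below_minimum_removed_and_reported(self):
        cons, rep = apply_inclusion_filters(self._one_practice(99),
                                            min_patients=100)
        assert len(cons) == 0 and rep.practices_excluded == ["P1"]

    def test_minimum_is_inclusive(self):
        cons, rep = apply_inclusion_filters(self._one_practice(100),
                                            min_patients=100)
        assert len(cons) == 100 and rep.practices_excluded == []

    def test_window_excludes_out_of_range_dates(self):
        df = self._one_practice(3)
        df.loc[0, "date"] = date(2017, 12, 31)
        cons, rep = apply_inclusion_filters(df, min_patients=1)
        assert rep.n_records_excluded_by_date == 1
        assert len(cons) == 2

    def test_raising_min_patients_never_adds_consultations(self):
        df = pd.concat([self._one_practice(50),
                        self._one_practice(50).assign(practice_id="P2")])
        sizes = [len(apply_inclusion_filters(df, min_patients=m)[0])
                 for m in (1, 25, 50, 51, 100)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_window_is_fatal(self):
        with pytest.raises(ValueError):
            apply_inclusion_filters(self._one_practice(5),
                                    window=(date(2020, 1, 2), date(2020, 1, 1)))


class TestComputeAge:
    def _horses(self, birth):
        return pd.DataFrame({"practice_id": ["P1"], "horse_id": ["H1"],
                             "birth_date": [birth]})

    def _cons(self, day):
        return pd.DataFrame({"practice_id": ["P1"], "horse_id": ["H1"],
                             "date": [day]})

    def test_ten_year_old(self):
        out = compute_age(self._cons(date(2020, 1, 1)),
                          self._horses(date(2010, 1, 1)))
        assert out.loc[0, "age_years"] == pytest.approx(10.0, abs=0.01)
        assert bool(out.loc[0, "age_plausible"])

    def test_missing_birth_date(self):
        out = compute_age(self._cons(date(2020, 1, 1)), self._horses(None))
        assert pd.isna(out.loc[0, "age_years"])
        assert not bool(out.loc[0, "age_plausible"])

    def test_negative_age_flagged_implausible(self):
        out = compute_age(self._cons(date(2019, 1, 1)),
                          self._horses(date(2020, 1, 1)))
        assert out.loc[0, "age_years"] < 0
        assert not bool(out.loc[0, "age_plausible"])
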