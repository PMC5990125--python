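"""Table readers/writers: round trips, schema validation, layout dialects."""

import logging

import numpy as np
import pandas as pd
import pytest

from hybridms import records_io
from hybridms.errors import MonotonicityError, SchemaError, ValidationError


@pytest.fixture()
def outcomes_df(rng):
    n = 40
    t720 = (rng.uniform(size=n) < 0.4).astype(int)
    t360 = t720 * (rng.uniform(size=n) < 0.6).astype(int)
    t180 = t360 * (rng.uniform(size=n) < 0.5).astype(int)
    return pd.DataFrame({"T_180": t180, "T_360": t360, "T_720": t720},
                        index=pd.Index(np.arange(n), name="record_id"))


@pytest.fixture()
def ratings_df():
    rows = [(r, rec, h, (len(r) + rec + h) % 6)
            for r in ("s1", "s22", "s333")
            for rec in range(10)
            for h in (180, 360, 720)]
    return pd.DataFrame(rows, columns=records_io.RATING_COLS)


class TestOutcomes:
    def test_round_trip_identity(self, outcomes_df, tmp_path):
        p = tmp_path / "outcomes.csv"
        records_io.write_outcomes(outcomes_df, p)
        back = records_io.read_outcomes(p)
        pd.testing.assert_frame_equal(back, outcomes_df.astype(np.int8))

    def test_three_row_monotone_fixture_is_clean(self, tmp_path, caplog):
        df = pd.DataFrame([(0, 0, 0, 0), (1, 0, 1, 1), (2, 1, 1, 1)],
                          columns=["record_id", "T_180", "T_360", "T_720"])
        p = tmp_path / "o.csv"
        df.to_csv(p, index=False)
        with caplog.at_level(logging.WARNING):
            back = records_io.read_outcomes(p)
        assert len(back) == 3
        assert not caplog.records

    def test_missing_column_schema_error_names_column(self, tmp_path):
        p = tmp_path / "o.csv"
        pd.DataFrame({"record_id": [0], "T_180": [0], "T_360": [0]}).to_csv(
            p, index=False)
        with pytest.raises(SchemaError, match="T_720"):
            records_io.read_outcomes(p)

    def test_empty_file_schema_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(SchemaError):
            records_io.read_outcomes(p)

    def test_non_binary_label_names_record(self, tmp_path):
        p = tmp_path / "o.csv"
        pd.DataFrame({"record_id": [5], "T_180": [2], "T_360": [1],
                      "T_720": [1]}).to_csv(p, index=False)
        with pytest.raises(ValidationError, match="5"):
            records_io.read_outcomes(p)

    def test_monotonicity_violations_flag_exact_records(self, outcomes_df,
                                                        tmp_path, caplog):
        planted = [3, 17]
        bad = outcomes_df.copy()
        bad.loc[planted, ["T_180", "T_360", "T_720"]] = [1, 0, 1]
        p = tmp_path / "o.csv"
        records_io.write_outcomes(bad, p)
        with caplog.at_level(logging.WARNING):
            records_io.read_outcomes(p)
        assert any(str(planted) in rec.message or "2 record" in rec.message
                   for rec in caplog.records)
        with pytest.raises(MonotonicityError) as exc:
            records_io.read_outcomes(p, on_violation="raise")
        assert exc.value.record_ids == planted

    def test_xlsx_dialect(self, outcomes_df, tmp_path):
        p = tmp_path / "o.xlsx"
        outcomes_df.reset_index().to_excel(p, index=False)
        back = records_io.read_outcomes(p)
        pd.testing.assert_frame_equal(back, outcomes_df.astype(np.int8))


class TestHumanPredictions:
    def test_long_csv_round_trip(self, ratings_df, tmp_path):
        p = tmp_path / "r.csv"
        records_io.write_human_predictions(ratings_df, p)
        back = records_io.read_human_predictions(p)
        pd.testing.assert_frame_equal(
            back.astype({"score": int}), ratings_df.astype({"score": int}))

    def test_out_of_range_score_rejected(self, ratings_df, tmp_path):
        bad = ratings_df.copy()
        bad.loc[0, "score"] = 6
        p = tmp_path / "r.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="0..5"):
            records_io.read_human_predictions(p)

    def test_duplicate_rating_rejected(self, ratings_df, tmp_path):
        dup = pd.concat([ratings_df, ratings_df.iloc[[0]]])
        p = tmp_path / "r.csv"
        dup.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            records_io.read_human_predictions(p)

    def test_questionnaire_block_layout(self, tmp_path):
        """A spreadsheet of per-rater blocks parses to the same ratings as a
        brute-force reading of the blocks."""
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        expected = []
        row = 1
        for q, (rater, recs) in enumerate(
                [("q1", [3, 1, 4]), ("q2", [1, 5, 9])], start=1):
            ws.cell(row=row, column=1, value="questionnaire")
            ws.cell(row=row, column=2, value=rater)
            ws.cell(row=row + 1, column=1, value="Clinical report N")
            for j, rec in enumerate(recs):
                ws.cell(row=row + 1, column=2 + j, value=rec)
            for k, h in enumerate((180, 360, 720)):
                ws.cell(row=row + 2 + k, column=1, value=f"Prediction @ {h}")
                for j, rec in enumerate(recs):
                    score = (q + j + k) % 6
                    ws.cell(row=row + 2 + k, column=2 + j, value=score)
                    expected.append((rater, rec, h, score))
            row += 6
        p = tmp_path / "blocks.xlsx"
        wb.save(p)
        back = records_io.read_human_predictions(p)
        exp = pd.DataFrame(expected, columns=records_io.RATING_COLS)
        merged = back.merge(exp, on=["rater_id", "record_id", "horizon"],
                            suffixes=("", "_exp"))
        assert len(merged) == len(exp)
        assert (merged["score"] == merged["score_exp"]).all()

    def test_shared_record_counted_once_per_questionnaire(self, tmp_path):
        """A record appearing in k questionnaires contributes exactly k
        ratings per horizon (brute-force count over the fixture)."""
        raters = ["a", "b", "c", "d"]
        rows = [(r, 99, h, 2) for r in raters for h in (180, 360, 720)]
        rows += [("a", 1, 180, 3)]
        p = tmp_path / "r.csv"
        pd.DataFrame(rows, columns=records_io.RATING_COLS).to_csv(p, index=False)
        back = records_io.read_human_predictions(p)
        per_h = back[back.record_id == 99].groupby("horizon").size()
        assert (per_h == len(raters)).all()

    def test_all_zero_questionnaire(self, tmp_path):
        rows = [("q", rec, h, 0) for rec in range(50) for h in (180, 360, 720)]
        p = tmp_path / "r.csv"
        pd.DataFrame(rows, columns=records_io.RATING_COLS).to_csv(p, index=False)
        back = records_io.read_human_predictions(p)
        assert len(back) == 150 and (back.score == 0).all()


class TestEnsemblePredictions:
    def test_round_trip_identity(self, rng, tmp_path):
        df = pd.DataFrame(rng.uniform(size=(20, 3)),
                          columns=records_io.SCORE_COLS,
                          index=pd.Index(np.arange(20), name="record_id"))
        p = tmp_path / "s.csv"
        records_io.write_ensemble_predictions(df, p)
        back = records_io.read_ensemble_predictions(p)
        pd.testing.assert_frame_equal(back, df)

    def test_single_row_boundary_values(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({"record_id": [0], "Score_180": [0.0], "Score_360": [0.5],
                      "Score_720": [1.0]}).to_csv(p, index=False)
        back = records_io.read_ensemble_predictions(p)
        assert back.loc[0].tolist() == [0.0, 0.5, 1.0]

    def test_probability_out_of_range_names_record(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({"record_id": [7], "Score_180": [1.2], "Score_360": [0.5],
                      "Score_720": [0.9]}).to_csv(p, index=False)
        with pytest.raises(ValidationError, match="7"):
            records_io.read_ensemble_predictions(p)


class TestResultsTable:
    def test_one_agent_three_horizons(self, tmp_path):
        res = pd.DataFrame({"agent": ["rf"] * 3, "horizon": [180, 360, 720],
                            "auc": [0.71, 0.67, 0.679]})
        p = tmp_path / "res.csv"
        records_io.write_results_table(res, p)
        back = records_io.read_results_table(p)
        assert back.shape == (1, 3)
        assert back.loc["rf", "auc_360"] == 0.67

    def test_empty_results_error(self, tmp_path):
        with pytest.raises(ValidationError):
            records_io.write_results_table(pd.DataFrame(), tmp_path / "x.csv")

    def test_round_trip_full_precision(self, tmp_path):
        res = pd.DataFrame({
            "agent": ["a", "a", "b", "b"], "horizon": [180, 360, 180, 360],
            "auc": [0.123456789012, 0.5, 0.7, 0.9],
            "ci_lower": [0.1, 0.4, 0.6, 0.8], "ci_upper": [0.2, 0.6, 0.8, 1.0]})
        p = tmp_path / "res.csv"
        records_io.write_results_table(res, p)
        back = records_io.read_results_table(p)
        assert back.loc["a", "auc_180"] == 0.123456789012
        assert back.loc["b", "ci_upper_360"] == 1.0
        assert list(back.index) == ["a", "b"]
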