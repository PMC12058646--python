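import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from terrapop.encounter_io import (
    EncounterHistorySet,
    EncounterValidationError,
    Individual,
    Occasion,
    body_condition,
    read_encounter_csv,
    read_mark_inp,
    summarize,
    write_encounter_csv,
    write_mark_inp,
)

from conftest import make_set


class TestValidation:
    def test_parses_simple_histories(self, three_occasion_set):
        assert len(three_occasion_set.individuals) == 3
        assert three_occasion_set.n_occasions == 3

    def test_all_zero_history_rejected(self):
        with pytest.raises(EncounterValidationError, match="all-zero"):
            Individual("x", "female", (0, 0, 0))

    def test_unknown_sex_rejected(self):
        with pytest.raises(EncounterValidationError, match="sex"):
            Individual("x", "hermit", (1, 0))

    def test_duplicate_id_rejected(self):
        occ = [Occasion(2001), Occasion(2002)]
        inds = [Individual("a", "female", (1, 0)), Individual("a", "male", (0, 1))]
        with pytest.raises(EncounterValidationError, match="duplicate"):
            EncounterHistorySet(occ, inds)

    def test_years_must_increase(self):
        with pytest.raises(EncounterValidationError, match="increasing"):
            EncounterHistorySet([Occasion(2002), Occasion(2001)], [])

    def test_interval_lengths_span_gaps(self):
        ehs = make_set(["11"], years=[2003, 2006])
        assert ehs.interval_lengths.tolist() == [3]


class TestCsvRoundTrip:
    def test_round_trip_identity(self, tmp_path, three_occasion_set):
        path = tmp_path / "enc.csv"
        write_encounter_csv(three_occasion_set, path)
        back = read_encounter_csv(path)
        assert [i.detections for i in back.individuals] == [
            i.detections for i in three_occasion_set.individuals
        ]
        assert [i.sex for i in back.individuals] == [
            i.sex for i in three_occasion_set.individuals
        ]
        assert back.years == three_occasion_set.years

    def test_bad_symbol_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,sex,y2001,y2002\na,female,1,2\n")
        with pytest.raises(EncounterValidationError, match="y2002"):
            read_encounter_csv(path)

    def test_morphometrics_preserved(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "id,sex,y2001,y2002,pl_cm,mass_g,measure_year\n"
            "a,female,1,1,14.2,760.0,2001\n"
        )
        ehs = read_encounter_csv(path)
        m = ehs.individuals[0].morphometrics[0]
        assert (m.occasion_index, m.plastron_length_cm, m.mass_g) == (0, 14.2, 760.0)


class TestMarkInp:
    def test_format_lines(self, tmp_path):
        ehs = make_set(["101", "011"], sexes=["female", "male"])
        path = tmp_path / "out.inp"
        write_mark_inp(ehs, path)
        lines = [l for l in path.read_text().splitlines() if l.endswith(";")]
        assert lines[0].endswith("101 1 0;")
        assert lines[1].endswith("011 0 1;")

    def test_empty_set_header_only(self, tmp_path):
        ehs = EncounterHistorySet([Occasion(2001), Occasion(2002)], [])
        path = tmp_path / "empty.inp"
        write_mark_inp(ehs, path)
        assert all(not l.endswith(";") for l in path.read_text().splitlines())

    def test_round_trip(self, tmp_path):
        ehs = make_set(
            ["1100", "0110", "1011"],
            sexes=["female", "male", "female"],
            years=[2001, 2002, 2004, 2005],
            effort=[3.0, 1.5, 2.0, 4.0],
            hurricane=[False, False, True, False],
        )
        path = tmp_path / "rt.inp"
        write_mark_inp(ehs, path)
        back = read_mark_inp(path)
        assert back.years == ehs.years
        assert [o.effort_hours for o in back.occasions] == [
            o.effort_hours for o in ehs.occasions
        ]
        assert [o.hurricane for o in back.occasions] == [
            o.hurricane for o in ehs.occasions
        ]
        assert [(i.sex, i.detections) for i in back.individuals] == [
            (i.sex, i.detections) for i in ehs.individuals
        ]


class TestSummarize:
    def test_hand_count(self, three_occasion_set):
        tab = summarize(three_occasion_set).table
        # histories 101, 011, 110: occasion 2 has captures {011,110}, one recapture
        row = tab.iloc[1]
        assert row.captures == 2
        assert row.recaptures == 1
        assert row.recapture_rate == 0.5

    def test_first_occasion_no_recaptures(self, three_occasion_set):
        assert summarize(three_occasion_set).table.iloc[0].recapture_rate == 0.0

    @given(st.lists(st.sampled_from(["101", "011", "110", "111", "100"]), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_totals_permutation_invariant_and_consistent(self, hists, rnd):
        ehs = make_set(hists, sexes=["female" if i % 2 else "male" for i in range(len(hists))])
        tab = summarize(ehs).table
        assert (tab["new"] + tab["recaptures"] == tab["captures"]).all()
        shuffled = list(zip(hists, [i.sex for i in ehs.individuals]))
        rnd.shuffle(shuffled)
        ehs2 = make_set([h for h, _ in shuffled], sexes=[s for _, s in shuffled])
        tab2 = summarize(ehs2).table
        pd.testing.assert_frame_equal(tab, tab2)

    def test_final_occasion_recapture_rate_matches_expectation(self):
        # constant phi, p: expected recapture rate at the last of 5 occasions
        # computed by conditioning on survival from release
        from terrapop.synthetic_data import constant_template, simulate_capture_histories

        phi, p, n = 0.8, 0.5, 2000
        tpl = constant_template(5, n, phi, p)
        ehs = simulate_capture_histories(tpl, seed=42)
        tab = summarize(ehs).table
        # all marked animals entered before the final occasion, so every
        # detection there is a recapture
        assert tab.iloc[-1].recapture_rate == 1.0
        # expected captures at the final occasion: sum over cohorts of
        # n_cohort * phi^(dt to end) * p
        per = n // 4
        expected = sum(per * phi ** (4 - e) * p for e in range(4))
        se = np.sqrt(sum(per * phi ** (4 - e) * p * (1 - phi ** (4 - e) * p) for e in range(4)))
        assert abs(tab.iloc[-1].captures - expected) < 3 * se


class TestBodyCondition:
    @staticmethod
    def _dataset(rng, n_per=500, shift=0.0, noise=0.1):
        pl = rng.uniform(10, 19, size=2 * n_per)
        year = np.r_[np.full(n_per, 2010), np.full(n_per, 2016)]
        logm = 2.0 + 0.1 * pl + noise * rng.standard_normal(2 * n_per)
        logm[n_per:] += shift
        return pd.DataFrame({"year": year, "pl_cm": pl, "mass_g": np.exp(logm)})

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            body_condition(self._dataset(rng, n_per=500), 2014).period_pvalue < 0.05
            for _ in range(200)
        )
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rejections / 200 - 0.05) < 1.96 * se + 1e-12

    def test_exact_line_gives_zero_effects(self):
        rng = np.random.default_rng(1)
        df = self._dataset(rng, n_per=50, noise=0.0)
        res = body_condition(df, 2014)
        assert abs(res.period_coef) < 1e-10
        assert abs(res.interaction_coef) < 1e-10

    def test_known_offset_recovered(self):
        rng = np.random.default_rng(3)
        df = self._dataset(rng, n_per=1000, shift=0.2)
        res = body_condition(df, 2014)
        assert abs(res.period_coef - 0.2) < 2 * res.period_se

    def test_empty_period_errors(self):
        rng = np.random.default_rng(5)
        df = self._dataset(rng, n_per=20)
        with pytest.raises(EncounterValidationError, match="period"):
            body_condition(df[df.year <= 2014], 2014)
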