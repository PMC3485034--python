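"""Grading filters, recall-bias adjustment, and series completion."""
import numpy as np
import pytest

from wuenic.config import Config
from wuenic.knowledge_base import (
    DataPoint,
    EstimateKey,
    SeriesPoint,
    SurveyDescription,
    SurveyResult,
    WorkingGroupDecision,
)
from wuenic.level1 import (
    REASON_GE100,
    REASON_SMALL_SAMPLE,
    REASON_SPIKE,
    REASON_WGD_ACCEPT,
    REASON_WGD_IGNORE,
    adjust_recall_bias,
    complete_reported_series,
    filter_reported,
    filter_surveys,
    interpolate,
    vaccine_dose,
)


def dp(year, coverage, country="egy", vaccine="dtp3", source="reported"):
    return DataPoint(EstimateKey(country, vaccine, year), source, coverage)


def desc(survey_id="s1", sample_size=1000, cohort=(12, 23), **kw):
    return SurveyDescription(
        survey_id=survey_id, title="t", survey_type="DHS", collection_year=2008,
        percent_cards_seen=80.0, confirmation_method="either",
        cohort_min_months=cohort[0], cohort_max_months=cohort[1],
        sample_size=sample_size, **kw,
    )


def sr(year, coverage, survey_id="s1", vaccine="dtp3", card=None):
    return SurveyResult(
        EstimateKey("egy", vaccine, year), survey_id, coverage, coverage_card=card
    )


class TestFilterReported:
    def test_ordinary_point_accepted(self, config):
        [g] = filter_reported([dp(2004, 97.0)], [], config)
        assert g.is_accepted and g.coverage == 97.0

    @pytest.mark.parametrize("coverage,excluded", [
        (100.0, True),   # boundary: >= 100 is excluded
        (105.0, True),
        (99.9, False),
    ])
    def test_ge100_exclusion_boundary(self, coverage, excluded, config):
        [g] = filter_reported([dp(2004, coverage)], [], config)
        assert (g.status == "excluded") == excluded
        if excluded:
            assert g.reason_code == REASON_GE100

    def test_one_year_spike_excludes_the_outlying_year_only(self):
        cfg = Config(jump_threshold=25.0)
        graded = filter_reported(
            [dp(2000, 90.0), dp(2001, 45.0), dp(2002, 92.0)], [], cfg
        )
        by_year = {g.key.year: g for g in graded}
        assert by_year[2001].status == "excluded"
        assert by_year[2001].reason_code == REASON_SPIKE
        assert by_year[2000].is_accepted and by_year[2002].is_accepted

    def test_accept_decision_reinstates_spike_year(self):
        cfg = Config(jump_threshold=25.0)
        decision = WorkingGroupDecision(
            EstimateKey("egy", "dtp3", 2001), "acceptReported", None,
            "genuine decline, not a reporting artefact",
        )
        graded = filter_reported(
            [dp(2000, 90.0), dp(2001, 45.0), dp(2002, 92.0)], [decision], cfg
        )
        g = next(g for g in graded if g.key.year == 2001)
        assert g.is_accepted
        assert g.reason_code == REASON_WGD_ACCEPT
        assert g.reason_text == decision.explanation

    def test_ignore_decision_excludes_accepted_point(self, config):
        decision = WorkingGroupDecision(
            EstimateKey("egy", "dtp3", 2004), "ignoreReported", None,
            "denominator known to be wrong",
        )
        [g] = filter_reported([dp(2004, 97.0)], [decision], config)
        assert g.status == "excluded" and g.reason_code == REASON_WGD_IGNORE
        assert g.reason_text == decision.explanation

    def test_isolated_jump_flags_without_excluding_by_default(self, config):
        graded = filter_reported([dp(2000, 50.0), dp(2001, 80.0)], [], config)
        assert all(g.is_accepted for g in graded)
        assert all(g.reason_code == "jump_flagged" for g in graded)

    def test_isolated_jump_excluded_when_configured(self):
        cfg = Config(exclude_flagged_jumps=True)
        graded = filter_reported([dp(2000, 50.0), dp(2001, 80.0)], [], cfg)
        assert all(g.status == "excluded" for g in graded)

    def test_source_precedence_selects_one_point_per_year(self, config):
        graded = filter_reported(
            [dp(2004, 97.0, source="admin"), dp(2004, 95.0, source="gov")],
            [], config,
        )
        by_source = {g.origin.source: g for g in graded}
        assert by_source["gov"].is_accepted
        assert by_source["admin"].status == "excluded"

    def test_partition_every_input_appears_once(self, config):
        points = [dp(y, c) for y, c in [(2000, 90.0), (2001, 101.0), (2002, 88.0)]]
        points.append(dp(2001, 95.0, source="admin"))
        graded = filter_reported(points, [], config)
        assert sorted((g.origin for g in graded), key=lambda p: (p.key, p.source)) == \
            sorted(points, key=lambda p: (p.key, p.source))

    def test_empty_input_empty_output(self, config):
        assert filter_reported([], [], config) == []


class TestFilterSurveys:
    def test_sample_size_299_excluded_300_kept(self, config):
        descs = {"a": desc("a", sample_size=299), "b": desc("b", sample_size=300)}
        graded = filter_surveys(
            [sr(2004, 90.0, "a"), sr(2004, 91.0, "b")], descs, [], config
        )
        by_id = {g.origin.survey_id: g for g in graded}
        assert by_id["a"].status == "excluded"
        assert by_id["a"].reason_code == REASON_SMALL_SAMPLE
        assert by_id["b"].is_accepted

    def test_accept_decision_reinstates_small_survey(self, config):
        decision = WorkingGroupDecision(
            EstimateKey("egy", "dtp3", 2004), "acceptSurvey", None,
            "well-conducted despite small sample",
        )
        [g] = filter_surveys(
            [sr(2004, 90.0)], {"s1": desc(sample_size=299)}, [decision], config
        )
        assert g.is_accepted and g.reason_text == decision.explanation

    def test_cohort_outside_valid_range_excluded(self, config):
        [g] = filter_surveys(
            [sr(2004, 90.0)], {"s1": desc(cohort=(36, 59))}, [], config
        )
        assert g.status == "excluded" and g.reason_code == "cohort"

    def test_ignore_survey_decision_dominates(self, config):
        decision = WorkingGroupDecision(
            EstimateKey("egy", "dtp3", 2004), "ignoreSurvey", None,
            "cards kept at health centres, not homes",
        )
        [g] = filter_surveys([sr(2004, 90.0)], {"s1": desc()}, [decision], config)
        assert g.status == "excluded" and g.reason_code == REASON_WGD_IGNORE


class TestRecallBias:
    def test_dose1_never_adjusted(self, config):
        g = adjust_recall_bias(sr(2004, 90.0, vaccine="dtp1", card=85.0), [], config)
        assert g.status == "accepted"

    def test_card_history_ratio(self, config):
        # dose-3 card-only 80, dose-1 either 90, dose-1 card-only 85
        dose1 = sr(2004, 90.0, vaccine="dtp1", card=85.0)
        dose3 = sr(2004, 82.0, vaccine="dtp3", card=80.0)
        g = adjust_recall_bias(dose3, [dose1, dose3], config)
        assert g.status == "modified"
        assert g.adjusted_coverage == pytest.approx(80.0 * 90.0 / 85.0)
        assert g.coverage == pytest.approx(84.70588, abs=1e-4)

    def test_no_card_data_leaves_point_unchanged_with_reason(self, config):
        g = adjust_recall_bias(sr(2004, 82.0, vaccine="dtp3"), [], config)
        assert g.status == "accepted"
        assert "insufficient data" in g.reason_text

    def test_zero_dose1_card_guarded(self, config):
        dose1 = sr(2004, 90.0, vaccine="dtp1", card=0.0)
        dose3 = sr(2004, 82.0, vaccine="dtp3", card=80.0)
        g = adjust_recall_bias(dose3, [dose1, dose3], config)
        assert g.status == "accepted" and g.adjusted_coverage is None

    def test_vaccine_dose_parsing(self):
        assert vaccine_dose("dtp3") == ("dtp", 3)
        assert vaccine_dose("mcv") == ("mcv", 1)
        assert vaccine_dose("pol1") == ("pol", 1)


class TestSeriesCompletion:
    def test_interior_gap_and_ends(self, config):
        graded = filter_reported([dp(2004, 97.0), dp(2006, 85.0)], [], config)
        series, kind = complete_reported_series(graded, range(2003, 2008))
        assert {y: p.coverage for y, p in series.items()} == {
            2003: 97.0, 2004: 97.0, 2005: 91.0, 2006: 85.0, 2007: 85.0
        }
        assert kind == {
            2003: "extrapolated", 2004: "reported", 2005: "interpolated",
            2006: "reported", 2007: "extrapolated",
        }

    def test_single_point_constant_extrapolation(self, config):
        graded = filter_reported([dp(2005, 96.0)], [], config)
        series, _ = complete_reported_series(graded, [2004, 2005, 2006])
        assert {y: p.coverage for y, p in series.items()} == {
            2004: 96.0, 2005: 96.0, 2006: 96.0
        }

    def test_no_gaps_series_equals_accepted(self, config):
        graded = filter_reported([dp(2004, 97.0), dp(2005, 96.0)], [], config)
        series, kind = complete_reported_series(graded, [2004, 2005])
        assert {y: p.coverage for y, p in series.items()} == {2004: 97.0, 2005: 96.0}
        assert set(kind.values()) == {"reported"}

    def test_zero_accepted_points_gives_empty_series(self, config):
        graded = filter_reported([dp(2004, 102.0)], [], config)
        series, kind = complete_reported_series(graded, [2004])
        assert series == {} and kind == {}


class TestInterpolate:
    @pytest.mark.parametrize("before,after,year,expected", [
        ((2000, 80.0), (2004, 88.0), 2002, 84.0),
        ((2004, 97.0), (2006, 85.0), 2005, 91.0),
        ((2000, 77.0), (2005, 77.0), 2003, 77.0),
    ])
    def test_printed_formula(self, before, after, year, expected):
        assert interpolate(
            SeriesPoint(*before), SeriesPoint(*after), year
        ) == pytest.approx(expected)

    def test_agrees_with_two_point_line_fit(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            y1, gap = int(rng.integers(1990, 2010)), int(rng.integers(2, 15))
            year = int(rng.integers(y1 + 1, y1 + gap))
            p1, p2 = rng.uniform(0, 100, size=2)
            slope, intercept = np.polyfit([y1, y1 + gap], [p1, p2], 1)
            assert interpolate(
                SeriesPoint(y1, p1), SeriesPoint(y1 + gap, p2), year
            ) == pytest.approx(slope * year + intercept, abs=1e-9)

    def test_precondition_is_a_programming_error(self):
        with pytest.raises(AssertionError):
            interpolate(SeriesPoint(2005, 90.0), SeriesPoint(2004, 91.0), 2006)
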