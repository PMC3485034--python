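"""Series completion between and beyond anchors; calibration behaviour."""
import pytest

from wuenic.config import Config
from wuenic.knowledge_base import EstimateKey, SeriesPoint, WorkingGroupDecision
from wuenic.level2 import AnchorPoint
from wuenic.level3 import calibrate_segment, estimate_series, estimate_single_source
from wuenic.level1 import grade_country_vaccine
from wuenic.level2 import find_anchor_years
from wuenic.fixtures import egypt_fixture, scenario_figure3


def _run(kb, config):
    """Grade + anchors + level-3 for the single pair of a fixture."""
    (country, vaccine) = kb.required_pairs()[0]
    decisions = kb.decisions
    graded = grade_country_vaccine(kb, country, vaccine, config)
    anchors = find_anchor_years(graded, decisions, config, kb.survey_descriptions)
    return estimate_series(
        graded, anchors, decisions, kb.required_years(country, vaccine), config
    )


class TestCalibrateSegment:
    def test_constant_ratio_from_single_anchor(self, config):
        segment = [SeriesPoint(2000, 90.0), SeriesPoint(2001, 92.0), SeriesPoint(2002, 94.0)]
        out = calibrate_segment(segment, [(2002, 84.6)], config)
        assert [p.coverage for p in out] == pytest.approx([81.0, 82.8, 84.6])

    def test_identity_when_anchors_equal_reported(self, config):
        segment = [SeriesPoint(2000, 90.0), SeriesPoint(2001, 85.0), SeriesPoint(2002, 94.0)]
        out = calibrate_segment(segment, [(2000, 90.0), (2002, 94.0)], config)
        assert [p.coverage for p in out] == pytest.approx([90.0, 85.0, 94.0])

    def test_passes_exactly_through_both_anchor_estimates(self, config):
        segment = [SeriesPoint(y, 80.0 + y - 2000) for y in range(2000, 2006)]
        out = calibrate_segment(segment, [(2000, 60.0), (2005, 90.0)], config)
        by_year = {p.year: p.coverage for p in out}
        assert by_year[2000] == pytest.approx(60.0)
        assert by_year[2005] == pytest.approx(90.0)

    def test_zero_reported_at_anchor_falls_back_to_additive_shift(self, config):
        segment = [SeriesPoint(2000, 0.0), SeriesPoint(2001, 10.0)]
        out = calibrate_segment(segment, [(2000, 5.0)], config)
        assert [p.coverage for p in out] == pytest.approx([5.0, 15.0])

    def test_results_clamped_to_valid_range(self, config):
        segment = [SeriesPoint(2000, 95.0), SeriesPoint(2001, 50.0)]
        out = calibrate_segment(segment, [(2001, 99.0)], config)
        assert all(0 <= p.coverage <= 100 for p in out)

    def test_calibration_continuity_near_identity(self, config):
        """As the anchor estimate approaches the reported value, the
        calibrated segment approaches the reported series."""
        segment = [SeriesPoint(2000, 80.0), SeriesPoint(2001, 85.0), SeriesPoint(2002, 90.0)]
        for eps in (1.0, 0.1, 0.001):
            out = calibrate_segment(segment, [(2002, 90.0 + eps)], config)
            for p, q in zip(out, segment):
                assert abs(p.coverage - q.coverage) <= eps * (100 / 90)


class TestSingleSource:
    def test_passthrough_with_series_kind_codes(self, config):
        kb, _ = egypt_fixture("base")
        kb.surveys = []
        graded = grade_country_vaccine(kb, "egy", "dtp3", config)
        out = estimate_single_source(graded, [], [2004, 2005], config)
        assert [(e.key.year, e.value, e.code) for e in out] == [
            (2004, 97.0, "R"), (2005, 96.0, "R")
        ]

    def test_interpolated_year_keeps_value_with_code_i(self, config):
        kb, _ = egypt_fixture("base")
        kb.surveys = []
        kb.required = frozenset(
            EstimateKey("egy", "dtp3", y) for y in (2004, 2005, 2006, 2007)
        )
        kb.reported = [p for p in kb.reported if p.key.year != 2005] + [
            type(kb.reported[0])(EstimateKey("egy", "dtp3", 2007), "reported", 90.0)
        ]
        graded = grade_country_vaccine(kb, "egy", "dtp3", config)
        out = estimate_single_source(graded, [], [2004, 2005, 2006, 2007], config)
        codes = {e.key.year: e.code for e in out}
        assert codes == {2004: "R", 2005: "I", 2006: "I", 2007: "R"}

    def test_assign_decision_overrides_a_year(self, config):
        kb, _ = egypt_fixture("base")
        kb.surveys = []
        d = WorkingGroupDecision(
            EstimateKey("egy", "dtp3", 2005), "assignWUENIC", 90.0, "override"
        )
        graded = grade_country_vaccine(kb, "egy", "dtp3", config)
        out = estimate_single_source(graded, [d], [2004, 2005], config)
        by_year = {e.key.year: e for e in out}
        assert (by_year[2005].value, by_year[2005].code) == (90.0, "W")
        assert by_year[2004].code == "R"


class TestAroundAnchors:
    def test_scenario_between_and_beyond(self, config):
        kb, expected = scenario_figure3()
        out, gaps = _run(kb, config)
        assert gaps == []
        got = {e.key.year: (e.value, e.code) for e in out}
        for key, raw in expected.raw.items():
            assert got[key.year][0] == pytest.approx(raw, abs=1e-9)
            assert got[key.year][1] == expected.estimates[key][1]

    def test_anchor_fidelity_exact_before_rounding(self, config):
        kb, _ = scenario_figure3()
        (country, vaccine) = kb.required_pairs()[0]
        graded = grade_country_vaccine(kb, country, vaccine, config)
        anchors = find_anchor_years(graded, kb.decisions, config)
        out, _ = estimate_series(
            graded, anchors, kb.decisions,
            kb.required_years(country, vaccine), config,
        )
        by_year = {e.key.year: e.value for e in out}
        for a in anchors:
            assert by_year[a.key.year] == a.coverage

    def test_interpolate_decision_replaces_segment(self, config):
        kb, _ = scenario_figure3()
        kb.decisions = list(kb.decisions) + [
            WorkingGroupDecision(
                EstimateKey("exm", "dtp3", 2007), "interpolate", None,
                "bridge the shortage year",
            )
        ]
        out, _ = _run(kb, config)
        got = {e.key.year: (e.value, e.code) for e in out}
        # anchors 2005 (81) and 2009 (86): straight line between them
        for y in (2006, 2007, 2008):
            assert got[y][1] == "W:I"
            assert got[y][0] == pytest.approx(81.0 + (y - 2005) * 5.0 / 4.0)

    def test_gap_reported_when_no_data_at_all(self, config):
        kb, _ = egypt_fixture("base")
        kb.reported, kb.surveys, kb.decisions = [], [], []
        graded = grade_country_vaccine(kb, "egy", "dtp3", config)
        out, gaps = estimate_series(graded, [], [], [2004, 2005], config)
        assert out == []
        assert [k.year for k in gaps] == [2004, 2005]

    def test_anchor_only_path_without_reported_series(self, config):
        kb, _ = egypt_fixture("base")
        kb.reported = []
        kb.surveys = []
        decisions = [
            WorkingGroupDecision(
                EstimateKey("egy", "dtp3", 2004), "assignWUENIC", 80.0, "expert"
            )
        ]
        graded = grade_country_vaccine(kb, "egy", "dtp3", config)
        anchors = find_anchor_years(graded, decisions, config)
        out, gaps = estimate_series(graded, anchors, decisions, [2004, 2005], config)
        got = {e.key.year: (e.value, e.code) for e in out}
        assert gaps == []
        assert got[2004] == (80.0, "AP:W")
        assert got[2005] == (80.0, "E")
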