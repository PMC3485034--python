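"""Loading, validation and round-trip behaviour of the knowledge-base tables."""
import random

import pytest

from wuenic.config import Config
from wuenic.fixtures import egypt_fixture, random_kb, scenario_figure3
from wuenic.knowledge_base import (
    DataPoint,
    Estimate,
    EstimateKey,
    KnowledgeBase,
    KnowledgeBaseError,
    SurveyDescription,
    SurveyResult,
    WorkingGroupDecision,
    load_estimates,
    load_knowledge_base,
    write_estimates,
    write_knowledge_base,
)


def k(country="egy", vaccine="dtp3", year=2004):
    return EstimateKey(country, vaccine, year)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "kb_factory",
        [
            lambda: egypt_fixture("2007")[0],
            lambda: scenario_figure3()[0],
            lambda: random_kb(7)[0],
        ],
        ids=["egypt", "scenario", "random"],
    )
    def test_write_then_load_is_identity(self, kb_factory, tmp_path):
        kb = kb_factory()
        write_knowledge_base(kb, tmp_path)
        loaded = load_knowledge_base(tmp_path)
        assert loaded.reported == kb.reported
        assert loaded.surveys == kb.surveys
        assert loaded.survey_descriptions == kb.survey_descriptions
        assert loaded.decisions == kb.decisions
        assert loaded.required == kb.required

    def test_estimates_round_trip(self, tmp_path):
        estimates = [
            Estimate(k(), 97.0, 97.0, "AP:R", "Reported coverage is supported by survey",
                     ("reported:egy:dtp3:2004",)),
            Estimate(k(year=2005), 67.0, 66.73333333333333, "C",
                     "Reported data calibrated, with a comma", ()),
        ]
        write_estimates(estimates, tmp_path / "est.csv")
        assert load_estimates(tmp_path / "est.csv") == sorted(
            estimates, key=lambda e: e.key
        )

    def test_empty_estimates_writes_header_only(self, tmp_path):
        write_estimates([], tmp_path / "est.csv")
        text = (tmp_path / "est.csv").read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("country,vaccine,year")
        assert load_estimates(tmp_path / "est.csv") == []

    def test_loading_is_row_order_insensitive(self, tmp_path):
        kb = random_kb(11)[0]
        write_knowledge_base(kb, tmp_path)
        rng = random.Random(0)
        for name in ("reported.csv", "surveys.csv", "decisions.csv", "required.csv"):
            lines = (tmp_path / name).read_text().splitlines()
            body = lines[1:]
            rng.shuffle(body)
            (tmp_path / name).write_text("\n".join([lines[0]] + body) + "\n")
        shuffled = load_knowledge_base(tmp_path)
        assert shuffled == load_knowledge_base(tmp_path)
        assert shuffled.reported == kb.reported
        assert shuffled.surveys == kb.surveys
        assert shuffled.decisions == kb.decisions


class TestValidation:
    def _write(self, tmp_path, **overrides):
        kb, _ = egypt_fixture("base")
        for field, value in overrides.items():
            setattr(kb, field, value)
        write_knowledge_base(kb, tmp_path)
        return tmp_path

    def test_paper_table_rows_load(self, tmp_path):
        kb, _ = egypt_fixture("base")
        write_knowledge_base(kb, tmp_path)
        loaded = load_knowledge_base(tmp_path)
        assert {(p.key.year, p.coverage) for p in loaded.reported} == {
            (2004, 97.0), (2005, 96.0)
        }

    def test_empty_survey_file_is_fine(self, tmp_path):
        self._write(tmp_path, surveys=[])
        kb = load_knowledge_base(tmp_path)
        assert kb.surveys == []

    def test_missing_file_is_distinct_error(self, tmp_path):
        self._write(tmp_path)
        (tmp_path / "reported.csv").unlink()
        with pytest.raises(KnowledgeBaseError, match="missing input file"):
            load_knowledge_base(tmp_path)

    def test_duplicate_key_source_rejected(self, tmp_path):
        kb, _ = egypt_fixture("base")
        dup = kb.reported[0]
        self._write(tmp_path, reported=kb.reported + [
            DataPoint(dup.key, dup.source, 50.0)
        ])
        with pytest.raises(KnowledgeBaseError, match="duplicate"):
            load_knowledge_base(tmp_path)

    def test_two_assign_decisions_for_same_key_rejected(self, tmp_path):
        decs = [
            WorkingGroupDecision(k(), "assignWUENIC", 90.0, "first"),
            WorkingGroupDecision(k(), "assignWUENIC", 91.0, "second"),
        ]
        self._write(tmp_path, decisions=decs)
        with pytest.raises(KnowledgeBaseError, match="multiple assignWUENIC"):
            load_knowledge_base(tmp_path)

    def test_assign_decision_without_coverage_rejected(self, tmp_path):
        self._write(tmp_path, decisions=[
            WorkingGroupDecision(k(), "assignWUENIC", None, "no value")
        ])
        with pytest.raises(KnowledgeBaseError, match="missing coverage"):
            load_knowledge_base(tmp_path)

    def test_empty_explanation_rejected(self, tmp_path):
        self._write(tmp_path, decisions=[
            WorkingGroupDecision(k(), "comment", None, "  ")
        ])
        with pytest.raises(KnowledgeBaseError, match="empty explanation"):
            load_knowledge_base(tmp_path)

    def test_dangling_survey_id_rejected(self, tmp_path):
        self._write(tmp_path, surveys=[
            SurveyResult(k(), "no_such_survey", 90.0)
        ])
        with pytest.raises(KnowledgeBaseError, match="unknown survey_id"):
            load_knowledge_base(tmp_path)

    def test_unknown_vaccine_rejected(self, tmp_path):
        self._write(tmp_path)
        cfg = Config(vaccines=("mcv",))
        with pytest.raises(KnowledgeBaseError, match="vocabulary"):
            load_knowledge_base(tmp_path, cfg)

    def test_year_outside_window_rejected(self, tmp_path):
        self._write(tmp_path)
        cfg = Config(year_min=2005, year_max=2011)
        with pytest.raises(KnowledgeBaseError, match="estimation window"):
            load_knowledge_base(tmp_path, cfg)

    def test_error_carries_row_context(self, tmp_path):
        self._write(tmp_path)
        lines = (tmp_path / "reported.csv").read_text().splitlines()
        lines[1] = lines[1].replace("97", "not_a_number")
        (tmp_path / "reported.csv").write_text("\n".join(lines) + "\n")
        with pytest.raises(KnowledgeBaseError, match=r"row=0"):
            load_knowledge_base(tmp_path)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = Config(jump_threshold=25.0, calibration="additive")
        cfg.to_yaml(tmp_path / "wuenic.yaml")
        assert Config.from_yaml(tmp_path / "wuenic.yaml") == cfg

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "wuenic.yaml").write_text("jump_treshold: 25\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            Config.from_yaml(tmp_path / "wuenic.yaml")

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            Config(calibration="geometric")
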