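"""Synthetic knowledge bases with known ground truth.

Three generators:

* :func:`egypt_fixture` — the classic Egypt DTP3 worked example (reported
  97/96 vs surveys 93.5/95), with variants adding a non-supporting 2006
  survey and a 2007 working-group assignment;
* :func:`scenario_figure3` — a 2000–2011 single-country scenario
  exercising every estimation behaviour: a small-sample survey exclusion,
  a non-supporting survey, calibration, passthrough between supporting
  anchors, a genuine one-year decline reinstated by decision, and
  nearest-neighbour extrapolation into a year with no report.  The country
  and its numbers are synthetic; what is fixed by construction is *which
  rule fires each year*;
* :func:`random_kb` — seeded random knowledge bases around latent true
  coverage trajectories, for property tests.

Expected values attached to the fixtures are derived analytically by plain
arithmetic in this module — never by running the engine.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .knowledge_base import (
    DataPoint,
    EstimateKey,
    KnowledgeBase,
    SurveyDescription,
    SurveyResult,
    WorkingGroupDecision,
)

__all__ = ["egypt_fixture", "scenario_figure3", "random_kb", "FixtureExpectation"]


@dataclass
class FixtureExpectation:
    """Analytically derived ground truth for a fixture."""

    #: key -> (published coverage, rule code)
    estimates: dict[EstimateKey, tuple[float, str]] = field(default_factory=dict)
    #: key -> full-precision coverage before rounding
    raw: dict[EstimateKey, float] = field(default_factory=dict)


def _k(country: str, vaccine: str, year: int) -> EstimateKey:
    return EstimateKey(country, vaccine, year)


# ---------------------------------------------------------------------------
# Egypt worked example
# ---------------------------------------------------------------------------

def egypt_fixture(variant: str = "base") -> tuple[KnowledgeBase, FixtureExpectation]:
    """Egypt DTP3 knowledge base.

    Variants:

    * ``base`` — reported {2004: 97, 2005: 96}, surveys {2004: 93.5,
      2005: 95}; both surveys support the reports, so both years resolve
      to the reported values.
    * ``2006`` — adds reported 97 / survey 85 in 2006; the 12-point gap
      exceeds the support threshold, so 2006 resolves to the survey.
    * ``2007`` — additionally a working-group decision assigns 94 for
      2007, overriding the data for that year.
    """
    if variant not in ("base", "2006", "2007"):
        raise ValueError(f"unknown variant {variant!r}")
    c, v = "egy", "dtp3"
    desc = SurveyDescription(
        survey_id="egy_dhs",
        title="Egypt Demographic and Health Survey",
        survey_type="DHS",
        collection_year=2008,
        percent_cards_seen=85.0,
        confirmation_method="either",
        cohort_min_months=12,
        cohort_max_months=23,
        sample_size=5000,
    )
    reported = {2004: 97.0, 2005: 96.0}
    surveys = {2004: 93.5, 2005: 95.0}
    decisions: list[WorkingGroupDecision] = []
    years = [2004, 2005]

    expected = FixtureExpectation(
        estimates={
            _k(c, v, 2004): (97.0, "AP:R"),
            _k(c, v, 2005): (96.0, "AP:R"),
        },
        raw={_k(c, v, 2004): 97.0, _k(c, v, 2005): 96.0},
    )
    if variant in ("2006", "2007"):
        reported[2006] = 97.0
        surveys[2006] = 85.0
        years.append(2006)
        expected.estimates[_k(c, v, 2006)] = (85.0, "AP:S")
        expected.raw[_k(c, v, 2006)] = 85.0
    if variant == "2007":
        reported[2007] = 96.0
        surveys[2007] = 90.0
        years.append(2007)
        decisions.append(
            WorkingGroupDecision(
                key=_k(c, v, 2007),
                action="assignWUENIC",
                assigned_coverage=94.0,
                explanation=(
                    "While the reported coverage seems to be supported by survey "
                    "results, the same survey does not support the reported "
                    "coverage for other vaccines. The estimate is based on the "
                    "survey results"
                ),
            )
        )
        expected.estimates[_k(c, v, 2007)] = (94.0, "AP:W")
        expected.raw[_k(c, v, 2007)] = 94.0

    kb = KnowledgeBase(
        reported=[
            DataPoint(_k(c, v, y), "reported", cov) for y, cov in reported.items()
        ],
        surveys=[
            SurveyResult(_k(c, v, y), "egy_dhs", cov) for y, cov in surveys.items()
        ],
        survey_descriptions={desc.survey_id: desc},
        decisions=decisions,
        required=frozenset(_k(c, v, y) for y in years),
    )
    kb.sort()
    kb.validate(Config())
    return kb, expected


# ---------------------------------------------------------------------------
# twelve-year scenario
# ---------------------------------------------------------------------------

def scenario_figure3() -> tuple[KnowledgeBase, FixtureExpectation]:
    """A 2000–2011 scenario in which every estimation behaviour fires once.

    Construction (country ``exm``, vaccine ``dtp3``):

    * reported data 2000–2010, none for 2011;
    * a 2000 survey with sample size 250 — excluded (< 300);
    * a 2002 survey 15 points below the report — a non-supporting anchor,
      so 2000–2001 are calibrated to the 2002 level and 2003–2004 are
      calibrated between the 2002 and 2005 anchors;
    * supporting surveys in 2005 and 2009 — reported data passes through
      between them and beyond 2009;
    * a genuine 28-point decline in 2007 that the spike filter would
      exclude, reinstated by an ``acceptReported`` decision;
    * 2011 extrapolated from the 2010 report.
    """
    c, v = "exm", "dtp3"
    reported = {
        2000: 70.0, 2001: 72.0, 2002: 75.0, 2003: 77.0, 2004: 79.0,
        2005: 81.0, 2006: 83.0, 2007: 55.0, 2008: 84.0, 2009: 86.0,
        2010: 87.0,
    }
    surveys = {  # survey_id -> (cohort_year, coverage, sample_size)
        "exm_epi_2000": (2000, 65.0, 250),
        "exm_dhs_2002": (2002, 60.0, 4000),
        "exm_mics_2005": (2005, 78.0, 3500),
        "exm_dhs_2009": (2009, 90.0, 4200),
    }
    survey_types = {
        "exm_epi_2000": "EPI-cluster",
        "exm_dhs_2002": "DHS",
        "exm_mics_2005": "MICS",
        "exm_dhs_2009": "DHS",
    }
    descriptions = {
        sid: SurveyDescription(
            survey_id=sid,
            title=f"synthetic scenario survey {sid}",
            survey_type=survey_types[sid],
            collection_year=year + 1,
            percent_cards_seen=80.0,
            confirmation_method="either",
            cohort_min_months=12,
            cohort_max_months=23,
            sample_size=n,
        )
        for sid, (year, _, n) in surveys.items()
    }
    decisions = [
        WorkingGroupDecision(
            key=_k(c, v, 2007),
            action="acceptReported",
            assigned_coverage=None,
            explanation=(
                "The decline is not a reporting artefact but a real decline in "
                "coverage due to a shortage of vaccine; the reported data point "
                "is reinstated."
            ),
        )
    ]
    years = list(range(2000, 2012))
    kb = KnowledgeBase(
        reported=[
            DataPoint(_k(c, v, y), "reported", cov) for y, cov in reported.items()
        ],
        surveys=[
            SurveyResult(_k(c, v, year), sid, cov)
            for sid, (year, cov, _) in surveys.items()
        ],
        survey_descriptions=descriptions,
        decisions=decisions,
        required=frozenset(_k(c, v, y) for y in years),
    )
    kb.sort()
    kb.validate(Config())

    # expected values, derived by hand-applying the rules:
    # anchors: 2002 -> survey (|60-75| >= 10), 2005 and 2009 -> reported.
    r2002 = surveys["exm_dhs_2002"][1] / reported[2002]  # constant pre-anchor ratio
    r2005 = 1.0  # anchor resolved to the reported value itself

    def blend(year: int) -> float:
        t = (year - 2002) / (2005 - 2002)
        return r2002 + t * (r2005 - r2002)

    raw = {
        2000: reported[2000] * r2002,
        2001: reported[2001] * r2002,
        2002: surveys["exm_dhs_2002"][1],
        2003: reported[2003] * blend(2003),
        2004: reported[2004] * blend(2004),
        2005: reported[2005],
        2006: reported[2006],
        2007: reported[2007],
        2008: reported[2008],
        2009: reported[2009],
        2010: reported[2010],
        2011: reported[2010],  # nearest-neighbour extrapolation
    }
    codes = {
        2000: "C", 2001: "C", 2002: "AP:S", 2003: "C", 2004: "C",
        2005: "AP:R", 2006: "R", 2007: "R", 2008: "R", 2009: "AP:R",
        2010: "R", 2011: "E",
    }
    expected = FixtureExpectation(
        estimates={
            _k(c, v, y): (float(np.floor(raw[y] + 0.5)), codes[y]) for y in years
        },
        raw={_k(c, v, y): raw[y] for y in years},
    )
    return kb, expected


# ---------------------------------------------------------------------------
# random knowledge bases
# ---------------------------------------------------------------------------

def random_kb(
    seed: int,
    n_countries: int = 3,
    vaccines: tuple[str, ...] = ("dtp1", "dtp3", "mcv"),
    years: tuple[int, int] = (1997, 2011),
    report_rate: float = 0.95,
    noise_sd: float = 2.0,
    bias_range: tuple[float, float] = (-2.0, 4.0),
    surveys_per_series: int = 2,
    survey_noise_sd: float = 2.0,
    sample_sizes: tuple[int, ...] = (250, 280, 299, 300, 800, 3000, 5000),
    decision_rate: float = 0.03,
    spike_rate: float = 0.02,
    ge100_rate: float = 0.01,
    assign_only: bool = False,
    config: Config | None = None,
) -> tuple[KnowledgeBase, dict[EstimateKey, float]]:
    """Seeded random knowledge base around latent true coverage walks.

    Latent truth per country/vaccine is a bounded random walk in [5, 95];
    reported data is truth plus a per-series bias and noise, with optional
    injected one-year spikes and >= 100% artefacts; surveys are truth plus
    noise with sample sizes spanning the exclusion boundary; decisions are
    drawn at ``decision_rate`` per key (``assign_only=True`` makes every
    decision an assignment).  Returns the knowledge base and the latent
    truth for recovery-style assertions.  Identical seeds give identical
    knowledge bases.
    """
    if not (0 <= report_rate <= 1 and 0 <= decision_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if years[0] > years[1]:
        raise ValueError("invalid year range")
    config = config or Config()
    rng = np.random.default_rng(seed)
    year_list = list(range(years[0], years[1] + 1))
    countries = [
        "z" + chr(ord("a") + i // 26) + chr(ord("a") + i % 26)
        for i in range(n_countries)
    ]

    truth: dict[EstimateKey, float] = {}
    reported: list[DataPoint] = []
    surveys: list[SurveyResult] = []
    descriptions: dict[str, SurveyDescription] = {}
    decisions: list[WorkingGroupDecision] = []

    for country in countries:
        # surveys are organized per country: one instrument covers all vaccines
        survey_years = sorted(
            rng.choice(year_list, size=min(surveys_per_series, len(year_list)),
                       replace=False).tolist()
        )
        survey_ids = {}
        for i, sy in enumerate(survey_years):
            sid = f"{country}_svy{i}"
            survey_ids[sy] = sid
            descriptions[sid] = SurveyDescription(
                survey_id=sid,
                title=f"synthetic household survey {sid}",
                survey_type=str(rng.choice(["DHS", "MICS", "EPI-cluster"])),
                collection_year=min(sy + 1, years[1]),
                percent_cards_seen=float(np.round(rng.uniform(50, 95), 1)),
                confirmation_method="either",
                cohort_min_months=12,
                cohort_max_months=23,
                sample_size=int(rng.choice(sample_sizes)),
            )

        for vaccine in vaccines:
            level = rng.uniform(40, 90)
            bias = rng.uniform(*bias_range)
            walk = []
            for _ in year_list:
                walk.append(level)
                level = float(np.clip(level + np.clip(rng.normal(0, 3), -8, 8), 5, 95))
            for y, tval in zip(year_list, walk):
                truth[_k(country, vaccine, y)] = tval

            for y, tval in zip(year_list, walk):
                if rng.random() > report_rate:
                    continue
                cov = tval + bias + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                if rng.random() < spike_rate:
                    cov += rng.choice([-1.0, 1.0]) * rng.uniform(
                        config.jump_threshold + 5, config.jump_threshold + 20
                    )
                if rng.random() < ge100_rate:
                    cov = rng.uniform(100, 110)
                source = str(rng.choice(["reported", "reported", "reported", "gov"]))
                reported.append(
                    DataPoint(_k(country, vaccine, y), source, float(max(0.0, cov)))
                )

            for sy in survey_years:
                tval = truth[_k(country, vaccine, sy)]
                cov = float(
                    np.clip(tval + (rng.normal(0, survey_noise_sd)
                                    if survey_noise_sd else 0.0), 0, 100)
                )
                card = None
                if vaccine in ("dtp1", "dtp3") and survey_noise_sd > 0:
                    card = float(np.clip(cov * rng.uniform(0.85, 1.0), 0, 100))
                surveys.append(
                    SurveyResult(_k(country, vaccine, sy), survey_ids[sy], cov, card)
                )

            for y in year_list:
                if rng.random() >= decision_rate:
                    continue
                key = _k(country, vaccine, y)
                action = (
                    "assignWUENIC" if assign_only
                    else str(rng.choice([
                        "assignWUENIC", "ignoreReported", "acceptReported",
                        "ignoreSurvey", "acceptSurvey", "comment",
                    ]))
                )
                decisions.append(
                    WorkingGroupDecision(
                        key=key,
                        action=action,
                        assigned_coverage=(
                            float(np.round(rng.uniform(20, 99), 1))
                            if action == "assignWUENIC" else None
                        ),
                        explanation=f"synthetic working-group decision for {key}",
                    )
                )

    kb = KnowledgeBase(
        reported=reported,
        surveys=surveys,
        survey_descriptions=descriptions,
        decisions=decisions,
        required=frozenset(
            _k(c, v, y) for c in countries for v in vaccines for y in year_list
        ),
    )
    kb.sort()
    kb.validate(config)
    return kb, truth
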