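"""Level 1 — grade the raw data and complete the reported time series.

Every reported and survey data point is passed through a series of filters
and ends up *accepted*, *modified* (surveys only, via the recall-bias
adjustment) or *excluded*, always with a machine-readable reason.  Filters
run in a fixed order and working-group decisions are evaluated last, so an
``acceptReported``/``acceptSurvey`` decision reinstates a point any filter
excluded, and an ``ignoreReported``/``ignoreSurvey`` decision excludes an
otherwise-accepted point.

From the accepted reported points a complete time series is built over the
required years: interior gaps are filled by linear interpolation and the
ends by nearest-neighbour extrapolation.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .config import Config
from .knowledge_base import (
    DataPoint,
    EstimateKey,
    KnowledgeBase,
    SeriesPoint,
    SurveyDescription,
    SurveyResult,
    WorkingGroupDecision,
)

log = logging.getLogger("wuenic.level1")

Origin = Union[DataPoint, SurveyResult]

#: reason codes emitted by the grading filters
REASON_OK = "ok"
REASON_GE100 = "ge100"
REASON_SPIKE = "jump_spike"
REASON_JUMP_FLAG = "jump_flagged"
REASON_SOURCE = "source_precedence"
REASON_SMALL_SAMPLE = "small_sample"
REASON_COHORT = "cohort"
REASON_WGD_ACCEPT = "wgd_accept"
REASON_WGD_IGNORE = "wgd_ignore"
REASON_RECALL = "recall_bias"
REASON_NO_RECALL = "no_recall_data"


@dataclass(frozen=True)
class GradedPoint:
    """One data point after grading.

    ``adjusted_coverage`` is present iff ``status == "modified"``; the
    effective coverage used downstream is :attr:`coverage`.
    """

    origin: Origin
    status: str  # accepted | modified | excluded
    reason_code: str
    reason_text: str = ""
    adjusted_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status == "modified" and self.adjusted_coverage is None:
            raise ValueError("modified point must carry adjusted_coverage")
        if self.status == "excluded" and not self.reason_code:
            raise ValueError("exclusion must carry a reason")

    @property
    def key(self) -> EstimateKey:
        return self.origin.key

    @property
    def coverage(self) -> float:
        if self.status == "modified":
            assert self.adjusted_coverage is not None
            return self.adjusted_coverage
        return self.origin.coverage

    @property
    def is_accepted(self) -> bool:
        return self.status in ("accepted", "modified")


@dataclass
class GradedSeries:
    """Level-1 output for one country/vaccine."""

    country: str
    vaccine: str
    graded_reported: list[GradedPoint]
    graded_surveys: list[GradedPoint]
    completed_series: dict[int, SeriesPoint]
    #: provenance of each completed-series year: reported | interpolated | extrapolated
    series_kind: dict[int, str]

    @property
    def graded_points(self) -> list[GradedPoint]:
        return self.graded_reported + self.graded_surveys

    def accepted_reported_years(self) -> dict[int, float]:
        return {
            g.key.year: g.coverage
            for g in self.graded_reported
            if g.is_accepted
        }

    def accepted_surveys_by_year(self) -> dict[int, list[GradedPoint]]:
        out: dict[int, list[GradedPoint]] = {}
        for g in self.graded_surveys:
            if g.is_accepted:
                out.setdefault(g.key.year, []).append(g)
        return out


# ---------------------------------------------------------------------------
# reported-data filters
# ---------------------------------------------------------------------------

def _decisions_by_key(
    decisions: Sequence[WorkingGroupDecision],
) -> dict[EstimateKey, list[WorkingGroupDecision]]:
    out: dict[EstimateKey, list[WorkingGroupDecision]] = {}
    for d in decisions:
        out.setdefault(d.key, []).append(d)
    return out


def filter_reported(
    points: Sequence[DataPoint],
    decisions: Sequence[WorkingGroupDecision],
    config: Config,
) -> list[GradedPoint]:
    """Grade the reported-type points of one country/vaccine.

    Filter order: source precedence, >= 100% exclusion, jump filter,
    working-group decisions last (so decisions dominate every filter).
    """
    if not points:
        return []
    assert len({(p.key.country, p.key.vaccine) for p in points}) == 1, (
        "filter_reported expects points of a single country/vaccine"
    )

    by_year: dict[int, list[DataPoint]] = {}
    for p in points:
        by_year.setdefault(p.key.year, []).append(p)

    graded: dict[int, GradedPoint] = {}
    superseded: list[GradedPoint] = []
    rank = {s: i for i, s in enumerate(config.source_precedence)}
    for year, pts in by_year.items():
        pts = sorted(pts, key=lambda p: (rank.get(p.source, len(rank)), p.source))
        selected = pts[0]
        graded[year] = GradedPoint(selected, "accepted", REASON_OK)
        for other in pts[1:]:
            superseded.append(
                GradedPoint(
                    other,
                    "excluded",
                    REASON_SOURCE,
                    f"superseded by {selected.source} data for {year}",
                )
            )

    # >= 100% filter
    for year, g in graded.items():
        if g.origin.coverage >= 100:
            graded[year] = GradedPoint(
                g.origin, "excluded", REASON_GE100,
                f"reported coverage {g.origin.coverage:g} >= 100%",
            )

    # jump filter, on calendar-consecutive surviving years
    surviving = {y: g.origin.coverage for y, g in graded.items() if g.is_accepted}
    spikes = _spike_years(surviving, config.jump_threshold)
    for year in spikes:
        g = graded[year]
        graded[year] = GradedPoint(
            g.origin, "excluded", REASON_SPIKE,
            "one-year spike: both the rise and the fall exceed the "
            f"jump threshold of {config.jump_threshold:g} points",
        )
    remaining = {y: c for y, c in surviving.items() if y not in spikes}
    for year in sorted(remaining):
        nxt = year + 1
        if nxt in remaining and abs(remaining[nxt] - remaining[year]) > config.jump_threshold:
            for flagged in (year, nxt):
                g = graded[flagged]
                if g.reason_code in (REASON_SPIKE, REASON_JUMP_FLAG):
                    continue
                text = (
                    f"year-over-year change between {year} and {nxt} exceeds "
                    f"{config.jump_threshold:g} points"
                )
                status = "excluded" if config.exclude_flagged_jumps else "accepted"
                graded[flagged] = GradedPoint(g.origin, status, REASON_JUMP_FLAG, text)

    # decisions dominate every filter
    dmap = _decisions_by_key(decisions)
    for year, g in graded.items():
        for d in dmap.get(g.key, []):
            if d.action == "acceptReported":
                graded[year] = GradedPoint(
                    g.origin, "accepted", REASON_WGD_ACCEPT, d.explanation
                )
            elif d.action == "ignoreReported":
                graded[year] = GradedPoint(
                    g.origin, "excluded", REASON_WGD_IGNORE, d.explanation
                )

    out = [graded[y] for y in sorted(graded)] + superseded
    for g in out:
        log.debug("grade_reported key=%s status=%s reason=%s", g.key, g.status, g.reason_code)
    return out


def _spike_years(series: dict[int, float], threshold: float) -> set[int]:
    """Years that rise and fall (or fall and rise) by more than ``threshold``
    relative to both calendar-adjacent neighbours — the outlying year of a
    one-year spike."""
    spikes = set()
    for y in series:
        if (y - 1) in series and (y + 1) in series:
            d_in = series[y] - series[y - 1]
            d_out = series[y + 1] - series[y]
            if abs(d_in) > threshold and abs(d_out) > threshold and d_in * d_out < 0:
                spikes.add(y)
    return spikes


# ---------------------------------------------------------------------------
# survey filters and recall-bias adjustment
# ---------------------------------------------------------------------------

def filter_surveys(
    results: Sequence[SurveyResult],
    descriptions: dict[str, SurveyDescription],
    decisions: Sequence[WorkingGroupDecision],
    config: Config,
) -> list[GradedPoint]:
    """Grade survey results: sample-size and age-cohort filters, then decisions."""
    dmap = _decisions_by_key(decisions)
    out: list[GradedPoint] = []
    for r in sorted(results, key=lambda r: (r.key, r.survey_id)):
        desc = descriptions[r.survey_id]
        g = GradedPoint(r, "accepted", REASON_OK)
        if desc.sample_size < config.survey_min_sample_size:
            g = GradedPoint(
                r, "excluded", REASON_SMALL_SAMPLE,
                f"sample size {desc.sample_size} < {config.survey_min_sample_size}",
            )
        elif (
            desc.cohort_min_months < config.cohort_valid_min_months
            or desc.cohort_max_months > config.cohort_valid_max_months
        ):
            g = GradedPoint(
                r, "excluded", REASON_COHORT,
                f"age cohort {desc.cohort_min_months}-{desc.cohort_max_months} months "
                f"outside the valid range {config.cohort_valid_min_months}-"
                f"{config.cohort_valid_max_months}",
            )
        for d in dmap.get(r.key, []):
            if d.action == "acceptSurvey":
                g = GradedPoint(r, "accepted", REASON_WGD_ACCEPT, d.explanation)
            elif d.action == "ignoreSurvey":
                g = GradedPoint(r, "excluded", REASON_WGD_IGNORE, d.explanation)
        log.debug("grade_survey key=%s id=%s status=%s reason=%s",
                  r.key, r.survey_id, g.status, g.reason_code)
        out.append(g)
    return out


_DOSE_RE = re.compile(r"^([a-z]+)(\d+)$")


def vaccine_dose(vaccine: str) -> tuple[str, int]:
    """Split a vaccine-dose code into (antigen, dose index); no digit means dose 1."""
    m = _DOSE_RE.match(vaccine)
    if m:
        return m.group(1), int(m.group(2))
    return vaccine, 1


def adjust_recall_bias(
    result: SurveyResult,
    survey_results: Sequence[SurveyResult],
    config: Config,
) -> GradedPoint:
    """Recall-bias correction for multi-dose antigens.

    Caretakers recall the first dose of a series better than later ones, so
    later-dose coverage from recall is corrected using the card-documented
    coverage: ``card-only dose-k x (dose-1 either-method / dose-1 card-only)``.
    Requires the same survey to report the dose-1 coverage by both methods
    for the same birth cohort; otherwise the point is accepted unchanged
    with the reason recorded.
    """
    antigen, dose = vaccine_dose(result.key.vaccine)
    if dose <= 1:
        return GradedPoint(result, "accepted", REASON_OK)
    if result.coverage_card is None:
        return GradedPoint(
            result, "accepted", REASON_NO_RECALL,
            "insufficient data for recall adjustment: no card-only coverage",
        )
    dose1 = None
    for other in survey_results:
        a, d = vaccine_dose(other.key.vaccine)
        if (
            other.survey_id == result.survey_id
            and a == antigen
            and d == 1
            and other.key.year == result.key.year
        ):
            dose1 = other
            break
    if dose1 is None or dose1.coverage_card is None or dose1.coverage_card == 0:
        return GradedPoint(
            result, "accepted", REASON_NO_RECALL,
            "insufficient data for recall adjustment: dose-1 card-only "
            "coverage unavailable",
        )
    adjusted = result.coverage_card * (dose1.coverage / dose1.coverage_card)
    return GradedPoint(
        result, "modified", REASON_RECALL,
        f"recall-bias adjusted: {result.coverage_card:g} x "
        f"({dose1.coverage:g} / {dose1.coverage_card:g}) = {adjusted:g}",
        adjusted_coverage=adjusted,
    )


# ---------------------------------------------------------------------------
# series completion
# ---------------------------------------------------------------------------

def interpolate(before: SeriesPoint, after: SeriesPoint, year: int) -> float:
    """Linear interpolation between two series points, exactly
    ``Pbefore + (Y - Ybefore) * (Pafter - Pbefore) / (Yafter - Ybefore)``."""
    assert before.year < year < after.year, "interpolate needs before.year < year < after.year"
    return before.coverage + (year - before.year) * (
        (after.coverage - before.coverage) / (after.year - before.year)
    )


def complete_reported_series(
    graded: Sequence[GradedPoint],
    required_years: Sequence[int],
) -> tuple[dict[int, SeriesPoint], dict[int, str]]:
    """Complete the accepted reported series over the required years.

    Accepted years keep their (possibly decision-reinstated) value; interior
    gaps are linearly interpolated; years outside the observed range take
    the nearest accepted value.  Returns the series and, per year, whether
    the value is ``reported``, ``interpolated`` or ``extrapolated``.
    Returns empty maps when no point is accepted.
    """
    accepted = {
        g.key.year: g.coverage
        for g in graded
        if g.is_accepted and isinstance(g.origin, DataPoint)
    }
    if not accepted:
        return {}, {}
    years = sorted(accepted)
    series: dict[int, SeriesPoint] = {}
    kind: dict[int, str] = {}
    for y in sorted(required_years):
        if y in accepted:
            series[y] = SeriesPoint(y, accepted[y])
            kind[y] = "reported"
        elif y < years[0]:
            series[y] = SeriesPoint(y, accepted[years[0]])
            kind[y] = "extrapolated"
        elif y > years[-1]:
            series[y] = SeriesPoint(y, accepted[years[-1]])
            kind[y] = "extrapolated"
        else:
            before = max(b for b in years if b < y)
            after = min(a for a in years if a > y)
            series[y] = SeriesPoint(
                y,
                interpolate(
                    SeriesPoint(before, accepted[before]),
                    SeriesPoint(after, accepted[after]),
                    y,
                ),
            )
            kind[y] = "interpolated"
    return series, kind


def grade_country_vaccine(
    kb: KnowledgeBase, country: str, vaccine: str, config: Config
) -> GradedSeries:
    """Run all Level-1 steps for one country/vaccine."""
    points = [
        p for p in kb.reported if p.key.country == country and p.key.vaccine == vaccine
    ]
    results = [
        s for s in kb.surveys if s.key.country == country and s.key.vaccine == vaccine
    ]
    decisions = [
        d for d in kb.decisions if d.key.country == country and d.key.vaccine == vaccine
    ]
    graded_reported = filter_reported(points, decisions, config)
    graded_surveys = filter_surveys(results, kb.survey_descriptions, decisions, config)

    adjusted: list[GradedPoint] = []
    for g in graded_surveys:
        if g.is_accepted:
            adj = adjust_recall_bias(g.origin, kb.surveys, config)
            # a reinstating decision outranks the plain-acceptance reason
            if adj.status == "accepted" and g.reason_code == REASON_WGD_ACCEPT:
                adj = g
            adjusted.append(adj)
        else:
            adjusted.append(g)

    required_years = kb.required_years(country, vaccine)
    # also cover accepted-data and decision years outside the required window,
    # because anchor resolution and calibration need series values there
    fill_years = set(required_years)
    fill_years.update(g.key.year for g in graded_reported if g.is_accepted)
    fill_years.update(g.key.year for g in adjusted if g.is_accepted)
    fill_years.update(d.key.year for d in decisions if d.action == "assignWUENIC")
    series, kind = complete_reported_series(graded_reported, sorted(fill_years))
    return GradedSeries(
        country=country,
        vaccine=vaccine,
        graded_reported=graded_reported,
        graded_surveys=adjusted,
        completed_series=series,
        series_kind=kind,
    )
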