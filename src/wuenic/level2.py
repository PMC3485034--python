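"""Level 2 — resolve anchor-point years.

An *anchor point* is a year with more than one source of information: an
accepted reported value plus at least one accepted survey, or a year for
which the working group has directly assigned an estimate.  Anchors are
resolved first and the surrounding years are tied to them in Level 3.

The closed-world override semantics of the rule base — "this rule engages
only if no working-group decision exists" — is realized as deterministic
guarded precedence: exactly one of the three resolutions fires per anchor:

1. ``AP:W`` — an ``assignWUENIC`` decision exists; its coverage wins.
2. ``AP:R`` — the survey supports the reported value; the estimate is the
   reported value.
3. ``AP:S`` — otherwise the estimate is the survey value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import Config
from .knowledge_base import (
    EstimateKey,
    SurveyDescription,
    WorkingGroupDecision,
    clamp,
)
from .level1 import GradedPoint, GradedSeries

log = logging.getLogger("wuenic.level2")

AP_REPORTED = "AP:R"
AP_SURVEY = "AP:S"
AP_WGD = "AP:W"


@dataclass(frozen=True)
class AnchorPoint:
    key: EstimateKey
    resolution: str  # AP:R | AP:S | AP:W
    coverage: float  # percentage points, clamped to [0, 100]
    supporting: tuple[str, ...] = ()
    explanation: str = ""  # decision text for AP:W, empty otherwise


def survey_supports_reported(p_surv: float, p_rpt: float, config: Config) -> bool:
    """True iff ``|p_surv - p_rpt|`` is strictly below the support threshold."""
    return abs(p_surv - p_rpt) < config.support_threshold


def combined_survey_coverage(
    surveys: Sequence[GradedPoint],
    config: Config,
    descriptions: Optional[dict[str, SurveyDescription]] = None,
) -> float:
    """Combine multiple same-year surveys into one value.

    Unweighted mean by default; optionally weighted by sample size when the
    descriptions are available.
    """
    assert surveys, "need at least one accepted survey"
    ordered = sorted(surveys, key=lambda g: g.origin.survey_id)
    if config.multi_survey_weighting == "sample_size" and descriptions is not None:
        weights = [descriptions[g.origin.survey_id].sample_size for g in ordered]
        total = sum(weights)
        return sum(w * g.coverage for w, g in zip(weights, ordered)) / total
    return sum(g.coverage for g in ordered) / len(ordered)


def resolve_anchor(
    key: EstimateKey,
    reported: Optional[GradedPoint],
    surveys: Sequence[GradedPoint],
    decisions: Sequence[WorkingGroupDecision],
    config: Config,
    descriptions: Optional[dict[str, SurveyDescription]] = None,
) -> AnchorPoint:
    """Resolve one anchor year by the AP:W > AP:R > AP:S precedence."""
    assign = next(
        (d for d in decisions if d.key == key and d.action == "assignWUENIC"), None
    )
    if assign is not None:
        assert assign.assigned_coverage is not None
        anchor = AnchorPoint(
            key, AP_WGD, clamp(assign.assigned_coverage), (assign.ref,), assign.explanation
        )
        log.debug("anchor key=%s rule=%s value=%g", key, AP_WGD, anchor.coverage)
        return anchor

    assert reported is not None and surveys, (
        "a data-driven anchor needs accepted reported data and >= 1 accepted survey"
    )
    p_surv = combined_survey_coverage(surveys, config, descriptions)
    p_rpt = reported.coverage
    refs = (reported.origin.ref,) + tuple(
        g.origin.ref for g in sorted(surveys, key=lambda g: g.origin.survey_id)
    )
    if survey_supports_reported(p_surv, p_rpt, config):
        anchor = AnchorPoint(key, AP_REPORTED, clamp(p_rpt), refs)
    else:
        anchor = AnchorPoint(key, AP_SURVEY, clamp(p_surv), refs)
    log.debug("anchor key=%s rule=%s value=%g", key, anchor.resolution, anchor.coverage)
    return anchor


def find_anchor_years(
    graded: GradedSeries,
    decisions: Sequence[WorkingGroupDecision],
    config: Config,
    descriptions: Optional[dict[str, SurveyDescription]] = None,
) -> list[AnchorPoint]:
    """All anchor points of one country/vaccine, sorted by year.

    A year is an anchor when it has both accepted reported data and at least
    one accepted survey, or — by fiat — when an ``assignWUENIC`` decision
    exists for it.  Other decision actions do not create anchors.
    """
    accepted_reported = {
        g.key.year: g for g in graded.graded_reported if g.is_accepted
    }
    surveys_by_year = graded.accepted_surveys_by_year()
    assign_years = {
        d.key.year for d in decisions if d.action == "assignWUENIC"
    }
    anchor_years = sorted(
        (set(accepted_reported) & set(surveys_by_year)) | assign_years
    )
    anchors = []
    for year in anchor_years:
        key = EstimateKey(graded.country, graded.vaccine, year)
        anchors.append(
            resolve_anchor(
                key,
                accepted_reported.get(year),
                surveys_by_year.get(year, ()),
                decisions,
                config,
                descriptions,
            )
        )
    return anchors
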