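"""Level 3 — complete the estimate time series around the anchors.

The completed reported series (Level 1) carries the shape of the trend;
the anchors (Level 2) pin its level.  Between two adjacent anchors that
were both resolved to reported data the series passes through unchanged.
Otherwise the series is *calibrated*: each year's reported value is scaled
by a ratio interpolated linearly in time between the endpoint ratios
``anchor estimate / reported value at that anchor`` (a single constant
ratio beyond the outermost anchors).  The multiplicative form preserves 0
and ordering; when a reported value at an anchor is exactly zero the ratio
is undefined and an additive shift is used instead (logged).  A working
group may instead decide to interpolate straight between two anchor
estimates.  When a country/vaccine has no anchors at all, the estimates
are the completed reported series itself.

Codes: ``R``/``I``/``E`` for passthrough of reported / interpolated /
extrapolated series years, ``C`` for calibrated years, ``W:I`` for
decision-driven interpolation, ``W`` for a direct assignment outside the
anchor machinery, and the anchor codes ``AP:R``/``AP:S``/``AP:W`` at
anchor years themselves.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import Config
from .knowledge_base import EstimateKey, SeriesPoint, WorkingGroupDecision, clamp
from .level1 import GradedSeries
from .level2 import AP_REPORTED, AnchorPoint
from .report import explain

log = logging.getLogger("wuenic.level3")


@dataclass(frozen=True)
class RawEstimate:
    """A full-precision estimate before final clamping and rounding."""

    key: EstimateKey
    value: float
    code: str
    explanation: str
    provenance: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_segment(
    segment: Sequence[SeriesPoint],
    anchors: Sequence[tuple[int, float]],
    config: Config,
) -> list[SeriesPoint]:
    """Calibrate a reported-series segment to the anchor estimate levels.

    ``anchors`` holds one or two ``(year, anchor_estimate)`` pairs whose
    years must appear in the segment.  With two anchors the scaling ratio
    is blended linearly in time between the endpoint ratios, so the output
    passes exactly through both anchor estimates; with one anchor a single
    constant ratio is applied.  If the reported value at any calibrating
    anchor is zero the ratio is undefined and an additive shift
    (difference instead of ratio) is used for the whole segment.  Results
    are clamped to [0, 100].
    """
    assert anchors, "calibration needs at least one anchor"
    by_year = {p.year: p.coverage for p in segment}
    for ay, _ in anchors:
        assert ay in by_year, f"anchor year {ay} not covered by the segment"

    additive = config.calibration == "additive" or any(
        by_year[ay] == 0 for ay, _ in anchors
    )
    if additive and config.calibration != "additive":
        log.info(
            "calibration ratio undefined (reported value 0 at an anchor); "
            "falling back to additive shift"
        )

    def factor(ay: int, est: float) -> float:
        return est - by_year[ay] if additive else est / by_year[ay]

    pairs = sorted(anchors)
    out = []
    for p in segment:
        if len(pairs) == 1:
            f = factor(*pairs[0])
        else:
            (y1, e1), (y2, e2) = pairs[0], pairs[-1]
            f1, f2 = factor(y1, e1), factor(y2, e2)
            t = (p.year - y1) / (y2 - y1)
            f = f1 + t * (f2 - f1)
        value = p.coverage + f if additive else p.coverage * f
        out.append(SeriesPoint(p.year, clamp(value)))
    return out


# ---------------------------------------------------------------------------
# estimation branches
# ---------------------------------------------------------------------------

def _series_ctx(graded: GradedSeries, year: int) -> dict:
    """Explanation context for passthrough years: flanking/nearest reported years."""
    accepted = sorted(graded.accepted_reported_years())
    ctx: dict = {}
    if accepted:
        before = [y for y in accepted if y < year]
        after = [y for y in accepted if y > year]
        if before and after:
            ctx["between"] = (before[-1], after[0])
        nearest = min(accepted, key=lambda y: (abs(y - year), y))
        ctx["nearest_year"] = nearest
    return ctx


def _reported_ref(graded: GradedSeries, year: int) -> tuple[str, ...]:
    for g in graded.graded_reported:
        if g.key.year == year and g.is_accepted:
            return (g.origin.ref,)
    return ()


def _anchor_ref(a: AnchorPoint) -> str:
    return f"anchor:{a.resolution}:{a.key.year}"


def _passthrough(
    key: EstimateKey,
    graded: GradedSeries,
    supporting_anchors: Sequence[AnchorPoint],
) -> RawEstimate:
    kind = graded.series_kind[key.year]
    value = graded.completed_series[key.year].coverage
    code = {"reported": "R", "interpolated": "I", "extrapolated": "E"}[kind]
    ctx = _series_ctx(graded, key.year)
    ctx["anchor_years"] = [a.key.year for a in supporting_anchors]
    prov = _reported_ref(graded, key.year) + tuple(
        _anchor_ref(a) for a in supporting_anchors
    )
    return RawEstimate(key, value, code, explain(code, ctx), prov)


def _calibrated(
    key: EstimateKey,
    graded: GradedSeries,
    anchors: Sequence[AnchorPoint],
    config: Config,
) -> RawEstimate:
    years = sorted({key.year} | {a.key.year for a in anchors})
    segment = [graded.completed_series[y] for y in years]
    calibrated = calibrate_segment(
        segment, [(a.key.year, a.coverage) for a in anchors], config
    )
    value = next(p.coverage for p in calibrated if p.year == key.year)
    kind = graded.series_kind[key.year]
    code = "E" if kind == "extrapolated" else "C"
    ctx = _series_ctx(graded, key.year)
    ctx["anchor_years"] = [a.key.year for a in anchors]
    prov = _reported_ref(graded, key.year) + tuple(_anchor_ref(a) for a in anchors)
    return RawEstimate(key, value, code, explain(code, ctx), prov)


def estimate_single_source(
    graded: GradedSeries,
    decisions: Sequence[WorkingGroupDecision],
    required_years: Sequence[int],
    config: Config,
) -> list[RawEstimate]:
    """Estimates when reported data is the only source (no anchors).

    The estimate for each required year is the completed reported series
    value; an ``assignWUENIC`` decision overrides a year (code ``W``).
    """
    out = []
    assigns = {
        d.key.year: d for d in decisions if d.action == "assignWUENIC"
    }
    for year in sorted(required_years):
        key = EstimateKey(graded.country, graded.vaccine, year)
        if year in assigns:
            d = assigns[year]
            out.append(
                RawEstimate(
                    key, d.assigned_coverage, "W",
                    explain("W", {"decision_explanation": d.explanation}),
                    (d.ref,),
                )
            )
        elif year in graded.completed_series:
            out.append(_passthrough(key, graded, ()))
    return out


def _anchor_only_estimates(
    graded: GradedSeries,
    anchors: Sequence[AnchorPoint],
    required_years: Sequence[int],
) -> list[RawEstimate]:
    """Degenerate path: anchors exist but there is no reported series at all
    (e.g. every report excluded and an estimate assigned by decision).
    Years between anchors are interpolated between the anchor estimates;
    years beyond take the nearest anchor estimate."""
    amap = {a.key.year: a for a in anchors}
    ayears = sorted(amap)
    out = []
    for year in sorted(required_years):
        key = EstimateKey(graded.country, graded.vaccine, year)
        if year in amap:
            a = amap[year]
            ctx = {"decision_explanation": a.explanation} if a.explanation else {}
            out.append(
                RawEstimate(key, a.coverage, a.resolution,
                            explain(a.resolution, ctx), a.supporting)
            )
            continue
        before = [y for y in ayears if y < year]
        after = [y for y in ayears if y > year]
        if before and after:
            y1, y2 = before[-1], after[0]
            a1, a2 = amap[y1], amap[y2]
            value = a1.coverage + (year - y1) * (
                (a2.coverage - a1.coverage) / (y2 - y1)
            )
            out.append(
                RawEstimate(
                    key, value, "I",
                    explain("I", {"between": (y1, y2)}),
                    (_anchor_ref(a1), _anchor_ref(a2)),
                )
            )
        else:
            ynear = before[-1] if before else after[0]
            a = amap[ynear]
            out.append(
                RawEstimate(
                    key, a.coverage, "E",
                    explain("E", {"nearest_year": ynear}),
                    (_anchor_ref(a),),
                )
            )
    return out


def complete_between_anchors(
    graded: GradedSeries,
    a1: AnchorPoint,
    a2: AnchorPoint,
    decisions: Sequence[WorkingGroupDecision],
    years: Sequence[int],
    config: Config,
) -> list[RawEstimate]:
    """Estimates for the years strictly between two adjacent anchors.

    Both anchors resolved to reported data -> passthrough; otherwise the
    segment is calibrated to the two anchor levels.  An ``interpolate``
    decision anywhere strictly inside the span replaces either behaviour
    with a straight line between the anchor estimates.
    """
    y1, y2 = a1.key.year, a2.key.year
    interp = next(
        (
            d for d in decisions
            if d.action == "interpolate" and y1 < d.key.year < y2
        ),
        None,
    )
    out = []
    for year in years:
        assert y1 < year < y2
        key = EstimateKey(graded.country, graded.vaccine, year)
        if interp is not None:
            value = a1.coverage + (year - y1) * (
                (a2.coverage - a1.coverage) / (y2 - y1)
            )
            out.append(
                RawEstimate(
                    key, value, "W:I",
                    explain("W:I", {"decision_explanation": interp.explanation}),
                    (interp.ref, _anchor_ref(a1), _anchor_ref(a2)),
                )
            )
        elif a1.resolution == AP_REPORTED and a2.resolution == AP_REPORTED:
            out.append(_passthrough(key, graded, (a1, a2)))
        else:
            out.append(_calibrated(key, graded, (a1, a2), config))
    return out


def complete_beyond_anchors(
    graded: GradedSeries,
    anchor: AnchorPoint,
    years: Sequence[int],
    config: Config,
) -> list[RawEstimate]:
    """Estimates for years before the earliest / after the latest anchor.

    Passthrough of the reported series when the outermost anchor was
    resolved to reported data; otherwise constant-ratio calibration to that
    anchor's level.  Years with no reported data at all take the nearest
    value (code ``E``).  An anchor assigned by decision does not certify
    the reported series, so it calibrates like a survey anchor.
    """
    out = []
    for year in years:
        key = EstimateKey(graded.country, graded.vaccine, year)
        if anchor.resolution == AP_REPORTED:
            out.append(_passthrough(key, graded, (anchor,)))
        else:
            out.append(_calibrated(key, graded, (anchor,), config))
    return out


# ---------------------------------------------------------------------------
# orchestration for one country/vaccine
# ---------------------------------------------------------------------------

def estimate_series(
    graded: GradedSeries,
    anchors: Sequence[AnchorPoint],
    decisions: Sequence[WorkingGroupDecision],
    required_years: Sequence[int],
    config: Config,
) -> tuple[list[RawEstimate], list[EstimateKey]]:
    """All Level-3 estimates for one country/vaccine.

    Returns ``(estimates, gaps)`` where gaps are required keys for which no
    data of any kind is available.
    """
    required_years = sorted(required_years)
    has_series = bool(graded.completed_series)
    anchors = sorted(anchors, key=lambda a: a.key.year)

    if not has_series and not anchors:
        gaps = [
            EstimateKey(graded.country, graded.vaccine, y) for y in required_years
        ]
        return [], gaps
    if not has_series:
        return _anchor_only_estimates(graded, anchors, required_years), []
    if not anchors:
        return (
            estimate_single_source(graded, decisions, required_years, config),
            [],
        )

    amap = {a.key.year: a for a in anchors}
    ayears = [a.key.year for a in anchors]
    out = []
    # anchor years themselves
    for year in required_years:
        if year in amap:
            a = amap[year]
            ctx = {"decision_explanation": a.explanation} if a.explanation else {}
            out.append(
                RawEstimate(key=a.key, value=a.coverage, code=a.resolution,
                            explanation=explain(a.resolution, ctx),
                            provenance=a.supporting)
            )
    # between adjacent anchors
    for a1, a2 in zip(anchors, anchors[1:]):
        span = [y for y in required_years if a1.key.year < y < a2.key.year]
        if span:
            out.extend(
                complete_between_anchors(graded, a1, a2, decisions, span, config)
            )
    # beyond the outermost anchors
    before = [y for y in required_years if y < ayears[0]]
    if before:
        out.extend(complete_beyond_anchors(graded, anchors[0], before, config))
    after = [y for y in required_years if y > ayears[-1]]
    if after:
        out.extend(complete_beyond_anchors(graded, anchors[-1], after, config))

    out.sort(key=lambda e: e.key)
    for e in out:
        log.debug("estimate key=%s rule=%s value=%g", e.key, e.code, e.value)
    return out, []
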