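"""Orchestration of the four estimation levels, contracts, and artifacts.

Countries never influence each other, and within a country vaccines only
interact in Level 4 (DTP1/DTP3), so the pipeline runs per country: grade
(Level 1), resolve anchors (Level 2), complete the series (Level 3),
reconcile DTP1 (Level 4), then finalize — clamp to [0, 100] and round to
the nearest integer, half away from zero — and check the global contracts:
exactly one estimate per required key with available data, and a logged
gap for every required key without any data.

Artifacts written by :func:`run`: ``estimates.csv``, ``audit.csv`` (one
row per graded data point — the transparency surface), ``anchors.csv``,
``gaps.csv``, a copy of ``required.csv`` (so consistency can be re-checked
from the output directory alone) and, optionally, per-country HTML
reports.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from .config import Config
from .knowledge_base import (
    DataPoint,
    Estimate,
    EstimateKey,
    KnowledgeBase,
    KnowledgeBaseError,
    clamp,
    load_knowledge_base,
    round_half_away,
    write_estimates,
)
from .level1 import GradedSeries, grade_country_vaccine
from .level2 import AnchorPoint, find_anchor_years
from .level3 import RawEstimate, estimate_series
from .level4 import reconcile_dtp1
from .report import RULE_REGISTRY, render_country_report, validate_rule_codes

log = logging.getLogger("wuenic.pipeline")

EXIT_OK = 0
EXIT_VIOLATION = 1
EXIT_IO_ERROR = 2


@dataclass
class PipelineResult:
    estimates: list[Estimate]
    graded: dict[tuple[str, str], GradedSeries]
    anchors: dict[tuple[str, str], list[AnchorPoint]]
    gaps: list[EstimateKey]
    violations: list[str]


def finalize(
    raw: Sequence[RawEstimate], kb: KnowledgeBase
) -> list[Estimate]:
    """Clamp, round and attach comment-decision notes.

    Comments are appended to the generated explanation; estimates whose
    explanation *is* a working-group decision (codes ``AP:W``/``W``) keep
    the decision text verbatim, untouched.
    """
    comments: dict[EstimateKey, list[str]] = {}
    for d in kb.decisions:
        if d.action == "comment":
            comments.setdefault(d.key, []).append(d.explanation)
    out = []
    for e in raw:
        explanation = e.explanation
        if e.code not in ("AP:W", "W") and e.key in comments:
            explanation += " Note: " + " ".join(sorted(comments[e.key]))
        value = clamp(e.value)
        out.append(
            Estimate(
                key=e.key,
                coverage=round_half_away(value),
                coverage_raw=value,
                rule_code=e.code,
                explanation=explanation,
                provenance=e.provenance,
            )
        )
    out.sort(key=lambda e: e.key)
    return out


def check_consistency(
    estimates: Sequence[Estimate],
    required: frozenset[EstimateKey] | set[EstimateKey],
    gaps: Sequence[EstimateKey] = (),
) -> list[str]:
    """Uniqueness and completeness of the final estimates.

    Returns one violation string per duplicate key and per required key
    that has neither an estimate nor a logged data gap.
    """
    violations = []
    seen: set[EstimateKey] = set()
    for e in estimates:
        if e.key in seen:
            violations.append(f"multiple estimates for {e.key}")
        seen.add(e.key)
    gap_set = set(gaps)
    for k in sorted(required):
        if k not in seen and k not in gap_set:
            violations.append(f"missing estimate for {k}")
    for e in estimates:
        if not (0 <= e.coverage <= 100):
            violations.append(f"estimate for {e.key} outside [0, 100]")
    return violations


def run_pipeline(
    kb: KnowledgeBase,
    config: Optional[Config] = None,
    countries: Optional[Sequence[str]] = None,
    _postprocess: Optional[Callable[[list[RawEstimate]], list[RawEstimate]]] = None,
) -> PipelineResult:
    """Run Levels 1–4 for every required country/vaccine.

    ``_postprocess`` is a test hook applied to the raw estimates of each
    country before finalization (used to exercise contract enforcement).
    """
    config = config or Config()
    validate_rule_codes(RULE_REGISTRY)  # fail fast if the registry is broken

    wanted = set(countries) if countries else None
    graded_map: dict[tuple[str, str], GradedSeries] = {}
    anchor_map: dict[tuple[str, str], list[AnchorPoint]] = {}
    all_estimates: list[Estimate] = []
    gaps: list[EstimateKey] = []

    for country in kb.countries():
        if wanted is not None and country not in wanted:
            continue
        raw_country: list[RawEstimate] = []
        for c, vaccine in kb.required_pairs():
            if c != country:
                continue
            decisions = [
                d for d in kb.decisions
                if d.key.country == country and d.key.vaccine == vaccine
            ]
            graded = grade_country_vaccine(kb, country, vaccine, config)
            anchors = find_anchor_years(
                graded, decisions, config, kb.survey_descriptions
            )
            graded_map[(country, vaccine)] = graded
            anchor_map[(country, vaccine)] = anchors
            est, missing = estimate_series(
                graded, anchors, decisions,
                kb.required_years(country, vaccine), config,
            )
            raw_country.extend(est)
            gaps.extend(missing)
            for k in missing:
                log.warning("no data of any kind for required key %s", k)

        required_country = {k for k in kb.required if k.country == country}
        raw_country = reconcile_dtp1(raw_country, required_country, config)
        if _postprocess is not None:
            raw_country = _postprocess(raw_country)
        all_estimates.extend(finalize(raw_country, kb))

    all_estimates.sort(key=lambda e: e.key)
    gaps.sort()
    required_scope = frozenset(
        k for k in kb.required if wanted is None or k.country in wanted
    )
    violations = check_consistency(all_estimates, required_scope, gaps)
    return PipelineResult(all_estimates, graded_map, anchor_map, gaps, violations)


# ---------------------------------------------------------------------------
# file-level entry point
# ---------------------------------------------------------------------------

def _write_audit(result: PipelineResult, path: Path) -> None:
    rows = []
    for (country, vaccine), graded in sorted(result.graded.items()):
        for g in graded.graded_points:
            origin = g.origin
            source = (
                origin.source if isinstance(origin, DataPoint)
                else f"survey:{origin.survey_id}"
            )
            rows.append(
                {
                    "country": country,
                    "vaccine": vaccine,
                    "year": g.key.year,
                    "source": source,
                    "coverage": origin.coverage,
                    "status": g.status,
                    "adjusted_coverage": (
                        "" if g.adjusted_coverage is None else repr(g.adjusted_coverage)
                    ),
                    "reason_code": g.reason_code,
                    "reason_text": g.reason_text,
                }
            )
    rows.sort(key=lambda r: (r["country"], r["vaccine"], r["year"], r["source"]))
    pd.DataFrame(
        rows,
        columns=[
            "country", "vaccine", "year", "source", "coverage", "status",
            "adjusted_coverage", "reason_code", "reason_text",
        ],
    ).to_csv(path, index=False)


def _write_anchors(result: PipelineResult, path: Path) -> None:
    rows = [
        {
            "country": a.key.country,
            "vaccine": a.key.vaccine,
            "year": a.key.year,
            "resolution": a.resolution,
            "coverage": repr(a.coverage),
        }
        for anchors in result.anchors.values()
        for a in anchors
    ]
    rows.sort(key=lambda r: (r["country"], r["vaccine"], r["year"]))
    pd.DataFrame(
        rows, columns=["country", "vaccine", "year", "resolution", "coverage"]
    ).to_csv(path, index=False)


def run(
    data_dir: str | Path,
    out_dir: str | Path,
    config: Optional[Config] = None,
    countries: Optional[Sequence[str]] = None,
    report: bool = False,
) -> tuple[int, Optional[PipelineResult]]:
    """Load a knowledge base, run the pipeline, write all artifacts.

    Returns ``(exit_code, result)``: 0 on success (gaps are warnings, not
    failures), 1 on a contract violation, 2 on an I/O or validation error.
    """
    config = config or Config()
    try:
        kb = load_knowledge_base(data_dir, config)
    except (KnowledgeBaseError, OSError) as exc:
        log.error("failed to load knowledge base: %s", exc)
        return EXIT_IO_ERROR, None

    result = run_pipeline(kb, config, countries)

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_estimates(result.estimates, out_dir / "estimates.csv")
        _write_audit(result, out_dir / "audit.csv")
        _write_anchors(result, out_dir / "anchors.csv")
        pd.DataFrame(
            [
                {"country": k.country, "vaccine": k.vaccine, "year": k.year}
                for k in result.gaps
            ],
            columns=["country", "vaccine", "year"],
        ).to_csv(out_dir / "gaps.csv", index=False)
        pd.DataFrame(
            [
                {"country": k.country, "vaccine": k.vaccine, "year": k.year}
                for k in sorted(kb.required)
                if countries is None or k.country in set(countries)
            ],
            columns=["country", "vaccine", "year"],
        ).to_csv(out_dir / "required.csv", index=False)
        if report:
            report_dir = out_dir / "reports"
            for country in sorted({e.key.country for e in result.estimates}
                                  | {k.country for k in result.gaps}):
                render_country_report(
                    country, result.estimates, result.graded, kb, report_dir
                )
    except OSError as exc:
        log.error("failed to write artifacts: %s", exc)
        return EXIT_IO_ERROR, result

    if result.violations:
        for v in result.violations:
            log.error("contract violation: %s", v)
        return EXIT_VIOLATION, result
    return EXIT_OK, result
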