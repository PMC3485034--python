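"""Rule-code registry, explanation generation and country reports.

Every estimate carries the short code of the rule that produced it and a
human-readable explanation.  Explanations for rule-driven estimates come
from a deterministic template per rule code; explanations attached to
working-group decisions are propagated to the output verbatim.  The
registry is a single table, so adding a refined rule means registering one
more code and template.

The country report is the transparency surface of the whole system: a plot
per vaccine overlaying the empirical data and the estimates, a combined CSV
table, and a per-year explanation list, emitted as one HTML file per
country plus the CSVs.  CSV output is byte-deterministic for identical
inputs.  (Explanation templates beyond the codes' canonical wording are
this implementation's phrasing.)
"""
from __future__ import annotations

from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .knowledge_base import (
    Estimate,
    KnowledgeBase,
    SurveyResult,
    write_estimates,
)
from .level1 import GradedSeries


class UnregisteredRuleCode(KeyError):
    """A rule produced a code the registry does not know."""


def _anchor_phrase(years: Sequence[int]) -> str:
    ys = [str(y) for y in years]
    if len(ys) == 1:
        return ys[0]
    return ", ".join(ys[:-1]) + " and " + ys[-1]


def _explain_apr(ctx: Mapping) -> str:
    return "Reported coverage is supported by survey"


def _explain_aps(ctx: Mapping) -> str:
    return "Estimate based on survey results; survey does not support reported coverage"


def _explain_wgd(ctx: Mapping) -> str:
    return ctx["decision_explanation"]


def _explain_reported(ctx: Mapping) -> str:
    anchors = ctx.get("anchor_years") or ()
    if anchors:
        return (
            "Estimate based on reported data because surveys support reported "
            f"data in {_anchor_phrase(anchors)}"
        )
    return "Estimate based on reported data"


def _explain_interpolated(ctx: Mapping) -> str:
    before, after = ctx.get("between", (None, None))
    if before is not None:
        return (
            f"Estimate interpolated between reported data for {before} and {after}"
        )
    return "Estimate interpolated between neighbouring reported years"


def _explain_extrapolated(ctx: Mapping) -> str:
    nearest = ctx.get("nearest_year")
    if nearest is not None:
        return (
            "Estimate extrapolated from the reported data because there was no "
            f"reported data; nearest reported value is for {nearest}"
        )
    return "Estimate extrapolated from the nearest reported data"


def _explain_calibrated(ctx: Mapping) -> str:
    anchors = ctx.get("anchor_years") or ()
    noun = "estimate" if len(anchors) == 1 else "estimates"
    return (
        "Reported data calibrated to the level of the "
        f"{_anchor_phrase(anchors)} {noun}"
    )


def _explain_wgd_interpolate(ctx: Mapping) -> str:
    return (
        "Interpolated between anchor point estimates by working group decision: "
        + ctx["decision_explanation"]
    )


def _explain_rmf(ctx: Mapping) -> str:
    return f"DTP1 estimate derived from the DTP3 estimate ({ctx['trigger']})"


#: rule code -> (description, template)
RULE_REGISTRY: dict[str, tuple[str, Callable[[Mapping], str]]] = {
    "AP:R": ("anchor point, resolved to reported data", _explain_apr),
    "AP:S": ("anchor point, resolved to survey results", _explain_aps),
    "AP:W": ("anchor point, assigned by working group decision", _explain_wgd),
    "W": ("estimate assigned by working group decision", _explain_wgd),
    "R": ("reported data passed through", _explain_reported),
    "I": ("interpolated between reported years", _explain_interpolated),
    "E": ("nearest-neighbour extrapolation", _explain_extrapolated),
    "C": ("reported data calibrated to anchor estimates", _explain_calibrated),
    "W:I": ("interpolation between anchors by working group decision", _explain_wgd_interpolate),
    "RMF": ("DTP1 reconciled from DTP3", _explain_rmf),
}


def validate_rule_codes(codes: Iterable[str]) -> None:
    """Fail fast if any code is not registered (checked before rendering)."""
    unknown = sorted(set(codes) - set(RULE_REGISTRY))
    if unknown:
        raise UnregisteredRuleCode(f"unregistered rule codes: {unknown}")


def explain(rule_code: str, ctx: Optional[Mapping] = None) -> str:
    """Deterministic explanation text for one estimate."""
    if rule_code not in RULE_REGISTRY:
        raise UnregisteredRuleCode(rule_code)
    return RULE_REGISTRY[rule_code][1](ctx or {})


# ---------------------------------------------------------------------------
# country report
# ---------------------------------------------------------------------------

def render_country_report(
    country: str,
    estimates: Sequence[Estimate],
    graded: Mapping[tuple[str, str], GradedSeries],
    kb: KnowledgeBase,
    out_dir: str | Path,
) -> list[Path]:
    """Write the per-country report: PNG plot per vaccine, combined CSV
    table, and an HTML page with the explanation list.  Returns the files
    written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    mine = sorted(
        (e for e in estimates if e.key.country == country), key=lambda e: e.key
    )
    table_path = out_dir / f"{country}_estimates.csv"
    write_estimates(mine, table_path)
    written.append(table_path)

    vaccines = sorted({e.key.vaccine for e in mine})
    plots: list[tuple[str, Path]] = []
    for vaccine in vaccines:
        path = out_dir / f"{country}_{vaccine}.png"
        _plot_vaccine(country, vaccine, mine, graded.get((country, vaccine)), path)
        plots.append((vaccine, path))
        written.append(path)

    html_path = out_dir / f"{country}.html"
    html_path.write_text(
        _render_html(country, mine, plots, graded, kb), encoding="utf-8"
    )
    written.append(html_path)
    return written


def _plot_vaccine(country, vaccine, estimates, gseries: Optional[GradedSeries], path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    est = [e for e in estimates if e.key.vaccine == vaccine]
    if est:
        ax.plot(
            [e.key.year for e in est], [e.coverage for e in est],
            "-o", color="black", label="estimate",
        )
    if gseries is not None:
        rep = [(g.key.year, g.origin.coverage, g.is_accepted) for g in gseries.graded_reported]
        if rep:
            rep.sort()
            ax.plot(
                [y for y, _, _ in rep], [c for _, c, _ in rep],
                "s--", color="tab:blue", alpha=0.7, label="reported",
            )
            rej = [(y, c) for y, c, ok in rep if not ok]
            if rej:
                ax.plot(
                    [y for y, _ in rej], [c for _, c in rej],
                    "x", color="tab:red", markersize=9, label="reported (excluded)",
                )
        surv = [
            (g.key.year, g.coverage, g.is_accepted) for g in gseries.graded_surveys
        ]
        if surv:
            acc = [(y, c) for y, c, ok in surv if ok]
            exc = [(y, c) for y, c, ok in surv if not ok]
            if acc:
                ax.plot([y for y, _ in acc], [c for _, c in acc], "^",
                        color="tab:green", markersize=9, label="survey")
            if exc:
                ax.plot([y for y, _ in exc], [c for _, c in exc], "v",
                        color="tab:orange", markersize=9, label="survey (excluded)")
    ax.set_title(f"{country} {vaccine}")
    ax.set_xlabel("year")
    ax.set_ylabel("coverage (%)")
    ax.set_ylim(0, 105)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _render_html(country, estimates, plots, graded, kb: KnowledgeBase) -> str:
    parts = [
        "<!DOCTYPE html>",
        f"<html><head><meta charset='utf-8'><title>{country} coverage estimates</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:3px 8px;font-size:13px}</style></head><body>",
        f"<h1>Immunization coverage estimates: {country}</h1>",
    ]
    if not estimates:
        parts.append("<p><strong>No estimate produced</strong> for this country: "
                     "no accepted data or working-group decision was available "
                     "for any required combination.</p>")
    else:
        for vaccine, path in plots:
            parts.append(f"<h2>{vaccine}</h2><img src='{path.name}' alt='{country} {vaccine}'>")
        parts.append("<h2>Estimates</h2><table><tr><th>vaccine</th><th>year</th>"
                     "<th>coverage (%)</th><th>rule</th></tr>")
        for e in estimates:
            parts.append(
                f"<tr><td>{e.key.vaccine}</td><td>{e.key.year}</td>"
                f"<td>{e.coverage:g}</td><td>{e.rule_code}</td></tr>"
            )
        parts.append("</table>")
        parts.append("<h2>Explanations</h2><ul>")
        for e in estimates:
            parts.append(
                f"<li><strong>{e.key.vaccine} {e.key.year}</strong> "
                f"({e.rule_code}): {e.explanation}</li>"
            )
        parts.append("</ul>")
    decisions = sorted(
        (d for d in kb.decisions if d.key.country == country),
        key=lambda d: (d.key, d.action),
    )
    if decisions:
        parts.append("<h2>Working group decisions</h2><ul>")
        for d in decisions:
            parts.append(
                f"<li>{d.key.vaccine} {d.key.year} — {d.action}: {d.explanation}</li>"
            )
        parts.append("</ul>")
    parts.append("</body></html>")
    return "\n".join(parts)
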