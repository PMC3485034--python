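"""A deliberately naive, straight-line re-derivation of the estimation rules.

Used as an independent oracle: it consumes the same knowledge-base
containers but shares no grading/estimation code with the engine.  Every
rule is applied in plain loops over dictionaries, closely following the
written rule statements.  Returns, per required key, the full-precision
estimate and the rule code that produced it.
"""
from __future__ import annotations

import re

from wuenic.config import Config
from wuenic.knowledge_base import EstimateKey, KnowledgeBase


def _clamp(x):
    return min(100.0, max(0.0, x))


def _dose(vaccine):
    m = re.match(r"^([a-z]+)(\d+)$", vaccine)
    return (m.group(1), int(m.group(2))) if m else (vaccine, 1)


def _accepted_reported(kb: KnowledgeBase, c, v, cfg: Config):
    """year -> coverage after source precedence, filters and decisions."""
    rows = {}
    for p in kb.reported:
        if p.key.country == c and p.key.vaccine == v:
            rows.setdefault(p.key.year, {})[p.source] = p.coverage
    chosen = {}
    for y, by_source in rows.items():
        for src in cfg.source_precedence:
            if src in by_source:
                chosen[y] = by_source[src]
                break
        else:
            chosen[y] = by_source[sorted(by_source)[0]]

    ok = {y: cov for y, cov in chosen.items() if cov < 100}

    spikes = set()
    for y in ok:
        if y - 1 in ok and y + 1 in ok:
            din, dout = ok[y] - ok[y - 1], ok[y + 1] - ok[y]
            if (abs(din) > cfg.jump_threshold and abs(dout) > cfg.jump_threshold
                    and din * dout < 0):
                spikes.add(y)
    ok = {y: cov for y, cov in ok.items() if y not in spikes}
    if cfg.exclude_flagged_jumps:
        flagged = set()
        for y in list(ok):
            if y + 1 in ok and abs(ok[y + 1] - ok[y]) > cfg.jump_threshold:
                flagged.update((y, y + 1))
        ok = {y: cov for y, cov in ok.items() if y not in flagged}

    for d in kb.decisions:
        if d.key.country == c and d.key.vaccine == v and d.key.year in chosen:
            if d.action == "acceptReported":
                ok[d.key.year] = chosen[d.key.year]
            elif d.action == "ignoreReported":
                ok.pop(d.key.year, None)
    return ok


def _accepted_surveys(kb: KnowledgeBase, c, v, cfg: Config):
    """year -> list of (survey_id, effective coverage) after filters,
    decisions and recall-bias adjustment."""
    decisions = {}
    for d in kb.decisions:
        if d.key.country == c and d.key.vaccine == v:
            decisions.setdefault(d.key.year, []).append(d.action)

    out = {}
    for s in kb.surveys:
        if s.key.country != c or s.key.vaccine != v:
            continue
        desc = kb.survey_descriptions[s.survey_id]
        keep = True
        if desc.sample_size < cfg.survey_min_sample_size:
            keep = False
        if (desc.cohort_min_months < cfg.cohort_valid_min_months
                or desc.cohort_max_months > cfg.cohort_valid_max_months):
            keep = False
        acts = decisions.get(s.key.year, [])
        if "acceptSurvey" in acts:
            keep = True
        if "ignoreSurvey" in acts:
            keep = False
        if not keep:
            continue

        value = s.coverage
        antigen, dose = _dose(v)
        if dose > 1 and s.coverage_card is not None:
            dose1 = [
                o for o in kb.surveys
                if o.survey_id == s.survey_id and o.key.year == s.key.year
                and _dose(o.key.vaccine) == (antigen, 1)
            ]
            if dose1 and dose1[0].coverage_card:
                value = s.coverage_card * dose1[0].coverage / dose1[0].coverage_card
        out.setdefault(s.key.year, []).append((s.survey_id, value))
    return out


def _survey_mean(entries, kb, cfg):
    entries = sorted(entries)
    if cfg.multi_survey_weighting == "sample_size":
        weights = [kb.survey_descriptions[sid].sample_size for sid, _ in entries]
        return sum(w * v for w, (_, v) in zip(weights, entries)) / sum(weights)
    return sum(v for _, v in entries) / len(entries)


def _completed(accepted, years):
    """Linear interpolation inside, nearest value outside; {} if no data."""
    if not accepted:
        return {}, {}
    known = sorted(accepted)
    series, kind = {}, {}
    for y in years:
        if y in accepted:
            series[y], kind[y] = accepted[y], "reported"
        elif y < known[0]:
            series[y], kind[y] = accepted[known[0]], "extrapolated"
        elif y > known[-1]:
            series[y], kind[y] = accepted[known[-1]], "extrapolated"
        else:
            lo = max(b for b in known if b < y)
            hi = min(a for a in known if a > y)
            series[y] = accepted[lo] + (y - lo) * (accepted[hi] - accepted[lo]) / (hi - lo)
            kind[y] = "interpolated"
    return series, kind


def naive_estimates(kb: KnowledgeBase, cfg: Config | None = None):
    """key -> (full-precision clamped estimate, rule code) for required keys."""
    cfg = cfg or Config()
    out = {}
    pairs = sorted({(k.country, k.vaccine) for k in kb.required})
    for c, v in pairs:
        req = sorted(k.year for k in kb.required if (k.country, k.vaccine) == (c, v))
        accepted = _accepted_reported(kb, c, v, cfg)
        surveys = _accepted_surveys(kb, c, v, cfg)
        assigns = {
            d.key.year: d for d in kb.decisions
            if (d.key.country, d.key.vaccine) == (c, v) and d.action == "assignWUENIC"
        }
        interp_years = {
            d.key.year for d in kb.decisions
            if (d.key.country, d.key.vaccine) == (c, v) and d.action == "interpolate"
        }

        fill = sorted(set(req) | set(accepted) | set(surveys) | set(assigns))
        series, kind = _completed(accepted, fill)

        anchors = {}
        for y in sorted((set(accepted) & set(surveys)) | set(assigns)):
            if y in assigns:
                anchors[y] = ("AP:W", _clamp(assigns[y].assigned_coverage))
            else:
                mean = _survey_mean(surveys[y], kb, cfg)
                if abs(mean - accepted[y]) < cfg.support_threshold:
                    anchors[y] = ("AP:R", _clamp(accepted[y]))
                else:
                    anchors[y] = ("AP:S", _clamp(mean))
        ayears = sorted(anchors)

        if not series and not anchors:
            continue  # gap: no estimates at all

        for y in req:
            if y in anchors:
                code, value = anchors[y]
            elif not series:
                before = [a for a in ayears if a < y]
                after = [a for a in ayears if a > y]
                if before and after:
                    y1, y2 = before[-1], after[0]
                    v1, v2 = anchors[y1][1], anchors[y2][1]
                    value = v1 + (y - y1) * (v2 - v1) / (y2 - y1)
                    code = "I"
                else:
                    value = anchors[before[-1] if before else after[0]][1]
                    code = "E"
            elif not anchors:
                if y in assigns:
                    code, value = "W", assigns[y].assigned_coverage
                else:
                    value = series[y]
                    code = {"reported": "R", "interpolated": "I",
                            "extrapolated": "E"}[kind[y]]
            else:
                before = [a for a in ayears if a < y]
                after = [a for a in ayears if a > y]
                if before and after:
                    y1, y2 = before[-1], after[0]
                    if any(y1 < iy < y2 for iy in interp_years):
                        v1, v2 = anchors[y1][1], anchors[y2][1]
                        value = v1 + (y - y1) * (v2 - v1) / (y2 - y1)
                        code = "W:I"
                    elif anchors[y1][0] == "AP:R" and anchors[y2][0] == "AP:R":
                        value = series[y]
                        code = {"reported": "R", "interpolated": "I",
                                "extrapolated": "E"}[kind[y]]
                    else:
                        value = _calibrate(series, anchors, (y1, y2), y, cfg)
                        code = "E" if kind[y] == "extrapolated" else "C"
                else:
                    a = before[-1] if before else after[0]
                    if anchors[a][0] == "AP:R":
                        value = series[y]
                        code = {"reported": "R", "interpolated": "I",
                                "extrapolated": "E"}[kind[y]]
                    else:
                        value = _calibrate(series, anchors, (a,), y, cfg)
                        code = "E" if kind[y] == "extrapolated" else "C"
            out[EstimateKey(c, v, y)] = (_clamp(value), code)

    # cross-vaccine reconciliation: DTP1 from DTP3
    a, b, cc = cfg.dtp1_coefficients
    for key, (dtp3, _) in sorted(out.items()):
        if key.vaccine != "dtp3":
            continue
        k1 = EstimateKey(key.country, "dtp1", key.year)
        have = out.get(k1)
        if have is not None and have[1] in ("AP:W", "W"):
            continue  # working-group assignments dominate reconciliation
        if (have is None and k1 in kb.required) or (have is not None and have[0] < dtp3):
            poly = _clamp(dtp3 + a * dtp3 * dtp3 + b * dtp3 + cc)
            out[k1] = (poly, "RMF")
    return out


def _calibrate(series, anchors, anchor_years, y, cfg):
    additive = cfg.calibration == "additive" or any(
        series[a] == 0 for a in anchor_years
    )

    def factor(a):
        est = anchors[a][1]
        return est - series[a] if additive else est / series[a]

    if len(anchor_years) == 1:
        f = factor(anchor_years[0])
    else:
        y1, y2 = anchor_years
        t = (y - y1) / (y2 - y1)
        f = factor(y1) + t * (factor(y2) - factor(y1))
    return _clamp(series[y] + f if additive else series[y] * f)
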