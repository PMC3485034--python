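# wuenic

A deterministic, fully explainable rule engine for estimating national
immunization coverage the way the WHO/UNICEF annual review does it:
country-by-country reconciliation of coverage reported by national
authorities with household-survey results, constrained by documented
expert decisions, producing one estimate per required
country/vaccine/year **with the rule that produced it and a
human-readable justification**.

## Who this is for

Public-health analysts and estimation teams who need coverage time series
that are *auditable*: every accepted, modified or excluded data point, every
anchor resolution and every expert override is logged with a reason, and the
whole pipeline is a pure function of its input tables — permuting input rows
or re-running on another machine gives byte-identical output.

## The estimation rules

Coverage is in percentage points throughout (97 means 97 %). For every
country *C*, vaccine *V* and year *Y*, with reported coverage *P*<sub>rpt</sub>
and survey coverage *P*<sub>surv</sub>, the engine applies four levels of rules:

**Level 1 — grade the data.** Reported values ≥ 100 % are excluded; a
one-year spike whose rise and fall both exceed the jump threshold (default
20 points) excludes the outlying year; surveys with sample size < 300 or an
age cohort outside the valid band are excluded; multi-dose survey results
are corrected for recall bias by the card/history ratio
*card-only*<sub>dose k</sub> × (*either*<sub>dose 1</sub> / *card-only*<sub>dose 1</sub>).
Working-group decisions are evaluated last and dominate every filter.
A complete reported series is then built: linear interpolation

  *P*<sub>inter</sub> = *P*<sub>before</sub> + (*Y*<sub>inter</sub> − *Y*<sub>before</sub>) ·
  (*P*<sub>after</sub> − *P*<sub>before</sub>) / (*Y*<sub>after</sub> − *Y*<sub>before</sub>)

inside the observed range, nearest-neighbour extrapolation outside it.

**Level 2 — resolve anchors.** A year with both accepted reported data and
an accepted survey is an *anchor point*. The survey *supports* the report
iff |*P*<sub>surv</sub> − *P*<sub>rpt</sub>| < 10 (strict). Precedence, realizing the
closed-world override semantics as deterministic guards: an expert
assignment wins (code `AP:W`), else support ⇒ reported value (`AP:R`), else
the survey value (`AP:S`). Multiple same-year surveys are averaged first.

**Level 3 — complete the series.** Between two `AP:R` anchors the reported
series passes through (`R`/`I`/`E` by provenance); otherwise it is
*calibrated*: scaled by a ratio interpolated linearly between the endpoint
ratios *anchor estimate / reported value*, so it passes exactly through the
anchors (`C`). Beyond the outermost anchor a constant ratio applies; years
with no report at all take the nearest estimate (`E`). A working-group
`interpolate` decision replaces a segment with a straight line between the
anchor estimates (`W:I`). With no anchors the completed reported series is
the estimate.

**Level 4 — reconcile across vaccines.** A missing DTP1 estimate, or one
below DTP3, is replaced (code `RMF`) by the modelled value

  DTP1 = DTP3 − 0.0066·DTP3² + 0.4799·DTP3 + 16.67,  clamped to [0, 100].

Estimates are clamped to [0, 100] and rounded (half away from zero) only at
output; full-precision values are kept in the `coverage_raw` column.

## Worked example

```python
from wuenic import run_pipeline
from wuenic.fixtures import egypt_fixture

kb, _ = egypt_fixture("2007")     # Egypt DTP3, 2004-2007
for e in run_pipeline(kb).estimates:
    print(e.key, int(e.coverage), e.rule_code, "-", e.explanation[:60])
```

prints

```
egy/dtp3/2004 97 AP:R - Reported coverage is supported by survey
egy/dtp3/2005 96 AP:R - Reported coverage is supported by survey
egy/dtp3/2006 85 AP:S - Estimate based on survey results; survey does not support re
egy/dtp3/2007 94 AP:W - While the reported coverage seems to be supported by survey
```

2004/2005: the surveys (93.5, 95) lie within 10 points of the reports
(97, 96), so the reported values stand. 2006: the survey (85) is 12 points
below the report (97), so the estimate follows the survey. 2007: an expert
assignment of 94 overrides the data, and its stored justification is
propagated verbatim.

The same run from the shell, with CSV artifacts and an HTML country report:

```bash
wuenic run --data DATA_DIR --out OUT_DIR            # estimates.csv, audit.csv, reports/
wuenic check --out OUT_DIR                          # re-verify uniqueness/completeness
```

`audit.csv` is the transparency surface: one row per graded data point with
its status and reason (e.g. `ge100`, `jump_spike`, `small_sample`,
`wgd_accept`).

Rule thresholds (support band, jump threshold, sample-size floor, DTP1
polynomial, calibration form) live in a YAML config; see
`wuenic.Config` and `docs/methods.md`.

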