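# Methods

## The procedure and its assumptions

The engine is a deterministic re-statement of the heuristic review process
behind annual national immunization coverage estimates. Its core premise
is that estimation here is *rule application plus documented judgement*,
not model fitting: data of uneven quality from national reporting systems
and household surveys are graded, reconciled at years where both exist,
and the resulting levels are propagated along the reported trend. Expert
(working-group) decisions are first-class inputs that dominate every rule,
which is the closed-world override semantics of a logic-programming rule
base ("this rule engages only if no decision exists") realized as guarded
if/else precedence. Consequences of that design:

* estimates are a pure function of the input tables — no randomness, no
  iteration order dependence, no hidden state;
* every output carries the code of the single rule that fired and an
  explanation, so a disputed estimate can be traced to the exact data and
  decisions behind it;
* countries never influence each other, and vaccines interact only in the
  DTP1/DTP3 reconciliation step.

The engine produces point estimates only; no uncertainty intervals are
attached, because the underlying procedure defines none.

## Parameters

All thresholds live in `wuenic.Config` (YAML-serializable). Units are
percentage points unless noted.

| parameter | default | meaning |
|---|---|---|
| `support_threshold` | 10 | survey supports report iff abs. difference is strictly below this |
| `survey_min_sample_size` | 300 | smaller surveys excluded unless reinstated by decision |
| `jump_threshold` | 20 | year-over-year change treated as a reporting artefact |
| `exclude_flagged_jumps` | false | isolated (non-spike) jumps flag both years; exclude only if true |
| `cohort_valid_min/max_months` | 12 / 35 | admissible survey age-cohort band |
| `dtp1_coefficients` | (−0.0066, 0.4799, 16.67) | DTP1−DTP3 difference polynomial in DTP3 |
| `multi_survey_weighting` | unweighted | same-year surveys averaged; optionally by sample size |
| `calibration` | ratio | multiplicative calibration; `additive` shifts instead |
| `source_precedence` | reported > gov > admin | winner when several reported-type sources exist for one key |
| `year_min` / `year_max` | 1997 / 2011 | estimation window enforced at load |

The 10-point support band, the 300-child sample floor, the ≥ 100 %
exclusion and the polynomial coefficients are the published operational
values of the procedure; the jump threshold is published only as "large
changes", so 20 points is this package's default, chosen so that typical
administrative year-to-year noise (a few points) never triggers it while
genuine one-year collapses do.

## Decisions where the design was open

* **Spike attribution.** A year whose incoming and outgoing changes both
  exceed the threshold with opposite signs is the outlying year and is
  excluded alone. An isolated large jump with no recovery is ambiguous —
  either year could be wrong — so both are flagged for review and excluded
  only if configured. This keeps the behaviour where a genuine one-year
  decline is excluded by the filter and then reinstated by an
  `acceptReported` decision.
* **Jump adjacency.** "From one year to the next" is read as consecutive
  *calendar* years; a gap (missing or excluded year) breaks the
  comparison.
* **Calibration form.** "Calibrated to the level of the anchor estimates"
  fixes the endpoints but not the path. The multiplicative ratio, blended
  linearly in time between the two endpoint ratios, is used because it
  preserves zero and ordering for proportions and degrades continuously
  to the identity as anchors approach the reported values. When a
  reported value at an anchor is exactly zero the ratio is undefined and
  an additive shift is used (logged). A decision-assigned anchor does not
  certify the reported series, so it calibrates like a survey anchor.
* **Recall-bias formula.** The adjustment for multi-dose antigens is
  specified here as the standard card/history correction:
  card-only dose-k coverage × (dose-1 either-method / dose-1 card-only),
  applied only when one survey reports all three quantities for the same
  birth cohort (the `coverage_card` column of `surveys.csv`); otherwise
  the point passes unchanged with the reason recorded. The exact
  correction used in production review is not published; this one is
  isolated behind a single function so it can be swapped.
* **Source precedence.** When reported, administrative and
  government-estimate values coexist for one key, one value per year is
  selected by configured precedence and the others are graded
  `source_precedence`-excluded, keeping the graded output an exact
  partition of the input.
* **Override scope.** Working-group assignments dominate *every* rule,
  including DTP1/DTP3 reconciliation: a decision-assigned DTP1 estimate is
  never rewritten even if it sits below DTP3.
* **Near-100 % DTP1 anomaly.** Above a DTP3 level of ≈ 98.4 (the positive
  root of the difference polynomial) the modelled DTP1 falls below DTP3.
  The raw polynomial is kept, clamped only to [0, 100]; DTP1 is not forced
  above DTP3, and the occurrence is logged.

## Numerical choices

Full precision is kept end to end; clamping to [0, 100] and rounding to
integers (half away from zero) happen only when finalizing output, and
`estimates.csv` retains the unrounded value in `coverage_raw`. The support
test is strictly `<`. Interpolation is the exact two-point line formula;
anchor fidelity (the estimate at an anchor equals the anchor value before
rounding) is exact by construction, not approximate. Degenerate inputs:
zero accepted reported points with no anchors yield a logged *gap*, not an
estimate; anchors without any reported series are connected by straight
lines and extended by constants.

## What the synthetic generators emulate

`egypt_fixture` reproduces the canonical two-to-four-year worked example
exactly. `scenario_figure3` is a twelve-year, one-country scenario
constructed so that each year exercises a distinct behaviour (small-sample
exclusion, non-supporting survey, calibration, passthrough, reinstated
decline, extrapolation into a report-free year); its country and numbers
are synthetic — what is fixed is which rule fires each year, with expected
values derived by plain arithmetic in the fixture itself. `random_kb`
draws latent true coverage trajectories as bounded random walks in
[5, 95], reported values as truth + per-series bias + noise with optional
injected spikes and ≥ 100 % artefacts, surveys as truth + noise with
sample sizes spanning the 300 boundary, and decisions at a configurable
rate. Default sizes — 3 countries × 3 vaccines × 15 years (1997–2011) —
mirror the per-country scale of the real review; property suites run 200
one-country seeds for override dominance and a handful of two-country
seeds elsewhere, which completes in seconds.

These generators do not emulate real-world coverage distributions,
reporting-system heterogeneity across 194 countries, or correlated
multi-vaccine survey errors. Passing tests therefore demonstrate that the
rules are implemented correctly and deterministically, not that the rules
themselves are epidemiologically optimal.

## Verification strategy

Besides unit tests with hand-evaluated expected values, a second, naive
evaluator (`tests/naive_reference.py`) re-derives every estimate with
plain loops over dictionaries, sharing no grading or estimation code with
the engine; engine and oracle must agree on value (1e-9) and rule code on
every fixture, golden and random. Interpolation is additionally checked
against a least-squares line fit on 1,000 random triples.

## Known limitations

* No uncertainty quantification, by design.
* The recall-bias correction and the jump threshold are this package's
  operational choices where the procedure's published description is
  silent; both are configurable.
* Only the DTP1/DTP3 pair is reconciled across vaccines.
* Explanation templates beyond the canonical anchor-rule wording are this
  implementation's phrasing.
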