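"""Run configuration.

Every numeric threshold the estimation rules depend on lives here, so
refining a rule (a different support band, a recalibrated DTP1 polynomial,
a stricter jump filter) is a config edit, not a code change.  Values are
percentage points throughout: a coverage of 97 means 97%.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_VACCINES: tuple[str, ...] = (
    "bcg",
    "dtp1",
    "dtp2",
    "dtp3",
    "hepb3",
    "hib3",
    "mcv",
    "mcv1",
    "mcv2",
    "pol1",
    "pol2",
    "pol3",
)


@dataclass(frozen=True)
class Config:
    """Tunable parameters of the estimation rules.

    Attributes
    ----------
    support_threshold:
        A survey supports reported coverage when the absolute difference is
        strictly below this many percentage points.
    survey_min_sample_size:
        Surveys with fewer respondents are excluded unless reinstated by a
        working-group decision.
    jump_threshold:
        Year-over-year changes in reported coverage larger than this are
        treated as reporting artefacts.
    exclude_flagged_jumps:
        A one-year spike (large rise *and* fall, or fall and rise) always
        excludes the outlying year.  An isolated large jump with no recovery
        only flags both flanking years for review; set this to True to
        exclude them as well.
    cohort_valid_min_months / cohort_valid_max_months:
        Survey age cohorts must lie inside this band (months) to count as
        measuring routine infant immunization.
    dtp1_coefficients:
        (a, b, c) of the second-degree polynomial modelling the
        DTP1 - DTP3 difference as a function of DTP3 coverage.
    multi_survey_weighting:
        "unweighted" averages multiple same-year surveys; "sample_size"
        weights them by sample size.
    calibration:
        "ratio" scales the reported series multiplicatively to pass through
        anchor estimates (falls back to an additive shift when the reported
        value at an anchor is zero); "additive" always shifts.
    source_precedence:
        When several reported-type sources exist for one country/vaccine/
        year, the first source in this tuple that is present wins.
    year_min / year_max:
        The estimation window; keys outside it are rejected at load time.
    vaccines:
        The vaccine-dose vocabulary accepted in input tables.
    """

    support_threshold: float = 10.0
    survey_min_sample_size: int = 300
    jump_threshold: float = 20.0
    exclude_flagged_jumps: bool = False
    cohort_valid_min_months: int = 12
    cohort_valid_max_months: int = 35
    dtp1_coefficients: tuple[float, float, float] = (-0.0066, 0.4799, 16.67)
    multi_survey_weighting: str = "unweighted"
    calibration: str = "ratio"
    source_precedence: tuple[str, ...] = ("reported", "gov", "admin")
    year_min: int = 1997
    year_max: int = 2011
    vaccines: tuple[str, ...] = DEFAULT_VACCINES

    def __post_init__(self) -> None:
        if self.multi_survey_weighting not in ("unweighted", "sample_size"):
            raise ValueError(
                f"multi_survey_weighting must be 'unweighted' or 'sample_size', "
                f"got {self.multi_survey_weighting!r}"
            )
        if self.calibration not in ("ratio", "additive"):
            raise ValueError(
                f"calibration must be 'ratio' or 'additive', got {self.calibration!r}"
            )
        if len(self.dtp1_coefficients) != 3:
            raise ValueError("dtp1_coefficients must be a (a, b, c) triple")
        if self.year_min > self.year_max:
            raise ValueError("year_min must not exceed year_max")

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "Config":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = dict(raw)
        for key in ("dtp1_coefficients", "source_precedence", "vaccines"):
            if key in coerced and isinstance(coerced[key], Sequence):
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=True), encoding="utf-8"
        )

    def with_(self, **kwargs) -> "Config":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
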