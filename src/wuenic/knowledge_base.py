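"""Domain types and delimited-text I/O for the coverage knowledge base.

A knowledge base is five relational tables, one CSV file each:

* ``reported.csv`` — source-tagged coverage reported by national
  authorities (``country,vaccine,year,source,coverage``);
* ``surveys.csv`` — per-vaccine, per-birth-cohort survey coverage
  (``survey_id,country,vaccine,cohort_year,coverage[,coverage_card]``),
  where the optional ``coverage_card`` column carries the card-documented
  coverage used by the recall-bias adjustment;
* ``survey_descriptions.csv`` — one row of metadata per survey;
* ``decisions.csv`` — working-group overrides, each with a mandatory
  explanation;
* ``required.csv`` — the country/vaccine/year combinations for which an
  estimate must be produced.

Coverage is stored in percentage points everywhere (97 means 97%).
Values >= 100 are representable in reported data because the grading rules
must see them in order to exclude them.  All invariants are enforced at
load time; violations raise :class:`KnowledgeBaseError` with row context.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import Config

SOURCES = ("reported", "admin", "gov")
ACTIONS = (
    "assignWUENIC",
    "ignoreReported",
    "ignoreSurvey",
    "acceptReported",
    "acceptSurvey",
    "interpolate",
    "comment",
)
SURVEY_TYPES = ("DHS", "MICS", "EPI-cluster", "other")
CONFIRMATION_METHODS = ("card", "caretaker", "either")


class KnowledgeBaseError(ValueError):
    """Raised on any schema or invariant violation in an input table."""

    def __init__(self, message: str, *, table: str | None = None, row: int | None = None):
        ctx = ""
        if table is not None:
            ctx = f" [table={table}" + (f", row={row}" if row is not None else "") + "]"
        super().__init__(message + ctx)
        self.table = table
        self.row = row


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class EstimateKey:
    """Unique join key across all tables: country / vaccine-dose / year."""

    country: str
    vaccine: str
    year: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.country}/{self.vaccine}/{self.year}"


@dataclass(frozen=True)
class DataPoint:
    """One source-tagged coverage observation reported by a national authority."""

    key: EstimateKey
    source: str  # one of SOURCES
    coverage: float  # percentage points, >= 0; >= 100 representable

    @property
    def ref(self) -> str:
        k = self.key
        return f"{self.source}:{k.country}:{k.vaccine}:{k.year}"


@dataclass(frozen=True)
class SurveyDescription:
    survey_id: str
    title: str
    survey_type: str
    collection_year: int
    percent_cards_seen: float
    confirmation_method: str
    cohort_min_months: int
    cohort_max_months: int
    sample_size: int


@dataclass(frozen=True)
class SurveyResult:
    """Survey coverage for one vaccine and birth-cohort year.

    ``key.year`` is the birth-cohort year surveyed, not the year of data
    collection.  ``coverage`` is by the survey's confirmation method;
    ``coverage_card`` (optional) is the card-documented coverage used for
    recall-bias correction of multi-dose antigens.
    """

    key: EstimateKey
    survey_id: str
    coverage: float  # percentage points in [0, 100]
    coverage_card: Optional[float] = None

    @property
    def ref(self) -> str:
        k = self.key
        return f"survey:{self.survey_id}:{k.vaccine}:{k.year}"


@dataclass(frozen=True)
class WorkingGroupDecision:
    """An expert override; always carries a documented explanation."""

    key: EstimateKey
    action: str  # one of ACTIONS
    assigned_coverage: Optional[float]  # required iff action == assignWUENIC
    explanation: str

    @property
    def ref(self) -> str:
        k = self.key
        return f"wgd:{self.action}:{k.country}:{k.vaccine}:{k.year}"


@dataclass(frozen=True)
class SeriesPoint:
    year: int
    coverage: float


@dataclass(frozen=True)
class Estimate:
    """Final estimate for one required key.

    ``coverage`` is the published value (clamped to [0, 100] and rounded to
    the nearest integer, half away from zero); ``coverage_raw`` keeps the
    full-precision clamped value for audit and calibration-fidelity checks.
    """

    key: EstimateKey
    coverage: float
    coverage_raw: float
    rule_code: str
    explanation: str
    provenance: tuple[str, ...] = ()


@dataclass
class KnowledgeBase:
    """All validated input tables for one run."""

    reported: list[DataPoint] = field(default_factory=list)
    surveys: list[SurveyResult] = field(default_factory=list)
    survey_descriptions: dict[str, SurveyDescription] = field(default_factory=dict)
    decisions: list[WorkingGroupDecision] = field(default_factory=list)
    required: frozenset[EstimateKey] = field(default_factory=frozenset)

    # -- convenience accessors --------------------------------------------

    def decisions_for(self, key: EstimateKey) -> list[WorkingGroupDecision]:
        return [d for d in self.decisions if d.key == key]

    def assign_decision(self, key: EstimateKey) -> Optional[WorkingGroupDecision]:
        for d in self.decisions:
            if d.key == key and d.action == "assignWUENIC":
                return d
        return None

    def required_pairs(self) -> list[tuple[str, str]]:
        return sorted({(k.country, k.vaccine) for k in self.required})

    def required_years(self, country: str, vaccine: str) -> list[int]:
        return sorted(
            k.year for k in self.required if k.country == country and k.vaccine == vaccine
        )

    def countries(self) -> list[str]:
        return sorted({k.country for k in self.required})

    def sort(self) -> None:
        """Canonical ordering; makes loading order-insensitive."""
        self.reported.sort(key=lambda p: (p.key, p.source))
        self.surveys.sort(key=lambda s: (s.survey_id, s.key))
        self.decisions.sort(key=lambda d: (d.key, d.action, d.explanation))

    def validate(self, config: Config) -> None:
        for p in self.reported:
            _check_key(p.key, config, table="reported")
            if p.coverage < 0:
                raise KnowledgeBaseError(
                    f"negative coverage {p.coverage} for {p.key}", table="reported"
                )
            if p.source not in SOURCES:
                raise KnowledgeBaseError(
                    f"unknown source {p.source!r} for {p.key}", table="reported"
                )
        seen: set[tuple[EstimateKey, str]] = set()
        for p in self.reported:
            if (p.key, p.source) in seen:
                raise KnowledgeBaseError(
                    f"duplicate (key, source) row {p.key} {p.source}", table="reported"
                )
            seen.add((p.key, p.source))

        result_keys: set[tuple[str, str, int]] = set()
        for s in self.surveys:
            _check_key(s.key, config, table="surveys")
            if not (0 <= s.coverage <= 100):
                raise KnowledgeBaseError(
                    f"survey coverage {s.coverage} outside [0, 100] for {s.key}",
                    table="surveys",
                )
            if s.coverage_card is not None and not (0 <= s.coverage_card <= 100):
                raise KnowledgeBaseError(
                    f"coverage_card {s.coverage_card} outside [0, 100] for {s.key}",
                    table="surveys",
                )
            if s.survey_id not in self.survey_descriptions:
                raise KnowledgeBaseError(
                    f"survey result references unknown survey_id {s.survey_id!r}",
                    table="surveys",
                )
            rk = (s.survey_id, s.key.vaccine, s.key.year)
            if rk in result_keys:
                raise KnowledgeBaseError(
                    f"duplicate survey result {rk}", table="surveys"
                )
            result_keys.add(rk)

        for d in self.survey_descriptions.values():
            if d.sample_size < 1:
                raise KnowledgeBaseError(
                    f"sample_size must be >= 1 for {d.survey_id}",
                    table="survey_descriptions",
                )
            if d.cohort_min_months > d.cohort_max_months:
                raise KnowledgeBaseError(
                    f"empty age cohort for {d.survey_id}", table="survey_descriptions"
                )
            if d.survey_type not in SURVEY_TYPES:
                raise KnowledgeBaseError(
                    f"unknown survey_type {d.survey_type!r}", table="survey_descriptions"
                )
            if d.confirmation_method not in CONFIRMATION_METHODS:
                raise KnowledgeBaseError(
                    f"unknown confirmation_method {d.confirmation_method!r}",
                    table="survey_descriptions",
                )

        assign_seen: set[EstimateKey] = set()
        for d in self.decisions:
            _check_key(d.key, config, table="decisions")
            if d.action not in ACTIONS:
                raise KnowledgeBaseError(
                    f"unknown action {d.action!r} for {d.key}", table="decisions"
                )
            if not d.explanation.strip():
                raise KnowledgeBaseError(
                    f"decision for {d.key} has empty explanation", table="decisions"
                )
            if d.action == "assignWUENIC":
                if d.assigned_coverage is None:
                    raise KnowledgeBaseError(
                        f"assignWUENIC decision for {d.key} missing coverage",
                        table="decisions",
                    )
                if not (0 <= d.assigned_coverage <= 100):
                    raise KnowledgeBaseError(
                        f"assigned coverage {d.assigned_coverage} outside [0, 100] "
                        f"for {d.key}",
                        table="decisions",
                    )
                if d.key in assign_seen:
                    raise KnowledgeBaseError(
                        f"multiple assignWUENIC decisions for {d.key}", table="decisions"
                    )
                assign_seen.add(d.key)

        if not self.required:
            raise KnowledgeBaseError("required set is empty", table="required")
        for k in self.required:
            _check_key(k, config, table="required")


def _check_key(key: EstimateKey, config: Config, *, table: str) -> None:
    if not (len(key.country) == 3 and key.country.isalpha() and key.country.islower()):
        raise KnowledgeBaseError(
            f"country {key.country!r} is not an ISO3-style lowercase code", table=table
        )
    if key.vaccine not in config.vaccines:
        raise KnowledgeBaseError(
            f"vaccine {key.vaccine!r} not in configured vocabulary", table=table
        )
    if not (config.year_min <= key.year <= config.year_max):
        raise KnowledgeBaseError(
            f"year {key.year} outside estimation window "
            f"[{config.year_min}, {config.year_max}]",
            table=table,
        )


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "reported": ["country", "vaccine", "year", "source", "coverage"],
    "surveys": ["survey_id", "country", "vaccine", "cohort_year", "coverage"],
    "survey_descriptions": [
        "survey_id",
        "title",
        "type",
        "collection_year",
        "percent_cards_seen",
        "confirmation_method",
        "cohort_min_months",
        "cohort_max_months",
        "sample_size",
    ],
    "decisions": ["country", "vaccine", "year", "action", "coverage", "explanation"],
    "required": ["country", "vaccine", "year"],
}


def _read_table(path: Path, table: str, optional_cols: Sequence[str] = ()) -> pd.DataFrame:
    if not path.exists():
        raise KnowledgeBaseError(f"missing input file {path}", table=table)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(
            f"{path} is missing columns {missing}; found {list(df.columns)}", table=table
        )
    for col in optional_cols:
        if col not in df.columns:
            df[col] = ""
    return df


def _as_float(value: str, table: str, row: int, col: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise KnowledgeBaseError(
            f"column {col!r} value {value!r} is not numeric", table=table, row=row
        ) from None
    if not math.isfinite(out):
        raise KnowledgeBaseError(
            f"column {col!r} value {value!r} is not finite", table=table, row=row
        )
    return out


def _as_int(value: str, table: str, row: int, col: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise KnowledgeBaseError(
            f"column {col!r} value {value!r} is not an integer", table=table, row=row
        ) from None


def load_knowledge_base(data_dir: str | Path, config: Config | None = None) -> KnowledgeBase:
    """Load and validate the five-table knowledge base from ``data_dir``.

    Loading is order-insensitive: tables are brought into canonical order, so
    any permutation of input rows yields an identical knowledge base.
    """
    config = config or Config()
    data_dir = Path(data_dir)

    kb = KnowledgeBase()

    df = _read_table(data_dir / "reported.csv", "reported")
    for i, row in df.iterrows():
        kb.reported.append(
            DataPoint(
                key=EstimateKey(
                    row["country"], row["vaccine"], _as_int(row["year"], "reported", i, "year")
                ),
                source=row["source"],
                coverage=_as_float(row["coverage"], "reported", i, "coverage"),
            )
        )

    df = _read_table(data_dir / "survey_descriptions.csv", "survey_descriptions")
    for i, row in df.iterrows():
        d = SurveyDescription(
            survey_id=row["survey_id"],
            title=row["title"],
            survey_type=row["type"],
            collection_year=_as_int(row["collection_year"], "survey_descriptions", i, "collection_year"),
            percent_cards_seen=_as_float(row["percent_cards_seen"], "survey_descriptions", i, "percent_cards_seen"),
            confirmation_method=row["confirmation_method"],
            cohort_min_months=_as_int(row["cohort_min_months"], "survey_descriptions", i, "cohort_min_months"),
            cohort_max_months=_as_int(row["cohort_max_months"], "survey_descriptions", i, "cohort_max_months"),
            sample_size=_as_int(row["sample_size"], "survey_descriptions", i, "sample_size"),
        )
        if d.survey_id in kb.survey_descriptions:
            raise KnowledgeBaseError(
                f"duplicate survey_id {d.survey_id!r}", table="survey_descriptions", row=i
            )
        kb.survey_descriptions[d.survey_id] = d

    df = _read_table(data_dir / "surveys.csv", "surveys", optional_cols=("coverage_card",))
    for i, row in df.iterrows():
        card = row["coverage_card"].strip()
        kb.surveys.append(
            SurveyResult(
                key=EstimateKey(
                    row["country"], row["vaccine"], _as_int(row["cohort_year"], "surveys", i, "cohort_year")
                ),
                survey_id=row["survey_id"],
                coverage=_as_float(row["coverage"], "surveys", i, "coverage"),
                coverage_card=_as_float(card, "surveys", i, "coverage_card") if card else None,
            )
        )

    df = _read_table(data_dir / "decisions.csv", "decisions")
    for i, row in df.iterrows():
        cov = row["coverage"].strip()
        kb.decisions.append(
            WorkingGroupDecision(
                key=EstimateKey(
                    row["country"], row["vaccine"], _as_int(row["year"], "decisions", i, "year")
                ),
                action=row["action"],
                assigned_coverage=_as_float(cov, "decisions", i, "coverage") if cov else None,
                explanation=row["explanation"],
            )
        )

    df = _read_table(data_dir / "required.csv", "required")
    req = set()
    for i, row in df.iterrows():
        req.add(
            EstimateKey(row["country"], row["vaccine"], _as_int(row["year"], "required", i, "year"))
        )
    kb.required = frozenset(req)

    kb.sort()
    kb.validate(config)
    return kb


# ---------------------------------------------------------------------------
# CSV writers (deterministic column and row order; exact round-trips)
# ---------------------------------------------------------------------------

def _num(x: float) -> str:
    """Shortest exact decimal text for a float (int-like floats print as int)."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_knowledge_base(kb: KnowledgeBase, data_dir: str | Path) -> None:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "country": p.key.country,
            "vaccine": p.key.vaccine,
            "year": p.key.year,
            "source": p.source,
            "coverage": _num(p.coverage),
        }
        for p in sorted(kb.reported, key=lambda p: (p.key, p.source))
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["reported"]).to_csv(
        data_dir / "reported.csv", index=False
    )

    rows = [
        {
            "survey_id": s.survey_id,
            "country": s.key.country,
            "vaccine": s.key.vaccine,
            "cohort_year": s.key.year,
            "coverage": _num(s.coverage),
            "coverage_card": "" if s.coverage_card is None else _num(s.coverage_card),
        }
        for s in sorted(kb.surveys, key=lambda s: (s.survey_id, s.key))
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["surveys"] + ["coverage_card"]).to_csv(
        data_dir / "surveys.csv", index=False
    )

    rows = [
        {
            "survey_id": d.survey_id,
            "title": d.title,
            "type": d.survey_type,
            "collection_year": d.collection_year,
            "percent_cards_seen": _num(d.percent_cards_seen),
            "confirmation_method": d.confirmation_method,
            "cohort_min_months": d.cohort_min_months,
            "cohort_max_months": d.cohort_max_months,
            "sample_size": d.sample_size,
        }
        for d in sorted(kb.survey_descriptions.values(), key=lambda d: d.survey_id)
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["survey_descriptions"]).to_csv(
        data_dir / "survey_descriptions.csv", index=False
    )

    rows = [
        {
            "country": d.key.country,
            "vaccine": d.key.vaccine,
            "year": d.key.year,
            "action": d.action,
            "coverage": "" if d.assigned_coverage is None else _num(d.assigned_coverage),
            "explanation": d.explanation,
        }
        for d in sorted(kb.decisions, key=lambda d: (d.key, d.action, d.explanation))
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["decisions"]).to_csv(
        data_dir / "decisions.csv", index=False
    )

    rows = [
        {"country": k.country, "vaccine": k.vaccine, "year": k.year}
        for k in sorted(kb.required)
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["required"]).to_csv(
        data_dir / "required.csv", index=False
    )


_ESTIMATE_COLUMNS = [
    "country",
    "vaccine",
    "year",
    "coverage",
    "coverage_raw",
    "rule_code",
    "explanation",
    "provenance",
]


def write_estimates(estimates: Iterable[Estimate], path: str | Path) -> None:
    """Write estimates sorted by (country, vaccine, year); round-trips exactly."""
    rows = [
        {
            "country": e.key.country,
            "vaccine": e.key.vaccine,
            "year": e.key.year,
            "coverage": _num(e.coverage),
            "coverage_raw": repr(float(e.coverage_raw)),
            "rule_code": e.rule_code,
            "explanation": e.explanation,
            "provenance": "|".join(e.provenance),
        }
        for e in sorted(estimates, key=lambda e: e.key)
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS).to_csv(path, index=False)


def load_estimates(path: str | Path) -> list[Estimate]:
    path = Path(path)
    if not path.exists():
        raise KnowledgeBaseError(f"missing estimates file {path}", table="estimates")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for i, row in df.iterrows():
        out.append(
            Estimate(
                key=EstimateKey(
                    row["country"], row["vaccine"], _as_int(row["year"], "estimates", i, "year")
                ),
                coverage=_as_float(row["coverage"], "estimates", i, "coverage"),
                coverage_raw=_as_float(row["coverage_raw"], "estimates", i, "coverage_raw"),
                rule_code=row["rule_code"],
                explanation=row["explanation"],
                provenance=tuple(row["provenance"].split("|")) if row["provenance"] else (),
            )
        )
    return out


def round_half_away(x: float) -> float:
    """Round to the nearest integer, ties away from zero (coverage is >= 0)."""
    return float(math.floor(x + 0.5)) if x >= 0 else -float(math.floor(-x + 0.5))


def clamp(x: float, lo: float = 0.0, hi: float = 100.0) -> float:
    return min(hi, max(lo, x))
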