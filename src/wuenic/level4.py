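"""Level 4 — cross-vaccine reconciliation of DTP1 against DTP3.

Levels 1–3 treat each vaccine independently.  In some countries the first
DTP dose is under-reported because it is not the "final" dose of the
schedule, so a DTP1 estimate below the DTP3 estimate (or a missing one) is
not credible: a child with three doses had a first dose.  For those years
DTP1 is re-estimated from DTP3 with a second-degree polynomial modelling
the DTP1−DTP3 difference as a function of DTP3 coverage:

    dtp1 = dtp3 + a·dtp3² + b·dtp3 + c,   (a, b, c) = (−0.0066, 0.4799, 16.67)

clamped to [0, 100].  The default coefficients make the modelled difference
positive up to a DTP3 level of about 98.4% (the positive root of
a·P² + b·P + c); above that the raw polynomial dips below DTP3.  The raw
polynomial is kept faithfully in that regime — DTP1 is *not* forced to
exceed DTP3 — and the occurrence is logged.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

from .config import Config
from .knowledge_base import EstimateKey, clamp
from .level3 import RawEstimate
from .report import explain

log = logging.getLogger("wuenic.level4")

RULE_RECONCILED = "RMF"


def dtp1_from_dtp3(
    p_dtp3: float, coefficients: Sequence[float] = (-0.0066, 0.4799, 16.67)
) -> float:
    """Modelled DTP1 coverage for a given DTP3 coverage, clamped to [0, 100]."""
    a, b, c = coefficients
    return clamp(p_dtp3 + a * p_dtp3 * p_dtp3 + b * p_dtp3 + c)


def breakeven_dtp3(coefficients: Sequence[float] = (-0.0066, 0.4799, 16.67)) -> float:
    """The DTP3 level at which the modelled DTP1−DTP3 difference crosses zero
    (positive root of a·P² + b·P + c = 0); ≈ 98.4 with the default
    coefficients.  Below it the polynomial guarantees DTP1 ≥ DTP3."""
    a, b, c = coefficients
    disc = b * b - 4 * a * c
    assert disc >= 0, "polynomial has no real root"
    roots = [(-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)]
    positive = [r for r in roots if r > 0]
    assert positive, "polynomial has no positive root"
    return min(positive)


def reconcile_dtp1(
    estimates: Iterable[RawEstimate],
    required: Optional[set[EstimateKey]] = None,
    config: Optional[Config] = None,
) -> list[RawEstimate]:
    """Reconcile DTP1 estimates against DTP3, per country and year.

    For each year with a DTP3 estimate, a missing or lower DTP1 estimate is
    replaced by the polynomial value (rule code ``RMF``).  Years where DTP1
    is at or above DTP3 are untouched, and only DTP1 rows are ever
    modified.  When ``required`` is given, missing DTP1 rows are created
    only for required keys.  The operation is idempotent: the replacement
    value depends only on the DTP3 estimate.
    """
    config = config or Config()
    coeff = config.dtp1_coefficients
    out = {e.key: e for e in estimates}
    dtp3_keys = sorted(k for k in out if k.vaccine == "dtp3")
    for k3 in dtp3_keys:
        k1 = EstimateKey(k3.country, "dtp1", k3.year)
        dtp3 = out[k3].value
        existing = out.get(k1)
        if existing is None:
            if required is not None and k1 not in required:
                continue
            trigger = "no DTP1 estimate available"
        elif existing.code in ("AP:W", "W"):
            # a working-group assignment dominates every rule, including this one
            continue
        elif existing.value < dtp3:
            trigger = (
                f"DTP1 estimate {existing.value:g} below DTP3 estimate {dtp3:g}"
            )
        else:
            continue
        value = dtp1_from_dtp3(dtp3, coeff)
        if value < dtp3:
            log.info(
                "reconciled DTP1 %.2f remains below DTP3 %.2f for %s "
                "(polynomial difference negative near 100%%)",
                value, dtp3, k1,
            )
        out[k1] = RawEstimate(
            key=k1,
            value=value,
            code=RULE_RECONCILED,
            explanation=explain(RULE_RECONCILED, {"trigger": trigger}),
            provenance=(f"estimate:dtp3:{k3.country}:{k3.year}",) + out[k3].provenance,
        )
        log.debug("reconcile key=%s rule=%s value=%g", k1, RULE_RECONCILED, value)
    return sorted(out.values(), key=lambda e: e.key)
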