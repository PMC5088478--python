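"""Cost engine: screening-cost build-up and the perspective cost ledger.

The genetic-test cost is assembled from CPT line items (2012 National
Limitation Amounts), compounded at the discount rate from screening age to
treatment age, and topped up with the extra exam/OCT monitoring cost to a
per-capita screening/monitoring cost.  The 12-year negative-cost ledger
(costs *saved* by early versus late treatment: non-ophthalmic medical,
caregiver, employment) is held per early-treatment case under the societal
and third-party-insurer perspectives; negative costs are stored negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .params import CptLine, ModelParameters

__all__ = [
    "PerspectiveCostLedger",
    "cpt_total",
    "compound_to_treatment_age",
    "per_capita_screening_cost",
    "ledger_adjust",
    "ledger_from_params",
    "net_cost_per_early_case",
    "cpt_table",
    "ledger_table",
]

NEGATIVE_BUCKETS = ("direct_non_ophthalmic", "caregiver", "employment")


@dataclass(frozen=True)
class PerspectiveCostLedger:
    """Signed USD components per early-treatment case for one perspective.

    ``screening_cost`` is positive expenditure; the negative buckets carry
    saved costs as negative numbers.  The third-party perspective includes
    only the direct non-ophthalmic medical savings.
    """

    perspective: str
    screening_cost: float
    direct_non_ophthalmic: float
    caregiver: float
    employment: float
    accrual_start_month: int = 7

    def __post_init__(self) -> None:
        if self.perspective not in ("societal", "third_party"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        for bucket in NEGATIVE_BUCKETS:
            if getattr(self, bucket) > 0:
                raise ValueError(f"{bucket} must be <= 0 (a saved cost)")

    @property
    def total_negative(self) -> float:
        if self.perspective == "third_party":
            return self.direct_non_ophthalmic
        return self.direct_non_ophthalmic + self.caregiver + self.employment


def cpt_total(items: Iterable[CptLine]) -> float:
    """Total cost per patient tested, whole dollars."""
    items = list(items)
    if not items:
        raise ValueError("CPT item list must be non-empty")
    for it in items:
        if it.unit_amount < 0:
            raise ValueError(f"CPT {it.code}: negative unit amount")
    return round(sum(it.line_total for it in items))


def compound_to_treatment_age(cost: float, rate: float, periods: int) -> float:
    """Compound a screening-age cost forward to treatment age, whole dollars."""
    if cost < 0 or rate < 0 or periods < 0:
        raise ValueError("cost, rate and periods must be >= 0")
    return round(cost * (1 + rate) ** periods)


def per_capita_screening_cost(compounded_test: float, monitoring_addon: float) -> float:
    if compounded_test < 0 or monitoring_addon < 0:
        raise ValueError("cost components must be >= 0")
    return compounded_test + monitoring_addon


def ledger_adjust(column_a: Mapping[str, float], factor: float) -> dict[str, float]:
    """Scale unadjusted (full-benefit) components by the presentation x
    sensitivity factor (base case 0.780 x 0.622 x 0.90 = 0.4366)."""
    if not 0.0 < factor <= 1.0:
        raise ValueError("adjustment factor must lie in (0, 1]")
    return {name: value * factor for name, value in column_a.items()}


def ledger_from_params(p: ModelParameters, perspective: str) -> PerspectiveCostLedger:
    """Base-case ledger using the printed adjusted components."""
    return PerspectiveCostLedger(
        perspective=perspective,
        screening_cost=p.cost_per_early_case_screening,
        direct_non_ophthalmic=p.cost_nonophthalmic_adjusted,
        caregiver=p.cost_caregiver_adjusted,
        employment=p.cost_employment_adjusted,
        accrual_start_month=p.savings_accrual_start_month,
    )


def net_cost_per_early_case(ledger: PerspectiveCostLedger) -> float:
    """Signed net cost per early-treatment case (negative = societal saving)."""
    return ledger.screening_cost + ledger.total_negative


def cpt_table(p: ModelParameters) -> pd.DataFrame:
    """The cost build-up as a table, ending in the per-capita total."""
    rows = [
        {
            "code": it.code,
            "description": it.description,
            "multiplier": it.multiplier,
            "unit_amount": it.unit_amount,
            "line_total": it.line_total,
        }
        for it in p.cpt_items
    ]
    df = pd.DataFrame(rows)
    df.attrs["cost_per_patient_tested"] = cpt_total(p.cpt_items)
    df.attrs["compounded_to_treatment_age"] = p.compounded_test_cost
    df.attrs["per_capita_with_monitoring"] = p.per_capita_screening_cost
    return df


def ledger_table(p: ModelParameters) -> pd.DataFrame:
    """Three-column ledger analogue: unadjusted, societal-adjusted, and
    third-party (direct medical only) per early-treatment case."""
    factor = p.adjustment_factor
    col_a = {
        "direct_non_ophthalmic": p.cost_nonophthalmic_unadjusted,
        "caregiver": p.cost_caregiver_unadjusted,
        "employment": p.cost_employment_unadjusted,
    }
    societal = ledger_from_params(p, "societal")
    third = ledger_from_params(p, "third_party")
    rows = []
    rows.append(
        {
            "component": "screening_and_monitoring",
            "unadjusted": p.cost_per_early_case_screening,
            "societal_adjusted": societal.screening_cost,
            "third_party": third.screening_cost,
        }
    )
    for name in NEGATIVE_BUCKETS:
        rows.append(
            {
                "component": name,
                "unadjusted": col_a[name],
                "societal_adjusted": getattr(societal, name),
                "third_party": getattr(third, name) if name == "direct_non_ophthalmic" else 0.0,
            }
        )
    rows.append(
        {
            "component": "total_negative",
            "unadjusted": sum(col_a.values()),
            "societal_adjusted": societal.total_negative,
            "third_party": third.total_negative,
        }
    )
    rows.append(
        {
            "component": "net_total",
            "unadjusted": p.cost_per_early_case_screening + sum(col_a.values()),
            "societal_adjusted": net_cost_per_early_case(societal),
            "third_party": net_cost_per_early_case(third),
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["adjustment_factor"] = factor
    return df
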