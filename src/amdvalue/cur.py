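"""Cost-utility ratios, break-even solving, national totals, and payer ROI.

For an incremental uptake p (percent of the ~161,754 annual 65+ NVAMD
patients shifted to early treatment), the national ledger is

    total(p)  = S + n(p) x c_neg,        n(p) = p/100 x N
    CUR(p)    = total(p) / (n(p) x g)

where S is the national screening cost (944,400 x $2,205), c_neg the signed
per-early-case negative cost for the perspective (-227,455 societal /
-40,914 third-party), and g the adjusted per-early-case QALY gain (0.595).
A negative CUR denotes dominance: more QALYs and net savings.  Patient
counts stay real-valued; rounding happens only at report time.
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

from .costs import ledger_from_params, net_cost_per_early_case
from .params import ModelParameters, derive_cohort_counts

__all__ = [
    "national_screening_cost",
    "per_patient_negative_cost",
    "adjusted_gain_per_early_case",
    "cur_table",
    "breakeven_uptake",
    "financial_breakeven_patients",
    "roi",
    "per_percent_saving",
    "payer_roi_table",
]

PERSPECTIVES = ("societal", "third_party")


def national_screening_cost(cohort: float, per_capita: float) -> float:
    """Annual national screening/monitoring outlay, USD."""
    if cohort < 0 or per_capita < 0:
        raise ValueError("cohort and per-capita cost must be >= 0")
    return cohort * per_capita


def per_patient_negative_cost(p: ModelParameters, perspective: str) -> float:
    """Signed negative (saved) cost per early-treatment case."""
    return ledger_from_params(p, perspective).total_negative


def adjusted_gain_per_early_case(p: ModelParameters) -> float:
    """Adjusted QALY gain per early-treatment case.

    Printed-precision convention: the early-vs-late gain times the
    presentation x sensitivity factor, rounded to 3 decimals (0.595 in the
    base case) — the precision at which the published tables were built.
    """
    return round(p.incremental_gain_early_late * p.adjustment_factor, 3)


def cur_table(
    pcts: Iterable[float],
    perspective: str,
    p: ModelParameters,
    screening_total: float | None = None,
) -> pd.DataFrame:
    """Cost-utility table over incremental early-treatment uptake percentages.

    Columns mirror the published layout: national totals in $ thousands,
    per-screened cost in dollars, per-screened QALY gain, and $/QALY.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    if screening_total is None:
        screening_total = national_screening_cost(
            p.annual_category3_cohort, p.per_capita_screening_cost
        )
    per1 = derive_cohort_counts(p)["per_one_percent"]
    c_neg = per_patient_negative_cost(p, perspective)
    gain = adjusted_gain_per_early_case(p)
    rows = []
    for pct in pcts:
        if pct <= 0:
            raise ValueError("uptake percent must be positive (CUR undefined at 0)")
        if pct > 100:
            raise ValueError("uptake percent cannot exceed 100")
        n = pct * per1
        negative_total = n * c_neg
        total = screening_total + negative_total
        qaly_total = n * gain
        # zero QALY gain: cost-effectiveness is unattainable at any uptake
        cur = total / qaly_total if qaly_total > 0 else math.inf
        rows.append(
            {
                "incremental_pct": pct,
                "n_patients": n,
                "screening_cost_total_k": screening_total / 1e3,
                "negative_cost_total_k": negative_total / 1e3,
                "total_cost_k": total / 1e3,
                "cost_per_screened": total / p.annual_category3_cohort,
                "qaly_per_screened": qaly_total / p.annual_category3_cohort,
                "cur": cur,
            }
        )
    return pd.DataFrame(rows)


def breakeven_uptake(
    threshold: float,
    perspective: str,
    p: ModelParameters,
    screening_total: float | None = None,
) -> float:
    """Smallest uptake percent whose CUR reaches the $/QALY threshold.

    Closed form: n = S / (|c_neg| + threshold x g).  ``math.inf`` threshold
    gives the financial zero-crossing of total cost.  Returns the percent at
    full precision (report to 1 decimal); ``inf`` if unattainable within
    100 % uptake.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    if screening_total is None:
        screening_total = national_screening_cost(
            p.annual_category3_cohort, p.per_capita_screening_cost
        )
    c_neg = per_patient_negative_cost(p, perspective)
    gain = adjusted_gain_per_early_case(p)
    denom = -c_neg + (0.0 if math.isinf(threshold) else threshold * gain)
    if denom <= 0:
        return math.inf
    n = screening_total / denom
    pct = n / derive_cohort_counts(p)["per_one_percent"]
    return pct if pct <= 100.0 else math.inf


def financial_breakeven_patients(p: ModelParameters) -> float:
    """Early-treated patients at which national screening cost is repaid."""
    saving = -net_cost_per_early_case(ledger_from_params(p, "societal"))
    if saving <= 0:
        raise ValueError("no positive net societal saving per early case")
    total = national_screening_cost(p.annual_category3_cohort, p.per_capita_screening_cost)
    return total / saving


def roi(expended: float, returned_magnitude: float) -> float:
    """12-year return-on-investment percent."""
    if expended <= 0:
        raise ValueError("expended amount must be positive")
    return (returned_magnitude - expended) / expended * 100.0


def per_percent_saving(p: ModelParameters) -> float:
    """Net societal saving, USD, per 1 % of annual NVAMD patients shifted
    to early treatment."""
    saving = -net_cost_per_early_case(ledger_from_params(p, "societal"))
    return derive_cohort_counts(p)["per_one_percent"] * saving


def payer_roi_table(p: ModelParameters) -> pd.DataFrame:
    """Per-screened ROI distribution across payers.

    ROI and diminution are recomputed from the printed per-payer dollar
    magnitudes; the published patient-row ROI (16,945 %) is not reproducible
    from its own cells, so the recomputed value is reported.
    """
    rows = []
    total_scr = p.payer_screening_total
    total_ret = p.negative_return_per_screened
    rows.append(
        {
            "payer": "overall",
            "screening": total_scr,
            "returned": -total_ret,
            "net_cost": total_scr - total_ret,
            "roi_pct": roi(total_scr, total_ret),
            "diminution_pct": total_ret / total_scr * 100.0,
        }
    )
    for share in p.payer_shares:
        rows.append(
            {
                "payer": share.name,
                "screening": share.screening,
                "returned": -share.returned,
                "net_cost": share.screening - share.returned,
                "roi_pct": roi(share.screening, share.returned),
                "diminution_pct": share.returned / share.screening * 100.0,
            }
        )
    return pd.DataFrame(rows)
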