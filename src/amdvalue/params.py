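"""Parameter registry for the NVAMD genetic-screening cost-utility model.

Every printed model input — cohort sizes, progression and presentation
fractions, time-tradeoff utilities, QALY accruals, cost-ledger components,
payer shares — lives here with a provenance anchor, so that no downstream
module buries a literal in computation code.  The registry is the base case
of a 12-year, discounted (3 %/year), 2012-USD, combined-eye cost-utility
analysis of genetic testing for progression of Category 3 (drusen >= 125 um)
age-related macular degeneration to its neovascular form (NVAMD).

Users override any parameter through a flat YAML config; unknown keys are
rejected and all invariants are re-checked after overrides.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "CptLine",
    "PayerShare",
    "ModelParameters",
    "ConfigError",
    "ValidationError",
    "load_parameters",
    "dump_defaults",
    "derive_cohort_counts",
    "parameter_hash",
    "PROVENANCE",
]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


class ValidationError(ValueError):
    """A parameter violates its documented bound or consistency rule."""


@dataclass(frozen=True)
class CptLine:
    """One CPT line item of the genetic-test cost build-up (2012 NLA dollars)."""

    code: str
    description: str
    multiplier: int
    unit_amount: float

    @property
    def line_total(self) -> float:
        return self.multiplier * self.unit_amount


@dataclass(frozen=True)
class PayerShare:
    """One payer row of the screening-cost / returned-cost distribution.

    Dollar amounts are per patient screened; ``returned`` is the magnitude of
    the negative (saved) cost credited back to that payer over 12 years.
    """

    name: str
    screening: float
    returned: float


# Default CPT build-up for the multi-gene panel (unit amounts are National
# Limitation Amounts; the printed per-line totals round each line first).
DEFAULT_CPT_ITEMS: tuple[CptLine, ...] = (
    CptLine("83891", "DNA isolation", 1, 5.7),
    CptLine("83900", "Amplification, multiplex, first two sequences", 1, 47.8),
    CptLine("83901", "Amplification, multiplex, each additional sequence", 10, 23.7),
    CptLine("83892", "Enzymatic digestion, each", 2, 5.7),
    CptLine("83914", "Mutation identification (OLA/SBCE/ASPE), each segment", 15, 23.7),
    CptLine("83912", "Interpretation and report", 1, 5.7),
    CptLine("83896", "Nucleic acid probe, each", 15, 5.7),
    CptLine("83903", "Mutation scanning by physical properties, each", 15, 23.7),
    CptLine("83908", "Signal amplification, each sequence", 15, 23.7),
)

DEFAULT_PAYER_SHARES: tuple[PayerShare, ...] = (
    PayerShare("medicare", 1559.0, 548.0),
    PayerShare("medicaid", 84.0, 53.0),
    PayerShare("commercial_medigap", 348.0, 83.0),
    PayerShare("commercial_under_65", 174.0, 53.0),
    PayerShare("patients", 40.0, 6765.0),
)


@dataclass(frozen=True)
class ModelParameters:
    # --- timeline and discounting -------------------------------------
    timeline_years: int = 12
    discount_rate: float = 0.03
    screening_age: int = 65
    treatment_age: int = 75
    #: annual compounding periods applied between genetic testing and the
    #: start of therapy; 9 reproduces the printed $1461 -> $1906 chain.
    compounding_periods: int = 9

    # --- cohort demographics ------------------------------------------
    annual_category3_cohort: float = 944_400.0
    annual_nvamd_cases_total: float = 171_350.0
    fraction_under_65: float = 0.056
    annual_nvamd_cases_65plus: float = 161_754.0

    # --- progression and detection ------------------------------------
    progression_10yr: float = 0.20
    high_risk_fraction: float = 0.225
    test_sensitivity: float = 0.90

    # --- presentation strata and eye-model multipliers ----------------
    first_eye_late_fraction: float = 0.780
    second_eye_late_fraction: float = 0.622
    first_eye_early_fraction: float = 0.18
    second_eye_early_fraction: float = 0.37
    combined_eye_multiplier: float = 0.857
    #: prose alternative to the combined-eye multiplier (documented, unused
    #: in base-case arithmetic).
    first_eye_accrual_ratio: float = 0.853

    # --- fellow-eye conversion trajectory inputs ----------------------
    conversion_year1_cum_pct: float = 21.2
    conversion_year2_cum_pct: float = 38.0
    baseline_bilateral_pct: float = 46.4
    #: share of baseline cases that are unilateral, as used in the printed
    #: bilateral-involvement formula (the prose also quotes 0.536).
    unilateral_share: float = 0.535

    # --- time-tradeoff utilities --------------------------------------
    utility_20_40_minus1: float = 0.789
    utility_20_160_plus2: float = 0.658
    utility_20_126: float = 0.682
    utility_20_160_minus2: float = 0.657
    utility_20_640: float = 0.538
    utility_nlp_bilateral: float = 0.26
    utility_good_bilateral: float = 0.97
    utility_good_unilateral: float = 0.89
    first_eye_utility_loss: float = 0.0398

    # --- 12-year discounted QALY accruals per treatment arm -----------
    accrual_sham: float = 5.990
    accrual_early: float = 7.924
    accrual_late: float = 6.561
    bonus_bilateral_good_vision: float = 0.121
    bonus_eligible_fraction: float = 0.179
    first_eye_gain: float = 0.0884
    adverse_event_disutility: float = 0.045

    # --- screening/monitoring costs -----------------------------------
    genetic_test_cost: float = 1461.0
    extra_visits_per_year: int = 1
    exam_oct_cost_per_visit: float = 299.0
    screened_per_early_case: float = 30.3
    cost_per_early_case_screening: float = 66_873.0
    screening_component_per_early_case: float = 57_805.0
    monitoring_component_per_early_case: float = 9_068.0
    savings_accrual_start_month: int = 7

    # --- 12-year negative-cost ledger, unadjusted (full benefit) ------
    cost_depression_unadjusted: float = -7_169.0
    cost_injuries_unadjusted: float = -3_793.0
    cost_nursing_home_unadjusted: float = -22_351.0
    cost_snf_unadjusted: float = -10_193.0
    cost_other_medical_unadjusted: float = -50_194.0
    cost_nonophthalmic_unadjusted: float = -93_699.0
    cost_caregiver_unadjusted: float = -394_929.0
    cost_employment_unadjusted: float = -32_288.0

    # --- ledger adjusted for presentation strata x sensitivity --------
    cost_depression_adjusted: float = -3_130.0
    cost_injuries_adjusted: float = -1_656.0
    cost_nursing_home_adjusted: float = -9_759.0
    cost_snf_adjusted: float = -4_451.0
    cost_other_medical_adjusted: float = -21_917.0
    cost_nonophthalmic_adjusted: float = -40_914.0
    cost_caregiver_adjusted: float = -172_443.0
    cost_employment_adjusted: float = -14_098.0

    # --- national/payer aggregates ------------------------------------
    #: overall-row anchors of the payer distribution (per patient screened)
    payer_screening_total: float = 2_205.0
    negative_return_per_screened: float = 7_500.0
    who_threshold: float = 144_000.0
    us_threshold: float = 100_000.0

    # --- structured blocks --------------------------------------------
    cpt_items: tuple[CptLine, ...] = DEFAULT_CPT_ITEMS
    payer_shares: tuple[PayerShare, ...] = DEFAULT_PAYER_SHARES

    # ------------------------------------------------------------------
    # derived conveniences (computed, never stored in config)
    # ------------------------------------------------------------------
    @property
    def annuity_factor(self) -> float:
        """Present value of a 1/year stream, end-of-year discounting."""
        r, n = self.discount_rate, self.timeline_years
        if r == 0:
            return float(n)
        return (1 - (1 + r) ** -n) / r

    @property
    def compounded_test_cost(self) -> float:
        return round(
            self.genetic_test_cost * (1 + self.discount_rate) ** self.compounding_periods
        )

    @property
    def monitoring_addon(self) -> float:
        """Per-capita extra exam+OCT monitoring cost ($299 x visits/year)."""
        return self.extra_visits_per_year * self.exam_oct_cost_per_visit

    @property
    def per_capita_screening_cost(self) -> float:
        return self.compounded_test_cost + self.monitoring_addon

    @property
    def adjustment_factor(self) -> float:
        """Presentation x sensitivity product 0.780 x 0.622 x 0.90 = 0.4366."""
        return (
            self.first_eye_late_fraction
            * self.second_eye_late_fraction
            * self.test_sensitivity
        )

    @property
    def incremental_gain_early_late(self) -> float:
        """Unadjusted early-vs-late 12-year QALY gain per treated patient."""
        return self.accrual_early - self.accrual_late

    @property
    def societal_negative_per_early_case(self) -> float:
        return (
            self.cost_nonophthalmic_adjusted
            + self.cost_caregiver_adjusted
            + self.cost_employment_adjusted
        )

    @property
    def third_party_negative_per_early_case(self) -> float:
        return self.cost_nonophthalmic_adjusted

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check every documented bound and cross-parameter consistency rule."""
        frac_fields = (
            "discount_rate",
            "fraction_under_65",
            "progression_10yr",
            "high_risk_fraction",
            "test_sensitivity",
            "first_eye_late_fraction",
            "second_eye_late_fraction",
            "first_eye_early_fraction",
            "second_eye_early_fraction",
            "combined_eye_multiplier",
            "first_eye_accrual_ratio",
            "unilateral_share",
        )
        for name in frac_fields:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v!r} outside [0, 1]")
        utility_fields = (
            "utility_20_40_minus1",
            "utility_20_160_plus2",
            "utility_20_126",
            "utility_20_160_minus2",
            "utility_20_640",
            "utility_nlp_bilateral",
            "utility_good_bilateral",
            "utility_good_unilateral",
        )
        for name in utility_fields:
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}={v!r} outside (0, 1]")
        nonneg = (
            "timeline_years",
            "screening_age",
            "treatment_age",
            "compounding_periods",
            "annual_category3_cohort",
            "annual_nvamd_cases_total",
            "annual_nvamd_cases_65plus",
            "genetic_test_cost",
            "exam_oct_cost_per_visit",
            "extra_visits_per_year",
            "screened_per_early_case",
            "cost_per_early_case_screening",
            "who_threshold",
            "us_threshold",
            "negative_return_per_screened",
            "first_eye_utility_loss",
            "accrual_sham",
            "accrual_early",
            "accrual_late",
            "adverse_event_disutility",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "cost_nonophthalmic_unadjusted",
            "cost_caregiver_unadjusted",
            "cost_employment_unadjusted",
            "cost_nonophthalmic_adjusted",
            "cost_caregiver_adjusted",
            "cost_employment_adjusted",
        ):
            if getattr(self, name) > 0:
                raise ValidationError(f"{name} is a negative (saved) cost; must be <= 0")

        expected_65plus = self.annual_nvamd_cases_total * (1 - self.fraction_under_65)
        if abs(self.annual_nvamd_cases_65plus - round(expected_65plus)) > 1:
            raise ValidationError(
                "annual_nvamd_cases_65plus inconsistent with "
                f"total x (1 - under-65 fraction): {self.annual_nvamd_cases_65plus} "
                f"vs {expected_65plus:.1f}"
            )

        for arm in ("accrual_sham", "accrual_early", "accrual_late"):
            if getattr(self, arm) > self.timeline_years:
                raise ValidationError(f"{arm} exceeds the model timeline")
        if not self.accrual_early >= self.accrual_late >= self.accrual_sham:
            raise ValidationError("arm accruals must order early >= late >= sham")

        # ledger sub-items must sum to their printed bucket within $5
        for bucket, items in (
            (
                "cost_nonophthalmic_unadjusted",
                (
                    "cost_depression_unadjusted",
                    "cost_injuries_unadjusted",
                    "cost_nursing_home_unadjusted",
                    "cost_snf_unadjusted",
                    "cost_other_medical_unadjusted",
                ),
            ),
            (
                "cost_nonophthalmic_adjusted",
                (
                    "cost_depression_adjusted",
                    "cost_injuries_adjusted",
                    "cost_nursing_home_adjusted",
                    "cost_snf_adjusted",
                    "cost_other_medical_adjusted",
                ),
            ),
        ):
            total = sum(getattr(self, it) for it in items)
            if abs(total - getattr(self, bucket)) > 5:
                raise ValidationError(
                    f"{bucket} ({getattr(self, bucket)}) != sum of sub-items ({total})"
                )
        comp_sum = (
            self.screening_component_per_early_case
            + self.monitoring_component_per_early_case
        )
        if abs(comp_sum - self.cost_per_early_case_screening) > 5:
            raise ValidationError(
                "screening + monitoring components do not sum to the "
                f"per-early-case screening cost ({comp_sum} vs "
                f"{self.cost_per_early_case_screening})"
            )

        # payer shares: both dollar columns must each cover the whole
        # per-screened amount (shares sum to 100 % +/- 0.1)
        scr = sum(p.screening for p in self.payer_shares)
        ret = sum(p.returned for p in self.payer_shares)
        if abs(scr / self.payer_screening_total - 1.0) > 1e-3:
            raise ValidationError(
                f"payer screening shares sum to {scr}, not the overall-row "
                f"total {self.payer_screening_total}"
            )
        if abs(ret / self.negative_return_per_screened - 1.0) > 1e-3:
            raise ValidationError(
                f"payer returned shares sum to {ret}, not the per-screened "
                f"negative return {self.negative_return_per_screened}"
            )
        for item in self.cpt_items:
            if item.multiplier < 1:
                raise ValidationError(f"CPT {item.code}: multiplier must be >= 1")
            if item.unit_amount < 0:
                raise ValidationError(f"CPT {item.code}: unit amount must be >= 0")

        pct_fields = (
            "conversion_year1_cum_pct",
            "conversion_year2_cum_pct",
            "baseline_bilateral_pct",
        )
        for name in pct_fields:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name}={v!r} outside [0, 100]")
        if self.conversion_year1_cum_pct > self.conversion_year2_cum_pct:
            raise ValidationError(
                "cumulative conversion must be non-decreasing (year 1 > year 2)"
            )


#: Provenance anchor for every registry field: where the printed value sits
#: in the source report (descriptive anchors; no literature re-derivation).
PROVENANCE: dict[str, str] = {
    "timeline_years": "model-assumptions table: 12-year mean NVAMD life expectancy",
    "discount_rate": "model-assumptions table: NPV discounting at 3 %/year",
    "screening_age": "model-assumptions table: genetic screening at age 65",
    "treatment_age": "model-assumptions table: mean first NVAMD presentation age 75",
    "compounding_periods": "cost build-up table arithmetic: 1461 x 1.03^9 = 1906",
    "annual_category3_cohort": "model-assumptions table: 944,400 Category 3 cases/year at 65",
    "annual_nvamd_cases_total": "demographics text: 171,350 new NVAMD cases annually",
    "fraction_under_65": "demographics text: 5.6 % present before age 65",
    "annual_nvamd_cases_65plus": "demographics text: leaving 161,754 annual new cases",
    "progression_10yr": "model-assumptions table: 20 % 10-year progression to NVAMD",
    "high_risk_fraction": "model-assumptions table: 22.5 % high-risk genetic profile",
    "test_sensitivity": "model-assumptions table: 90 % of progressors detected",
    "first_eye_late_fraction": "presentation table: 78.0 % first eyes <=20/160",
    "second_eye_late_fraction": "presentation table: 62.2 % second eyes <=20/160",
    "first_eye_early_fraction": "presentation table: 18 % first eyes 20/40-20/80",
    "second_eye_early_fraction": "presentation table: 37 % second eyes 20/40-20/80",
    "combined_eye_multiplier": "value-gain text: 85.7 % combined-eye multiplier",
    "first_eye_accrual_ratio": "model-assumptions table: first-eye accrual 85.3 % of second-eye",
    "conversion_year1_cum_pct": "conversion table: year-1 cumulative 21.2 %",
    "conversion_year2_cum_pct": "conversion table: year-2 cumulative 38.0 %",
    "baseline_bilateral_pct": "conversion table: baseline bilateral involvement 46.4 %",
    "unilateral_share": "conversion table header: B = 46.4 % + (A x 53.5 %)",
    "utility_20_40_minus1": "model-assumptions table: 20/40-1 utility 0.789",
    "utility_20_160_plus2": "model-assumptions table: 20/160+2 utility 0.658",
    "utility_20_126": "patient-value table: 12-month sham 20/126 utility 0.682",
    "utility_20_160_minus2": "patient-value table: 24-month sham utility 0.657",
    "utility_20_640": "patient-value table: 96-month sham 20/640 utility 0.538",
    "utility_nlp_bilateral": "utility-analysis text: bilateral NLP utility 0.26",
    "utility_good_bilateral": "results text: 0.97 for bilateral 20/20-20/25",
    "utility_good_unilateral": "results text: 0.89 for unilateral 20/20-20/25",
    "first_eye_utility_loss": "model-assumptions table: 0.0398 first-eye utility loss",
    "accrual_sham": "patient-value table: sham 12-year QALY accrual 5.990",
    "accrual_early": "patient-value table: early-treatment accrual 7.924",
    "accrual_late": "patient-value table: late-treatment accrual 6.561",
    "bonus_bilateral_good_vision": "results text: additional 0.121 QALY for bilateral >=20/25",
    "bonus_eligible_fraction": "results text: 17.9 % of early eyes achieved >=20/25",
    "first_eye_gain": "results text: first-eye therapy conferred 0.0884 QALY",
    "adverse_event_disutility": "model-assumptions table: 0.045 QALY adverse-event disutility",
    "genetic_test_cost": "cost build-up table: $1461 per patient tested",
    "extra_visits_per_year": "costs text: three annual visits rather than two",
    "exam_oct_cost_per_visit": "costs text: $299 extra annual exam + OCT",
    "screened_per_early_case": "costs text: 30.3 screened per early-treatment case",
    "cost_per_early_case_screening": "costs text: $66,873 (30.3 x $2205)",
    "screening_component_per_early_case": "cost-ledger table: $57,805 screening component",
    "monitoring_component_per_early_case": "cost-ledger table: $9068 monitoring component",
    "savings_accrual_start_month": "cost-ledger table footnote: savings accrue from month 7",
    "cost_depression_unadjusted": "cost-ledger table column A: depression -$7169",
    "cost_injuries_unadjusted": "cost-ledger table column A: injuries -$3793",
    "cost_nursing_home_unadjusted": "cost-ledger table column A: nursing home -$22,351",
    "cost_snf_unadjusted": "cost-ledger table column A: SNF -$10,193",
    "cost_other_medical_unadjusted": "cost-ledger table column A: other Medicare -$50,194",
    "cost_nonophthalmic_unadjusted": "cost-ledger table column A: -$93,699",
    "cost_caregiver_unadjusted": "cost-ledger table column A: caregiver -$394,929",
    "cost_employment_unadjusted": "cost-ledger table column A: employment -$32,288",
    "cost_depression_adjusted": "cost-ledger table column B: depression -$3130",
    "cost_injuries_adjusted": "cost-ledger table column B: injuries -$1656",
    "cost_nursing_home_adjusted": "cost-ledger table column B: nursing home -$9759",
    "cost_snf_adjusted": "cost-ledger table column B: SNF -$4451",
    "cost_other_medical_adjusted": "cost-ledger table column B: other Medicare -$21,917",
    "cost_nonophthalmic_adjusted": "cost-ledger table column B: -$40,914",
    "cost_caregiver_adjusted": "cost-ledger table column B: caregiver -$172,443",
    "cost_employment_adjusted": "cost-ledger table column B: employment -$14,098",
    "payer_screening_total": "payer table overall row: $2205 expended per patient screened",
    "negative_return_per_screened": "payer table: -$7500 returned per patient screened",
    "who_threshold": "discussion text: WHO limit ~3x GDP/capita = $144,000/QALY",
    "us_threshold": "discussion text: customary US limit $100,000/QALY",
    "cpt_items": "cost build-up table: CPT line items",
    "payer_shares": "payer table rows",
}

_SCALAR_FIELDS = {
    f.name: f.type
    for f in dataclasses.fields(ModelParameters)
    if f.name not in ("cpt_items", "payer_shares")
}


def _coerce_structured(key: str, value: Any) -> Any:
    if key == "cpt_items":
        try:
            return tuple(
                CptLine(
                    str(d["code"]),
                    str(d.get("description", "")),
                    int(d["multiplier"]),
                    float(d["unit_amount"]),
                )
                for d in value
            )
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"cpt_items: malformed entry ({exc})") from exc
    if key == "payer_shares":
        try:
            return tuple(
                PayerShare(str(d["name"]), float(d["screening"]), float(d["returned"]))
                for d in value
            )
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"payer_shares: malformed entry ({exc})") from exc
    raise AssertionError(key)


def load_parameters(config_source: str | Mapping[str, Any] | None = None) -> ModelParameters:
    """Build a validated parameter set: defaults plus optional overrides.

    ``config_source`` may be a YAML string, a pre-parsed mapping, or None for
    the base case.  Unknown keys raise :class:`ConfigError`; bound violations
    raise :class:`ValidationError`.
    """
    overrides: dict[str, Any] = {}
    if config_source is not None:
        if isinstance(config_source, Mapping):
            raw: Any = dict(config_source)
        else:
            try:
                raw = yaml.safe_load(config_source)
            except yaml.YAMLError as exc:
                raise ConfigError(f"config does not parse as YAML: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a flat key/value mapping")
        for key, value in raw.items():
            if key in ("cpt_items", "payer_shares"):
                overrides[key] = _coerce_structured(key, value)
            elif key in _SCALAR_FIELDS:
                if not isinstance(value, (int, float)):
                    raise ConfigError(f"{key}: expected a number, got {value!r}")
                overrides[key] = value
            else:
                raise ConfigError(f"unknown parameter {key!r}")
    params = ModelParameters(**overrides)
    params.validate()
    return params


def dump_defaults(with_provenance: bool = True) -> str:
    """Emit the base-case config as YAML, one ``# provenance`` comment per key."""
    base = ModelParameters()
    lines: list[str] = ["# Base-case model parameters (2012 USD)."]
    for name in _SCALAR_FIELDS:
        if with_provenance and name in PROVENANCE:
            lines.append(f"# {PROVENANCE[name]}")
        lines.append(yaml.safe_dump({name: getattr(base, name)}).strip())
    lines.append("# " + PROVENANCE["cpt_items"])
    lines.append(
        yaml.safe_dump(
            {
                "cpt_items": [
                    {
                        "code": c.code,
                        "description": c.description,
                        "multiplier": c.multiplier,
                        "unit_amount": c.unit_amount,
                    }
                    for c in base.cpt_items
                ]
            },
            sort_keys=False,
        ).strip()
    )
    lines.append("# " + PROVENANCE["payer_shares"])
    lines.append(
        yaml.safe_dump(
            {
                "payer_shares": [
                    {"name": p.name, "screening": p.screening, "returned": p.returned}
                    for p in base.payer_shares
                ]
            },
            sort_keys=False,
        ).strip()
    )
    return "\n".join(lines) + "\n"


def derive_cohort_counts(p: ModelParameters) -> dict[str, float]:
    """Derived cohort counts: annual 65+ NVAMD cases and the per-1 % count.

    Counts stay real-valued; rounding to whole persons happens only in
    report formatting.
    """
    over65 = p.annual_nvamd_cases_total * (1 - p.fraction_under_65)
    return {
        "annual_nvamd_cases_65plus": over65,
        # the tables scale from the registry's printed 65+ count
        "per_one_percent": p.annual_nvamd_cases_65plus / 100.0,
    }


def parameter_hash(p: ModelParameters) -> str:
    """Stable short hash of the full parameter set (for report provenance)."""
    payload = repr(dataclasses.astuple(p)).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
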