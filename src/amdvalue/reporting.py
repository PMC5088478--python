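"""Report writers: every reproduced table in stable CSV/JSON form.

Identical parameters produce byte-identical CSV output; each bundle records
the parameter hash and the seed used for the microsimulation tables.
Currency is serialized as integer dollars (tables in thousands carry a
``units`` entry in the metadata); QALYs at 4 decimal places.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import costs as costs_mod
from . import cur as cur_mod
from .cohort import simulate_cohort
from .params import ModelParameters, parameter_hash
from .progression import trajectory_from_params
from .scenarios import sensitivity_table
from .value import value_table

__all__ = ["ReportBundle", "run_full_analysis", "DEFAULT_CUR_PCTS"]

DEFAULT_CUR_PCTS = (1, 2, 3, 4, 4.1, 4.5, 5, 10, 15, 20, 30)

_QALY_COLS = {
    "qaly_per_screened",
    "qaly_gain_unadjusted",
    "qaly_gain_adjusted",
    "accrual_12yr",
    "utility",
}


@dataclass
class ReportBundle:
    parameter_hash: str
    seed: int | None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    def write(self, output_dir: str | Path, fmt: str = "csv") -> list[Path]:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables.items():
            df = _format_table(df)
            path = out / f"{name}.{fmt}"
            if fmt == "csv":
                df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
            elif fmt == "json":
                path.write_text(df.to_json(orient="records", indent=2))
            else:
                raise ValueError(f"unknown format {fmt!r}")
            written.append(path)
        meta = {
            "parameter_hash": self.parameter_hash,
            "seed": self.seed,
            "tables": sorted(self.tables),
            "table_metadata": self.metadata,
        }
        meta_path = out / "run_metadata.json"
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        written.append(meta_path)
        return written


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        if col in _QALY_COLS and pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].round(4)
    return df


def run_full_analysis(
    p: ModelParameters,
    seed: int | None = None,
    microsim_n: int = 0,
) -> ReportBundle:
    """Assemble every deterministic table (plus the microsimulation summary
    when ``microsim_n`` > 0) into a bundle ready to write."""
    bundle = ReportBundle(parameter_hash=parameter_hash(p), seed=seed)
    bundle.tables["conversion_trajectory"] = trajectory_from_params(p).to_frame()
    bundle.tables["patient_value"] = value_table(p)
    bundle.tables["cost_buildup"] = costs_mod.cpt_table(p)
    bundle.tables["cost_ledger"] = costs_mod.ledger_table(p)
    for perspective in cur_mod.PERSPECTIVES:
        bundle.tables[f"cur_{perspective}"] = cur_mod.cur_table(
            DEFAULT_CUR_PCTS, perspective, p
        )
        bundle.metadata[f"cur_{perspective}"] = {"units": "totals in USD thousands"}
    bundle.tables["payer_roi"] = cur_mod.payer_roi_table(p)
    bundle.tables["sensitivity"] = sensitivity_table(p)
    bundle.metadata["sensitivity"] = {"units": "totals in USD thousands"}
    bundle.metadata["headline"] = {
        "national_screening_cost_usd": cur_mod.national_screening_cost(
            p.annual_category3_cohort, p.per_capita_screening_cost
        ),
        "financial_breakeven_patients": cur_mod.financial_breakeven_patients(p),
        "per_percent_saving_usd": cur_mod.per_percent_saving(p),
        "who_breakeven_pct_societal": cur_mod.breakeven_uptake(
            p.who_threshold, "societal", p
        ),
        "us_breakeven_pct_societal": cur_mod.breakeven_uptake(
            p.us_threshold, "societal", p
        ),
    }
    if microsim_n > 0:
        if seed is None:
            raise ValueError("a seed is required for the microsimulation table")
        summary = simulate_cohort(microsim_n, seed, p)
        bundle.tables["microsimulation"] = pd.DataFrame([summary.to_dict()])
    return bundle
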