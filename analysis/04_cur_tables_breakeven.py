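"""Cost-utility tables, break-even uptakes, national totals and payer ROI.

Scales the per-early-case economics to the nation: 944,400 Category 3
patients screened annually at $2,205 each ($2.082 billion), against
161,754 annual new 65+ NVAMD cases of whom an incremental p % are shifted
to early treatment.

Findings: from the societal perspective genetic screening is cost-effective
at the WHO $144,000/QALY threshold once an incremental 4.1 % of annual
NVAMD patients reach early treatment (4.5 % at the $100,000/QALY US
convention), financially breaks even at ~12,968 early-treated patients
(8.0 %), saves ~$260 million per additional 1 % uptake, and returns 240 %
on screening dollars ($7,500 back per $2,205 spent).  A third-party
insurer needs ~10.2 % uptake at the WHO threshold.

Writes results/cur_societal.csv, results/cur_third_party.csv,
results/payer_roi.csv and results/breakeven.csv.
"""

from pathlib import Path

import pandas as pd

from amdvalue.cur import (
    PERSPECTIVES,
    breakeven_uptake,
    cur_table,
    financial_breakeven_patients,
    national_screening_cost,
    payer_roi_table,
    per_percent_saving,
)
from amdvalue.params import derive_cohort_counts, load_parameters

OUT = Path(__file__).resolve().parents[1] / "results"
PCTS = (1, 2, 3, 4, 4.1, 4.5, 5, 10, 15, 20, 30, 34.6, 38.5)


def main() -> None:
    p = load_parameters()
    OUT.mkdir(exist_ok=True)

    for perspective in PERSPECTIVES:
        df = cur_table(PCTS, perspective, p)
        df.round(4).to_csv(OUT / f"cur_{perspective}.csv", index=False)
        print(f"\n--- {perspective} perspective ($ thousands) ---")
        print(df.round(1).to_string(index=False))

    per1 = derive_cohort_counts(p)["per_one_percent"]
    rows = []
    for perspective in PERSPECTIVES:
        for name, threshold in (("WHO", p.who_threshold), ("US", p.us_threshold)):
            pct = breakeven_uptake(threshold, perspective, p)
            rows.append(
                {
                    "perspective": perspective,
                    "threshold": threshold,
                    "label": name,
                    "breakeven_pct": round(pct, 2),
                    "breakeven_patients": round(pct * per1),
                }
            )
    be = pd.DataFrame(rows)
    be.to_csv(OUT / "breakeven.csv", index=False)
    print("\n" + be.to_string(index=False))

    roi = payer_roi_table(p)
    roi.round(1).to_csv(OUT / "payer_roi.csv", index=False)
    print("\n" + roi.round(1).to_string(index=False))

    total = national_screening_cost(p.annual_category3_cohort, p.per_capita_screening_cost)
    print(f"\nNational screening outlay:      ${total/1e9:.3f} billion")
    print(f"Financial break-even patients:  {financial_breakeven_patients(p):,.0f}")
    print(f"Societal saving per 1 % uptake: ${per_percent_saving(p)/1e6:.1f} million")


if __name__ == "__main__":
    main()
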