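"""Screening-cost build-up and the perspective cost ledger.

Builds the $1,461 multi-gene panel cost from CPT line items, compounds it
at 3 %/year over the 9 periods between screening (age 65) and mean
treatment onset (age 75) to $1,906, adds the $299 extra annual exam+OCT
monitoring cost, and assembles the 12-year negative-cost ledger per
early-treatment case.

Finding: screening/monitoring costs $2,205 per capita ($66,873 per
early-treatment case at 30.3 screened per case).  Against that, early
treatment saves $227,455 per case from the societal perspective
($40,914 direct non-ophthalmic medical alone for a third-party insurer),
so each early-treatment case *saves* society $160,582 net, while a
third-party insurer nets a $25,960 outlay.

Writes results/cost_buildup.csv and results/cost_ledger.csv.
"""

from pathlib import Path

from amdvalue.costs import cpt_table, ledger_table
from amdvalue.params import load_parameters

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p = load_parameters()
    OUT.mkdir(exist_ok=True)

    cpt = cpt_table(p)
    cpt.to_csv(OUT / "cost_buildup.csv", index=False)
    print(cpt.to_string(index=False))
    print(f"\nCost per patient tested:           ${cpt.attrs['cost_per_patient_tested']:,.0f}")
    print(f"Compounded to treatment age:       ${cpt.attrs['compounded_to_treatment_age']:,.0f}")
    print(f"Per capita incl. extra monitoring: ${cpt.attrs['per_capita_with_monitoring']:,.0f}")

    ledger = ledger_table(p)
    ledger.to_csv(OUT / "cost_ledger.csv", index=False)
    print("\n" + ledger.to_string(index=False))
    print(f"\nAdjustment factor (1st x 2nd eye x sensitivity): {ledger.attrs['adjustment_factor']:.4f}")


if __name__ == "__main__":
    main()
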