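"""Trial eligibility under age bands versus ASIS bands.

Evaluates the nine built-in inclusion criteria (three trial age windows
with a neurological-sign requirement; six ASIS bands) at every patient's
first visit, with seizure-group breakdowns, and cross-tabulates each age
band against each ASIS band.  Writes results/eligibility.csv and
results/eligibility_crosstab.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from asis_kit.io import read_cohort, write_report
from asis_kit.stratification import criteria_catalog, cross_tabulate, evaluate_criterion


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort = read_cohort(args.results / "cohort.csv")

    rows = []
    for crit in criteria_catalog():
        rep = evaluate_criterion(cohort, crit)
        rows.append(
            {"criterion": crit.name, "kind": crit.kind,
             "percent_included": rep.percent_included,
             "percent_included_seizure": rep.percent_included_seizure,
             "percent_included_nonseizure": rep.percent_included_nonseizure}
        )
        print(f"{crit.name:<28} {rep.percent_included:5.1f}% included "
              f"(seizure {rep.percent_included_seizure:5.1f}%, "
              f"non-seizure {rep.percent_included_nonseizure:5.1f}%)")
    write_report(pd.DataFrame(rows), args.results / "eligibility.csv")

    cat = criteria_catalog()
    xrows = []
    for a in (c for c in cat if c.kind == "age_band"):
        for b in (c for c in cat if c.kind == "asis_band"):
            cell = cross_tabulate(cohort, a, b)
            xrows.append({"age_criterion": a.name, "asis_criterion": b.name, **cell})
    xtab = pd.DataFrame(xrows)
    write_report(xtab, args.results / "eligibility_crosstab.csv")
    example = xtab[(xtab.age_criterion == "age_4_21_cyclodextrin")
                   & (xtab.asis_criterion == "asis_0.5_2.0")].iloc[0]
    print(f"\nage 4-21 vs ASIS 0.5-2: {example.pct_both_included:.1f}% recruited to "
          f"both, {example.pct_both_excluded:.1f}% excluded from both")


if __name__ == "__main__":
    main()
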