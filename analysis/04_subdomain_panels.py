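"""Can a few subdomains substitute for the full 16-domain severity score?

Runs the exhaustive Spearman scans of all single, paired and triple major
subdomains against the total score (with and without the subset's own
contribution), the pairwise major-domain correlation matrix, and the
quality-of-life panel (ambulation, swallowing, speech, cognition, fine
motor skills).  Also aggregates a synthetic questionnaire whose
respondents prefer those same five domains, to exercise the rank
aggregation path.  Writes results/subdomain_scan.csv,
results/domain_correlations.csv and results/subdomain_ranking.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from asis_kit.io import read_cohort, write_report
from asis_kit.severity import MAJOR_DOMAINS
from asis_kit.subdomains import (
    aggregate_ranks,
    pairwise_domain_correlations,
    panel_correlation,
    subset_scan,
)

QOL_PANEL = ["ambulation", "swallowing", "speech", "cognition", "fine_motor_skills"]


def synthetic_responses(group: str, n_respondents: int, seed: int) -> pd.DataFrame:
    """Synthetic importance rankings (1 = most impact) over the 8 major domains.

    Respondents broadly agree that the QoL panel matters most; individual
    rankings are noisy permutations around that shared preference.
    """
    rng = np.random.default_rng(seed)
    base = {d: (QOL_PANEL.index(d) + 1 if d in QOL_PANEL else 6) for d in MAJOR_DOMAINS}
    rows = []
    for i in range(n_respondents):
        noisy = {d: base[d] + rng.normal(0, 1.5) for d in MAJOR_DOMAINS}
        order = sorted(MAJOR_DOMAINS, key=lambda d: noisy[d])
        rows.append({d: order.index(d) + 1 for d in MAJOR_DOMAINS})
    return pd.DataFrame(rows, index=[f"{group[0]}{i}" for i in range(n_respondents)])


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    cohort = read_cohort(args.results / "cohort.csv")
    first_visits = [s.first_visit for s in cohort]

    tables = [subset_scan(first_visits, m) for m in (1, 2, 3)]
    scan = pd.concat(tables, ignore_index=True)
    write_report(scan, args.results / "subdomain_scan.csv")
    for m, t in zip((1, 2, 3), tables):
        ok = t["rho_included"].dropna()
        print(f"m={m}: {len(t)} subsets, rho_included range "
              f"{ok.min():.2f}-{ok.max():.2f}")

    write_report(
        pairwise_domain_correlations(first_visits).reset_index(names="domain"),
        args.results / "domain_correlations.csv",
    )

    rho_inc = panel_correlation(first_visits, QOL_PANEL, exclude=False)
    rho_exc = panel_correlation(first_visits, QOL_PANEL, exclude=True)
    print(f"QoL panel vs total severity: rho {rho_inc:.3f} (included), "
          f"{rho_exc:.3f} (panel removed from total)")

    rows = []
    for group, n in [("parents", 22), ("adults", 15), ("clinicians", 16)]:
        responses = synthetic_responses(group, n, seed=args.seed)
        table = aggregate_ranks(responses, group)
        for item in MAJOR_DOMAINS:
            rows.append({"group": group, "item": item,
                         "rank_sum": table.rank_sums[item],
                         "position": table.positions[item]})
        top5 = sorted(MAJOR_DOMAINS, key=lambda d: table.positions[d])[:5]
        print(f"{group}: top five domains {top5}")
    write_report(pd.DataFrame(rows), args.results / "subdomain_ranking.csv")


if __name__ == "__main__":
    main()
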