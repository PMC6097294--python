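"""Prognostic value of ASIS: through-origin predictions scored by MAD.

For each patient, predicts severity as asis_ref * age with asis_ref the
first-visit ASIS or the mean over all visits, and scores the prediction
with the per-patient maximum absolute deviation.  Summarises by group
(all / seizure / non-seizure) and by follow-up window (0-2, 2-4, 4-6
years), with the usual two-sample tests.  Writes results/mad.csv.
"""

import argparse
from pathlib import Path

from asis_kit.io import read_cohort, write_report
from asis_kit.prognosis import compare_modes, group_mad_summary, mad_table, windowed_mad


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort = read_cohort(args.results / "cohort.csv")

    table = mad_table(cohort)
    write_report(table, args.results / "mad.csv")

    for mode in ("first", "mean"):
        summaries, tests = group_mad_summary(cohort, mode)
        for s in summaries:
            print(f"MAD[{mode:<5}] {s.label:<12} median {s.median:5.2f} "
                  f"IQR ({s.q1:.2f}, {s.q3:.2f}) n={s.n}")
        if tests:
            print(f"         seizure vs non-seizure: Wilcoxon-Mann-Whitney "
                  f"p={tests['mannwhitney_p']:.3f}, Ansari-Bradley p={tests['ansari_p']:.3f}")

    mode_tests = compare_modes(cohort)
    print(f"first vs mean reference: Wilcoxon-Mann-Whitney p="
          f"{mode_tests['mannwhitney_p']:.3f}, Ansari-Bradley p={mode_tests['ansari_p']:.3f}")

    for mode in ("first", "mean"):
        for s in windowed_mad(cohort, mode):
            print(f"MAD[{mode:<5}] window {s.label:<6} median {s.median:5.2f} n={s.n}")


if __name__ == "__main__":
    main()
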