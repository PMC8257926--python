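#!/usr/bin/env python
"""Demographics and group comparisons on the simulated cohort.

Fisher's exact test on subject-level sex-by-group counts, Mann-Whitney U on
age and on the per-compartment ELS ratios (control vs uMD), and the simple
linear regression of each ELS ratio on log10(1 + days since onset) for
patients.  Writes results/group_statistics.json.
"""

import json
from pathlib import Path

from elshydro.io import NumpyJSONEncoder, read_cohort_csv
from elshydro.pipeline import _demographics, _group_tests, _onset_regressions

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    report = {
        "demographics": _demographics(cohort),
        "group_tests": _group_tests(cohort),
        "onset_regressions": _onset_regressions(cohort),
    }
    (OUT / "group_statistics.json").write_text(
        json.dumps(report, indent=2, cls=NumpyJSONEncoder)
    )
    d = report["demographics"]
    print(f"sex (subjects): {d['sex_counts']}  Fisher p = {d['sex_fisher_p']:.2f}")
    print(f"age: control {d['age_mean_control']:.1f}±{d['age_sd_control']:.1f}, "
          f"uMD {d['age_mean_uMD']:.1f}±{d['age_sd_uMD']:.1f}, "
          f"MWU p = {d['age_mannwhitney_p']:.2f}")
    for comp, g in report["group_tests"].items():
        print(f"{comp}: control median {g['median_control']:.2f}% vs uMD "
              f"{g['median_uMD']:.2f}%  (p {g['mannwhitney_p_display']})")
    for comp, r in report["onset_regressions"].items():
        print(f"onset regression {comp}: y = {r['intercept']:.2f} + {r['slope']:.2f}x, "
              f"p_slope = {r['p_slope']:.2f}")


if __name__ == "__main__":
    main()
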