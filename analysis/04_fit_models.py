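#!/usr/bin/env python
"""Fit the two diagnostic models on the simulated cohort.

The 2D model uses the conventional ordinal hydrops grades (MD~Sex+EHV+EHC);
the 3D model uses the published 17-term volumetric formula.  Writes both fit
reports (coefficients, log-likelihood, AIC) to results/model_fits.json.
"""

import json
from pathlib import Path

from elshydro.features import add_predictors
from elshydro.glm import MODEL_2D, MODEL_3D, fit_logistic
from elshydro.io import NumpyJSONEncoder, read_cohort_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = add_predictors(read_cohort_csv(OUT / "cohort.csv"))
    report = {}
    for name, formula in (("2D", MODEL_2D), ("3D", MODEL_3D)):
        fit = fit_logistic(formula, table)
        report[name] = fit.to_dict()
        print(f"{name} model: logLik = {fit.log_likelihood:.2f}, "
              f"AIC = {fit.aic:.1f}, converged = {fit.converged} "
              f"({fit.iterations} IRLS iterations)")
    (OUT / "model_fits.json").write_text(
        json.dumps(report, indent=2, cls=NumpyJSONEncoder)
    )


if __name__ == "__main__":
    main()
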