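#!/usr/bin/env python
"""Compare diagnostic accuracy of the 2D and 3D models.

Builds each model's ROC, picks the closest-top-left threshold, tabulates the
four indices (sensitivity, specificity, PPV, NPV) with AUC and AIC, then
tests the AUC difference (DeLong) and the reclassification improvement
(continuous NRI).  Writes the accuracy table, the comparison statistics and
the per-ear reclassification table under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from elshydro.evaluation import (
    closest_topleft,
    continuous_nri,
    delong_test,
    indices_at,
    reclassification_data,
    roc,
)
from elshydro.features import add_predictors
from elshydro.glm import MODEL_2D, MODEL_3D, fit_logistic, predict_prob
from elshydro.io import NumpyJSONEncoder, read_cohort_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = add_predictors(read_cohort_csv(OUT / "cohort.csv"))
    y = np.asarray(table["MD"], dtype=float)
    probs = {}
    rows = []
    for name, formula in (("2D", MODEL_2D), ("3D", MODEL_3D)):
        fit = fit_logistic(formula, table)
        p = predict_prob(fit, table)
        probs[name] = p
        r = roc(p, y)
        thr = closest_topleft(r)
        idx = indices_at(p, y, thr)
        rows.append({
            "model": name, "Threshold": round(thr, 3),
            "Sensitivity": round(idx.sensitivity, 3),
            "Specificity": round(idx.specificity, 3),
            "Positive predictive value": round(idx.ppv, 3),
            "Negative predictive value": round(idx.npv, 3),
            "AUC": round(r.auc, 3), "AIC": round(fit.aic, 1),
        })
    acc = pd.DataFrame(rows)
    acc.to_csv(OUT / "accuracy_table.csv", index=False)
    print(acc.to_string(index=False))

    dl = delong_test(probs["2D"], probs["3D"], y)
    nri = continuous_nri(probs["2D"], probs["3D"], y)
    stats = {
        "delong": {"auc_2D": dl.auc_a, "auc_3D": dl.auc_b, "z": dl.z,
                   "p_value": dl.p_value},
        "nri": {"nri": nri.nri, "z": nri.z, "p_value": nri.p_value},
    }
    (OUT / "model_comparison.json").write_text(
        json.dumps(stats, indent=2, cls=NumpyJSONEncoder)
    )
    print(f"DeLong: AUC {dl.auc_a:.3f} -> {dl.auc_b:.3f}, z = {dl.z:.2f}, "
          f"p = {dl.p_value:.3g}")
    print(f"continuous NRI = {nri.nri:.3f}, z = {nri.z:.2f}, p = {nri.p_value:.3g}")

    reclassification_data(probs["2D"], probs["3D"], y).to_csv(
        OUT / "reclassification.csv", index=False
    )


if __name__ == "__main__":
    main()
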