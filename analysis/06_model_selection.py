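#!/usr/bin/env python
"""Model selection over the engineered predictor pool.

Runs bidirectional stepwise search on AIC from the Sex-only model over the
full candidate pool (all derived terms plus ratio-family interactions), then
reports the cross-validation table — AIC, full-data AUC, and leave-one-out
mean square error — for every visited model plus the published 2D and 3D
anchors.  Writes results/selection_table.csv.
"""

from pathlib import Path

import pandas as pd

from elshydro.features import add_predictors
from elshydro.io import read_cohort_csv
from elshydro.selection import search

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = add_predictors(read_cohort_csv(OUT / "cohort.csv"))
    records = search(table, strategy="stepwise", loo=True)
    df = pd.DataFrame([r.to_dict() for r in records])
    df[["aic", "auc", "mse"]] = df[["aic", "auc", "mse"]].round(4)
    df.to_csv(OUT / "selection_table.csv", index=False)
    print(df.to_string(index=False))
    best = df.iloc[0]
    print(f"\nlowest-AIC model: {best['formula']} "
          f"(AIC {best['aic']}, AUC {best['auc']}, LOO-MSE {best['mse']})")


if __name__ == "__main__":
    main()
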