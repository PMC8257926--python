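"""End-to-end orchestration: simulate/load a cohort, compute demographics and
group statistics, fit the 2D and 3D diagnostic models, compare them
(thresholds, four indices, AUC, DeLong, continuous NRI), and optionally run
model selection.

Every number in the report bundle is produced by exactly one stage module;
this layer only assembles and serialises.  Identical config + seed give an
identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COMPARTMENTS, CohortConfig, generate_cohort
from .cohortstats import fisher_exact_2x2, format_p, mann_whitney_u, onset_regression
from .evaluation import (
    closest_topleft,
    continuous_nri,
    delong_test,
    indices_at,
    reclassification_data,
    roc,
)
from .features import add_predictors
from .glm import MODEL_2D, MODEL_3D, ModelFormula, fit_logistic, predict_prob
from .io import NumpyJSONEncoder, write_cohort_csv
from .selection import cross_validation_table

logger = logging.getLogger("elshydro")

__all__ = ["RunConfig", "run_pipeline"]

_RATIO_COLS = {"cochlea": ("Ch", "Cv"), "vestibule": ("Vh", "Vv"), "scc": ("Sh", "Sv")}


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple[str, str] = (MODEL_2D.text, MODEL_3D.text)
    threshold_rule: str = "closest_topleft"
    nri: bool = True
    selection_models: tuple[str, ...] = ()
    outdir: str | None = None

    def __post_init__(self) -> None:
        for m in self.models + self.selection_models:
            ModelFormula.parse(m)
        if self.threshold_rule != "closest_topleft":
            raise ValueError("only the closest-top-left threshold rule is implemented")


def _demographics(table: pd.DataFrame) -> dict:
    subj = table.drop_duplicates("subject_id")
    ctrl = subj[subj["group"] == "control"]
    pat = subj[subj["group"] == "uMD"]
    counts = {
        "male_control": int((ctrl["sex"] == "male").sum()),
        "female_control": int((ctrl["sex"] == "female").sum()),
        "male_uMD": int((pat["sex"] == "male").sum()),
        "female_uMD": int((pat["sex"] == "female").sum()),
    }
    sex_test = fisher_exact_2x2(
        counts["male_control"], counts["female_control"],
        counts["male_uMD"], counts["female_uMD"],
    )
    age_test = mann_whitney_u(ctrl["age"], pat["age"])
    return {
        "sex_counts": counts,
        "sex_fisher_p": sex_test.p_value,
        "age_mean_control": float(ctrl["age"].mean()),
        "age_sd_control": float(ctrl["age"].std()),
        "age_mean_uMD": float(pat["age"].mean()),
        "age_sd_uMD": float(pat["age"].std()),
        "age_mannwhitney_p": age_test.p_value,
    }


def _group_tests(table: pd.DataFrame) -> dict:
    out = {}
    for comp, (els, tot) in _RATIO_COLS.items():
        ratio_pct = 100.0 * table[els] / table[tot]
        ctrl = ratio_pct[table["group"] == "control"]
        pat = ratio_pct[table["group"] == "uMD"]
        test = mann_whitney_u(ctrl, pat)
        out[comp] = {
            "median_control": float(ctrl.median()),
            "q1_control": float(ctrl.quantile(0.25)),
            "q3_control": float(ctrl.quantile(0.75)),
            "median_uMD": float(pat.median()),
            "q1_uMD": float(pat.quantile(0.25)),
            "q3_uMD": float(pat.quantile(0.75)),
            "mannwhitney_p": test.p_value,
            "mannwhitney_p_display": format_p(test.p_value),
        }
    return out


def _onset_regressions(table: pd.DataFrame) -> dict:
    pat = table[table["group"] == "uMD"].dropna(subset=["onset_interval_days"])
    out = {}
    for comp, (els, tot) in _RATIO_COLS.items():
        line = onset_regression(
            pat["onset_interval_days"], 100.0 * pat[els] / pat[tot]
        )
        out[comp] = {
            "intercept": line.intercept, "slope": line.slope,
            "p_slope": line.p_slope, "n": line.n,
        }
    return out


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the full analysis and return (and optionally write) the bundle."""
    config = config or RunConfig()
    logger.info("[simulate] generating cohort (seed=%d)", config.cohort.seed)
    cohort = generate_cohort(config.cohort)
    table = add_predictors(cohort)
    y = np.asarray(table["MD"], dtype=float)

    logger.info("[stats] demographics + group tests")
    bundle: dict = {
        "metadata": {
            "package": "elshydro",
            "version": __version__,
            "seed": config.cohort.seed,
            "n_control_ears": int((table["group"] == "control").sum()),
            "n_uMD_ears": int((table["group"] == "uMD").sum()),
        },
        "demographics": _demographics(table),
        "group_tests": _group_tests(table),
        "onset_regressions": _onset_regressions(table),
    }
    cfg_digest = hashlib.sha256(
        json.dumps(bundle["metadata"], sort_keys=True).encode()
        + repr(config).encode()
    ).hexdigest()[:16]
    bundle["metadata"]["config_hash"] = cfg_digest

    logger.info("[fit] fitting %d model(s)", len(config.models))
    fits = {}
    probs = {}
    for text in config.models:
        fit = fit_logistic(text, table)
        fits[text] = fit
        probs[text] = predict_prob(fit, table)
    bundle["models"] = {text: fit.to_dict() for text, fit in fits.items()}

    logger.info("[evaluate] ROC / thresholds / indices")
    comparison_rows = []
    for text in config.models:
        r = roc(probs[text], y)
        thr = closest_topleft(r)
        idx = indices_at(probs[text], y, thr)
        comparison_rows.append({
            "model": text,
            "Threshold": idx.threshold,
            "Sensitivity": idx.sensitivity,
            "Specificity": idx.specificity,
            "Positive predictive value": idx.ppv,
            "Negative predictive value": idx.npv,
            "AUC": r.auc,
            "AIC": fits[text].aic,
            "confusion": {"tp": idx.tp, "fp": idx.fp, "tn": idx.tn, "fn": idx.fn},
        })
    bundle["comparison"] = {"rows": comparison_rows}

    if len(config.models) >= 2:
        a, b = config.models[0], config.models[1]
        logger.info("[compare] DeLong + NRI: %s vs %s", a, b)
        dl = delong_test(probs[a], probs[b], y)
        bundle["comparison"]["delong"] = {
            "auc_a": dl.auc_a, "auc_b": dl.auc_b, "z": dl.z,
            "p_value": dl.p_value, "p_display": format_p(dl.p_value),
        }
        if config.nri:
            nri = continuous_nri(probs[a], probs[b], y)
            bundle["comparison"]["nri"] = {
                "nri": nri.nri, "z": nri.z, "p_value": nri.p_value,
                "p_display": format_p(nri.p_value),
            }
        bundle["reclassification"] = reclassification_data(
            probs[a], probs[b], y
        ).to_dict(orient="list")

    if config.selection_models:
        logger.info("[select] cross-validation table (%d models)",
                    len(config.selection_models))
        records = cross_validation_table(list(config.selection_models), table)
        bundle["selection"] = [r.to_dict() for r in records]

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(cohort, out / "cohort.csv")
        if "reclassification" in bundle:
            pd.DataFrame(bundle["reclassification"]).to_csv(
                out / "reclassification.csv", index=False
            )
        (out / "report.json").write_text(
            json.dumps(bundle, indent=2, cls=NumpyJSONEncoder)
        )
        logger.info("[report] bundle written to %s", out)
    return bundle
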