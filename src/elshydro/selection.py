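"""Model search and leave-one-out validation.

The published model-building procedure screens a pool of candidate
predictors — the seven raw measurements plus engineered reciprocal, ratio and
squared-ratio terms, and first-order interactions among the ratio-family
terms — aiming to maximise the ROC AUC while minimising AIC, and checks
candidates by leave-one-out cross-validation (LOO) mean square error between
the predicted disease probability and the 0/1 diagnosis.

Because the original search mechanics are not documented, the default
strategy here is bidirectional stepwise selection on AIC starting from the
Sex-only model (Sex is kept as a forced adjustment factor), with interactions
admissible regardless of main-effect presence — the published 3D model itself
violates marginality.  AUC and LOO-MSE are reported alongside AIC for every
visited model rather than merged into a joint objective.  An exhaustive mode
exists for small pools, and a "fixed" mode scores a given model list.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import roc
from .glm import MODEL_2D, MODEL_3D, FittedModel, ModelFormula, fit_logistic, predict_prob

__all__ = [
    "CandidatePool",
    "CvRecord",
    "default_pool",
    "loo_cv",
    "search",
    "cross_validation_table",
]

#: ratio-family terms whose pairwise products form the interaction candidates
RATIO_TERMS = ("Vr", "Cr", "Sr", "VCr", "Ir")


@dataclass(frozen=True)
class CandidatePool:
    """Candidate terms for the search.  The default pool covers every term of
    the published 3D model; restricted pools (e.g. for exhaustive
    enumeration) are permitted and checked only by :func:`covers_published`.
    """

    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]

    def covers_published(self) -> bool:
        pairs = {frozenset(p) for p in self.interactions}
        return all(
            t == "Sex" or t in self.main_effects for t in MODEL_3D.main_terms
        ) and all(frozenset(p) in pairs for p in MODEL_3D.interaction_terms)


def default_pool() -> CandidatePool:
    """Full candidate pool: every derived predictor as a main effect, and all
    unordered pairs of ratio-family terms as interactions."""
    from .features import DERIVED_NAMES

    mains = ("Sex", "Vv", "Cv", "Sv", "Vh", "Ch", "Sh") + DERIVED_NAMES
    inters = tuple(itertools.combinations(RATIO_TERMS, 2))
    return CandidatePool(main_effects=mains, interactions=inters)


@dataclass(frozen=True)
class CvRecord:
    formula: ModelFormula
    aic: float
    auc: float
    mse: float
    n_skipped_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "formula": self.formula.text,
            "aic": self.aic,
            "auc": self.auc,
            "mse": self.mse,
            "n_skipped_folds": self.n_skipped_folds,
        }


def _full_fit(formula: ModelFormula, table: pd.DataFrame, ridge: float) -> FittedModel:
    fit = fit_logistic(formula, table, ridge=ridge)
    if not fit.converged and ridge == 0.0:
        fit = fit_logistic(formula, table, ridge=1e-8)
    return fit


def loo_cv(
    formula: ModelFormula | str,
    table: pd.DataFrame,
    ridge: float = 0.0,
    unit: str = "ear",
) -> CvRecord:
    """Leave-one-out cross-validation of one model.

    For each held-out unit the model is refit on the remainder (warm-started
    at the full-data coefficients, which matches cold-start fits to high
    precision) and the held-out disease probability is predicted; MSE is the
    mean of (P_i - MD_i)^2 over folds.  AIC and AUC are reported from the
    full-data fit.  ``unit`` is "ear" (one row per fold, matching the
    published analysis that treats ears as independent) or "subject" (all
    rows of a subject held out together, a clustering-honest sensitivity
    analysis).  A fold whose training data loses an outcome class is skipped
    with a warning and counted.
    """
    if isinstance(formula, str):
        formula = ModelFormula.parse(formula)
    table = table.reset_index(drop=True)
    full = _full_fit(formula, table, ridge)
    probs_full = predict_prob(full, table)
    y = np.asarray(table[formula.response], dtype=float)
    auc = roc(probs_full, y).auc

    if unit == "ear":
        folds = [np.array([i]) for i in range(len(table))]
    elif unit == "subject":
        folds = [np.flatnonzero(table["subject_id"] == s)
                 for s in table["subject_id"].unique()]
    else:
        raise ValueError("unit must be 'ear' or 'subject'")

    sq_errors: list[float] = []
    skipped = 0
    ridge_eff = full.ridge
    for fold in folds:
        keep = np.ones(len(table), dtype=bool)
        keep[fold] = False
        y_train = y[keep]
        if y_train.sum() in (0, len(y_train)):
            skipped += 1
            continue
        fit = fit_logistic(formula, table.loc[keep], ridge=ridge_eff,
                           start=full.coefficients, check_rank=False)
        if not fit.converged and ridge_eff == 0.0:
            fit = fit_logistic(formula, table.loc[keep], ridge=1e-8,
                               start=full.coefficients, check_rank=False)
        p = predict_prob(fit, table.loc[fold])
        sq_errors.extend((p - y[fold]) ** 2)
    if skipped:
        warnings.warn(f"loo_cv: {skipped} fold(s) skipped (training lost a class)")
    mse = float(np.mean(sq_errors)) if sq_errors else float("nan")
    return CvRecord(formula=formula, aic=full.aic, auc=auc, mse=mse,
                    n_skipped_folds=skipped)


def cross_validation_table(
    models: list[ModelFormula | str], table: pd.DataFrame, ridge: float = 0.0
) -> list[CvRecord]:
    """AIC, AUC and LOO-MSE for each model, in input order."""
    if not models:
        raise ValueError("need at least one model")
    return [loo_cv(m, table, ridge=ridge) for m in models]


def _formula_with(main: list[str], inter: list[tuple[str, str]]) -> ModelFormula:
    return ModelFormula(response="MD", main_terms=tuple(main),
                        interaction_terms=tuple(inter))


def _aic_of(formula: ModelFormula, table: pd.DataFrame) -> float:
    try:
        return _full_fit(formula, table, 0.0).aic
    except (ValueError, KeyError, np.linalg.LinAlgError):
        return float("inf")


def search(
    table: pd.DataFrame,
    pool: CandidatePool | None = None,
    strategy: str = "stepwise",
    models: list[ModelFormula | str] | None = None,
    max_steps: int = 50,
    loo: bool = True,
    include_anchors: bool = True,
) -> list[CvRecord]:
    """Search the candidate pool and score models.

    Strategies: ``stepwise`` (bidirectional on AIC from the Sex-only model),
    ``exhaustive`` (all subsets; pools of at most 15 candidate terms), and
    ``fixed`` (score ``models`` as given).  The published 2D and 3D models
    are appended as anchors when their columns are available.  Returns
    records sorted by AIC.
    """
    pool = pool or default_pool()
    visited: list[ModelFormula] = []

    if strategy == "fixed":
        if not models:
            raise ValueError("strategy 'fixed' needs a model list")
        visited = [ModelFormula.parse(m) if isinstance(m, str) else m for m in models]
    elif strategy == "stepwise":
        main = ["Sex"]
        inter: list[tuple[str, str]] = []
        current = _formula_with(main, inter)
        best_aic = _aic_of(current, table)
        visited.append(current)
        for _ in range(max_steps):
            moves: list[tuple[float, list[str], list[tuple[str, str]]]] = []
            for t in pool.main_effects:
                if t not in main:
                    cand = _formula_with(main + [t], inter)
                    moves.append((_aic_of(cand, table), main + [t], inter))
            for p in pool.interactions:
                if p not in inter:
                    cand = _formula_with(main, inter + [p])
                    moves.append((_aic_of(cand, table), main, inter + [p]))
            for t in main:
                if t != "Sex":
                    m2 = [u for u in main if u != t]
                    moves.append((_aic_of(_formula_with(m2, inter), table), m2, inter))
            for p in inter:
                i2 = [q for q in inter if q != p]
                moves.append((_aic_of(_formula_with(main, i2), table), main, i2))
            if not moves:
                break
            aic, m_new, i_new = min(moves, key=lambda t: t[0])
            if aic >= best_aic - 1e-9:
                break
            main, inter, best_aic = m_new, i_new, aic
            visited.append(_formula_with(main, inter))
    elif strategy == "exhaustive":
        terms = [("main", t) for t in pool.main_effects if t != "Sex"]
        terms += [("inter", p) for p in pool.interactions]
        if len(terms) > 15:
            raise ValueError("exhaustive search limited to pools of <= 15 terms")
        for r in range(len(terms) + 1):
            for subset in itertools.combinations(terms, r):
                main = ["Sex"] + [t for k, t in subset if k == "main"]
                inter = [t for k, t in subset if k == "inter"]
                visited.append(_formula_with(main, inter))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if include_anchors:
        for anchor in (MODEL_2D, MODEL_3D):
            if all(t in table.columns for t in anchor.main_terms) and anchor.text not in {
                f.text for f in visited
            }:
                visited.append(anchor)

    records: list[CvRecord] = []
    for f in visited:
        try:
            if loo:
                records.append(loo_cv(f, table))
            else:
                fit = _full_fit(f, table, 0.0)
                probs = predict_prob(fit, table)
                y = np.asarray(table[f.response], dtype=float)
                records.append(CvRecord(formula=f, aic=fit.aic,
                                        auc=roc(probs, y).auc, mse=float("nan")))
        except (ValueError, KeyError) as exc:
            warnings.warn(f"model {f.text} failed: {exc}")
    return sorted(records, key=lambda r: r.aic)
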