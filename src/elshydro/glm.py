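"""Logistic regression with the abridged formula notation of the diagnostic models.

Formulas are written ``MD~Sex+EHV+EHC`` with first-order interactions as
``A1:A2``; an interaction column is the literal elementwise product of its two
predictor columns (no re-centring).  Fitting is maximum likelihood via
iteratively reweighted least squares (IRLS) with step-halving; AIC counts the
intercept, ``aic = 2*(p+1) - 2*logLik``.

The two shipped diagnostic models are frozen exactly as published, including
their hierarchy violations (Sr appears only inside Sr:VCr; Ch and Sh appear in
no main effect):

* ``MODEL_2D`` — conventional ordinal-grading model, MD~Sex+EHV+EHC
* ``MODEL_3D`` — volumetric model with 17 predictor terms
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ModelFormula",
    "FittedModel",
    "MODEL_2D",
    "MODEL_3D",
    "build_design",
    "fit_logistic",
    "predict_prob",
    "RankDeficiencyError",
]


class RankDeficiencyError(ValueError):
    """Design matrix is not full column rank."""


@dataclass(frozen=True)
class ModelFormula:
    """Parsed ``response~term+term+A:B`` formula.

    ``main_terms`` and ``interaction_terms`` preserve the order written, which
    fixes the design-matrix column order.
    """

    response: str
    main_terms: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.term_names:
            if t in seen:
                raise ValueError(f"duplicate term {t!r} in formula")
            seen.add(t)

    @classmethod
    def parse(cls, text: str) -> "ModelFormula":
        """Parse formula text; whitespace is ignored."""
        compact = "".join(text.split())
        if compact.count("~") != 1:
            raise ValueError(f"formula must contain exactly one '~': {text!r}")
        response, rhs = compact.split("~")
        if not response:
            raise ValueError("empty response name")
        main: list[str] = []
        inter: list[tuple[str, str]] = []
        if rhs not in ("", "1"):
            for term in rhs.split("+"):
                if not term:
                    raise ValueError(f"empty term in formula {text!r}")
                if ":" in term:
                    parts = term.split(":")
                    if len(parts) != 2 or not all(parts):
                        raise ValueError(f"malformed interaction {term!r}")
                    inter.append((parts[0], parts[1]))
                else:
                    main.append(term)
        return cls(response=response, main_terms=tuple(main), interaction_terms=tuple(inter))

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.main_terms + tuple(f"{a}:{b}" for a, b in self.interaction_terms)

    @property
    def text(self) -> str:
        rhs = "+".join(self.term_names) or "1"
        return f"{self.response}~{rhs}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


MODEL_2D = ModelFormula.parse("MD~Sex+EHV+EHC")
MODEL_3D = ModelFormula.parse(
    "MD~Sex+Vv+Cv+Sv+Vi+Si+VCi+Vh+Vr+Cr+VCr+Ir+Vr2+Cr2+Vr:Cr+Sr:VCr+VCr:Ir"
)


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name not in table.columns:
        raise KeyError(f"term {name!r} not found in table columns")
    col = np.asarray(table[name], dtype=float)
    if np.isnan(col).any():
        row = int(np.flatnonzero(np.isnan(col))[0])
        raise ValueError(f"missing value in column {name!r} at row {row}")
    return col


def build_design(
    formula: ModelFormula, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (intercept first, then terms in formula order), response
    vector, and column names."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for t in formula.main_terms:
        cols.append(_column(table, t))
        names.append(t)
    for a, b in formula.interaction_terms:
        cols.append(_column(table, a) * _column(table, b))
        names.append(f"{a}:{b}")
    y = _column(table, formula.response)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"response {formula.response!r} must be binary 0/1")
    return np.column_stack(cols), y, names


@dataclass(frozen=True)
class FittedModel:
    formula: ModelFormula
    coefficients: np.ndarray
    names: list[str]
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    iterations: int
    ridge: float
    separated: bool = False

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.coefficients)))

    def to_dict(self) -> dict:
        return {
            "formula": self.formula.text,
            "coefficients": self.coef,
            "logLik": self.log_likelihood,
            "AIC": self.aic,
            "n": self.n_obs,
            "converged": self.converged,
            "iterations": self.iterations,
        }


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable -2*logLik via logaddexp
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise RankDeficiencyError(f"collinear design columns: {bad}")


def fit_logistic(
    formula: ModelFormula | str,
    table: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
    start: np.ndarray | None = None,
    check_rank: bool = True,
) -> FittedModel:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Convergence: relative deviance change below ``tol`` (default 1e-10) or
    100 iterations.  Perfect or quasi-perfect separation does not converge;
    the fit is returned at the iteration cap with ``converged=False``, or a
    tiny ridge penalty (``ridge=1e-8``) can be supplied to stabilise the
    Hessian without materially changing the estimates.  Rank-deficient
    designs raise :class:`RankDeficiencyError` naming the collinear columns.
    """
    if isinstance(formula, str):
        formula = ModelFormula.parse(formula)
    X, y, names = build_design(formula, table)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    if check_rank and ridge == 0.0:
        _check_rank(X, names)
    p = X.shape[1]
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta
    dev = _deviance(y, eta) + ridge * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X
        if ridge > 0:
            A = A + ridge * np.eye(p)
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(A, b, rcond=None)
        # step-halving keeps the (penalised) deviance monotone
        step = beta_new - beta
        new_dev = None
        for _ in range(30):
            cand = beta + step
            cand_eta = X @ cand
            cand_dev = _deviance(y, cand_eta) + ridge * cand @ cand
            if np.isfinite(cand_dev) and cand_dev <= dev + 1e-12:
                beta, eta, new_dev = cand, cand_eta, cand_dev
                break
            step *= 0.5
        if new_dev is None:
            converged = True  # no improving step: at the optimum
            break
        if abs(dev - new_dev) / (abs(new_dev) + 0.1) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    loglik = -0.5 * _deviance(y, eta)
    # perfect separation drives the deviance to zero (the MLE is on the
    # boundary); quasi-separation shows as divergence at the iteration cap.
    # Individual well-classified observations with extreme fitted
    # probabilities do not trip the flag.
    separated = bool(dev < 1e-6 or (not converged and np.abs(eta).max() > 20.0))
    return FittedModel(
        formula=formula,
        coefficients=beta,
        names=names,
        log_likelihood=loglik,
        aic=2.0 * p - 2.0 * loglik,
        n_obs=len(y),
        converged=converged and not separated,
        iterations=it,
        ridge=ridge,
        separated=separated,
    )


def predict_prob(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Predicted disease probabilities, P = 1/(1+exp(-x.beta)), in (0, 1)."""
    n = len(table)
    cols = [np.ones(n)]
    for t in model.formula.main_terms:
        cols.append(_column(table, t))
    for a, b in model.formula.interaction_terms:
        cols.append(_column(table, a) * _column(table, b))
    X = np.column_stack(cols)
    return expit(X @ model.coefficients)
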