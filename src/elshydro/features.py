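"""Engineered predictor pool for the diagnostic models.

Seven independent predictors come straight off the per-ear record: Sex and
the six volumes (total and ELS, per compartment).  The remaining candidates
are deterministic functions of those — reciprocals of total volumes, ELS
ratios, squared ratios, and pooled (vestibule+cochlea and whole-inner-ear)
variants:

    Vi = 1/Vv          Vr = Vh*Vi          Vr2 = Vr^2
    Ci = 1/Cv          Cr = Ch*Ci          Cr2 = Cr^2
    Si = 1/Sv          Sr = Sh*Si          Sr2 = Sr^2
    VCi = 1/(Vv+Cv)    VCr = (Vh+Ch)*VCi   VCr2 = VCr^2
    Ii = 1/(Vv+Cv+Sv)  Ir = (Vh+Ch+Sh)*Ii  Ir2 = Ir^2

Ratio terms are fractions in [0, 1] (not percent); volumes enter in mm^3 as
measured.  Sex is coded male=0 (reference), female=1 so a higher female odds
of disease maps to a positive coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DERIVED_NAMES",
    "VOLUME_NAMES",
    "encode_sex",
    "decode_sex",
    "derive",
    "add_predictors",
]

VOLUME_NAMES = ("Vv", "Cv", "Sv", "Vh", "Ch", "Sh")
DERIVED_NAMES = (
    "Vi", "Vr", "Vr2",
    "Ci", "Cr", "Cr2",
    "Si", "Sr", "Sr2",
    "VCi", "VCr", "VCr2",
    "Ii", "Ir", "Ir2",
)

_SEX_CODES = {"male": 0, "female": 1}
_SEX_NAMES = {0: "male", 1: "female"}


def encode_sex(sex: str) -> int:
    try:
        return _SEX_CODES[sex]
    except KeyError:
        raise ValueError(f"unknown sex level {sex!r}; expected male/female") from None


def decode_sex(code: int) -> str:
    try:
        return _SEX_NAMES[int(code)]
    except KeyError:
        raise ValueError(f"unknown sex code {code!r}") from None


def _validate_volumes(rec) -> None:
    for name in ("Vv", "Cv", "Sv"):
        if not rec[name] > 0:
            raise ValueError(f"total volume {name} must be positive, got {rec[name]}")
    for els, tot in (("Vh", "Vv"), ("Ch", "Cv"), ("Sh", "Sv")):
        if rec[els] < 0:
            raise ValueError(f"ELS volume {els} must be non-negative, got {rec[els]}")
        if rec[els] > rec[tot]:
            raise ValueError(f"{els}={rec[els]} exceeds {tot}={rec[tot]}")


def derive(record) -> dict[str, float]:
    """All 15 derived predictor terms from one ear's six volumes.

    ``record`` is any mapping with keys Vv, Cv, Sv, Vh, Ch, Sh (mm^3).
    """
    _validate_volumes(record)
    Vv, Cv, Sv = float(record["Vv"]), float(record["Cv"]), float(record["Sv"])
    Vh, Ch, Sh = float(record["Vh"]), float(record["Ch"]), float(record["Sh"])
    Vi, Ci, Si = 1.0 / Vv, 1.0 / Cv, 1.0 / Sv
    Vr, Cr, Sr = Vh * Vi, Ch * Ci, Sh * Si
    VCi = 1.0 / (Vv + Cv)
    VCr = (Vh + Ch) * VCi
    Ii = 1.0 / (Vv + Cv + Sv)
    Ir = (Vh + Ch + Sh) * Ii
    return {
        "Vi": Vi, "Vr": Vr, "Vr2": Vr * Vr,
        "Ci": Ci, "Cr": Cr, "Cr2": Cr * Cr,
        "Si": Si, "Sr": Sr, "Sr2": Sr * Sr,
        "VCi": VCi, "VCr": VCr, "VCr2": VCr * VCr,
        "Ii": Ii, "Ir": Ir, "Ir2": Ir * Ir,
    }


def add_predictors(table: pd.DataFrame) -> pd.DataFrame:
    """Append the response, encoded sex, and all derived terms to a cohort table.

    Adds column MD (control=0, uMD=1), recodes Sex to 0/1, and appends the 15
    derived columns under their conventional symbols.  Vectorised equivalent
    of :func:`derive` row-wise.
    """
    df = table.copy()
    for name in ("Vv", "Cv", "Sv"):
        bad = df.index[~(df[name] > 0)]
        if len(bad):
            raise ValueError(f"non-positive {name} at rows {list(bad[:5])}")
    for els, tot in (("Vh", "Vv"), ("Ch", "Cv"), ("Sh", "Sv")):
        bad = df.index[(df[els] < 0) | (df[els] > df[tot])]
        if len(bad):
            raise ValueError(f"{els} outside [0, {tot}] at rows {list(bad[:5])}")
    if "group" in df.columns:
        df["MD"] = (df["group"] == "uMD").astype(int)
    if df["sex"].dtype == object:
        df["Sex"] = df["sex"].map(_SEX_CODES)
        if df["Sex"].isna().any():
            raise ValueError("unknown sex level in table")
    else:
        df["Sex"] = df["sex"].astype(int)
    Vv, Cv, Sv = df["Vv"], df["Cv"], df["Sv"]
    Vh, Ch, Sh = df["Vh"], df["Ch"], df["Sh"]
    df["Vi"], df["Ci"], df["Si"] = 1.0 / Vv, 1.0 / Cv, 1.0 / Sv
    df["Vr"], df["Cr"], df["Sr"] = Vh / Vv, Ch / Cv, Sh / Sv
    df["Vr2"], df["Cr2"], df["Sr2"] = df["Vr"] ** 2, df["Cr"] ** 2, df["Sr"] ** 2
    df["VCi"] = 1.0 / (Vv + Cv)
    df["VCr"] = (Vh + Ch) * df["VCi"]
    df["VCr2"] = df["VCr"] ** 2
    df["Ii"] = 1.0 / (Vv + Cv + Sv)
    df["Ir"] = (Vh + Ch + Sh) * df["Ii"]
    df["Ir2"] = df["Ir"] ** 2
    return df
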