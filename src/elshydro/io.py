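"""Cohort CSV and configuration I/O with schema validation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, GradeCutpoints, GroupDistribution

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_cohort_config",
    "dump_cohort_config",
]

COHORT_COLUMNS = [
    "subject_id", "ear", "group", "sex", "age",
    "Vv", "Cv", "Sv", "Vh", "Ch", "Sh", "EHV", "EHC",
    "onset_interval_days",
]

_GRADES = (0.0, 0.5, 1.0)


class CohortSchemaError(ValueError):
    pass


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a per-ear cohort table.

    Checks the header, positivity of volumes, the ELS <= total ordering, and
    membership of the ordinal grades in {0, 0.5, 1}; errors name the
    offending row (0-based data row index).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise CohortSchemaError(f"{path}: no data rows")
    for name in ("Vv", "Cv", "Sv"):
        bad = df.index[~(df[name] > 0)]
        if len(bad):
            raise CohortSchemaError(f"{path}: non-positive {name} at row {bad[0]}")
    for els, tot in (("Vh", "Vv"), ("Ch", "Cv"), ("Sh", "Sv")):
        bad = df.index[(df[els] < 0) | (df[els] > df[tot])]
        if len(bad):
            raise CohortSchemaError(f"{path}: {els} outside [0, {tot}] at row {bad[0]}")
    for g in ("EHV", "EHC"):
        bad = df.index[~df[g].isin(_GRADES)]
        if len(bad):
            raise CohortSchemaError(
                f"{path}: {g} must be one of {{0, 0.5, 1}}, bad value at row {bad[0]}"
            )
    for col, levels in (("group", {"control", "uMD"}), ("sex", {"male", "female"}),
                        ("ear", {"left", "right"})):
        bad = df.index[~df[col].isin(levels)]
        if len(bad):
            raise CohortSchemaError(f"{path}: invalid {col} at row {bad[0]}")
    return df


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, index=False, columns=cols)


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["distributions"] = [dataclasses.asdict(g) for g in config.distributions]
    d["grade_cutpoints"] = {
        "cochlea": list(config.grade_cutpoints.cochlea),
        "vestibule": list(config.grade_cutpoints.vestibule),
    }
    return d


def dump_cohort_config(config: CohortConfig, path) -> None:
    """Write a CohortConfig as JSON (or YAML if the suffix says so)."""
    d = _config_to_dict(config)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_cohort_config(path) -> CohortConfig:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        d = yaml.safe_load(path.read_text())
    else:
        d = json.loads(path.read_text())
    if "distributions" in d:
        d["distributions"] = tuple(GroupDistribution(**g) for g in d["distributions"])
    if "grade_cutpoints" in d:
        gc = d["grade_cutpoints"]
        d["grade_cutpoints"] = GradeCutpoints(
            cochlea=tuple(gc["cochlea"]), vestibule=tuple(gc["vestibule"])
        )
    if "total_volume_params" in d:
        d["total_volume_params"] = {
            k: tuple(v) for k, v in d["total_volume_params"].items()
        }
    if "onset_interval_params" in d:
        d["onset_interval_params"] = tuple(d["onset_interval_params"])
    return CohortConfig(**d)


class NumpyJSONEncoder(json.JSONEncoder):
    """JSON encoder accepting numpy scalars/arrays and NaN-free floats."""

    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)
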