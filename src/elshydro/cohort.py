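"""Synthetic case-control cohort generator for endolymphatic-hydrops volumetry.

The study design emulated here compares unilateral Meniere's disease (uMD)
patients against healthy controls on the endolymphatic-space (ELS) ratio —
ELS volume over total fluid volume — measured per inner-ear compartment
(cochlea, vestibule, semicircular canals).  Because no patient-level
measurements are publicly deposited, every downstream stage is exercised on
cohorts drawn from log-normal ratio distributions calibrated, in closed form,
to the published per-group median and interquartile range of each
compartment.

Controls contribute both ears; patients contribute the affected ear only, so
the default configuration yields 94 control ears and 86 patient ears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GroupDistribution",
    "GradeCutpoints",
    "CohortConfig",
    "PUBLISHED_DISTRIBUTIONS",
    "calibrate_lognormal",
    "sample_ratios_pct",
    "grade_from_ratio",
    "generate_cohort",
    "generate_phantom",
    "PhantomResult",
]

COMPARTMENTS = ("cochlea", "vestibule", "scc")
GROUPS = ("control", "uMD")

#: standard-normal 75th-percentile deviate used by the median/IQR calibration
_Z75 = float(norm.ppf(0.75))


class InvalidDistributionError(ValueError):
    """Raised when quantile summaries cannot define a log-normal."""


@dataclass(frozen=True)
class GroupDistribution:
    """Published per-group ELS-ratio summary: median and quartiles, in percent."""

    compartment: str
    group: str
    median_pct: float
    q1_pct: float
    q3_pct: float

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise InvalidDistributionError(f"unknown compartment {self.compartment!r}")
        if self.group not in GROUPS:
            raise InvalidDistributionError(f"unknown group {self.group!r}")
        if not (0.0 < self.q1_pct < self.median_pct < self.q3_pct <= 100.0):
            raise InvalidDistributionError(
                f"quantiles must satisfy 0 < q1 < median < q3 <= 100, got "
                f"q1={self.q1_pct}, median={self.median_pct}, q3={self.q3_pct}"
            )


#: Published group summaries (median [IQR] of the ELS ratio, percent) that the
#: generator is calibrated to: control vs uMD for each compartment.
PUBLISHED_DISTRIBUTIONS: tuple[GroupDistribution, ...] = (
    GroupDistribution("cochlea", "control", 8.15, 4.93, 14.45),
    GroupDistribution("cochlea", "uMD", 22.50, 12.20, 31.12),
    GroupDistribution("vestibule", "control", 16.25, 9.70, 23.65),
    GroupDistribution("vestibule", "uMD", 32.85, 15.75, 52.20),
    GroupDistribution("scc", "control", 11.65, 6.45, 19.25),
    GroupDistribution("scc", "uMD", 19.50, 11.90, 27.15),
)


def calibrate_lognormal(dist: GroupDistribution) -> tuple[float, float]:
    """Closed-form log-normal calibration from a median and an IQR.

    A log-normal with log-scale location ``mu`` and spread ``sigma`` has
    median ``exp(mu)`` and quartile ratio ``q3/q1 = exp(2*sigma*z75)`` where
    ``z75`` is the standard-normal 75th-percentile deviate.  Inverting:

        mu    = ln(median)
        sigma = ln(q3/q1) / (2 * z75)

    The resulting distribution reproduces the target median exactly and the
    target quartile *ratio* exactly; a two-parameter family cannot also match
    the absolute IQR width.
    """
    mu = math.log(dist.median_pct)
    sigma = math.log(dist.q3_pct / dist.q1_pct) / (2.0 * _Z75)
    return mu, sigma


@dataclass(frozen=True)
class GradeCutpoints:
    """Ratio thresholds mapping a continuous ELS ratio to the ordinal
    none/mild/significant grading used by the conventional 2D evaluation.

    The numeric cutpoints of the cited grading systems are not restated in the
    source report; these defaults are implementer conventions and fully
    configurable.  Values are fractions of the total fluid space.
    """

    cochlea: tuple[float, float] = (0.20, 1.0 / 3.0)
    vestibule: tuple[float, float] = (1.0 / 3.0, 0.50)

    def __post_init__(self) -> None:
        for name in ("cochlea", "vestibule"):
            t_mild, t_sig = getattr(self, name)
            if not (0.0 < t_mild < t_sig < 1.0):
                raise ValueError(
                    f"{name} cutpoints must satisfy 0 < t_mild < t_significant < 1"
                )


def grade_from_ratio(
    ratio: float, compartment: str, cutpoints: GradeCutpoints | None = None
) -> float:
    """Ordinal hydrops grade (0 / 0.5 / 1 = none / mild / significant).

    Half-open convention: a ratio exactly at a cutpoint takes the higher
    grade.  ``ratio`` is a fraction in [0, 1].
    """
    cutpoints = cutpoints or GradeCutpoints()
    if compartment not in ("cochlea", "vestibule"):
        raise ValueError(f"no grading defined for compartment {compartment!r}")
    if not (0.0 <= ratio <= 1.0):
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    t_mild, t_sig = getattr(cutpoints, compartment)
    if ratio < t_mild:
        return 0.0
    if ratio < t_sig:
        return 0.5
    return 1.0


def sample_ratios_pct(
    dist: GroupDistribution,
    n: int,
    rng: np.random.Generator,
    truncate: bool = False,
) -> np.ndarray:
    """Draw ``n`` ELS ratios (percent) from the calibrated log-normal.

    With ``truncate=True`` values above 100% are resampled, which is what the
    cohort generator does to keep ELS volume below the total volume; note
    truncation pulls the median of heavy-tailed cells below the calibration
    target, so calibration checks sample the plain log-normal (the default).
    """
    mu, sigma = calibrate_lognormal(dist)
    out = rng.lognormal(mu, sigma, size=n)
    if truncate:
        over = out > 100.0
        while over.any():
            out[over] = rng.lognormal(mu, sigma, size=int(over.sum()))
            over = out > 100.0
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the simulated cohort.

    Defaults reproduce the published composition: 47 control volunteers (both
    ears analysed) and 86 uMD patients (affected ear only), the printed
    sex counts (25/47 male controls, 33/86 male patients) and age summaries
    (58.4 +/- 16.3 vs 56.9 +/- 14.7 years), and ELS-ratio distributions
    calibrated to the published per-group medians and IQRs.

    Total fluid volumes per compartment are not published; the log-normal
    defaults below (cochlea 75 mm^3, vestibule 60 mm^3, SCC 60 mm^3, 15%
    coefficient of variation) are synthetic conventions.  ``ratio_correlation``
    is a Gaussian-copula correlation shared by the three compartment ratios
    within an ear (0 = independent, the default).
    """

    n_controls: int = 47
    n_patients: int = 86
    seed: int = 0
    p_male_control: float = 25.0 / 47.0
    p_male_patient: float = 33.0 / 86.0
    age_mean_control: float = 58.4
    age_sd_control: float = 16.3
    age_mean_patient: float = 56.9
    age_sd_patient: float = 14.7
    distributions: tuple[GroupDistribution, ...] = PUBLISHED_DISTRIBUTIONS
    #: per-compartment (median mm^3, coefficient of variation) of total volume
    total_volume_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "cochlea": (75.0, 0.15),
            "vestibule": (60.0, 0.15),
            "scc": (60.0, 0.15),
        }
    )
    grade_cutpoints: GradeCutpoints = field(default_factory=GradeCutpoints)
    #: (min_days, max_days) of the log-uniform onset-interval distribution
    onset_interval_params: tuple[float, float] = (1.0, 3650.0)
    ratio_correlation: float = 0.0
    include_contralateral: bool = False

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_patients <= 0:
            raise ValueError("subject counts must be positive")
        for p in (self.p_male_control, self.p_male_patient):
            if not (0.0 <= p <= 1.0):
                raise ValueError("sex probabilities must be in [0, 1]")
        for s in (self.age_sd_control, self.age_sd_patient):
            if s <= 0:
                raise ValueError("age scale parameters must be positive")
        keys = {(d.compartment, d.group) for d in self.distributions}
        need = {(c, g) for c in COMPARTMENTS for g in GROUPS}
        if keys != need:
            raise ValueError("distributions must cover all 6 compartment x group cells")
        for c in COMPARTMENTS:
            med, cv = self.total_volume_params[c]
            if med <= 0 or cv <= 0:
                raise ValueError("total-volume parameters must be positive")
        lo, hi = self.onset_interval_params
        if not (0.0 <= lo < hi):
            raise ValueError("onset interval bounds must satisfy 0 <= lo < hi")
        if not (-1.0 < self.ratio_correlation < 1.0):
            raise ValueError("ratio_correlation must be in (-1, 1)")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _draw_ratios(
    rng: np.random.Generator,
    params: dict[str, tuple[float, float]],
    rho: float,
) -> dict[str, float]:
    """One correlated triple of ELS ratios (fractions), truncated at 100%.

    A Gaussian copula with common pairwise correlation ``rho`` couples the
    three compartments; truncation resamples the whole triple so the copula
    is preserved.
    """
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    for _ in range(1000):
        z = chol @ rng.standard_normal(3)
        pct = {
            c: math.exp(params[c][0] + params[c][1] * z[i])
            for i, c in enumerate(COMPARTMENTS)
        }
        if all(v <= 100.0 for v in pct.values()):
            return {c: v / 100.0 for c, v in pct.items()}
    raise RuntimeError("truncation resampling failed to converge")


def _draw_ear(
    rng: np.random.Generator,
    config: CohortConfig,
    ratio_params: dict[str, tuple[float, float]],
) -> dict[str, float]:
    """Volumes and grades for one ear.  Sampling order is fixed:
    total volumes (cochlea, vestibule, scc), then the ratio triple."""
    totals = {}
    for c in COMPARTMENTS:
        med, cv = config.total_volume_params[c]
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        totals[c] = math.exp(math.log(med) + sigma * rng.standard_normal())
    ratios = _draw_ratios(rng, ratio_params, config.ratio_correlation)
    row = {
        "Cv": totals["cochlea"],
        "Vv": totals["vestibule"],
        "Sv": totals["scc"],
        "Ch": ratios["cochlea"] * totals["cochlea"],
        "Vh": ratios["vestibule"] * totals["vestibule"],
        "Sh": ratios["scc"] * totals["scc"],
    }
    row["EHC"] = grade_from_ratio(ratios["cochlea"], "cochlea", config.grade_cutpoints)
    row["EHV"] = grade_from_ratio(
        ratios["vestibule"], "vestibule", config.grade_cutpoints
    )
    return row


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate a per-ear cohort table.

    Each control subject contributes two rows (left and right ear, both drawn
    from the control distributions); each patient contributes one row (the
    affected ear, drawn from the uMD distributions).  Per compartment the ELS
    ratio is log-normal with the calibrated parameters, truncated at 100%;
    ELS volume is ratio x total volume; ordinal grades EHV/EHC derive from
    the sampled ratios.  Deterministic given ``config.seed``.

    Sampling order (one RNG stream): controls in subject order (sex, age, left
    ear, right ear), then patients in subject order (sex, age, affected side,
    ear, onset interval, optional contralateral ear).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    dists = {(d.compartment, d.group): d for d in config.distributions}
    params = {
        g: {c: calibrate_lognormal(dists[(c, g)]) for c in COMPARTMENTS}
        for g in GROUPS
    }
    rows: list[dict] = []
    for i in range(config.n_controls):
        sex = "male" if rng.random() < config.p_male_control else "female"
        age = config.age_mean_control + config.age_sd_control * rng.standard_normal()
        for ear in ("left", "right"):
            row = {
                "subject_id": f"C{i + 1:03d}",
                "ear": ear,
                "group": "control",
                "sex": sex,
                "age": age,
                "onset_interval_days": np.nan,
            }
            row.update(_draw_ear(rng, config, params["control"]))
            rows.append(row)
    lo, hi = config.onset_interval_params
    for i in range(config.n_patients):
        sex = "male" if rng.random() < config.p_male_patient else "female"
        age = config.age_mean_patient + config.age_sd_patient * rng.standard_normal()
        side = "left" if rng.random() < 0.5 else "right"
        row = {
            "subject_id": f"P{i + 1:03d}",
            "ear": side,
            "group": "uMD",
            "sex": sex,
            "age": age,
        }
        row.update(_draw_ear(rng, config, params["uMD"]))
        row["onset_interval_days"] = math.exp(
            rng.uniform(math.log(1.0 + lo), math.log(1.0 + hi))
        ) - 1.0
        rows.append(row)
        if config.include_contralateral:
            other = {"left": "right", "right": "left"}[side]
            crow = {
                "subject_id": f"P{i + 1:03d}",
                "ear": other,
                "group": "uMD",
                "sex": sex,
                "age": age,
                "onset_interval_days": row["onset_interval_days"],
            }
            crow.update(_draw_ear(rng, config, params["control"]))
            crow["affected"] = False
            rows.append(crow)
            row["affected"] = True
    columns = [
        "subject_id", "ear", "group", "sex", "age",
        "Vv", "Cv", "Sv", "Vh", "Ch", "Sh", "EHV", "EHC",
        "onset_interval_days",
    ]
    if config.include_contralateral:
        for r in rows:
            r.setdefault("affected", True)
        columns.append("affected")
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# voxel phantoms


@dataclass(frozen=True)
class PhantomResult:
    """A labelled signed-signal phantom plus its construction ground truth."""

    volume: "SignedVolume"  # noqa: F821 - forward ref, see volumetry
    counts: dict[str, tuple[int, int]]  # compartment -> (n_fluid, n_els)


def generate_phantom(
    record,
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    grid_shape: tuple[int, int, int] = (36, 24, 24),
) -> PhantomResult:
    """Build a signed-signal phantom realising one ear's volumes.

    Three disjoint cuboid slabs (along the first axis) stand in for cochlea,
    vestibule and SCC; no anatomical geometry is attempted.  Each slab is
    filled, in raster order, with ``round(volume / voxel_volume)`` fluid
    voxels; the first ``round(ELS volume / voxel_volume)`` of them carry
    signal -1 (endolymph) and the remainder +1 (perilymph), so ELS voxels
    form a face-connected region.  Ground-truth counts are returned so tests
    can compare voxel-counting output with construction.

    ``record`` is any mapping with keys Cv, Vv, Sv, Ch, Vh, Sh (mm^3).
    """
    from .volumetry import COMPARTMENT_LABELS, SignedVolume

    vx = float(np.prod(voxel_size))
    if vx <= 0:
        raise ValueError("voxel dimensions must be positive")
    signal = np.zeros(grid_shape, dtype=np.float32)
    labels = np.zeros(grid_shape, dtype=np.uint8)
    slab = grid_shape[0] // 3
    if slab < 1:
        raise ValueError("grid too small: first axis must allow 3 slabs")
    spans = {"cochlea": (0, slab), "vestibule": (slab, 2 * slab), "scc": (2 * slab, grid_shape[0])}
    vol_keys = {"cochlea": ("Cv", "Ch"), "vestibule": ("Vv", "Vh"), "scc": ("Sv", "Sh")}
    counts: dict[str, tuple[int, int]] = {}
    for comp, (k_tot, k_els) in vol_keys.items():
        n_tot = int(round(float(record[k_tot]) / vx))
        n_els = min(int(round(float(record[k_els]) / vx)), n_tot)
        if n_tot < 10:
            raise ValueError(
                f"{comp}: volume {record[k_tot]} mm^3 spans fewer than 10 voxels "
                f"at voxel volume {vx} mm^3"
            )
        lo, hi = spans[comp]
        capacity = (hi - lo) * grid_shape[1] * grid_shape[2]
        if n_tot > capacity:
            raise ValueError(
                f"{comp}: needs {n_tot} voxels but slab holds {capacity}; "
                "enlarge grid_shape or coarsen voxel_size"
            )
        block = np.zeros((hi - lo) * grid_shape[1] * grid_shape[2], dtype=np.float32)
        lab = np.zeros_like(block, dtype=np.uint8)
        block[:n_els] = -1.0
        block[n_els:n_tot] = 1.0
        lab[:n_tot] = COMPARTMENT_LABELS[comp]
        shape3 = (hi - lo, grid_shape[1], grid_shape[2])
        signal[lo:hi] = block.reshape(shape3)
        labels[lo:hi] = lab.reshape(shape3)
        counts[comp] = (n_tot, n_els)
    return PhantomResult(
        volume=SignedVolume(signal=signal, labels=labels, voxel_dims=tuple(voxel_size)),
        counts=counts,
    )
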