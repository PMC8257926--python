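"""Voxel-counting volumetry of the endolymphatic space.

The processed inner-ear MR image assigns endolymph voxels negative signal and
perilymph voxels positive signal within each labelled compartment.  Volumetry
is therefore pure counting: total fluid volume is the labelled voxel count
times the voxel volume, ELS volume counts the negative voxels, and the ELS
ratio is their quotient.  The clinical protocol measures three times and
averages; on identical digital input the repeats are deterministic, with an
optional label-mask perturbation to emulate human re-tracing variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignedVolume",
    "CompartmentMeasure",
    "VolumetryResult",
    "COMPARTMENT_LABELS",
    "classify_voxels",
    "measure",
    "measure_repeats",
    "average_repeats",
    "save_nifti_pair",
    "load_nifti_pair",
]

#: label codes in the mask image: 0 is background
COMPARTMENT_LABELS = {"cochlea": 1, "vestibule": 2, "scc": 3}
_LABEL_NAMES = {v: k for k, v in COMPARTMENT_LABELS.items()}

# voxel classes returned by classify_voxels
EXCLUDED, ELS, PERILYMPH = 0, 1, 2


class MissingCompartmentError(ValueError):
    """A requested compartment has no labelled voxels."""


@dataclass(frozen=True)
class SignedVolume:
    """Signed signal grid + compartment label mask + voxel dimensions (mm)."""

    signal: np.ndarray
    labels: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.signal.shape != self.labels.shape:
            raise ValueError(
                f"signal shape {self.signal.shape} != labels shape {self.labels.shape}"
            )
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be three positive lengths (mm)")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass(frozen=True)
class CompartmentMeasure:
    total_volume: float  # mm^3
    els_volume: float  # mm^3
    els_ratio: float  # fraction in [0, 1]
    n_voxels: int
    n_els_voxels: int
    n_zero_voxels: int


@dataclass(frozen=True)
class VolumetryResult:
    compartments: dict[str, CompartmentMeasure]
    repeats: list[dict[str, tuple[float, float]]] = field(default_factory=list)


def classify_voxels(vol: SignedVolume) -> np.ndarray:
    """Per-voxel class: ELS (negative signal), perilymph (positive signal,
    with zero-signal voxels conservatively counted as perilymph), or excluded
    (background label)."""
    out = np.full(vol.signal.shape, PERILYMPH, dtype=np.int8)
    out[vol.signal < 0] = ELS
    out[vol.labels == 0] = EXCLUDED
    return out


def measure(
    vol: SignedVolume,
    compartments: tuple[str, ...] = ("cochlea", "vestibule", "scc"),
) -> VolumetryResult:
    """Count voxels per compartment and convert to volumes and ELS ratios."""
    classes = classify_voxels(vol)
    vx = vol.voxel_volume
    out: dict[str, CompartmentMeasure] = {}
    for comp in compartments:
        code = COMPARTMENT_LABELS[comp]
        mask = vol.labels == code
        n = int(mask.sum())
        if n == 0:
            raise MissingCompartmentError(f"compartment {comp!r} has no labelled voxels")
        n_els = int((classes[mask] == ELS).sum())
        n_zero = int((vol.signal[mask] == 0).sum())
        total = n * vx
        els = n_els * vx
        out[comp] = CompartmentMeasure(
            total_volume=total,
            els_volume=els,
            els_ratio=els / total,
            n_voxels=n,
            n_els_voxels=n_els,
            n_zero_voxels=n_zero,
        )
    return VolumetryResult(compartments=out)


def _perturb_labels(
    vol: SignedVolume, drop_fraction: float, rng: np.random.Generator
) -> SignedVolume:
    """Randomly drop a fraction of labelled voxels, emulating re-tracing."""
    labels = vol.labels.copy()
    labelled = np.flatnonzero(labels.ravel() != 0)
    n_drop = int(round(drop_fraction * labelled.size))
    if n_drop:
        drop = rng.choice(labelled, size=n_drop, replace=False)
        labels.ravel()[drop] = 0
    return SignedVolume(signal=vol.signal, labels=labels, voxel_dims=vol.voxel_dims)


def measure_repeats(
    vol: SignedVolume,
    n_repeats: int = 3,
    perturbation: float = 0.0,
    rng: np.random.Generator | None = None,
    compartments: tuple[str, ...] = ("cochlea", "vestibule", "scc"),
) -> VolumetryResult:
    """Measure ``n_repeats`` times and average.

    With ``perturbation == 0`` (the default) the repeats are identical; a
    positive fraction drops that share of labelled voxels independently per
    repeat before counting.
    """
    if perturbation > 0 and rng is None:
        rng = np.random.default_rng(0)
    results = []
    for _ in range(n_repeats):
        v = _perturb_labels(vol, perturbation, rng) if perturbation > 0 else vol
        results.append(measure(v, compartments))
    return average_repeats(results, n_required=n_repeats)


def average_repeats(
    results: list[VolumetryResult], n_required: int = 3
) -> VolumetryResult:
    """Average the repeated measurements.

    Volumes are averaged arithmetically and the ratio is recomputed from the
    averaged volumes (ratio of mean volumes, not mean of ratios).
    """
    if len(results) != n_required:
        raise ValueError(f"expected {n_required} repeats, got {len(results)}")
    comps = set(results[0].compartments)
    for r in results[1:]:
        if set(r.compartments) != comps:
            raise ValueError("repeats cover different compartments")
    out: dict[str, CompartmentMeasure] = {}
    repeats: list[dict[str, tuple[float, float]]] = [
        {c: (r.compartments[c].total_volume, r.compartments[c].els_volume) for c in comps}
        for r in results
    ]
    for comp in comps:
        totals = [r.compartments[comp].total_volume for r in results]
        els = [r.compartments[comp].els_volume for r in results]
        mean_total = float(np.mean(totals))
        mean_els = float(np.mean(els))
        out[comp] = CompartmentMeasure(
            total_volume=mean_total,
            els_volume=mean_els,
            els_ratio=mean_els / mean_total if mean_total > 0 else 0.0,
            n_voxels=int(round(np.mean([r.compartments[comp].n_voxels for r in results]))),
            n_els_voxels=int(round(np.mean([r.compartments[comp].n_els_voxels for r in results]))),
            n_zero_voxels=int(round(np.mean([r.compartments[comp].n_zero_voxels for r in results]))),
        )
    return VolumetryResult(compartments=out, repeats=repeats)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_nifti_pair(vol: SignedVolume, signal_path, labels_path) -> None:
    """Write the signal (float32) and label mask (uint8) as NIfTI-1 files."""
    import nibabel as nib

    affine = np.diag(list(vol.voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(vol.signal.astype(np.float32), affine), str(signal_path))
    nib.save(nib.Nifti1Image(vol.labels.astype(np.uint8), affine), str(labels_path))


def load_nifti_pair(signal_path, labels_path) -> SignedVolume:
    import nibabel as nib

    sig = nib.load(str(signal_path))
    lab = nib.load(str(labels_path))
    dims = tuple(float(z) for z in sig.header.get_zooms()[:3])
    return SignedVolume(
        signal=np.asarray(sig.dataobj, dtype=np.float32),
        labels=np.asarray(lab.dataobj, dtype=np.uint8),
        voxel_dims=dims,
    )
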