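"""Digital mouse-head phantom: image-domain oracle for the analytic model.

A phantom is a stack of identical 2D slices (a cylindrical approximation of
the head) whose regions — elliptical head outline, an offset circular tumor
emulating the 2 mm-lateral implant, small CSF pockets — are painted with the
magnitude of the analytic sequence signal of their tissue, plus seeded
Gaussian or Rician noise.  An ROI pipeline reproduces the image-based CNR
measurement: per-slice ROI means/SDs, slice-averaged CNR and its cross-slice
coefficient of variation.  Rendering is purely functional in
(spec, sequence, tissues, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionGeometry
from .signals import sequence_signal
from .tissues import TissueRelaxation

__all__ = [
    "Region",
    "PhantomSpec",
    "SyntheticImage",
    "RoiStats",
    "CnrMeasurement",
    "default_head_phantom",
    "render",
    "roi_stats",
    "measured_cnr",
    "write_nifti",
]


@dataclass(frozen=True)
class Region:
    """Elliptical region: center and radii in mm (FOV-centered coordinates)."""

    label: str
    center_mm: tuple[float, float]
    radii_mm: tuple[float, float]
    tissue: str

    def __post_init__(self) -> None:
        if min(self.radii_mm) < 0:
            raise ValueError("radii must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Labeled phantom layout with noise provenance.

    Regions are painted in order (later regions overwrite earlier ones);
    voxels outside every region take the background signal 0.  Region labels
    must be unique and shapes must lie within the FOV.
    """

    geometry: AcquisitionGeometry
    regions: tuple[Region, ...]
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0
    n_slices: int = 3

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"region labels must be unique, got {labels}")
        half_x = self.geometry.fov_x_mm / 2
        half_y = self.geometry.fov_y_mm / 2
        for r in self.regions:
            if (abs(r.center_mm[0]) + r.radii_mm[0] > half_x
                    or abs(r.center_mm[1]) + r.radii_mm[1] > half_y):
                raise ValueError(f"region {r.label!r} extends beyond the FOV")


@dataclass(frozen=True)
class SyntheticImage:
    """Magnitude image stack (slice, y, x) with geometry and provenance."""

    data: np.ndarray
    geometry: AcquisitionGeometry
    provenance: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class RoiStats:
    """Per-slice, per-ROI mean/SD table (1-based slice numbers in reports)."""

    table: pd.DataFrame  # columns: roi, slice, mean, sd, n_voxels

    def slice_means(self, roi: str) -> np.ndarray:
        sub = self.table[self.table["roi"] == roi]
        if sub.empty:
            raise KeyError(f"roi {roi!r} not present; have {sorted(self.table['roi'].unique())}")
        return sub.sort_values("slice")["mean"].to_numpy()

    def cross_slice_mean(self, roi: str) -> float:
        return float(np.mean(self.slice_means(roi)))

    def cross_slice_cv(self, roi: str) -> float:
        means = self.slice_means(roi)
        m = np.mean(means)
        if m == 0:
            raise ValueError("cross-slice CV undefined for zero mean")
        return float(100.0 * np.std(means, ddof=1) / abs(m))


@dataclass(frozen=True)
class CnrMeasurement:
    """Slice-averaged ROI-mean difference and its cross-slice variability."""

    value: float
    per_slice: tuple[float, ...]
    cv_percent: float | None  # None when the slice-mean CNR is zero


def default_head_phantom(
    geometry: AcquisitionGeometry,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
    n_slices: int = 3,
) -> PhantomSpec:
    """Elliptical head with an offset tumor and two CSF pockets.

    Dimensions are scaled to the mouse-brain FOV: an 8×6 mm head ellipse of
    brain parenchyma, a 2 mm-radius tumor centered 2 mm lateral (emulating
    the implantation site) and two 1.2×0.8 mm CSF ventricle ellipses.
    Arbitrary fixture values — the study does not publish a phantom.
    """
    regions = (
        Region("head", (0.0, 0.0), (8.0, 6.0), "brain_parenchyma"),
        Region("csf_left", (-2.5, 2.5), (1.2, 0.8), "csf"),
        Region("csf_right", (2.5, 2.5), (1.2, 0.8), "csf"),
        Region("tumor", (2.0, -1.5), (2.0, 2.0), "tumor"),
    )
    return PhantomSpec(geometry, regions, noise_sd, noise_model, seed, n_slices)


def _grids_mm(geom: AcquisitionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-center coordinates (mm), FOV-centered, axis-aligned."""
    dx = geom.fov_x_mm / geom.n_fe
    dy = geom.fov_y_mm / geom.n_pe
    x = (np.arange(geom.n_fe) + 0.5) * dx - geom.fov_x_mm / 2
    y = (np.arange(geom.n_pe) + 0.5) * dy - geom.fov_y_mm / 2
    return np.meshgrid(x, y)


def _ellipse_mask(geom: AcquisitionGeometry, region: Region) -> np.ndarray:
    if min(region.radii_mm) == 0:
        return np.zeros((geom.n_pe, geom.n_fe), dtype=bool)
    xx, yy = _grids_mm(geom)
    cx, cy = region.center_mm
    rx, ry = region.radii_mm
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def render(spec: PhantomSpec, seq, tissues: Mapping[str, TissueRelaxation]) -> SyntheticImage:
    """Paint each region with the magnitude of its tissue's analytic signal.

    Noise is drawn per voxel with a generator seeded by ``spec.seed``:
    Gaussian adds N(0, σ); Rician replaces the voxel value v by
    ``sqrt((v+n1)² + n2²)`` with independent N(0, σ) components, as in
    magnitude reconstruction.
    """
    geom = spec.geometry
    slice_img = np.zeros((geom.n_pe, geom.n_fe))
    for region in spec.regions:
        if region.tissue not in tissues:
            raise KeyError(
                f"region {region.label!r} references unknown tissue "
                f"{region.tissue!r}; have {sorted(tissues)}"
            )
        signal = abs(sequence_signal(seq, tissues[region.tissue]).s_over_m0)
        slice_img[_ellipse_mask(geom, region)] = signal
    data = np.repeat(slice_img[None, :, :], spec.n_slices, axis=0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        else:
            n1 = rng.normal(0.0, spec.noise_sd, size=data.shape)
            n2 = rng.normal(0.0, spec.noise_sd, size=data.shape)
            data = np.sqrt((data + n1) ** 2 + n2**2)
    provenance = {
        "sequence": type(seq).__name__,
        "sequence_params": {k: getattr(seq, k) for k in seq.__dataclass_fields__},
        "tissues": {n: (t.t1_ms, t.t2_ms, t.t2star_ms) for n, t in tissues.items()},
        "noise_sd": spec.noise_sd,
        "noise_model": spec.noise_model,
        "seed": spec.seed,
    }
    return SyntheticImage(data, geom, provenance)


def roi_stats(
    img: SyntheticImage,
    rois: Mapping[str, Region | np.ndarray],
    slices: Sequence[int] | None = None,
) -> RoiStats:
    """Per-slice mean and SD in each ROI (circle/ellipse region or boolean mask).

    ``slices`` are 0-based indices (default: all); the output table reports
    1-based slice numbers.
    """
    geom = img.geometry
    if slices is None:
        slices = range(img.n_slices)
    rows = []
    for label, roi in rois.items():
        mask = roi if isinstance(roi, np.ndarray) else _ellipse_mask(geom, roi)
        if mask.shape != img.data.shape[1:]:
            raise ValueError(
                f"roi {label!r} mask shape {mask.shape} does not match image "
                f"plane {img.data.shape[1:]}"
            )
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError(f"roi {label!r} is empty")
        for k in slices:
            if not 0 <= k < img.n_slices:
                raise IndexError(f"slice index {k} out of range [0, {img.n_slices})")
            values = img.data[k][mask]
            rows.append({
                "roi": label,
                "slice": k + 1,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if n_vox > 1 else 0.0,
                "n_voxels": n_vox,
            })
    return RoiStats(pd.DataFrame(rows))


def measured_cnr(stats: RoiStats, roi_a: str, roi_b: str) -> CnrMeasurement:
    """Image-based CNR: slice-averaged difference of ROI means.

    The per-slice CNR is mean_A − mean_B on each slice; the reported value is
    its average across slices, with the cross-slice CV (percent) as the
    repeatability measure.
    """
    per_slice = stats.slice_means(roi_a) - stats.slice_means(roi_b)
    value = float(np.mean(per_slice))
    if value == 0.0:
        cv = None
    else:
        cv = float(100.0 * np.std(per_slice, ddof=1) / abs(value)) if per_slice.size > 1 else 0.0
    return CnrMeasurement(value, tuple(float(v) for v in per_slice), cv)


def write_nifti(img: SyntheticImage, path: str | Path) -> None:
    """Write the stack as NIfTI with voxel sizes from the geometry (mm)."""
    import nibabel as nib

    geom = img.geometry
    # (x, y, slice) voxel order for NIfTI
    vol = np.transpose(img.data, (2, 1, 0)).astype(np.float32)
    affine = np.diag([
        geom.fov_x_mm / geom.n_fe,
        geom.fov_y_mm / geom.n_pe,
        geom.dz_mm,
        1.0,
    ])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
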