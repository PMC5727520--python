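"""Anatomical-resolution heatmaps and hemisphere ROI statistics.

CSI-resolution maps are interpolated bilinearly to the anatomical matrix,
with the CSI field of view (24 mm) embedded at its true physical position
inside the anatomical field of view (30 mm); both grids share the gradient
isocenter.  ROI summaries are arithmetic means over quality-masked voxels,
and the injured hemisphere is normalized to the contralateral one as a
percent change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fitting import RatioMap


@dataclass(frozen=True)
class ROIResult:
    """Mean ratio over one region of interest."""

    roi_name: str
    mean_ratio: float
    voxel_count: int
    animal_id: str | None = None
    timepoint_label: str | None = None

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


def _voxel_centers_mm(n: int, fov_mm: float) -> np.ndarray:
    """Physical voxel-center coordinates, isocenter at 0."""
    pitch = fov_mm / n
    return (np.arange(n) + 0.5) * pitch - fov_mm / 2.0


def interpolate_heatmap(
    values: np.ndarray | RatioMap,
    source_fov_mm: float,
    target_shape: tuple[int, int],
    target_fov_mm: float,
) -> np.ndarray:
    """Bilinear interpolation of a CSI-grid map onto the anatomical grid.

    Masked (NaN) source voxels propagate: any target pixel whose bilinear
    stencil touches a masked voxel is NaN, and pixels outside the CSI
    footprint are NaN as well.
    """
    if isinstance(values, RatioMap):
        values = values.ratio
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2D map")
    if not (source_fov_mm > 0 and target_fov_mm > 0):
        raise ValueError("fields of view must be positive")
    if target_fov_mm < source_fov_mm:
        raise ValueError("anatomical FOV must contain the CSI FOV")
    if target_shape[0] < values.shape[0] or target_shape[1] < values.shape[1]:
        raise ValueError("target shape must be at least the source shape")

    src_r = _voxel_centers_mm(values.shape[0], source_fov_mm)
    src_c = _voxel_centers_mm(values.shape[1], source_fov_mm)
    interp = RegularGridInterpolator(
        (src_r, src_c), values, method="linear", bounds_error=False, fill_value=np.nan
    )
    tgt_r = _voxel_centers_mm(target_shape[0], target_fov_mm)
    tgt_c = _voxel_centers_mm(target_shape[1], target_fov_mm)
    rr, cc = np.meshgrid(tgt_r, tgt_c, indexing="ij")
    return interp(np.stack([rr.ravel(), cc.ravel()], axis=-1)).reshape(target_shape)


def roi_mean(
    ratio_map: RatioMap,
    roi_mask: np.ndarray,
    name: str,
    animal_id: str | None = None,
    timepoint_label: str | None = None,
) -> ROIResult:
    """Arithmetic mean ratio over ``roi_mask AND quality_mask``."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != ratio_map.ratio.shape:
        raise ValueError("ROI mask shape does not match the ratio map")
    effective = roi_mask & ratio_map.quality_mask
    count = int(effective.sum())
    if count == 0:
        raise ValueError(f"ROI {name!r} contains no quality-masked voxels")
    return ROIResult(
        roi_name=name,
        mean_ratio=float(ratio_map.ratio[effective].mean()),
        voxel_count=count,
        animal_id=animal_id,
        timepoint_label=timepoint_label,
    )


def percent_of_contralateral(injured: ROIResult, contralateral: ROIResult) -> float:
    """100 * (injured - contralateral) / contralateral."""
    if not contralateral.mean_ratio > 0:
        raise ValueError(
            f"contralateral mean must be positive, got {contralateral.mean_ratio!r}"
        )
    return 100.0 * (injured.mean_ratio - contralateral.mean_ratio) / contralateral.mean_ratio


def downsample_mask_majority(
    anat_mask: np.ndarray,
    anat_fov_mm: float,
    csi_shape: tuple[int, int],
    csi_fov_mm: float,
) -> np.ndarray:
    """Transfer an anatomical-grid ROI mask to the CSI grid by majority vote.

    Each CSI voxel becomes True when more than half of the anatomical pixels
    whose centers fall inside its physical footprint belong to the ROI.
    Both grids are concentric (shared isocenter).
    """
    anat_mask = np.asarray(anat_mask, dtype=bool)
    if anat_fov_mm < csi_fov_mm:
        raise ValueError("anatomical FOV must contain the CSI FOV")
    ar = _voxel_centers_mm(anat_mask.shape[0], anat_fov_mm)
    ac = _voxel_centers_mm(anat_mask.shape[1], anat_fov_mm)
    pitch_r = csi_fov_mm / csi_shape[0]
    pitch_c = csi_fov_mm / csi_shape[1]
    idx_r = np.floor((ar + csi_fov_mm / 2.0) / pitch_r).astype(int)
    idx_c = np.floor((ac + csi_fov_mm / 2.0) / pitch_c).astype(int)
    ok_r = (idx_r >= 0) & (idx_r < csi_shape[0])
    ok_c = (idx_c >= 0) & (idx_c < csi_shape[1])

    inside = np.zeros(csi_shape, dtype=np.int64)
    hits = np.zeros(csi_shape, dtype=np.int64)
    rr = idx_r[ok_r][:, None]
    cc = idx_c[ok_c][None, :]
    sub = anat_mask[np.ix_(ok_r, ok_c)]
    np.add.at(inside, (np.broadcast_to(rr, sub.shape), np.broadcast_to(cc, sub.shape)), 1)
    np.add.at(hits, (np.broadcast_to(rr, sub.shape), np.broadcast_to(cc, sub.shape)), sub.astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = hits / inside
    return np.nan_to_num(frac, nan=0.0) > 0.5
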