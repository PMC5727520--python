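"""Digital tissue phantoms emulating a focal cortical contusion.

The phantom lives on the acquired CSI voxel grid (default 8x8 over a 24 mm
field of view): a centered brain disk split into left (contralateral) and
right (injured-side) hemispheres, with an optional circular lesion in the
right cortex whose pyruvate->lactate exchange rate is elevated.  A matched
set of anatomical labels (lesion / cavity / ventricle) is generated on a
256x256 grid over a 30 mm field of view for volumetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .kinetics import KineticParams

# label-grid classes
BACKGROUND = 0
TISSUE = 1
INJURED = 2
LESION_CORE = 3
TISSUE_CLASSES = (TISSUE, INJURED, LESION_CORE)

# anatomical-grid classes
ANAT_OTHER = 0
ANAT_LESION = 1
ANAT_CAVITY = 2
ANAT_VENTRICLE = 3
ANAT_LABELS: Mapping[int, str] = {
    ANAT_OTHER: "other",
    ANAT_LESION: "lesion",
    ANAT_CAVITY: "cavity",
    ANAT_VENTRICLE: "ventricle",
}

ANATOMICAL_MATRIX = 256
ANATOMICAL_FOV_MM = 30.0


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and kinetics of the injured region on the CSI grid.

    ``center_rc`` is in (row, col) voxel coordinates; ``radius_vox`` in
    voxels.  ``params`` holds the injured-tissue kinetics; if omitted the
    healthy parameters with kpl doubled are used.  ``core_radius_vox``
    optionally carves an inner lesion-core class with its own kinetics.
    """

    center_rc: tuple[float, float]
    radius_vox: float
    params: KineticParams | None = None
    core_radius_vox: float = 0.0
    core_params: KineticParams | None = None

    def __post_init__(self) -> None:
        if self.radius_vox < 0 or self.core_radius_vox < 0:
            raise ValueError("lesion radii must be >= 0")
        if self.core_radius_vox > self.radius_vox:
            raise ValueError("core radius cannot exceed lesion radius")


@dataclass(frozen=True)
class TissuePhantom:
    """Label grid + per-class kinetics + anatomical labels."""

    label_grid: np.ndarray
    params_by_class: Mapping[int, KineticParams]
    anatomical_labels: np.ndarray | None = None
    anatomical_fov_mm: float = ANATOMICAL_FOV_MM

    def __post_init__(self) -> None:
        labels = np.unique(self.label_grid)
        declared = {BACKGROUND, *TISSUE_CLASSES}
        unknown = set(labels.tolist()) - declared
        if unknown:
            raise ValueError(f"label grid contains undeclared classes: {sorted(unknown)}")
        missing = [int(c) for c in labels if c != BACKGROUND and c not in self.params_by_class]
        if missing:
            raise ValueError(f"no kinetic params for classes: {missing}")

    @property
    def grid_side(self) -> int:
        return self.label_grid.shape[0]

    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.label_grid, TISSUE_CLASSES)

    def hemisphere_masks(self, shape: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(injured-side, contralateral) tissue masks, optionally upsampled.

        The injured hemisphere is the right half (columns >= n/2).  When
        ``shape`` is an integer multiple of the phantom grid the labels are
        block-replicated before splitting, matching a zero-filled grid.
        """
        labels = self.upsampled_labels(shape)
        tissue = np.isin(labels, TISSUE_CLASSES)
        n_cols = labels.shape[1]
        cols = np.arange(n_cols)[None, :]
        injured = tissue & (cols >= n_cols // 2)
        contra = tissue & (cols < n_cols // 2)
        return injured, contra

    def upsampled_labels(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        if shape is None or tuple(shape) == self.label_grid.shape:
            return self.label_grid
        fy, rem_y = divmod(shape[0], self.label_grid.shape[0])
        fx, rem_x = divmod(shape[1], self.label_grid.shape[1])
        if rem_y or rem_x or fy < 1 or fx < 1:
            raise ValueError(f"{shape} is not an integer upsampling of {self.label_grid.shape}")
        return np.kron(self.label_grid, np.ones((fy, fx), dtype=self.label_grid.dtype))

    def ratio_truth_grid(
        self, config, shape: tuple[int, int] | None = None
    ) -> np.ndarray:
        """Per-voxel ground-truth time-summed lactate-to-pyruvate ratio."""
        from .kinetics import time_summed_ratio

        labels = self.upsampled_labels(shape)
        out = np.full(labels.shape, np.nan)
        for cls, params in self.params_by_class.items():
            if np.any(labels == cls):
                out[labels == cls] = time_summed_ratio(params, config)
        return out


def disk_mask(shape: tuple[int, int], center_rc: tuple[float, float], radius: float) -> np.ndarray:
    """Voxel-center-inside-circle membership (strict radius comparison)."""
    rr, cc = np.indices(shape)
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 < radius**2


def make_phantom(
    grid_side: int = 8,
    lesion: LesionSpec | None = None,
    base_params: KineticParams | None = None,
    seed: int = 0,
    kpl_jitter_rel: float = 0.0,
    brain_radius_frac: float = 0.42,
    with_anatomy: bool = True,
) -> TissuePhantom:
    """Build a hemispherically symmetric brain phantom with an optional lesion.

    ``kpl_jitter_rel`` applies one log-normal factor (seeded) to the kpl of
    every tissue class, emulating between-animal physiological variation
    without breaking within-animal hemisphere symmetry.  Deterministic for a
    fixed seed.
    """
    if grid_side < 4:
        raise ValueError("grid_side must be >= 4")
    base = base_params if base_params is not None else KineticParams()
    center = (grid_side - 1) / 2.0
    brain = disk_mask((grid_side, grid_side), (center, center), brain_radius_frac * grid_side)
    labels = np.where(brain, TISSUE, BACKGROUND).astype(np.int64)

    rng = np.random.default_rng(seed)
    jitter = float(np.exp(rng.normal(0.0, kpl_jitter_rel))) if kpl_jitter_rel > 0 else 1.0
    base = base.with_kpl(base.kpl_per_s * jitter)

    params_by_class: dict[int, KineticParams] = {TISSUE: base}
    lesion_mask = np.zeros_like(brain)
    core_mask = np.zeros_like(brain)
    if lesion is not None and lesion.radius_vox > 0:
        r0, c0 = lesion.center_rc
        if not (0 <= r0 <= grid_side - 1 and 0 <= c0 <= grid_side - 1):
            raise ValueError(f"lesion center {lesion.center_rc} outside the {grid_side}x{grid_side} grid")
        for coord in (r0, c0):
            if coord - lesion.radius_vox < -0.5 or coord + lesion.radius_vox > grid_side - 0.5:
                raise ValueError("lesion extends outside the grid")
        lesion_mask = disk_mask(labels.shape, lesion.center_rc, lesion.radius_vox) & brain
        injured_params = lesion.params
        if injured_params is None:
            injured_params = base.with_kpl(2.0 * base.kpl_per_s)
        else:
            injured_params = injured_params.with_kpl(injured_params.kpl_per_s * jitter)
        labels[lesion_mask] = INJURED
        params_by_class[INJURED] = injured_params
        if lesion.core_radius_vox > 0:
            core_mask = disk_mask(labels.shape, lesion.center_rc, lesion.core_radius_vox) & brain
            labels[core_mask] = LESION_CORE
            core_params = lesion.core_params if lesion.core_params is not None else injured_params
            params_by_class[LESION_CORE] = core_params

    n_cols = labels.shape[1]
    if not (np.isin(labels[:, : n_cols // 2], TISSUE_CLASSES).any()
            and np.isin(labels[:, n_cols // 2:], TISSUE_CLASSES).any()):
        raise ValueError("both hemispheres must contain tissue voxels")

    anat = _anatomical_labels(grid_side, lesion) if with_anatomy else None
    return TissuePhantom(label_grid=labels, params_by_class=params_by_class, anatomical_labels=anat)


def _anatomical_labels(grid_side: int, lesion: LesionSpec | None) -> np.ndarray:
    """256x256 anatomical label map geometrically matched to the CSI phantom.

    CSI voxel coordinates are mapped through the shared isocenter: both
    fields of view are concentric, the CSI FOV (24 mm) occupying the central
    block of the anatomical FOV (30 mm).
    """
    n = ANATOMICAL_MATRIX
    csi_fov = 24.0
    scale = (csi_fov / grid_side) / (ANATOMICAL_FOV_MM / n)  # anat pixels per CSI voxel

    anat = np.full((n, n), ANAT_OTHER, dtype=np.int64)
    center = (n - 1) / 2.0

    # ventricles: two small ellipses flanking the midline
    rr, cc = np.indices((n, n))
    for dx in (-0.35, +0.35):
        vx = center + dx * scale
        vy = center + 0.3 * scale
        anat[((rr - vy) / (0.5 * scale)) ** 2 + ((cc - vx) / (0.2 * scale)) ** 2 < 1.0] = ANAT_VENTRICLE

    if lesion is not None and lesion.radius_vox > 0:
        csi_center = (grid_side - 1) / 2.0
        ly = center + (lesion.center_rc[0] - csi_center) * scale
        lx = center + (lesion.center_rc[1] - csi_center) * scale
        lesion_px = disk_mask((n, n), (ly, lx), lesion.radius_vox * scale)
        anat[lesion_px] = ANAT_LESION
        cavity_px = disk_mask((n, n), (ly, lx), 0.45 * lesion.radius_vox * scale)
        anat[cavity_px] = ANAT_CAVITY
    return anat


def default_lesion(grid_side: int = 8, radius_vox: float = 1.3,
                   params: KineticParams | None = None) -> LesionSpec:
    """Lesion in the right cortex, mirroring a parietal contusion site."""
    return LesionSpec(
        center_rc=(0.3 * grid_side, 0.7 * grid_side),
        radius_vox=radius_vox,
        params=params,
    )
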