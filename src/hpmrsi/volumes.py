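"""Region volumetry from multi-slice anatomical label masks.

Volumes are exact voxel counts times the voxel volume, with the in-plane
pixel size derived from the anatomical field of view and matrix (default
30 mm / 256) and the slice thickness of the T2-weighted stack (default
0.5 mm).  Lesion shrinkage over time is reported as a percent decrease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VolumeGeometry:
    fov_mm: float = 30.0
    matrix: int = 256
    slice_thickness_mm: float = 0.5

    def __post_init__(self) -> None:
        if not (self.fov_mm > 0 and self.matrix > 0 and self.slice_thickness_mm > 0):
            raise ValueError("geometry values must be positive")

    @property
    def pixel_size_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_size_mm**2 * self.slice_thickness_mm


@dataclass(frozen=True)
class LabelVolumeReport:
    """Per-label voxel counts and volumes for one label stack."""

    counts: Mapping[str, int]
    volumes_mm3: Mapping[str, float]
    geometry: VolumeGeometry
    animal_id: str | None = None
    timepoint_label: str | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.counts),
                "voxel_count": list(self.counts.values()),
                "volume_mm3": [self.volumes_mm3[k] for k in self.counts],
                "animal_id": self.animal_id,
                "timepoint": self.timepoint_label,
            }
        )


def label_volume(
    label_stack: np.ndarray,
    geometry: VolumeGeometry,
    label_names: Mapping[int, str],
    background_label: int = 0,
    animal_id: str | None = None,
    timepoint_label: str | None = None,
) -> LabelVolumeReport:
    """Exact per-label volumetry of an integer label stack (slices x ny x nx).

    Every voxel value must be the background label or a declared label;
    undeclared values raise an error listing the offenders.
    """
    label_stack = np.asarray(label_stack)
    if label_stack.size == 0:
        raise ValueError("label stack is empty")
    if label_stack.ndim == 2:
        label_stack = label_stack[None]
    if label_stack.ndim != 3:
        raise ValueError("expected a (slices, ny, nx) stack")
    if not np.issubdtype(label_stack.dtype, np.integer):
        raise ValueError("label stack must be integer-valued")

    present = np.unique(label_stack)
    allowed = set(label_names) | {background_label}
    unknown = sorted(set(present.tolist()) - allowed)
    if unknown:
        raise ValueError(f"unknown labels present: {unknown}")

    counts: dict[str, int] = {}
    volumes: dict[str, float] = {}
    for value, name in label_names.items():
        n = int(np.count_nonzero(label_stack == value))
        counts[name] = n
        volumes[name] = n * geometry.voxel_volume_mm3
    return LabelVolumeReport(
        counts=counts,
        volumes_mm3=volumes,
        geometry=geometry,
        animal_id=animal_id,
        timepoint_label=timepoint_label,
    )


def percent_volume_change(v_later_mm3: float, v_earlier_mm3: float) -> float:
    """Percent decrease from the earlier to the later volume.

    Positive values mean shrinkage (the conventional reading of a lesion
    'decreasing by X%'); growth yields a negative decrease.
    """
    if v_earlier_mm3 <= 0:
        raise ValueError("earlier volume must be positive")
    return 100.0 * (v_earlier_mm3 - v_later_mm3) / v_earlier_mm3
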