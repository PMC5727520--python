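"""HDF5 / NIfTI / CSV serialization for the pipeline stages.

Raw dynamic CSI datasets travel as HDF5 (``/kspace`` complex array, the
acquisition parameters as attributes of ``/config`` and the generating
phantom, when present, under ``/phantom``).  Reconstructed summed spectra
use ``/summed_spectra`` + ``/frequency_axis``.  Maps and label masks use
NIfTI; ROI and volume summaries append to CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .kinetics import KineticParams
from .phantom import TissuePhantom
from .recon import VoxelSpectrumGrid
from .synth import DynamicCSIData

_CONFIG_SCALARS = (
    "te_s", "tr_s", "spectral_width_hz", "n_fid_points", "flip_angle_deg",
    "fov_mm", "n_phase_encodes", "slice_thickness_mm", "frame_period_s", "n_frames",
)
_PARAM_SCALARS = (
    "kpl_per_s", "r1p_per_s", "r1l_per_s", "bolus_start_s",
    "bolus_duration_s", "bolus_amplitude",
)


def save_csi_h5(path: str | Path, data: DynamicCSIData) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=data.kspace)
        cfg = h5.create_group("config")
        for name in _CONFIG_SCALARS:
            cfg.attrs[name] = getattr(data.config, name)
        cfg.attrs["larmor_offsets_hz"] = json.dumps(dict(data.config.larmor_offsets_hz))
        if data.ground_truth is not None:
            ph = h5.create_group("phantom")
            ph.create_dataset("labels", data=data.ground_truth.label_grid)
            if data.ground_truth.anatomical_labels is not None:
                ph.create_dataset("anatomical_labels", data=data.ground_truth.anatomical_labels)
                ph.attrs["anatomical_fov_mm"] = data.ground_truth.anatomical_fov_mm
            for cls, params in data.ground_truth.params_by_class.items():
                grp = ph.create_group(f"class_params/{cls}")
                for name in _PARAM_SCALARS:
                    grp.attrs[name] = getattr(params, name)
                grp.attrs["t2star_s"] = json.dumps(dict(params.t2star_s))


def load_csi_h5(path: str | Path) -> DynamicCSIData:
    with h5py.File(path, "r") as h5:
        kspace = h5["kspace"][()]
        attrs = dict(h5["config"].attrs)
        offsets = json.loads(attrs.pop("larmor_offsets_hz"))
        ints = {"n_fid_points", "n_phase_encodes", "n_frames"}
        kwargs = {k: (int(v) if k in ints else float(v)) for k, v in attrs.items()}
        config = AcquisitionConfig(larmor_offsets_hz=offsets, **kwargs)
        phantom = None
        if "phantom" in h5:
            ph = h5["phantom"]
            params_by_class = {}
            if "class_params" in ph:
                for cls in ph["class_params"]:
                    a = dict(ph[f"class_params/{cls}"].attrs)
                    t2 = json.loads(a.pop("t2star_s"))
                    params_by_class[int(cls)] = KineticParams(
                        t2star_s=t2, **{k: float(v) for k, v in a.items()}
                    )
            anat = ph["anatomical_labels"][()] if "anatomical_labels" in ph else None
            phantom = TissuePhantom(
                label_grid=ph["labels"][()],
                params_by_class=params_by_class,
                anatomical_labels=anat,
                anatomical_fov_mm=float(ph.attrs.get("anatomical_fov_mm", 30.0)),
            )
    return DynamicCSIData(kspace=kspace, config=config, ground_truth=phantom)


def save_summed_spectra_h5(path: str | Path, grid: VoxelSpectrumGrid) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("summed_spectra", data=grid.spectra)
        h5.create_dataset("frequency_axis", data=grid.frequency_axis_hz)
        h5.attrs["fov_mm"] = grid.fov_mm


def load_summed_spectra_h5(path: str | Path) -> VoxelSpectrumGrid:
    with h5py.File(path, "r") as h5:
        return VoxelSpectrumGrid(
            spectra=h5["summed_spectra"][()],
            frequency_axis_hz=h5["frequency_axis"][()],
            fov_mm=float(h5.attrs["fov_mm"]),
        )


def write_nifti(path: str | Path, array: np.ndarray, pixdim_mm: tuple[float, ...]) -> None:
    """Write a 2D/3D array as NIfTI with a diagonal affine of the pixel sizes."""
    arr = np.asarray(array)
    affine = np.eye(4)
    for i, p in enumerate(pixdim_mm[: min(3, arr.ndim)]):
        affine[i, i] = p
    nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def read_label_nifti(path: str | Path) -> np.ndarray:
    return np.rint(read_nifti(path)).astype(np.int64)


def append_roi_csv(path: str | Path, rows: pd.DataFrame) -> None:
    path = Path(path)
    header = not path.exists()
    rows.to_csv(path, mode="a", header=header, index=False)


def ratio_map_to_dataframe(ratio_map) -> pd.DataFrame:
    """Flatten a RatioMap to one row per voxel (row, col, ratio, AUCs, residual)."""
    rows = []
    ny, nx = ratio_map.ratio.shape
    for r in range(ny):
        for c in range(nx):
            pyr, lac = ratio_map.fits[r, c]
            rows.append({
                "row": r, "col": c,
                "ratio": ratio_map.ratio[r, c],
                "pyruvate_auc": ratio_map.pyruvate_auc[r, c],
                "lactate_auc": ratio_map.lactate_auc[r, c],
                "residual_norm": pyr.residual_norm,
                "converged": bool(pyr.converged and lac.converged),
            })
    return pd.DataFrame(rows)
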