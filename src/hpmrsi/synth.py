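"""Raw dynamic CSI k-space synthesis from a tissue phantom.

Each voxel's free induction decay (FID) is the sum over metabolites of
``amplitude * exp(2j*pi*offset*t) * exp(-t/T2*)`` with the amplitude given
by the frame-snapshot longitudinal magnetization times sin(flip angle).
Spatial encoding is the unitary, DC-centered 2D discrete Fourier transform
of the voxel-FID grid, applied independently per frame and FID point, with
i.i.d. complex Gaussian noise added to every k-space sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig
from .kinetics import frame_magnetization
from .phantom import TissuePhantom


@dataclass(frozen=True)
class DynamicCSIData:
    """Raw dynamic CSI k-space: (n_frames, ky, kx, n_fid_points)."""

    kspace: np.ndarray
    config: AcquisitionConfig
    ground_truth: TissuePhantom | None = None

    def __post_init__(self) -> None:
        expected = (
            self.config.n_frames,
            self.config.n_phase_encodes,
            self.config.n_phase_encodes,
            self.config.n_fid_points,
        )
        if self.kspace.shape != expected:
            raise ValueError(f"kspace shape {self.kspace.shape} != {expected} from config")
        if not np.iscomplexobj(self.kspace):
            raise ValueError("kspace must be complex")
        if not np.all(np.isfinite(self.kspace)):
            raise ValueError("kspace contains non-finite values")


def spatial_dft(image_grid: np.ndarray) -> np.ndarray:
    """Unitary DC-centered forward 2D spatial DFT over the first two axes."""
    shifted = np.fft.ifftshift(image_grid, axes=(0, 1))
    k = np.fft.fft2(shifted, axes=(0, 1), norm="ortho")
    return np.fft.fftshift(k, axes=(0, 1))


def spatial_idft(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`spatial_dft`."""
    shifted = np.fft.ifftshift(kspace, axes=(0, 1))
    img = np.fft.ifft2(shifted, axes=(0, 1), norm="ortho")
    return np.fft.fftshift(img, axes=(0, 1))


def voxel_fids(phantom: TissuePhantom, config: AcquisitionConfig) -> np.ndarray:
    """Noiseless per-voxel FIDs, shape (n_frames, ny, nx, n_fid_points)."""
    n = phantom.grid_side
    t = config.fid_times_s()
    sin_fa = np.sin(np.deg2rad(config.flip_angle_deg))
    out = np.zeros((config.n_frames, n, n, config.n_fid_points), dtype=np.complex128)
    for cls, params in phantom.params_by_class.items():
        mask = phantom.label_grid == cls
        if not mask.any():
            continue
        pyr, lac = frame_magnetization(params, config)
        amps = {"pyruvate": pyr, "lactate": lac}
        fid = np.zeros((config.n_frames, config.n_fid_points), dtype=np.complex128)
        for met, offset in config.larmor_offsets_hz.items():
            if met not in amps:
                continue
            basis = np.exp((2j * np.pi * offset - 1.0 / params.t2star_s[met]) * t)
            fid += sin_fa * amps[met][:, None] * basis[None, :]
        out[:, mask, :] += fid[:, None, :]
    return out


def synthesize_kspace(
    phantom: TissuePhantom,
    config: AcquisitionConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DynamicCSIData:
    """Encode the phantom into noisy dynamic CSI k-space.

    ``noise_sd`` is the standard deviation of the real and imaginary noise
    components added to every k-space sample; a single seed governs the
    whole dataset.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if phantom.grid_side != config.n_phase_encodes:
        raise ValueError(
            f"phantom grid {phantom.grid_side} != config n_phase_encodes {config.n_phase_encodes}"
        )
    fids = voxel_fids(phantom, config)
    kspace = np.empty_like(fids)
    for f in range(config.n_frames):
        kspace[f] = spatial_dft(fids[f])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        kspace = kspace + (
            rng.normal(0.0, noise_sd, kspace.shape)
            + 1j * rng.normal(0.0, noise_sd, kspace.shape)
        )
    return DynamicCSIData(kspace=kspace, config=config, ground_truth=phantom)


def noise_sd_for_snr(
    phantom: TissuePhantom,
    config: AcquisitionConfig,
    snr: float,
    reference: str = "lactate",
) -> float:
    """k-space noise sd giving a target peak SNR in the time-summed spectrum.

    SNR is defined as the tallest noiseless peak magnitude of the reference
    metabolite across voxels of the time-summed spectrum divided by the
    per-component noise sd of that summed spectrum.  The default reference
    is lactate — the weaker resonance whose uncertainty limits the ratio —
    so "SNR 20" means the quantified lactate peak stands 20 noise sd tall;
    pass ``reference="pyruvate"`` to anchor on the injected substrate
    instead.  Both the spatial and spectral transforms are unitary, so
    k-space noise of sd ``sigma`` stays sd ``sigma`` per voxel-spectrum
    sample and grows by sqrt(n_frames) when frames are summed.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if reference not in config.larmor_offsets_hz:
        raise ValueError(f"unknown reference metabolite {reference!r}")
    from .recon import reconstruct, sum_over_time

    clean = synthesize_kspace(phantom, config, noise_sd=0.0)
    frames = reconstruct(clean, zero_fill=False)
    summed = sum_over_time(frames)
    axis = summed.frequency_axis_hz
    offset = config.larmor_offsets_hz[reference]
    window = np.abs(axis - offset) <= 300.0
    peak = float(np.abs(summed.spectra[..., window]).max())
    return peak / (snr * np.sqrt(config.n_frames))
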