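# hpmrsi

Quantification pipeline for hyperpolarized [1-¹³C] pyruvate MRSI of the
injured mouse brain: from raw dynamic 2D chemical shift imaging (CSI)
k-space to Lorentzian-fit lactate-to-pyruvate AUC ratio maps, hemisphere
ROI statistics, anatomical lesion volumetry and the group-comparison ANOVA
layer — together with a synthetic-data module that emulates the in vivo
acquisitions with known ground-truth kinetics, so every stage is testable
without animal data.

## Who this is for

Preclinical imaging groups using hyperpolarized ¹³C MRSI to monitor
cerebral energy metabolism — e.g. after traumatic brain injury, where the
injured cortex shows an elevated lactate-to-pyruvate ratio relative to the
contralateral hemisphere — and anyone who needs a reproducible, testable
reference implementation of the standard CSI → ratio-map → ROI → ANOVA
processing chain.

## The model

**Exchange kinetics.** The longitudinal magnetization of the injected
pyruvate pool *P* and its exchange product lactate *L* follows
unidirectional two-site exchange with relaxation and a bolus input *u(t)*:

    dP/dt = u(t) − (k_PL + R1P)·P
    dL/dt = k_PL·P − R1L·L

with each RF excitation depleting both pools by cos(α). The apparent
conversion rate k_PL is the biological quantity of interest: lactate
dehydrogenase-mediated label exchange rises when pyruvate dehydrogenase
activity falls.

**Acquisition.** Dynamic 2D CSI on an 8×8 phase-encode grid (24 mm FOV,
5 mm slice), TE/TR = 1.2/60 ms, 2500 Hz spectral width over 128 FID
points, 10° flip angle, one frame every 4 s for ~1 minute.

**Quantification.** k-space is zero-filled to 16×16, inverse Fourier
transformed, spectra are summed over time, and each voxel's pyruvate and
lactate resonances are fitted with Lorentzians
A / (1 + (2(f−f₀)/w)²), whose analytic area is AUC = A·π·(w/2). The
per-voxel lactate-to-pyruvate ratio is the AUC ratio; hemisphere ROIs are
reported as the mean over quality-masked voxels and the injured side as a
percent change of the contralateral:

    %change = 100 · (mean_injured − mean_contralateral) / mean_contralateral

Group tables feed two-way (hemisphere × time), one-way and
repeated-measures ANOVA with Tukey HSD correction.

## Worked example

Simulate one "animal" whose lesion elevates the injured-hemisphere ratio
by a programmed +40%, acquire at lactate-peak SNR 20, and quantify:

```python
import hpmrsi as hp
from hpmrsi.cohort import lesion_for_hemisphere_elevation, quantify_phantom

config = hp.AcquisitionConfig()
base = hp.KineticParams(kpl_per_s=0.02)
lesion = lesion_for_hemisphere_elevation(config, base, elevation_pct=40.0)
phantom = hp.make_phantom(grid_side=8, lesion=lesion, base_params=base)
noise_sd = hp.noise_sd_for_snr(phantom, config, snr=20.0)
res = quantify_phantom(phantom, config, noise_sd, seed=1)
print(f"lesion kpl          : {lesion.params.kpl_per_s:.4f} 1/s (tissue {base.kpl_per_s:.4f})")
print(f"injured hemisphere  : mean ratio {res.injured.mean_ratio:.4f} over {res.injured.voxel_count} voxels")
print(f"contralateral       : mean ratio {res.contralateral.mean_ratio:.4f} over {res.contralateral.voxel_count} voxels")
print(f"percent change      : {res.percent_change:+.1f}%  (ground truth {res.truth_percent_change:+.1f}%)")
```

prints

```
lesion kpl          : 0.0515 1/s (tissue 0.0200)
injured hemisphere  : mean ratio 0.1085 over 16 voxels
contralateral       : mean ratio 0.0744 over 16 voxels
percent change      : +45.9%  (ground truth +40.0%)
```

The lesion's k_PL (0.0515 s⁻¹) was solved so that the *hemisphere-mean*
ratio truth is +40% over contralateral; the single-animal pipeline
estimate (+45.9% at this noise seed) scatters around it, and a ten-animal
cohort mean recovers the programmed elevation to within a couple of
percentage points. Averaged over a cohort this mirrors the in vivo
observation of a 30–40% ratio elevation in the injured hemisphere.

There is also a CLI for shell use:

```bash
hpmrsi simulate --seed 1 --noise-sd 0.01 --out data.h5
hpmrsi reconstruct --in data.h5 --out recon.h5
hpmrsi quantify --in recon.h5 --out ratio.nii --csv fits.csv
hpmrsi stats --in roi.csv --design "hemisphere*time"
```

## Layout

| module | role |
|---|---|
| `hpmrsi.config` | acquisition geometry and sequence timing |
| `hpmrsi.kinetics` | two-site exchange simulation, ground-truth ratios |
| `hpmrsi.phantom` | lesion/brain phantoms + matched anatomical labels |
| `hpmrsi.synth` | FID synthesis, spatial Fourier encoding, noise |
| `hpmrsi.recon` | zero-fill, spatial/spectral transforms, time sum |
| `hpmrsi.fitting` | Lorentzian fits, AUC ratio maps, quality masking |
| `hpmrsi.roi` | heatmap interpolation, ROI means, % of contralateral |
| `hpmrsi.volumes` | label-mask volumetry (lesion / cavity / ventricles) |
| `hpmrsi.stats` | ANOVA (two-way / one-way / repeated), Tukey HSD, t-test |
| `hpmrsi.cohort` | end-to-end cohort helpers and table generators |
| `hpmrsi.io`, `hpmrsi.cli` | HDF5 / NIfTI / CSV serialization, CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
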