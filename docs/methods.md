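# Methods

This note documents the models, conventions and numerical choices behind
`hpmrsi`, what the synthetic data do and do not emulate, and the design
decisions made where the problem was genuinely open.

## Two-site exchange simulation

Pyruvate and lactate longitudinal magnetization follow

    dP/dt = u(t) − (k_PL + R1P)·P
    dL/dt = k_PL·P − R1L·L

with a rectangular bolus u(t) of unit-height polarization delivered over
12 s from t = 0 (matching a slow intravenous injection), and every RF
excitation multiplying both pools by cos(α). Because the input is
piecewise constant, the system is propagated between events with its
exact analytic solution (expm1-based, including the degenerate
equal-rates limit) rather than a numerical integrator; tests verify
agreement with an independently coded matrix-exponential solution to
better than 1e−8 relative.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `kpl_per_s` (healthy tissue) | 0.02 s⁻¹ | literature-scale apparent conversion in normal brain |
| `r1p_per_s`, `r1l_per_s` | 1/30, 1/25 s⁻¹ | typical T1 of carbonyl ¹³C at high field |
| `t2star_s` | 1/(π·40) s | gives a 40 Hz FWHM linewidth, typical in vivo |
| `bolus_duration_s` | 12 s | injection duration |
| flip angle / TR / frames | 10° / 60 ms / 16 × 4 s | the dynamic CSI protocol (~1 min coverage) |

The acquisition's Methods-level frame period (4 s) is used rather than
the discussion-level 3 s figure; `frame_period_s` is configurable.

**Frame snapshot idealization.** All 64 phase encodes of a frame share
the magnetization at frame start; the cumulative depletion of the encode
train, cos(α)^64 (≈0.375 at 10°), is applied between frames. This keeps
spatial encoding separable (every k-space sample of a frame sees the same
voxel amplitudes) and makes the reconstruction exactly invertible, at the
cost of ignoring intra-frame signal decay. `simulate_dynamics` also
exposes the per-excitation trajectory for kinetic work.

## Phantoms

The phantom is a centered brain disk on the acquired 8×8 grid, split at
the midline into contralateral (left) and injured (right) hemispheres,
with a circular lesion in the right cortex whose k_PL is elevated.
Voxel-center-in-circle membership defines all regions, so region sizes
are exactly enumerable. A matched 256×256 anatomical label map (lesion,
cavity, ventricles; 30 mm FOV, concentric with the CSI FOV) supports the
volumetry stage. Optional per-animal log-normal jitter on k_PL emulates
between-animal physiological variation without breaking within-animal
hemisphere symmetry.

`cohort.lesion_for_hemisphere_elevation` solves (by bisection on the
noiseless ground truth) for the lesion k_PL that elevates the
*hemisphere-mean* time-summed ratio by a programmed percentage — the
lesion occupies only part of the hemisphere, so its voxel-level elevation
is correspondingly larger. This makes the programmed elevation an exact
ground truth for end-to-end recovery tests.

## Signal synthesis and noise

Each voxel's FID is Σ_m A_m·exp(2πi·f_m·t − t/T2*_m) with A_m =
sin(α)·M_z at frame start; pyruvate and lactate sit at ∓920 Hz about the
carrier (≈12.2 ppm apart at 14.1 T, both inside the 2500 Hz bandwidth —
the offsets are a package convention, configurable). Spatial encoding is
the unitary, DC-centered 2D DFT per frame and FID point. Noise is i.i.d.
complex Gaussian in k-space with one seed per dataset.

**SNR convention.** The in vivo noise level is not anchored anywhere, so
the package defines it: `noise_sd_for_snr` references the *lactate* peak
— the weaker resonance whose uncertainty limits the ratio — of the
time-summed spectrum (tallest voxel), with the noise sd of that summed
spectrum in the denominator. "SNR 20" therefore means the quantified
lactate peak stands 20 sd above the noise; the corresponding pyruvate SNR
is an order of magnitude higher, consistent with in vivo data where
pyruvate is never the limiting signal. A pyruvate-referenced definition
is available via `reference="pyruvate"`.

## Reconstruction conventions

- DC-centered (fftshift) k-space ordering; unitary scaling for both the
  spatial and spectral transforms, so Parseval's identity holds exactly
  and noise statistics are preserved stage to stage.
- Zero-fill embeds the 8×8 frame as the centered block of the 16×16 grid
  (DC sample preserved; for even sizes the split is symmetric). The
  zero-filled k-space is rescaled by the enlargement factor so that
  interpolated voxel amplitudes stay on the acquired-grid scale.
- Spectra are obtained by FFT along the FID dimension with fftshift, so
  the frequency axis is monotone over ±spectral_width/2.
- No apodization, line broadening, partial-Fourier handling or drift
  correction. Frames are summed complex by default (the synthesized FIDs
  are phase-coherent); magnitude summation is available behind a flag.

## Spectral fitting

Each resonance is fitted inside its own ±300 Hz window with a Lorentzian
A/(1 + (2(f−f₀)/w)²) plus a *window-local* constant baseline, by bounded
trust-region least squares with analytic Jacobians (centers bounded
inside the window, widths in [one bin, window width], amplitudes ≥ 0;
initialization from the window maximum). The analytic AUC is A·π·(w/2).

Two deliberate choices depart from the most obvious design, both because
the obvious design measurably fails at realistic signal levels:

1. **Phased real-part spectra, not magnitude.** The synthesized FIDs
   start at phase zero, so after a per-voxel zero-order phase correction
   (taken from the pyruvate peak) the real part is absorption-mode and
   exactly Lorentzian. Magnitude spectra are not: the magnitude lineshape
   is √3 wider, the discrete pyruvate resonance leaves a broad tail
   across the lactate window comparable to the lactate peak itself
   (ratio ≈ 0.08 in healthy tissue), and the Rician noise floor biases
   the weak lactate peak upward. Fitting magnitude spectra biased voxel
   ratios several-fold low in noiseless tests; fitting phased real parts
   recovers them to well under 5%. `mode="magnitude"` is retained.
2. **Shared-lineshape lactate estimate.** At in vivo lactate SNR a freely
   fitted amplitude×width product has large variance. Both resonances
   share the local field inhomogeneity, so `ratio_map` by default locks
   the lactate center to the pyruvate center plus the nominal separation
   and inherits the pyruvate width, leaving a linear amplitude+baseline
   solve. A negative amplitude is clipped to zero with the voxel kept
   (lactate may genuinely be absent; dropping such voxels would bias ROI
   means upward). `lactate_mode="free"` restores independent fits, which
   is also what `fit_lorentzian_pair` does.

**Quality mask.** Voxels are masked (NaN, never zero) when the fit fails
or the pyruvate AUC falls below a floor, defaulting to 5× the area of a
reference-linewidth Lorentzian whose height is the median out-of-window
background level. Voxels whose in-window maximum is below 3× their own
background are not fitted at all.

## ROI statistics and heatmaps

Hemisphere ROIs are means over (ROI ∧ quality-mask) voxels; the injured
hemisphere is normalized as 100·(injured−contralateral)/contralateral.
Anatomical-grid ROI masks transfer to the CSI grid by majority vote of
the anatomical pixels whose centers fall inside each CSI voxel. Heatmaps
are bilinear interpolations of the CSI-grid map onto the anatomical
matrix with both FOVs concentric (shared isocenter, no registration);
masked voxels and pixels outside the CSI footprint propagate as NaN.

**Quantification grid.** ROI statistics are computed on the acquired 8×8
grid by default. Zero-fill interpolation is kept for maps and display,
but forming voxel ratios *after* spatial interpolation passes the Gibbs
overshoot at the lesion boundary through a nonlinearity and biased the
recovered hemisphere elevation by ≈+3 percentage points in noiseless
tests; on acquired voxels the noiseless recovery is exact to <0.1 pp.

## Volumetry

Exact voxel counting: volume = count × (FOV/matrix)² × slice thickness
(defaults 30 mm / 256 / 0.5 mm — the anatomical T2-weighted protocol).
Binary labels, no partial-volume handling, no mesh smoothing; percent
volume change is signed so that shrinkage is positive.

## Statistics

Fixed-effects two-way ANOVA with interaction, one-way ANOVA, and a
repeated-measures ANOVA (subject as blocking factor; balanced panels
enforced; no sphericity correction — recorded in the result metadata).
Model fits delegate to statsmodels OLS/anova_lm; degenerate inputs
(zero-variance responses) are mapped to F = 0, p = 1 explicitly. Tukey
HSD uses the studentized range distribution with Tukey–Kramer standard
errors from the pooled within-group mean square; because adjusted and
unadjusted p share the same error term, adjusted ≥ unadjusted holds
structurally, and with two levels the adjustment degenerates to the
pooled t-test. The star convention is *p<0.05, **p<0.01, ***p<0.001,
****p<0.0001.

`cohort.simulate_ratio_table` generates table-level group data (animal
offsets ~N(0, 0.05), measurement error ~N(0, 0.03) on a contralateral
ratio of 0.4) sized so a ten-animal cohort shows standard errors of a few
percentage points on the percent-change scale, matching the magnitude of
in vivo ratio data.

## What the synthetic data do not emulate

No B0/B1 inhomogeneity, coil sensitivity structure, perfusion/vascular
compartment, chemical-shift displacement, motion, frequency drift or
non-Gaussian (structured) noise; bolus dispersion is rectangular unless
configured otherwise; lesions are circular and hemispheres perfectly
symmetric. Passing tests therefore demonstrate the correctness of the
processing chain and its statistical behavior under the stated model —
not robustness to in vivo artifacts, which would need measured data.

## Problem sizes used in tests

The default test-suite and acceptance-script workloads are desk-scale by
design: 8×8×128-point CSI frames × 16 time frames per animal, cohorts of
10 (injured-like) and 5 (sham-like) animals, 3–5 noise seeds for cohort
recovery, 1000 Monte-Carlo replicates for null calibration and 200 for
detection rates, and 100 randomized masks for volumetry exactness.
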