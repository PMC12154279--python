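# Methods

`hpcsi` simulates, reconstructs and quantifies 2-D phase-encoded FID-CSI
(free-induction-decay chemical shift imaging) of hyperpolarized
[1-¹³C]pyruvate in a small gyrencephalic brain, and runs the hemisphere and
group statistics used to detect an injury-related drop in oxidative pyruvate
metabolism.  Everything below is implemented in `src/hpcsi/` and exercised by
the test suite; no empirical number in this note comes from anywhere but the
package's own computations.

## Forward model

**Spectral species.** Four quantified resonances — pyruvate (171.0 ppm, the
carrier), lactate (183.2), alanine (176.5) and ¹³C-bicarbonate (161.1) — plus
an optional pyruvate-hydrate confounder (179.5 ppm, off by default). The
ppm↔Hz conversion uses f₀ = 32.13 MHz (¹³C at 3 T), so 1 ppm = 32.13 Hz. All
species default to T₂* = 16 ms (≈20 Hz Lorentzian linewidth); in vivo
linewidths of the carbonyl resonances are similar across species, and the
quantification exploits this by constraining weak-peak fits to the pyruvate
linewidth.

**Kinetics.** Unidirectional precursor–product exchange,

    dM_P/dt = u(t) − (r1_P + k_PL + k_PB + k_PA)·M_P
    dM_X/dt = k_PX·M_P − r1_X·M_X ,  X ∈ {L, B, A},

with apparent longitudinal rates r1 that lump T₁ with polarization loss
(defaults r1_P = 0.033 s⁻¹, products 0.04 s⁻¹).  The input u(t) is a
gamma-variate bolus (α = 4, β = 4 s, peak at 16 s) standing in for a ~25 s
hand injection.  The system is linear, so it is solved by an exact
exponential integrator with the input treated as piecewise linear between
samples — exact for the homogeneous decay and second-order accurate overall,
which the tests verify against the two-pool closed form at 10⁻⁶ relative.

**Phantom.** A labeled 16×16 map over a 60 mm field of view: an elliptical
brain (17×13 mm semi-axes) split at the midline into ipsi-/contralateral
hemispheres, a scalp-muscle ring, a two-voxel midline vessel, and (for
injured subjects) a 7 mm-radius lesion disc in the ipsilateral hemisphere.
Default rates (s⁻¹): brain k_PL = 0.021, k_PB = 0.0078, k_PA = 0.0018;
muscle 0.013 / 0.002 / 0.013; vessel converts nothing and carries 3× the
bolus (bright vascular pyruvate).  The lesion keeps glycolytic conversion
but has k_PB scaled by 0.5 (PDH/mitochondrial dysfunction).  These rates
were chosen once so that the *reconstructed* brain ratios land in the range
reported for anesthetized in vivo measurements (Lac/Pyr ≈ 0.2, Bic/Pyr ≈
0.07 on the contralateral side); the hemisphere *relative difference* they
produce (≈ −0.44) is a consequence of the 50% k_PB lesion and the geometry,
not a tuned quantity.

**Acquisition.** 16×16 phase encodes, concentric (center-out) ordering by
‖k‖ (ties by polar angle, then k_y) over a circularly reduced k-space
(‖k‖ ≤ matrix/2 inclusive on the half-open grid [−8, 8), k = 0 at index 8;
195 sampled encodes), uniformly spread over 16 s starting 30 s after bolus
start.  Each encode acquires 256 FID points at 5 kHz; the first 4 points
(0.8 ms at 0.2 ms dwell) are lost to the excitation–acquisition delay and
stored truncated with `n_missing` as metadata.  The variable flip angle
schedule θ_i = arctan(1/√(N−i)) keeps sin θ·Π cos θ constant, ending at 90°;
the signal at encode e is M(t_e)·sin θ_e·Π_{j<e} cos θ_j (hyperpolarized
magnetization is consumed, never recovered).  Spatial encoding is the exact
DFT of the compartment images; i.i.d. circular complex Gaussian noise
(per-component σ) is added to every stored sample of sampled encodes.
Raw-data SNR is defined as the peak magnitude of the k-space-center FID
(pyruvate-dominated) divided by σ; cohorts are calibrated to SNR 30.

## Reconstruction

Stages run in a fixed order: (1) spatial Hanning window
w = ½(1 + cos(π‖k‖/k_max)) over the sampled radius; (2) centered spatial
zero-fill ×2 (16×16 → 32×32); (3) per-encode backward linear prediction —
an order-8 anticausal autoregression fitted by least squares to the earliest
64 observed samples, with a ridge fallback (λ = 10⁻⁸·tr/p) and a warning
when the design is ill-conditioned — restoring the 4 missing points;
(4) Voigt apodization exp(−π·L·t)·exp(−(π·G·t)²/(4 ln 2)) with G = 25 Hz and
L = −5 Hz (each factor alone adds its FWHM; the negative Lorentzian narrows
lines by 5 Hz); (5) first-point ½-weighting (trapezoid correction, removing
the constant spectral baseline the strong pyruvate t = 0 sample would add to
every integration window); (6) spectral zero-fill ×8 (256 → 2048);
(7) centered unitary inverse spatial FFT and forward spectral FFT with the
frequency axis in Hz (fftshifted, increasing) and ppm.  The spatial
transform is applied before the spectral zero-fill — bit-identical to the
opposite order, since appended zero time-slices transform to zeros — to
avoid transforming 8× more data.  Zero-order phasing is per voxel: the
phase of the complex integral over a 44 Hz window at the pyruvate reference
(which maximizes the real-part integral); voxels whose reference amplitude
is below 5× the spectral noise level inherit the nearest confident voxel's
phase, so noise never drives a phase estimate.

## Quantification

Metabolite maps integrate the real (absorption-mode) spectrum over 44 Hz
windows (bin centers within ±22 Hz) around each resonance.  Peak centers
are referenced globally — pyruvate located in the maximum-SNR voxel, all
other centers fixed at their chemical-shift offsets — because per-voxel
searches fail for low-SNR bicarbonate.  Ratio maps (Lac/Pyr, Bic/Pyr,
Bic/Lac, Ala/Pyr) are masked to the brain; voxels whose denominator falls
below a floor (default 3× the robust background SD of the denominator map)
are undefined (NaN), never zero.

ROI quantification averages the complex spectra over mirrored disc ROIs
placed at the lesion site and its contralateral reflection (plus the muscle
ring), then fits each peak with a Gaussian A·exp(−(f−c)²/2σ²) plus constant
baseline over a 120 Hz span — wider than the integration window so the
baseline is identifiable beside the ≈34 Hz processed linewidth.  The center
is bounded to ±30 Hz of the referenced position; weak peaks borrow the
pyruvate fit's σ (×[0.6, 1.5]) since the lineshape is
apodization-dominated.  Area = A·σ·√(2π); fits with A below 3× the spectral
noise SD are flagged rejected and their ratios propagate as NaN.  Muscle
alanine provides the per-subject internal reference for the X/Ala_muscle
normalizations.

## Statistics

Hemispheres are compared with two-sided paired t-tests; zero-variance
differences report p = 1 with a warning (statistic 0 when identical, ±∞
when the common difference is nonzero).  Hemisphere asymmetry is the
relative difference (ipsi − contra)/contra, averaged per subject within a
group (the ratio-of-means variant is also reported; the two coincide when
all subjects share a contra value).  Groups are compared on the
per-subject relative differences with an assumption gate at α = 0.05:
Shapiro–Wilk per group and Brown–Forsythe (median-centered Levene) across
groups; both passing selects one-way ANOVA, otherwise Kruskal–Wallis with
Dunn's tie-corrected rank post-hoc (unadjusted p, implemented for ≥2
groups).  No multiple-comparison correction is applied, matching the small
pre-planned comparison set.  Calibration: under the null the gated
procedure's type-I error is ≈0.05 (10⁴ repetitions, n = 5 per group), and
paired-t power matches the noncentral-t closed form within 2%.

## Problem sizes and verification

The default cohort is 4 naive + 5 injured subjects (the study's group
sizes); a full subject (synthesis → reconstruction → quantification) takes
well under a second, so the replicated recovery study uses 20 cohort seeds
× 10 subjects.  The recovery experiment compares the noisy-cohort mean
Bic/Pyr relative difference against the *forward-model ground truth*,
defined as the output of the identical deterministic pipeline at σ = 0
without inter-subject jitter — the acquisition point-spread function is
part of the forward model, so this is the estimand of the noisy cohorts.  A
kinetics-level (PSF-free) reference ratio is also computed; it is larger in
magnitude (≈ −0.51 vs ≈ −0.44) because the Hanning PSF mixes healthy
tissue into the lesion ROI.

## What the generator does and does not emulate

It emulates: compartmental exchange with a lesion-specific k_PB deficit,
bolus delivery and polarization decay, VFA magnetization consumption,
concentric circularly-reduced phase encoding, acquisition-delay FID
truncation, and receiver noise at a calibrated SNR.  It does not emulate:
B₀/B₁ inhomogeneity, bidirectional (Bloch–McConnell) exchange, arterial
dispersion or transit delays, 3-D slab effects, chemical-shift
displacement, motion, or coil sensitivity profiles.  Passing tests
therefore demonstrate the correctness and calibration of the processing
chain under these idealized physics — not robustness to field
inhomogeneity or motion in real acquisitions.

## Numerical choices and degenerate inputs

Double precision throughout; all randomness flows through explicit seeds
(cohorts draw subject seeds < 2³¹ from one generator).  All-zero FIDs skip
LP (extended with zeros); empty ROIs, overlapping integration windows,
non-monotone timebases, negative rates and mis-sized flip schedules raise
input errors; Gaussian-fit non-convergence yields a rejected row rather
than an exception.  Concentric ordering tie-breaks (angle, then k_y) and
the inclusive circular-mask radius are fixed so the encode-count
enumeration oracle is well defined.

## Known limitations

Single-time-point acquisition: rate constants are not fitted, only signal
ratios (k_PL/k_PB enter the generator, not the analysis).  The ratio
estimator inherits a small upward Jensen bias from noise in the denominator
at low bicarbonate SNR (visible as recovered rel-diff ≈ −0.38 vs truth
−0.44 at SNR 30, within the recovery tolerance).  ROIs are derived from the
phantom geometry rather than drawn on an anatomical image.  The two-animal
repeated-measures structure of a real study is not modelled; subjects are
independent.
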