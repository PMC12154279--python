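# hpcsi — hyperpolarized [1-¹³C]pyruvate FID-CSI simulation and analysis

Hyperpolarized [1-¹³C]pyruvate MRI measures brain energy metabolism in
vivo: injected pyruvate is converted to lactate (via LDH, reporting
glycolysis) and to ¹³C-bicarbonate (via pyruvate dehydrogenase, reporting
oxidative metabolism), and the ratio maps Bic/Pyr, Lac/Pyr and Bic/Lac
localize where each pathway dominates.  After a focal traumatic brain
injury, pyruvate-dehydrogenase flux falls at the injury site, so Bic/Pyr
drops in the ipsilateral hemisphere while Lac/Pyr can remain unchanged in
the subacute phase.

`hpcsi` is a tested, end-to-end pipeline for this experiment at the scale
of a small gyrencephalic (ferret-like) brain on a clinical 3 T system:

* **synthetic data** — a digital head phantom (brain hemispheres, focal
  lesion with reduced k_PB, scalp muscle, vessel), unidirectional
  pyruvate→lactate/bicarbonate/alanine exchange kinetics

      dM_P/dt = u(t) − (r1_P + k_PL + k_PB + k_PA)·M_P,
      dM_X/dt = k_PX·M_P − r1_X·M_X,

  and a 2-D phase-encoded FID-CSI acquisition (16×16 matrix, 60 mm FOV,
  256 points at 5 kHz, concentric circularly-reduced k-space, variable
  flip angles, 16 s) with hyperpolarized magnetization consumption,
  acquisition-delay FID truncation and calibrated complex Gaussian noise;
* **reconstruction** — spatial Hanning apodization, 2× spatial zero-fill,
  backward linear prediction of the missing FID points, Voigt apodization
  (25 Hz Gaussian / −5 Hz Lorentzian line narrowing), 8× spectral
  zero-fill, FFT to a 32×32 map of spectra, per-voxel zero-order phasing;
* **quantification** — absorption-mode 44 Hz window integration for
  metabolite maps, brain-masked ratio maps, and Gaussian peak fits of
  ROI-averaged spectra with muscle-alanine normalization;
* **statistics** — paired ipsi/contra t-tests, hemisphere relative
  differences (ipsi − contra)/contra, and assumption-gated
  (Shapiro–Wilk + Brown–Forsythe) ANOVA / Kruskal–Wallis + Dunn group
  comparisons.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end and print
what they find:

```bash
python analysis/01_simulate_cohort.py      # 4 naive + 5 injured subjects
python analysis/02_reconstruct.py
python analysis/03_quantify.py
python analysis/04_group_statistics.py
python analysis/05_recovery_and_calibration.py
```

Step 04 prints, for the default seed (20250923):

```
bic_pyr:
   injury: ipsi 0.039 +/- 0.005, contra 0.071 +/- 0.002, rel diff -0.441
    naive: ipsi 0.065 +/- 0.009, contra 0.070 +/- 0.006, rel diff -0.065
  paired naive: t = -0.55, p = 0.6198
  paired injury: t = -4.58, p = 0.0102
  group comparison (one-way ANOVA): p = 0.0305
```

Read: in injured subjects the bicarbonate-to-pyruvate ratio at the lesion
site (0.039) is roughly half the contralateral value (0.071) — the paired
test detects the asymmetry (p = 0.01) and the naive–injury comparison of
hemisphere relative differences is also significant — while the same
pipeline on naive subjects finds no asymmetry, and Lac/Pyr shows no
difference in either group.  That is exactly the dissociation expected
when a focal injury halves oxidative (PDH) flux but leaves glycolytic flux
intact.

The same stages are scriptable from a shell via the thin CLI
(`hpcsi simulate|recon|quantify|stats|run`), e.g.

```bash
hpcsi simulate --seed 3 --injured --out raw.h5
hpcsi recon --in raw.h5 --out spec.h5
hpcsi quantify --in spec.h5 --out quant.csv
```

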