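# physnoise

Physiological noise correction and characterization for high-field (7 T) EPI
time series.

At high static field the dominant contribution to fMRI time-series noise is
not thermal but *physiological*: cardiac pulsation, respiration, slow changes
in breathing depth and heart rate, and residual head motion all modulate the
signal in proportion to its amplitude. `physnoise` is aimed at fMRI
methodologists and physicists who want to (a) build the standard nuisance
regressor families from peripheral recordings and regress them out of EPI
data, and (b) quantify what the correction buys, both as temporal SNR and as
BOLD detection sensitivity.

## What it computes

**Nuisance regressors**, sampled at the reference slice of each volume:

- **CRP** — RETROICOR-style cardiac and respiratory phase Fourier sets
  (sin kφ, cos kφ up to the 3rd harmonic; 12 regressors). Cardiac phase is
  linear between detected heart beats; respiratory phase uses
  amplitude-histogram equalization of the belt signal signed by its slope.
- **RV** — the 6 s sliding-window standard deviation of the respiratory belt,
  convolved with a respiratory response function.
- **HR** — the inverse mean beat-to-beat interval over a 6 s window,
  convolved with a cardiac response function.
- **MP** — the six rigid-body motion parameters.
- **HW** — linear + quadratic drifts (or a 128 s discrete-cosine high-pass
  basis for activation analyses).

These combine into the 12 standard model combinations (model 1 = HW only,
model 6 = HW & CRP & RV & HR & MP, ...).

**The extended signal-dependent noise model.** With λ the fractional
amplitude of signal-proportional fluctuations and SNR₀ the image SNR,

    tSNR = SNR₀ / √(1 + λ² SNR₀²),

so 1/λ is the tSNR asymptote no increase in image SNR can beat. The image SNR
actually measured from no-excitation noise volumes with a multi-channel coil
is biased by channel covariance; writing SNR′₀ = κ·SNR₀,

    tSNR = SNR′₀ / √(κ² + λ² SNR′₀²).

`SnrModel.fit()` estimates (λ, κ) by Nelder–Mead least squares from
(SNR′₀, tSNR) pairs measured across a flip-angle series (spoiled steady state,
Ernst angle arccos e^(−TR/T1) ≈ 70° for gray matter at 7 T with T1 = 1.9 s,
TR = 2 s).

**Activation analysis.** Block design (left / fixation / right / fixation,
20 s blocks, five 80 s cycles), canonical double-gamma HRF, volume-wise
Gaussian smoothing, voxel-wise t-tests per condition, and significant-voxel
counts under family-wise error control (Bonferroni over in-brain voxels, or a
max-statistic permutation threshold).

**Synthetic data.** `simulate_physio` / `simulate_epi` generate peripheral
recordings and multi-flip-angle EPI with exactly the statistical structure
the model assumes — plus ground truth (true beats, injected regressors,
λ_true, κ_true, active mask) — so every step is testable without any scanner
data.

## Worked example

Characterize one synthetic subject across the flip-angle series
8°–70°, comparing no correction (model 1), cardio-respiratory phase
correction (model 2), and the full model (model 6):

```python
from physnoise import run_flip_angle_study

res = run_flip_angle_study(seed=1, model_ids=(1, 2, 6))
print(res.summary())
```

```
Flip-angle tSNR study, ROI VC
============================================
flip angles: [8.0, 16.0, 26.0, 38.0, 70.0]
SNR0' at 70 deg: 707.1

   model  tSNR(max)   1/lambda   kappa   dtSNR%
       1       94.7       97.5    1.76      0.0
       2      137.0      145.0    1.69     44.7
       6      162.3      175.3    1.63     71.4
```

Reading: uncorrected, the visual-cortex-like ROI saturates at a tSNR
asymptote 1/λ ≈ 98 even though the measured image SNR at 70° is ≈ 707 —
signal-dependent fluctuations, not thermal noise, limit the time series.
Correcting cardiac/respiratory phases alone (model 2) lifts the asymptote to
145; the full nuisance model raises the measured tSNR at 70° by 71%, and the
fitted κ ≈ 1.7 recovers the simulated miscalibration of the thermal-noise
measure. Per-fit details:

```python
print(res.fits[1].summary())
```

```
Extended tSNR-vs-SNR0' model fit
================================
n points:   5
lambda:     0.0102561
1/lambda:   97.5   (tSNR asymptote)
kappa:      1.763   (SNR0'/SNR0 scale factor)
SSE:        0.1305
converged:  True
```

A thin CLI wraps the same machinery: `physnoise simulate --seed 3 --out dir/`
writes a complete synthetic study (EPI + noise NIfTIs, physio TSV + sidecar,
motion, ROIs, ground truth), and `physnoise activation --config run.yaml
--out counts.tsv` runs the task GLM under several noise models and tabulates
significant-voxel counts.

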