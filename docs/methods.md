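# Methods

## Signal model and assumptions

A gradient-echo EPI voxel time series is modelled as

    y(v, t) = S(α) g(v) [1 + p(t) + m(v, t) + d(t) + u(v, t)] + ε(t)

with S(α) the spoiled steady-state signal at flip angle α
(S ∝ sin α (1 − E1)/(1 − E1 cos α), E1 = e^(−TR/T1)), g(v) a smooth coil/
tissue profile, p(t) shared cardio-respiratory fluctuations, m(v, t) a
motion-coupled term, d(t) a slow drift, u(v, t) signal-proportional
fluctuation that no nuisance regressor captures, and ε additive thermal
noise. Everything inside the brackets scales with the signal; this is the
structure under which temporal SNR obeys

    tSNR = SNR₀ / √(1 + λ² SNR₀²),      λ² = var(p + m + u),

and under which 1/λ is the attainable tSNR ceiling. Because a multi-channel
root-sum-of-squares reconstruction biases the thermal-noise estimate taken
from no-excitation volumes, the measured image SNR is SNR′₀ = κ SNR₀ and the
fitted curve is tSNR = SNR′₀/√(κ² + λ² SNR′₀²) — algebraically the same
relation with the measured abscissa.

Assumptions worth keeping in mind: noise is treated as Gaussian on magnitude
images (valid at the simulated SNRs, where the Rician/chi regime is
irrelevant); nuisance effects enter linearly and are removed by OLS; tSNR is
computed on the residualized series with the voxel mean restored.

## Nuisance regressors

- Cardiac phase: linear in time between consecutive detected beats,
  φ = 2π(t − t_k)/(t_{k+1} − t_k); outside the beat span the nearest interval
  is extrapolated and wrapped. The Fourier set [sin kφ, cos kφ], k = 1..3,
  makes the correction insensitive to a constant pulse-transit lag between
  finger and head (a pure phase shift); an explicit lag parameter is
  deliberately not fitted.
- Respiratory phase: the belt signal is resampled to 20 Hz (the slice
  frequency), its run-wide amplitude histogram (100 bins) defines a
  cumulative transfer H(b) ∈ [0,1], and φ = πH(b) on inhalation,
  2π − πH(b) on exhalation. Histogram equalization makes the phase
  distribution approximately uniform regardless of belt calibration, which
  is why the uncalibrated belt amplitude is used as-is.
- RV: 6 s sliding-window standard deviation (sample, N−1) of the belt,
  convolved with the respiratory response function
  RRF(t) = 0.6 t^2.1 e^(−t/1.6) − 0.0023 t^3.54 e^(−t/4.25);
  the kernel peaks near 3 s with a broad negative lobe near 15 s.
- HR: inverse mean beat-to-beat interval over a centred 6 s window (intervals
  intersecting the window; units s⁻¹), convolved with the cardiac response
  function CRF(t) = 0.6 t^2.7 e^(−t/1.6) − 16/√(18π) e^(−(t−12)²/18).
  Both kernels are sampled at 0.05 s over 60 s and are swappable inputs.
- Convolutions are causal with zero-padded history; the first kernel-length
  of the run is retained (the five discarded dummy volumes of a real
  acquisition cover part of this transient).
- Windows are truncated at run edges, never NaN-padded.
- Drift: centred linear and quadratic functions of image number, scaled to
  unit maximum for conditioning. For activation analyses a discrete-cosine
  high-pass basis (all components with period ≥ 128 s,
  floor(2·n·TR/cutoff) columns) replaces the drift pair, matching standard
  fMRI practice.

Model combinations 1–12 concatenate these families (1 = HW, 2 = HW & CRP,
3 = HW & RV & HR, 4 = HW & CRP & RV & HR, 5 = HW & MP, 6 = all, 7–12 the
single-family and motion variants); all designs are mean-centred and an
intercept is always added by the GLM, so SNR′₀ (a mean) is identical across
models.

## Fitting and statistics

- Voxel-wise OLS via pseudoinverse; rank-deficient designs are solved with a
  logged warning rather than an error (all-zero motion files are a real
  occurrence). Sample (N−1) standard deviations are used throughout so that
  tSNR and sum-of-squares definitions agree exactly in tests.
- Adjusted R²: R²adj = 1 − (SS_err/SS_tot)(df_tot/df_err), df_tot = n − 1,
  df_err = df_tot − p with p the design columns excluding the intercept.
  A "conservative" switch (df_err = df_tot − 1 − p) is provided because the
  printed definition in the source literature is ambiguous on this point.
- The (λ, κ) fit is Nelder–Mead on (log λ, log κ) — unconstrained search,
  positivity by construction — with xatol = fatol = 1e-9, a deterministic
  initialization (λ₀ = 1/max tSNR; κ₀ from the two lowest-SNR points, where
  the curve is near the thermal line SNR′₀/κ), and one restart from the
  optimum to re-expand the simplex. Fits are performed on ROI-mean
  (SNR′₀, tSNR) pairs per flip angle (five points); per-voxel fitting is
  possible but noisy and not the default. λ → 0 is reported as
  inv_lambda = +inf.
- Thermal noise is the per-voxel sample sd over the no-excitation volumes.
  Its reciprocal is slightly biased (E[1/σ̂] > 1/σ; about +4% at 20 volumes),
  which inflates SNR′₀ and is absorbed by κ exactly as channel covariance
  is — one more reason κ is a nuisance scale, not a physical constant. An
  optional multiplicative chi-correction factor is available but off by
  default.
- Activation: one-sided t-tests per condition (left > baseline,
  right > baseline) with a canonical double-gamma HRF (peak 6 s, undershoot
  16 s, ratio 1/6). Family-wise error is controlled by Bonferroni over
  in-brain voxels by default; a max-statistic permutation threshold
  (permuting task-regressor rows) is available. Random-field-theory
  correction is out of scope: on synthetic data the calibration properties,
  not field-theoretic thresholds, are the testable surface.
- The default brain mask is mean intensity above 10% of the robust (99.5th
  percentile) maximum; it is configurable since any in-brain voxel set
  changes Bonferroni thresholds.

## The synthetic generator

`simulate_physio` draws beat-to-beat intervals from a bounded random walk of
the heart rate (default 1.0 ± 0.05 s⁻¹), renders each beat as a pulse with a
one-sample systolic upstroke and exponential decay (so detected rising edges
align with true upstrokes to within one sample), a belt sinusoid with slowly
varying rate (1/3 ± 0.02 s⁻¹) and 20% depth modulation, and 2-sample slice
trigger pulses at 100 Hz. Recording starts 1 s before the first trigger;
t = 0 is the first retained volume's first slice trigger.

`simulate_epi` injects, at the reference-slice times: cardiac and
respiratory phase harmonics (random harmonic weights, total fractional sd
0.0055 and 0.0045), RV and HR components (0.0012, 0.0010), a motion term
(0.0055) built from orthonormalized true motion traces coupled to spatial
gradients — so it lies exactly in the span of the motion-parameter
regressors — and an unexplained signal-proportional white component
(1/160 = 0.00625) that sets the post-correction ceiling. Motion traces are
partially correlated with the belt (coupling 0.5), reproducing
respiration-coupled apparent motion. κ_true (default 1.7) is applied as a
multiplicative miscalibration of the stored thermal-noise scale rather than
by simulating 24 physical receive channels: it reproduces the identifiable
quantity (the SNR′₀ scale bias) at desk scale. Default grid 24×24×12 at
3 mm, 150 volumes, TR 2 s, flip angles 8°–70°, 20 noise volumes.

These amplitudes were chosen once so the uncorrected fitted asymptote lands
near the published ~90 regime (1/λ_true ≈ 90 by construction:
√(Σ amp²) ≈ 0.0111) and σ_thermal = 1.96 puts the ROI-mean SNR′₀ at 70°
near 700. They are synthetic design choices, not estimates of any subject.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: k-space/EPI artifacts (ghosting, distortion), B0
modulation by breathing (only its motion-trace signature is present),
spatially structured vascular noise, autocorrelated BOLD-like background
fluctuations, realignment interpolation effects (motion enters as a
first-order spatial-gradient modulation, not resampling — a resampling mode
would be slower and is not needed for the variance accounting tested here),
and Rician noise floors at very low SNR.

## Degenerate inputs and tie-breaks

Constant cardiac trace → "fewer than 2 beats" error; constant belt →
"respiratory phase undefined"; zero temporal sd → tSNR undefined (NaN),
excluded from ROI means and counted in logs; zero thermal sd → SNR′₀
undefined; reference count of zero significant voxels → percent difference
undefined (NaN), never a division error. Beat detection uses a threshold at
the 60th percentile of the amplitude range with a 0.25 s refractory period —
robust to dicrotic notches, parameters exposed. Triggers are edge-detected,
never level-detected, so pulse width is irrelevant down to 2 samples.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 24×24×12 grid with a 500-voxel VC-like ROI, 20 simulated subjects
for the flip-angle medians, 100 null simulations (22³ voxels, 200 volumes,
4 mm smoothing) for family-wise-error calibration, and 20 000 null voxels
for the type-I rate; the complete acceptance run takes well under a minute
of simulation plus calibration on a single core.

## Known limitations

- The respiratory-phase histogram transfer is run-wide; runs with drastic
  baseline shifts in belt tension would benefit from windowed equalization.
- The HR model inherits any finger-to-head pulse-transit lag (the phase
  model does not); no lag is fitted.
- ROI-mean curve fitting mixes voxels with different g(v); the mild
  convexity bias this induces in fitted 1/λ (a few percent) is visible in
  the recovery ratios the acceptance script reports.
- Bonferroni is conservative under smoothing; the permutation alternative is
  exact but costs n_perm GLM fits.
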