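# Methods

This note documents the models implemented in `nervedce`, the numerical
and design choices made where the underlying protocol left them open, and
what the synthetic validation does and does not demonstrate.

## Physical model of the measurement

The acquisition emulated throughout is a 3 T spoiled gradient-echo (VIBE)
protocol: a pre-contrast variable-flip-angle (VFA) block at
α ∈ {5°, 8°, 11°, 14°, 17°} with TR = 3.3 ms, followed by 50 dynamic
repetitions at α_R = 15° with the gadolinium bolus administered after
completion of the sixth repetition.  Dynamic frames are taken as
uniformly spaced; from a total acquisition time of 4:09 min over 50
repetitions, Δt = 249 s / 50 = 4.98 s.  All of these constants live in
one `AcquisitionProtocol` object that every physics stage reads.

### VFA T1 estimation

The spoiled-GRE steady state SI(α) = M0 sin α (1 − E1)/(1 − E1 cos α),
E1 = e^(−TR/T1), becomes linear under x = SI/tan α, y = SI/sin α with
slope m = E1, so T1,0 = −TR/log m.  Choices:

* **Unweighted OLS of y on x.**  The linearization correlates noise into
  both coordinates; weighting schemes exist but plain OLS is the standard
  VFA practice and is exact on noiseless data (recovered to ~1e−12
  relative).
* **Nominal angles, no B1+ correction.**  Transmit-field errors at thigh
  level bias T1 multiplicatively; with a transmit-receive extremity coil
  the effect is modest and no correction is modelled.
* **Validity window.**  Voxelwise estimates outside (0.05 s, 10 s) are
  flagged invalid and excluded from ROI aggregates — a guard against
  noise-driven slopes m ≥ 1 or m ≤ 0 (which raise on the ROI path).

### Concentration conversion

The enhancement factor Ca and the post-contrast rate 1/T1,t invert the
spoiled-GRE signal equation exactly; concentration is
C = (1/r1)(1/T1,t − 1/T1,0) with r1 = 3.43 L/mmol/s (blood at 3 T).
Choices:

* **SI_0 is the mean over all detected pre-bolus frames**, not a single
  frame: reduces baseline noise and matches the averaging used for bolus
  detection.
* **The same r1 is used for nerve tissue and artery.**  A tissue-specific
  relaxivity is not modelled; `Relaxivity` is a parameter wherever the
  conversion is invoked, so a different value is a one-argument change.
* **The arterial curve is converted to concentration** before kinetic
  modelling (unit consistency requires the AIF in mmol/L; feeding raw
  signal into the kinetic model would make K^trans unit-less nonsense).
* **Out-of-domain enhancement** ((1 − Ca) ≤ 0 or (1 − cos α_R · Ca) ≤ 0)
  marks single frames NaN/invalid rather than aborting the curve;
  invalid frames are excluded from fitting.  Rationale: an isolated noisy
  frame should not discard an ROI.

### Arterial input function

Artery-ROI voxels are averaged pointwise; bolus arrival is the first
frame k whose signal exceeds 1.25 × the mean of frames 0..k−1
(strict inequality — a rise of exactly 25% does not trigger); the frame
before it is the baseline end.  All indices are 0-based.  The converted
concentration curve is smoothed with a 3-point moving average.  Choices:

* **Centered window with shrinking edges** (output length preserved); a
  trailing window is available via `smooth_mode` for sensitivity checks.
* **Detection runs on the raw averaged signal**, before smoothing, and
  smoothing operates in the concentration domain.
* **Artery T1,0** comes from the subject's own VFA fit over the artery
  ROI by default; a literature constant (e.g. 1.4 s for blood at 3 T) can
  be passed instead.

**Smoothing bias.**  A 3-point moving average at Δt ≈ 5 s attenuates
curvature of order Δt²·|C″|/3.  With the dispersed femoral first pass
used by the simulator this is a ~1% RMSE perturbation of the AIF, but it
propagates nonlinearly into the kinetic fit: on noise-free simulations
the median parameter bias is below 10%, yet it can be large for tissues
whose interstitial volume approaches zero (poorly identifiable kinetics).
Because the filter exists solely to suppress measurement noise, the
estimator-chain exactness test disables it (`smooth_aif=False`), which
makes the noise-free pipeline recover every parameter to well below 2%;
the default pipeline keeps it on.

### Extended Tofts model

C_M(t) = K^trans ∫₀ᵗ AIF(t′) e^(−K^trans(t−t′)/v_e) dt′ + v_p AIF(t).

* **Quadrature.**  The convolution is evaluated on the acquisition grid
  by integrating the exponential kernel exactly against the
  piecewise-linear interpolant of the sampled AIF.  This is the scheme's
  natural refinement of the trapezoid rule (its kep → 0 limit): plain
  node-trapezoid quadrature errs by up to several percent of peak once
  kep = K^trans/v_e approaches the frame rate, whereas the exact-kernel
  form agrees with a 100×-refined reference to < 0.001% across the whole
  parameter range of interest and is no slower.
* **Optimization.**  Nelder–Mead on Σ_t [C_M(t) − C(t)]² over valid
  frames, started at K^trans = 0.007 s⁻¹, v_e = 0.15, v_p = 0.025.  The
  simplex moves in (log K^trans, logit v_e, logit v_p) so iterates cannot
  leave the physical domain on noisy curves; a raw-space mode
  (`transform=False`) is retained for fidelity comparisons and agrees on
  well-posed fits.  Simplex tolerances 1e−10 (parameters and objective),
  max 2000 iterations.
* **Units.**  Internal rates are s⁻¹ and fractions dimensionless;
  reporting properties convert to min⁻¹ and percent.  File columns carry
  units in their names (`ktrans_per_min`, `ve_pct`) to keep the two unit
  systems from mixing silently.
* **Fit plausibility window.**  Joined cohort tables flag fits with
  K^trans ≥ 0.3 min⁻¹, v_e ≥ 50% or v_p ≥ 30% as invalid
  (`fit_valid=False`), by analogy with the T1 validity window.  These
  arise when a tissue's v_e is so small that its kinetics are not
  resolvable at Δt ≈ 5 s: the objective then has a near-degenerate
  fast-exchange ridge (K^trans large, model ≈ (v_e+v_p)·AIF) onto which
  noise can move the global minimum.  This is a property of the inverse
  problem, not of the optimizer — restarts do not cure it — so such fits
  are excluded from statistics rather than "repaired".  At default
  simulation settings this excludes ~1 of 56 subjects per cohort.

## Cohort statistics

* Neuropathy grouping: DN iff NDS ≥ 3 (strict threshold at 3).
* Severity score: 1 if sural SNAP ≥ 5 µV; otherwise 2/3/4 for tibial
  CMAP ≥ 5 mV, ∈ [2, 5) mV, < 2 mV.  The published category bounds
  overlap at exactly 5 mV; the milder score (2) wins there.
* Normality gate: D'Agostino–Pearson omnibus test at α = 0.05 per group
  or marginal; groups below the test's minimum n (8) take the
  nonparametric branch with a warning.  All tests are two-sided.
* Gated paths: t vs Mann–Whitney (two groups); one-way ANOVA vs
  Kruskal–Wallis with Dunn pairwise z-tests, Bonferroni-adjusted over all
  pairs (three or more groups).
* Correlation: Pearson when both marginals pass the gate, else Spearman
  with p multiplied by the Bonferroni family size `m_tests` (capped at
  1).  The family size defaults to the number of rows in one biomarker
  column of the results table and is deliberately explicit — the choice
  of family is a reporting decision, not a property of the data.
* Partial correlation: correlation of OLS residuals after regressing
  each variable on the controls (age, BMI by default), p from
  t = r√((n−2−k)/(1−r²)) on n−2−k df.  This residual construction is
  checked in the tests against the correlation-matrix-inversion formula
  to 1e−10.
* Missing data: pairwise deletion for correlations, listwise within each
  comparison.

## Synthetic cohort: what it emulates, and what it does not

`simulate_covariates` draws one latent standard-normal field per subject
with a planted correlation matrix (biomarker–perfusion entries such as
hsTNT–K^trans = −0.38, hsTNT–NCV ≈ −0.5, K^trans–v_e = 0.75, plus
physiologically motivated cross-correlations among conduction
velocities), then rescales each margin to its group mean/SD and truncates
at zero; NDS/NSS are rounded to integers.  The planted matrix is not
jointly positive semi-definite as written; it is repaired by eigenvalue
clipping and diagonal renormalization (largest entry shift ≈ 0.01), and
the repaired matrix is stored on the returned `SyntheticTruth`.

Two marginals deviate deliberately from the emulated cohort table: the
v_e spread is narrowed (SD 2.0 / 1.0 percentage points for the two
groups) because the reported SD would put a quarter of subjects at the
zero-truncation boundary where the kinetic model is unidentifiable, and
true v_e is floored at 0.8% for the same reason (see the plausibility
window above).

`simulate_acquisition` forward-simulates raw data per subject: SPGR VFA
signals for nerve (T1 = 1.2 s) and artery (T1 = 1.4 s); a dynamic artery
series embedding a population AIF (gamma-variate first pass, arrival
26 s ≈ injection after the sixth repetition plus transit, time-to-peak
30 s, peak ≈ 6 mmol/L, slow recirculation tail); a nerve series
embedding the extended-Tofts response to that AIF; exact
concentration→signal mapping; Gaussian noise of SD = baseline/SNR per
voxel (default SNR 40), averaged over 25 nerve / 9 artery voxels.  The
Gaussian noise model approximates magnitude-MRI Rician noise in the
high-SNR ROI-mean regime.

Not emulated: anatomical geometry, motion, registration error, B1
inhomogeneity, T2*/susceptibility leakage, water exchange, partial-volume
and inflow effects in the artery, and scanner drift.  Passing tests
therefore demonstrate correctness of the mathematics and code and
recoverability of planted effects under idealized noise — not robustness
to the full physics of patient data.

## Problem sizes used in validation

Validation experiments are sized to run on a single CPU in minutes: the
planted-effect recovery experiment uses 200 independent cohorts of
44 + 12 subjects at ROI (not voxel) resolution; type-I calibration uses
5000 null cohorts of n = 44; the VFA round trip uses 1000 random draws;
Monte-Carlo correlation calibration uses 1000 cohorts.  Voxelwise fitting
is exercised on small phantoms (single-digit voxel counts) since the
per-voxel path is identical to the ROI path.

## Known limitations

* The optimizer start value K^trans = 0.007 s⁻¹ (= 0.42 min⁻¹) sits an
  order of magnitude above typical fitted nerve values (~0.040 min⁻¹).
  Both conventions are honored as documented (start in s⁻¹, reporting in
  min⁻¹); the fit is insensitive to this for well-posed curves.
* The Bonferroni family for Spearman corrections is a caller-supplied
  constant; no attempt is made to infer "the" family from a table layout.
* The severity score implements only the stated amplitude thresholds.
* DICOM ingestion is out of scope; volumes are expected as NIfTI with
  masks already in dynamic-series space.
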