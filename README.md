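# nervedce

Quantitative dynamic contrast-enhanced (DCE) MR neurography of peripheral
nerves: a tested Python implementation of the full quantification chain
used to study sciatic-nerve microcirculation in type 2 diabetes, together
with the cohort statistics that relate nerve perfusion to clinical and
serological markers, and a synthetic-cohort generator that makes every
stage testable without patient data.

## Who this is for

Researchers working with DCE MRI of peripheral nerves (or other
low-perfusion tissues) who need a transparent, scriptable alternative to
scanner-vendor perfusion tools: each processing step is an importable,
unit-tested function with explicit units, and the whole chain can be
validated against simulations with known ground truth.

## The quantification chain

1. **Variable-flip-angle T1 mapping** (`nervedce.vfa`).  Spoiled
   gradient-echo signals at flip angles α = 5°, 8°, 11°, 14°, 17°
   (TR = 3.3 ms) are linearized as x(α) = SI/tan α, y(α) = SI/sin α; an
   ordinary least-squares fit gives the slope m and the pre-contrast
   relaxation time T1,0 = −TR / log m.

2. **Signal → concentration** (`nervedce.concentration`).  For the
   dynamic series at α_R = 15°, the enhancement factor
   Ca = (SI_t/SI_0)·(1 − e^(−TR/T1,0)) / (1 − cos α_R · e^(−TR/T1,0))
   is inverted to the instantaneous relaxation rate
   1/T1,t = −log[(1 − Ca)/(1 − cos α_R · Ca)]/TR, and tracer
   concentration follows as C(t) = (1/r1)[1/T1,t − 1/T1,0] with
   r1 = 3.43 L/mmol/s at 3 T.  An exact inverse is provided for
   simulation and round-trip testing.

3. **Arterial input function** (`nervedce.aif`).  Femoral-artery ROI
   voxels are averaged; bolus arrival is the first frame exceeding the
   running pre-bolus mean by more than 25%; the converted concentration
   curve is smoothed with a 3-point moving average.

4. **Extended Tofts model** (`nervedce.etm`).
   C_M(t) = K^trans ∫₀ᵗ AIF(t′) e^(−K^trans (t−t′)/v_e) dt′ + v_p·AIF(t),
   fitted to C(t) by Nelder–Mead least squares from starting values
   K^trans = 0.007 s⁻¹, v_e = 0.15, v_p = 0.025.  Internally all rates
   are s⁻¹; reports use min⁻¹ and percent.

5. **Cohort statistics** (`nervedce.stats`).  Neuropathy grouping
   (NDS ≥ 3), an electrophysiology-based severity score,
   normality-gated comparisons (t / Mann–Whitney, ANOVA /
   Kruskal–Wallis + Dunn), gated correlations (Pearson /
   Bonferroni-corrected Spearman), and partial correlation controlling
   for age and BMI.

6. **Synthetic cohorts** (`nervedce.simulate`).  A Gaussian-copula
   cohort (default 44 diabetes + 12 control subjects) with planted
   biomarker–perfusion correlations, plus a forward-simulated
   acquisition (population AIF → tissue response → raw spoiled-GRE
   signal → noise) for end-to-end validation.

## Worked example

```python
import numpy as np
from nervedce import (SimulationConfig, simulate_covariates,
                      simulate_acquisition, build_cohort_table,
                      partial_correlation)

cfg = SimulationConfig()                      # 44 + 12 subjects, SNR 40
truth = simulate_covariates(cfg, seed=1)
acqs = simulate_acquisition(truth, cfg, seed=2)
cohort = build_cohort_table(truth, acqs, cfg)  # runs T1 -> AIF -> fit

t2d = cohort[(cohort.group == "T2D") & cohort.fit_valid]
res = partial_correlation(
    t2d.hstnt_pg_ml, t2d.ktrans_per_min,
    t2d[["age_years", "bmi_kg_m2"]].to_numpy().T,
)
print(f"fitted Ktrans: {t2d.ktrans_per_min.mean():.4f} /min")
print(f"partial r(hsTNT, Ktrans | age, BMI) = {res.r:.3f} (p = {res.p:.4f})")
```

prints

```
fitted Ktrans: 0.0399 /min
partial r(hsTNT, Ktrans | age, BMI) = -0.468 (p = 0.0020)
```

i.e. the mean fitted transfer constant of the simulated diabetic group is
0.040 min⁻¹ (the generator plants means near 0.040 min⁻¹), and the
age/BMI-controlled partial correlation between the cardiac biomarker
hsTNT and nerve K^trans comes back negative, close to the planted −0.38 —
the chain recovers the planted biomarker–perfusion association from raw
simulated signal.

A command-line interface mirrors the stages
(`nervedce simulate | t1map | aif | fit | stats | run`).

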