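# exhaustscope

PET/CT radiomics of CD8+ T-cell exhaustion in tumors.

Tumor-infiltrating CD8+ T cells progressively exhaust: early exhausted
cells (PD-1 intermediate) still respond to checkpoint blockade, while
terminally exhausted cells (PD-1 high) do not. The fraction of
terminally exhausted cells therefore predicts whether immunotherapy can
still help — but measuring it requires invasive sampling and flow
cytometry. In murine tumor models (Lewis lung carcinoma and B16
melanoma), terminal exhaustion leaves a visible imprint on
¹⁸F-FDG-PET: exhausted infiltrates locally suppress glucose uptake, so
more exhausted tumors show a more heterogeneous uptake landscape, and
GLCM texture features that measure local homogeneity fall as terminal
exhaustion rises.

`exhaustscope` is a tested re-implementation of the radiomics pipeline
built on that observation, for researchers working on imaging biomarkers
of the tumor immune microenvironment. It provides:

- **Digital FDG phantoms** — 3D PET/CT tumor volumes with ellipsoidal
  ROIs whose uptake heterogeneity is coupled to a latent exhaustion
  state (early/terminal Tex fractions, E/T ratio, PD-1 MFI), calibrated
  to the murine dynamics: LLC baseline ≈ 40% terminal Tex, B16 ≈ 20%,
  post-irradiation peak 69.44–76.35% at days 7–14.
- **SUV conversion and feature extraction** — activity → SUV via
  `SUV = activity[kBq/mL] × body_weight[g] / injected_dose[kBq]`, then
  fixed catalogs of 61 PET and 57 CT radiomic features
  (intensity-direct, intensity-histogram, 3D GLCM and GLRLM texture,
  and — for CT — mesh-based shape features).
- **Test–retest robustness filtering** — Lin's concordance correlation
  coefficient across paired acquisitions, retaining features with
  CCC > 0.75 (CT) or CCC > 0.65 (PET).
- **The T-exhaustion score** — the published three-feature logistic
  model, shipped verbatim and immutable:

  ```
  score = −297.597 · InverseVariance(GLCM)
          + 178.689 · Homogeneity2(GLCM)
          + 1.088 · Kurtosis(IntensityHistogram)
          + 1.485
  P(high exhaustion) = 1 / (1 + e^(−score))
  ```

  plus LASSO screening of robust features against the exhaustion
  characteristics and a stabilized logistic refit on new cohorts,
  evaluated by C-index, Brier score and calibration curves.

## Worked example

```python
from exhaustscope import (
    PhantomSpec, RunConfig, extract, generate_phantom,
    llc_rt_timecourse, sample_exhaustion_state, to_suv,
    run_training_arm, run_validation_arm,
)

# one post-irradiation subject near the exhaustion peak
state = sample_exhaustion_state(llc_rt_timecourse(), day=7, seed=3)
pet, ct, mask = generate_phantom(PhantomSpec(seed=3), state)
fv = extract(to_suv(pet), mask, "PET")
print(state.terminal_tex_frac, fv["Homogeneity2(GLCM)"])

# the full experiment: train on a mixed ICI-surrogate cohort (n=20),
# validate on an independent post-irradiation cohort (n=20)
cfg = RunConfig()               # seed 42, default heterogeneity gain
result = run_training_arm(cfg)
report, _, _ = run_validation_arm(cfg, result.model)
print(result.evaluation.c_index, result.evaluation.brier, report.c_index)
```

prints

```
0.6479172542645997 0.14989233309185418
0.98 0.04621061019078431 0.88
```

The subject's terminal-Tex fraction is 0.648 and its lesion's GLCM
Homogeneity2 is 0.150 — lower than the 0.194 of the same lesion
realization at a day-21 exhaustion level of 0.232, the inverse
correlation the score exploits. The experiment
reaches a training C-index of 0.98 (Brier 0.046) and a validation
C-index of 0.88: the refit score ranks high-exhaustion tumors above
low-exhaustion ones in an independent cohort.

The scripts in `examples/` walk through each capability (simulation,
feature extraction, robustness filtering, scoring); a thin CLI mirrors
them (`exhaustscope simulate|extract|robustness|fit|score|evaluate|run-all`).

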