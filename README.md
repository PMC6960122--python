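# deltarad

Delta-radiomics + CA19-9 analysis of treatment response and survival for
CT-guided chemoradiation of pancreatic cancer.

During a 28-fraction chemoradiation course, a pancreatic-head tumor is imaged
daily by CT. The texture of the tumor ROI changes as the tumor responds, and
the serum biomarker CA19-9 (carbohydrate antigen 19-9, U/mL) rises or falls
with tumor burden. Neither signal alone is a reliable early predictor of
pathological response; this package implements the combined analysis:

1. **Texture features** — from each ROI-masked volume, a 13-feature panel:
   GLCM entropy, contrast, cluster tendency, inverse variance, information
   measure (IMC1) and IDN; NGTDM coarseness and complexity; GLRLM gray-level
   non-uniformity; first-order mean, skewness and (Pearson) kurtosis; and
   NESTD, the mean over the ROI of the voxel-wise difference between
   normalized neighborhood entropy and normalized neighborhood SD.
2. **Delta transform** — the relative net change from the first fraction,

   DRFₙ = (F₁ − Fₙ) / F₁,  n = 2..28,

   applied identically to CA19-9 against its pre-treatment baseline, so a
   *decline* is a *positive* change for both biomarker families.
3. **Feature selection** — Spearman redundancy filter (|r_s| > 0.9), per-group
   trend fits, and two association tests that must both reject at α = 0.05:
   a pooled Welch t-test and the likelihood-ratio test of the linear
   mixed-effects model `DRF ~ Response + (1|Patient) + (1|Fraction)` with
   crossed random intercepts, fitted by maximum likelihood.
4. **Response model** — logistic regression of response (good G1/G2 vs bad
   G3 by modified Ryan grade) on the standardized changes, scored by the
   concordance index (= AUC for a binary outcome), plus the earliest
   treatment week at which the groups separate (start of sustained weekly
   significance).
5. **Survival** — Kaplan–Meier comparison of increasing- vs decreasing-CA19-9
   patients and a ladder of Cox proportional-hazards models (Efron ties)
   combining the CA19-9 change with the selected texture changes.

A synthetic cohort generator emulates the full data structure (longitudinal
textured volumes, sparse lognormal CA19-9 trajectories, response labels,
progression-free survival with censoring) so every stage is testable without
clinical data.

## Worked example

Run the full pipeline on a default synthetic cohort (24 patients, 28 daily
fractions; volumes are written as uncompressed NIfTI, tables as CSV):

```sh
deltarad run-all --out run1 --seed 1
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The second command prints, for seed 1:

```
stages: simulate, extract, delta, select, respond, survive
selected features: 5 of 13
c-index (ca199): 0.750 (n=24)
c-index (combined): 1.000 (n=24)
c-index (drf): 0.965 (n=24)
detection week (ca199): none
detection week (combined): none
detection week (drf): none
KM decreasing: median 23.2 mo, S(60mo) 0.15 (n=8)
KM increasing: median 7.6 mo, S(60mo) 0.16 (n=16)
```

Reading this: 5 of the 13 texture-change features passed both association
tests on this cohort; CA19-9 change alone separates responders with
concordance 0.75, texture changes alone 0.97, and the combined logistic model
1.00 (in-sample, 24 patients — small-sample optimism is expected and
documented). No biomarker reached *sustained* weekly significance on this
24-patient draw (weekly detection needs either more patients or stronger
divergence; the package's simulation studies quantify when it appears).
Patients whose CA19-9 declined or normalized had longer median
progression-free survival (23.2 vs 7.6 months) — the qualitative pattern the
analysis is designed to expose.

## Library use

```python
from deltarad import CohortConfig, generate_cohort
from deltarad.textures import extract_feature_table
from deltarad.delta import compute_drf, normalize_ca199
from deltarad.selection import run_selection

cohort = generate_cohort(CohortConfig(seed=7))
features = extract_feature_table(cohort.volumes)        # long DataFrame
drf, _ = compute_drf(features)                          # Eq.-style transform
report = run_selection(drf, cohort.labels)              # per-feature tests
```

## What `scripts/acceptance.py` does

It regenerates the default synthetic cohort from `--seed`, runs every
pipeline stage from scratch (texture extraction on all 672 volumes, delta
transform, selection, response model, detection weeks, KM/Cox survival),
prints the summary above and writes the results JSON to `--out`. It takes
about a minute on one CPU.

## Layout

- `src/deltarad/textures.py` — quantization, GLCM/NGTDM/GLRLM, first-order,
  NESTD, panel extraction
- `src/deltarad/delta.py` — relative net change, weekly aggregation
- `src/deltarad/selection.py` — Spearman filter, trend fits, t-test,
  crossed random-intercept LME (profiled ML)
- `src/deltarad/response.py` — logistic model, concordance, detection weeks
- `src/deltarad/survival.py` — KM, Cox ladder
- `src/deltarad/simulate.py` — synthetic cohort + trajectory generators
- `src/deltarad/pipeline.py`, `cli.py` — orchestration, I/O, `deltarad` CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
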