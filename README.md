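# cariescan

Automated occlusal-caries scoring from fluorescence-enabled intraoral-scan
signals, with ROC-calibrated cut-offs and cluster-adjusted diagnostic-accuracy
statistics.

## The problem

Fluorescence-enabled 3D intraoral scanners capture, for every point on a
tooth, red and green fluorescence under ~415 nm excitation (R_fluo, G_fluo)
and the white-light color channels (R, G, B). Demineralized enamel loses
green autofluorescence (the QLF principle) and dentin lesions gain porphyrin
red fluorescence, so simple signal statistics can grade occlusal caries
automatically. Validating such a scoring system requires the full
diagnostic-accuracy machinery of a clinical study: a histological gold
standard, ROC calibration of ordinal cut-offs on one sample and blind
validation on another, and statistics that respect the clustering of
examination sites within teeth.

This package implements that pipeline end to end for researchers in
cariology and diagnostic-test methodology:

* **Four scoring algorithms.** With site signals and the same tooth's sound
  reference (per-channel mean over caries-free patches):
  - `ALG1 = 1 − G_fluo` (absolute green loss),
  - `ALG2 = 1 − G_site/G_ref` (sound-normalized green loss),
  - `ALG3 = log[(R_site/R_ref)/(G_site/G_ref)]` (red/green log-ratio),
  - `ALG4` = ridge-penalized logistic regression on the five log-ratio
    features `log(c_site/c_ref)`, scored as the fitted caries probability.
* **Histological reference.** E0–D3 from lesion depth and tissue thickness:
  enamel fraction `< 0.5` → E1, `≥ 0.5` (incl. the DEJ) → E2; dentin
  fraction `< 0.33` → D1, `0.33–0.66` → D2, `≥ 0.66` → D3; dichotomized at
  ≥E1 / ≥D1 / ≥D2.
* **Cut-off calibration.** Per level, the threshold maximizing SE + SP on
  the ROC curve (midpoint candidates; a cut-off is *reliable* when
  SE + SP > 1.7), with cross-level monotonicity enforced.
* **Validation statistics.** Mann–Whitney Az with DeLong variance and the
  paired DeLong z-test; sensitivity/specificity with the cluster
  ratio-estimator SE (sites nested in teeth); exact McNemar;
  McNemar–Bowker symmetry for paired in vivo/in vitro ordinal scores;
  Spearman r_s with clustered-bootstrap SE; compact A > B > C letter
  groups; the Burderer minimum-sample-size formula.
* **Synthetic cohort generator.** The clinical data of such studies are not
  public, so a seeded generator emulates the study structure: 53 teeth,
  118 sites (composition 17 E0 / 79 E1–E2 / 8 D1 / 14 ≥D2), 1–3 sites per
  tooth, tooth-level random effects, paired in vivo / in vitro signals, an
  ICDAS visual observer, in vivo biofilm red-fluorescence confounding and
  "insufficient scan" missingness.

## Worked example

```python
from cariescan import run_pipeline, study_run_config

result = run_pipeline(study_run_config(seed=0))
print(result.report)
```

prints (abridged):

```
(a) In vivo
        ALG1              ALG2              ALG3              ALG4              VISUAL
r_s     0.46 (0.07)       0.51 (0.07)       0.47 (0.08)       0.53 (0.07)       0.79 (0.04)
>=E1 Az 0.87 (0.04)^A     0.87 (0.04)^A     0.79 (0.06)^B     0.85 (0.05)^A     0.93 (0.02)^A
     SE 0.59 (0.05)^C     0.69 (0.05)^B     0.54 (0.05)^C     0.80 (0.04)^B     0.93 (0.02)^A
     SP 0.88 (0.08)^A     0.82 (0.10)^A     0.88 (0.08)^A     0.71 (0.12)^A     0.76 (0.11)^A
     ACC0.63              0.71              0.59              0.78              0.91
>=D1 Az 0.73 (0.07)^A     0.75 (0.06)^A     0.73 (0.07)^A     0.76 (0.06)^A     N/A
...
```

Each cell is the point estimate with its standard error in parentheses
(DeLong SE for Az, cluster-adjusted SE for SE/SP, clustered-bootstrap SE for
r_s) and a significance letter: within a row, methods sharing a letter are
not significantly different at the 95% level (A > B > C by point estimate).
The visual (ICDAS) method is assessed in vivo only and never at the ≥D1
level, where no ICDAS score separates enamel from initial outer-dentin
lesions. Cut-offs are calibrated on an independent calibration cohort and
applied blind to the validation cohort, so the table reflects out-of-sample
performance.

The same stages run from the shell, either end to end

```bash
cariescan all --seed 0 --out results/run0
```

or stage by stage (`cariescan generate | calibrate | score | validate |
report`), and as numbered drivers under `analysis/` (01 generate cohorts,
02 calibrate cut-offs, 03 score the validation cohort, 04 diagnostic
performance table, 05 in vivo vs. in vitro agreement), which write their
tables under `results/`.

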