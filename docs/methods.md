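# Methods

This note documents the models and procedures implemented in `cariescan`,
their assumptions and tunable parameters, and the design choices made where
the design was genuinely open.

## Histological reference

Each examination site is graded from sectioned-tooth geometry: maximum
lesion depth `d`, enamel thickness `e` and dentin thickness `t` (mm) at the
same position. `d = 0` is sound (E0). Lesions within enamel are graded by
the fraction `d/e`: `< 0.5` → E1, `≥ 0.5` → E2; a lesion reaching the
dentin–enamel junction exactly (`d = e`) is E2. Lesions past the DEJ are
graded by the fraction of dentin penetrated `(d − e)/t`: `< 0.33` → D1,
`0.33 ≤ f < 0.66` → D2, `≥ 0.66` → D3.

Two conventions required a decision. First, the dentin fraction is computed
from the depth *beyond the DEJ* rather than total depth — this keeps the
fraction in [0, 1] and aligns the band boundaries with the outer / middle /
inner thirds of dentin. Second, the split points 0.5, 0.33 and 0.66 are
exact decimal constants, closed on the more-severe side (a fraction of
exactly 0.33 is D2), matching the cut-off convention used everywhere else
in the package (score ≥ threshold is positive).

## Scoring algorithms

All four raw statistics are oriented so that higher means more severe.
ALG1 is the absolute green-fluorescence loss `1 − G_fluo` and is
deliberately not brightness-invariant. ALG2–ALG4 normalize against the
same tooth's sound reference (the per-channel mean over caries-free
patches), which cancels tooth-level brightness: ALG2 is `1 − G_site/G_ref`
(negative if the site is brighter than the reference), ALG3 the red/green
log-ratio `log[(R_site/R_ref)/(G_site/G_ref)]`, and ALG4 a logistic model
on the five log-ratio features `log(c_site/c_ref)` whose raw score is the
fitted probability of caries (histology ≥ E1).

The device's exact proprietary functions are unpublished; these forms are
minimal reconstructions consistent with each algorithm's published
one-sentence description, and no numerical equivalence with any commercial
implementation is claimed.

The ALG4 fit uses scikit-learn's L2-penalized logistic regression with a
fixed small ridge strength (C = 1000, lbfgs, tol 1e-10). The penalty keeps
the fit defined and deterministic even under perfect separation, which
noise-free synthetic cohorts produce by construction. Fitting requires at
least 10 sites per class. The model is trained on the calibration cohort's
in vitro signals, the condition under which such reference datasets are
collected.

Sites with missing or non-positive signals propagate as "insufficient"
(NaN raw, NA ordinal); nothing is imputed, and every downstream analysis is
complete-case per method (paired tests use the intersection of non-missing
sites).

## Cut-off calibration

For each algorithm and diagnostic level (≥E1, ≥D1 and, for the four-point
algorithms ALG3/ALG4, ≥D2), labels are an independent dichotomization of
the same raw scores and the cut-off maximizes SE + SP (the Youden-optimal
operating point). Candidate thresholds are midpoints between adjacent
distinct scores plus the two infinite endpoints — every achievable
classification is covered and ties with data values cannot occur. Among
equal maximizers the highest threshold is returned, favoring specificity,
consistent with the ≥ positivity convention. A cut-off is flagged
*reliable* when SE + SP > 1.7 at the optimum; two-point algorithms
(ALG1/ALG2) carry no ≥D2 cut-off and requesting one is an error.

Under noise the per-level optima can invert across levels, which a nested
ordinal scale cannot represent; a pool-adjacent-violators pass restores
non-decreasing thresholds (levels are re-scored at the pooled value). On
noise-free data the calibrated cut-offs reproduce the histology-derived
ordinal scores exactly, which the test suite verifies.

The pipeline calibrates on one cohort and validates on an independently
drawn cohort, mirroring the use of previously defined cut-offs on a new
blind sample; an in-sample flag exists for the recovery tests only.

## Validation statistics

**Az / DeLong.** Az is the Mann–Whitney statistic with ties counted 1/2.
With positive scores X₁..X_m and negative scores Y₁..Y_n, the placement
values V10ᵢ = P̂(Y < Xᵢ), V01ⱼ = P̂(Yⱼ < X) give Var(Az) = S10/m + S01/n
(empirical variances of the placements); the same components give the
covariance of two correlated AUCs measured on the same sites, hence the
paired two-sided z-test. Identical score vectors return z = 0, p = 1.

**SE / SP / ACC.** From the 2×2 contingency table against dichotomized
histology. Standard errors use the cluster ratio estimator
`var = K/(K−1) · Σ(a_k − p·n_k)² / (Σn_k)²` over the K teeth contributing
to the margin, because sites on the same tooth are positively correlated
(the generator's tooth effect makes this measurable; binomial SEs would be
anti-conservative). With all-singleton clusters the estimator reduces to
the binomial SE times √(n/(n−1)).

**McNemar.** Exact two-sided binomial test on the discordant pairs —
discordant counts are small at n ≈ 118, where the chi-square approximation
is unreliable. **McNemar–Bowker** sums (n_ij − n_ji)²/(n_ij + n_ji) over
informative off-diagonal pairs only, with df equal to their number
(standard handling of empty cells); an all-symmetric table returns p = 1.

**Spearman r_s** is the tie-corrected (mid-rank) correlation of a method's
ordinal scores with the histology codes. Its SE comes from a clustered
bootstrap resampling teeth with replacement (default 2000 replicates,
seeded) — the same clustering philosophy as the SE/SP adjustment, since no
closed form is standard for clustered ordinal data.

**Letter groups.** Within a table row, methods are sorted descending by
point estimate and greedily grouped: a method joins the current group iff
it is not significantly different (pairwise p > α) from every member;
groups are lettered A, B, C. Pairwise tests are DeLong for Az and McNemar
for SE (among truly positive sites) and SP (among negatives), at α = 0.05
without multiplicity correction, matching the descriptive-table practice
this display imitates. The assignment is invariant to input order.

**Burderer sample size.** `n = max(ceil(Z²·SE(1−SE)/(d²·prev)),
ceil(Z²·SP(1−SP)/(d²·(1−prev))))` with Z the two-sided normal quantile.
Prevalence must lie in (0, 1); 1.0 is an explicit sentinel disabling the
prevalence adjustment in both terms, since the prevalence assumption behind
published minimum-site counts is often unstated. With the classical inputs
(SE 0.84, SP 0.76, 95% CI, absolute error 0.1) the unadjusted formula gives
71 sites, and 141 at prevalence 0.5.

**Visual method.** The ICDAS observer is evaluated in vivo only, at ≥E1
(ICDAS ≥ 1) and ≥D2 (ICDAS ≥ 3, configurable); no ICDAS score reliably
separates enamel lesions from initial outer-dentin lesions, so the ≥D1
level is guarded against for the visual method. The full 0–6 ICDAS score
serves as the ROC input for the visual Az.

## Synthetic cohort generator

The generator emulates the *structure* of a clinical validation study of a
fluorescence intraoral scanner, not any particular dataset. The driver is
a continuous latent severity in [0, 6): the histology code plus the site's
fractional position within its band. Geometry is sampled so the histology
rule applied to it returns the assigned class exactly (band fractions are
kept in [0.02, 0.98] of each band, away from the closed boundaries), and
when class targets are given as counts the realized composition matches
them exactly by dealing classes without replacement; the site counts per
tooth (1–3) are repaired to the exact total.

Signals follow log-linear channel models clipped to [0, 1]:

* `G_fluo = g₀·exp(−γ_G·s + u_tooth + ε)` — green loss with severity;
* `R_fluo = r₀·exp(γ_R·max(0, s − 3) + u_tooth + ε)` — porphyrin red gain
  from dentin involvement onward (onset at severity 3, i.e. class D1), plus
  an additive biofilm excess with probability `plaque_prob_in_vivo`, in
  vivo only;
* color channels drift monotonically toward stain (R up, G/B down).

`u_tooth ~ N(0, 0.15²)` is a shared tooth effect (clustering sites within
teeth; it cancels in the ratio-based scores through the sound reference,
which is the mean of three severity-zero draws from the same tooth).
Measurement noise is log-normal per channel and condition; defaults are
0.22 (in vivo) and 0.20 (in vitro, dark-room scanning) for the green and
color channels and half that for red fluorescence, which is measured more
stably. Missingness ("insufficient scan") is independent Bernoulli per
site and condition (4% in vivo, 2% in vitro). The ICDAS observer maps
E0..D3 monotonically to 0..5 and adds a symmetric rounded-Gaussian
perturbation (SD 0.8) clipped to 0..6.

Default study conditions: 53 teeth, 118 sites, composition 17 E0 / 79
E1–E2 / 8 D1 / 14 ≥D2. The grouped enamel and deep-dentin counts are split
40/39 and 9/5 across their subclasses, a roughly even split consistent with
the grouped totals. No quantitative signal model for such scanners is
published: the decay, gain, noise and biofilm parameters are
reconstructions chosen once so that the realistic preset lands validation
Az in the 0.7–0.95 band typical of published occlusal-caries studies, with
the plaque confounder degrading the in vivo red-fluorescence scores
relative to in vitro.

**What passing tests do and do not show.** The generator reproduces the
study's sampling structure (composition, clustering, paired conditions,
missingness, a red-fluorescence confounder), so it exercises every code
path of the statistics under realistic sample sizes. It does not reproduce
real fluorescence physics — surface geometry, stains, calculus and
developmental defects are absent — so passing tests validate the
*statistical machinery*, not the field performance of any scoring
algorithm or device.

## Numerical choices and problem sizes

* Positivity is always `score ≥ threshold`; boundaries are closed on the
  more-severe side throughout.
* Cohort CSVs print floats with shortest round-trip repr and are re-read
  with round-trip parsing, so write → read is lossless to the bit; reading
  re-derives the histology class from the stored geometry and rejects
  inconsistent or duplicated rows.
* The pipeline derives the calibration seed from the run seed and the
  validation seed from a fixed offset, making cohorts independent but
  jointly reproducible; reruns are byte-identical.
* Monte-Carlo checks in the test suite use 1000 instances for oracle
  equivalences (AUC vs. pair counting, cut-off vs. exhaustive search),
  2000 replicates for type-I error of the paired tests at n = 120, 10,000
  replicates for bootstrap-vs-analytic SE comparisons, 1000 replicate
  cohorts for the condition-symmetry null, and means over 8 replicate
  studies for the realistic Az envelope — sizes at which the binomial
  noise of the checked rates is well below the asserted tolerances.

## Known limitations

* The scoring forms are reconstructions; absolute raw-score values are not
  comparable to any device output.
* The cluster ratio estimator assumes many clusters (53 here); with very
  few teeth its SE is unstable.
* The Bowker chi-square approximation is conservative when discordant
  counts are small; at the default scale its null rejection rate is
  slightly below nominal.
* Letter groups use unadjusted pairwise tests; they are a descriptive
  display, not a simultaneous inference procedure.
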