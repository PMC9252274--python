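# Methods

This note records the models, conventions and numerical choices behind
`fctopo`, in the order the pipeline runs them, together with the design
decisions that were genuinely open and how they were settled.

## Synthetic cohort model

Regional time series are zero-mean multivariate Gaussian with optional
per-region AR(1) temporal autocorrelation: x_t = φ x_{t−1} + √(1−φ²) e_t
with correlated innovations, so the stationary cross-sectional covariance
equals the target matrix and each region has lag-1 autocorrelation φ
(default φ = 0.3, a typical value for ~3 s sampling). This is the simplest
model carrying exactly the correlation structure that FC estimation
assumes; it deliberately omits voxelwise signal, scanner noise, motion,
physiological confounds, and non-stationarity. Passing tests therefore
show that the *statistical machinery* is correct and calibrated under the
assumed covariance model — not that real fMRI artifacts are handled.

**Group covariance.** The male group's correlation matrix has a block
community structure (default 4 blocks, within-community r = 0.35, between
r = 0.12, diagonally loaded to positive definiteness if needed). The
female matrix multiplies the off-diagonals by `sex_effect_scale` (default
0.9; < 1 implants lower connectivity in women), inverted for
`reversal_regions` (defaults, at 94 regions, to bilateral thalamus, right
caudate and left putamen — regions where the effect runs the other way),
and optionally confined to `deficit_regions` for a spatially localized
deficit. No field-standard effect size exists on the correlation scale for
this contrast, so the default scale is a free parameter; recovery tests
compare against the configured truth, not against any published magnitude.

**Subject random effects.** Each subject receives a perturbed copy of
their group matrix: symmetric Gaussian noise (SD `subject_cov_sd` = 0.05
correlation units) on the off-diagonals, projected back to a valid
correlation matrix by eigenvalue clipping. All of a subject's sessions
share this matrix, which makes repeated sessions genuinely more alike than
sessions from different subjects — the exchangeability structure the
mixed models and subject-level permutation are designed for. The 0.05
default makes the subject-level variance comparable to the sampling noise
of a ~150-volume session, a realistic regime for individual differences
in FC.

**Covariates, sessions, SUVR, cognition.** Subjects draw age, education,
ADAS-Cog (truncated at the eligibility cutoffs), handedness and APOE4
carrier status from per-sex distributions matching a typical
cognitively-normal aging cohort (men 72.2 ± 4.3 y, 17.7 ± 2.2 y education,
APOE4 25%; women 72.6 ± 4.5 y, 16.3 ± 2.3 y, APOE4 36%). Session counts
per subject follow a {1: 0.50, 2: 0.35, 3: 0.15} distribution (mean 1.65,
matching the ~1.6–1.8 sessions/subject regime). SUVR is a two-component
mixture (negative 1.00 ± 0.05, positive 1.26 ± 0.08) straddling the 1.11
cutoff, with APOE4 carriers drawing the positive component with higher
probability (0.55 vs 0.32); ~11% of sessions lack a PET scan within the
one-year window, yielding unknown status downstream. These magnitudes are
plumbing choices that let the classification and ANOVA stages be
exercised; they are not empirical claims. Cognition scores are affine in a
chosen global metric with per-sex slopes plus Gaussian noise; the default
(women's slope −3, men's 0, noise SD 12 on a z-scored metric) produces a
within-sex correlation of about −0.23 for women and none for men.

All randomness flows from one seed through spawned `SeedSequence`
children (one per subject), so identical configurations reproduce
byte-identical cohorts and any subject can be regenerated in isolation.

## FC and thresholding conventions

Correlations are clipped to |r| ≤ 1 − 10⁻⁷ before atanh so duplicated
series cannot produce infinities. A zero-variance region is an error
naming the region. Proportional thresholding retains the top
round(s·N(N−1)/2) **positive** edges at their original weights — graphs
stay weighted at every level, never binarized. Negative Fisher-z edges are
excluded before ranking (the dominant convention; the strength and
geometric-mean-triangle formulas presuppose nonnegative weights);
absolute-value ranking is available behind `negative_weights="absolute"`.
Rounding of the edge count is half-away-from-zero; ties among equal
weights break by ascending (i, j) index, making edge sets deterministic
and exactly nested across the sweep (the sweep implementation exploits
this by sorting once and growing one matrix).

## Graph metrics

Strength is the row sum. Efficiency uses edge length 1/w (−log w behind a
flag) with shortest paths by a vectorized Floyd–Warshall; disconnected
pairs contribute zero. Clustering follows the geometric-mean (Onnela)
form with weights normalized by the graph maximum before the cube-root
products; the denominator is the binary degree deg(deg−1) — with nodal
strength in the denominator the coefficient is no longer bounded by 1 and
the "proportion of neighbors" interpretation fails — though a
`strength` variant is switchable. C_i = 0 for degree < 2. Global metrics
are the **mean** over nodes for all three (a sum variant for strength
exists behind `aggregate="sum"`; after z-scoring the two are equivalent up
to a constant, so inference is unaffected). Sparsity integration is the
unweighted mean over the 46 levels; trapezoid AUC divided by the range is
switchable and differs only in endpoint weights. Absolute magnitudes of
integrated metrics depend on these conventions and on the data, so the
pipeline's inferential claims are about contrasts, never about matching a
particular printed magnitude.

Correctness is established against brute-force oracles (explicit row
sums, triple-loop Floyd–Warshall, exhaustive triangle enumeration) to
1e−10 on random graphs, and cross-checked against networkx (Onnela
clustering, Dijkstra path lengths).

## Group inference

`fit_lme_adjust` fits the random-intercept model metric ~ sex + age_c +
handedness + education_c + APOE4 + (1|subject) by REML (statsmodels
MixedLM; optimizer chain lbfgs → powell → ML → OLS on non-convergence;
with no repeated sessions the subject variance is unidentifiable and the
OLS path is used directly). Nuisance covariates are centered so removing
their contributions preserves the grand level. Covariate coding:
handedness R=0/L=1, APOE4 carrier 0/1, sex M=0/F=1; sessions with missing
covariates are dropped with a logged count.

**A calibration pitfall, and the design chosen.** The seemingly natural
two-step scheme — subtract fitted nuisance effects *and* predicted (BLUP)
subject intercepts, then run a session-level two-sample t — is severely
anticonservative (≈ 0.28 rejection at nominal 0.05 in simulation): BLUP
shrinkage pulls every subject toward their own group's mean, deflating
the within-group spread while the sampling noise of the group contrast
remains. The pipeline therefore adjusts for nuisance fixed effects only,
collapses each subject's sessions to their mean, and applies the pooled t
across subjects (`adjusted_sex_contrast`); simulation confirms this holds
the type-I error at nominal under a clustered null. The BLUP-removing
adjustment remains available (`remove_subject_effect=True`) for producing
display-adjusted values, with the caveat documented on the function.

Bonferroni families: 94 regions within each nodal-metric family, 3 tests
for the global metrics. Demographic tests use Pearson chi-square without
continuity correction (df = 1) and the pooled-variance t from summary
statistics. Amyloid: positive iff SUVR strictly above 1.11 (a value at
exactly 1.11 is negative), unknown without a PET scan within 365 days of
the MRI, nearest scan wins when several qualify; negative SUVR is a data
error. Eligibility: sessions with age > 80 or ADAS-Cog > 10 are excluded
(strict inequalities), with per-reason counts logged. The two-way ANOVA
uses Type II sums of squares, appropriate for the unbalanced sex-by-APOE4
and sex-by-amyloid designs. The slope-difference test is
t = (b₁−b₂)/√(SE₁²+SE₂²) with Welch–Satterthwaite degrees of freedom from
the per-group residual dfs.

The bundled 94-region mapping to six macroareas (prefrontal, other
frontal, occipital, temporal, parietal, central structures) approximates
standard lobar anatomy and ships as an editable CSV; it is configuration,
not a canonical atlas.

## Network-based statistic

Edge-wise adjustment uses one vectorized OLS (the design matrix is shared
by all N(N−1)/2 edges, so a single pseudoinverse adjusts every edge; an
exact per-edge mixed-model path exists for validation). Sessions are then
collapsed to subject means and a one-sided pooled t is computed per edge;
edges with raw p < 0.005 form the supra-threshold graph and its connected
components are the candidate clusters (extent = edge count; an intensity
variant sums the component's t values). The null distribution is the
maximal component statistic under random reassignment of sex to
*subjects* — sessions move with their subject, because repeated sessions
make session-level labels non-exchangeable — with
FWE p = (1 + #{null ≥ observed})/(1 + B), which is never zero and
monotone in the observed statistic.

Three adjustment schemes were evaluated on null cohorts before settling
the default. Subtracting BLUP subject intercepts before the edge t-tests
is ruinous (false-positive rate 0.64 at nominal 0.05): shrinkage encodes
the observed labels into the values. Keeping the sex term in the
adjustment fit is anticonservative whether the fit is computed once
(0.17) or re-estimated inside every permutation (≈ 0.10): the cohort's
covariates genuinely differ by sex, so the observed labeling is the most
collinear with the nuisance columns and carries the most adjustment
noise. The default (`adjustment="reduced"`) is therefore Freedman–Lane
residualization on the reduced model — nuisance covariates only, no sex
term, computed once. That adjustment is label-independent, subject
relabeling is then a true symmetry of the adjusted data, and the
permutation test is essentially exact (measured null FWE ≈ 0.01–0.03;
below 0.05 because the integer-valued extent statistic makes the
permutation p-values conservative on small graphs). The with-sex variant
remains as `adjustment="full"` for comparison. If fewer distinct
subject-label assignments exist than requested permutations, all are
enumerated with a warning.

## Calibration and recovery studies (`fctopo.validation`)

The studies run the full chain on compact cohorts so multi-hundred-replicate
runs finish in minutes on one CPU; the statistical structure (repeated
sessions, subject covariance perturbations, covariate–sex associations)
is the full generator's. Sizes, chosen once as a speed/fidelity
compromise:

| study | cohort | regions | T | replicates |
|---|---|---|---|---|
| metric type-I | 30 M / 40 F | 10 | 48 | 500 |
| NBS null FWE | 20 M / 20 F | 24 | 60 | 200 × 500 perms |
| metric recovery (scale 0.8) | 40/40 | 16 | 120 | 25 |
| NBS block localization (scale 0.8) | 40/40 | 24 | 120 | 10 × 500 perms |

The NBS null study uses 24 regions (276 edges) rather than a smaller toy
because the component-extent statistic is integer-valued: on sparser
graphs the null maximal-extent tail is so coarse that the largest
attainable rejection level falls well below nominal, and the study would
measure discreteness rather than calibration.

The localization study places the 10-node deficit block inside a single
baseline community (2-community base covariance): a block straddling
communities genuinely splits into several supra-threshold clusters,
because its low-baseline-correlation edges carry a proportionally smaller
absolute deficit and miss the primary threshold — a property of the
statistic, not a bug, but one that would conflate "found the deficit"
with "deficit happens to be connected".

## Known limitations

- The generator's covariates do not influence the time series, so
  covariate-adjustment power is demonstrated only for implanted linear
  effects in the inference-level simulations, not through the FC model.
- Moment/OLS edge adjustment assumes a shared design across edges; edges
  with missing sessions are not supported (the generator never produces
  them).
- Absolute metric magnitudes are convention-dependent (integration rule,
  negative-edge policy, aggregation) and are not comparable across
  pipelines; contrasts and their error rates are.
- The AR(1) + Gaussian model ignores spectral structure beyond lag 1;
  effective-df corrections for correlation estimates are not needed
  downstream because inference never uses per-correlation p-values.
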