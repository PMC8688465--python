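# Methods

## What the package computes

`varitx` estimates where in a white-matter mask the seed-based FC
profile differs most between people, after removing two nuisance
contributions, and then asks what transcriptomic, cellular and
macroscale features covary with that map.  The statistic of interest at
voxel *v* and session *t* is

    V_v(t) = R'_v(t) − β₁ N_v − β₂ Noise_v − c

where `R'_v(t) = 1 − R_v(t)` is one minus the mean pairwise correlation
between subjects' seed-*v* FC profiles, `N_v` is the subject-averaged
intra-subject analogue over session pairs, `Noise_v` is the pooled
inverse temporal SNR, and (β₁, β₂, c) are ordinary-least-squares
coefficients fit per session across voxels.  The final map is the
session average of the residuals.  The model assumes profiles are
comparable across subjects voxel by voxel (a shared mask), that the
nuisance contributions enter approximately linearly at the map level,
and that averaging raw correlation coefficients (no Fisher transform)
is an acceptable summary — the last matches the estimator's definition;
Fisher-z averaging is available via `VariabilityModel(fisher=True)` and
changes results only in the heavy-|r| regime.

## Synthetic cohorts: what is emulated, and what is not

The generator (`varitx.datasets`) works directly in FC space.  For seed
*v*, subject *s*, session *t*:

    f_v(s,t) = base_v + inter_sd[v]·u_{v,s} + intra_sd[v]·e_{v,s,t} + ε

with `u` fixed per subject (shared across sessions), `e` fresh per
session, `ε` i.i.d. measurement noise, and values clipped to the valid
correlation range.  No generative model for intersubject FC variability
is established in the literature; this additive variance-components
model is the package's own choice — it is the simplest model in which
"between-subject", "within-subject" and "measurement" contributions are
separable and individually plantable, which is exactly what the
downstream estimator claims to separate.

Three design details matter and were chosen on generative grounds:

* **Baseline profiles are row-standardized** (mean 0.25, SD 0.25 in FC
  units) after being built from a distance-decay kernel plus a smooth
  gradient term.  Without this, seeds near the bounding-box edge have
  systematically different profile variance than central seeds, and that
  geometric artifact — not the planted field — dominates the similarity
  maps.
* **The intra-subject field has its own spatial structure**
  (`0.05 + 0.2·minmax(y)`, independent of the planted inter-subject
  field `0.1 + 0.3·gradient` along *x*).  If the intra field is flat,
  `N_v` becomes a deterministic monotone function of the inter field
  through the shared variance denominator, and the confound GLM
  regresses out the signal itself.  Real intra-subject variability has
  its own spatial organization; modelling that is what makes the
  adjustment meaningful rather than destructive.
* **Defaults are desk-scale**: 20 subjects × 4 sessions × 300 voxels,
  chosen so the full pipeline runs in seconds while keeping ≥ 190
  subject pairs per voxel; a test-retest design with more subjects,
  two runs per session and thousands of voxels is reachable through
  `CohortConfig`.

A latent-time-course mode emits raw BOLD-like runs (five shared latent
signals, smooth loadings perturbed per subject/session, baseline 100 so
tSNR is well defined) for end-to-end tests of the profile and noise
path.  The generator does not attempt scanner physics, head motion,
hemodynamics, or partial-volume mixing, and its noise is Gaussian and
spatially white.  Passing recovery tests therefore demonstrates that
the estimator separates the variance components it claims to separate —
not that it is robust to motion artifacts or non-Gaussian physiology.

Expression matrices plant `n_signal_genes` genes at a target absolute
correlation (`effect`) with a spatial gradient, signs randomized so both
PLS1 tails are populated; gene sets draw a stated fraction of members
from the signal genes.  Term maps and index stacks are built the same
way (mixture coefficients hit a target correlation).

## Numerical and inferential choices

* Temporal SD in tSNR uses **ddof = 1** (stated explicitly; the
  estimator definition is silent on this and the difference vanishes at
  realistic run lengths).
* The technical-noise regressor is **one pooled map** (1/tSNR averaged
  over all runs, sessions and subjects): a single stable regressor
  rather than per-session maps; the GLM is per session only through
  `R'_v(t)`.
* Voxels flagged anywhere (zero-variance series, undefined tSNR) are
  dropped from all maps before the GLM so one consistent voxel set is
  used; a constant regressor (e.g. `N ≡ 0` in the no-session-noise
  limit) is dropped from the GLM with a warning instead of failing.
* The Moran weight matrix is **k-NN (k = 8), inverse distance,
  max-symmetrized**, optionally row-standardized; the eigenbasis comes
  from the doubly centered dense matrix, with the constant direction
  removed and optional truncation to the top-m eigenvectors by
  |eigenvalue| (default m = min(n−1, 1000); the out-of-basis residual is
  permuted per surrogate).  With the full basis, surrogates preserve
  Moran's I exactly up to float error because the singleton procedure
  leaves both quadratic forms of the centered map invariant.
* Empirical p-values default to the **add-one two-tailed rule**
  `(1 + #{|s| ≥ |obs|})/(n + 1)` — never zero, properly calibrated; the
  5th/95th-centile decision rule is available (`rule="centile"`) for
  fidelity with common practice.  For **discrete statistics** (gene-set
  overlap counts) the add-one p is super-uniform because of ties; an
  optional randomized tie-break (`randomize=True`, the standard
  randomized-PIT construction) yields an exactly uniform null p and is
  what the calibration diagnostics use.  Reported enrichment p-values
  remain the conservative add-one rule.
* PLS1 weights are `X'y` on z-scored columns, normalized — for a
  univariate response this is the leading singular direction of the
  cross-covariance, so no iterative solver is needed.  Bootstrap weight
  vectors are sign-aligned to the full-sample weights before the SD is
  taken.  Column z-scoring makes weights correlation-scaled and
  bootstrap ratios comparable across genes.  `explained_covariance` is
  reported as the squared correlation between scores and the response
  (for a univariate response the first component trivially carries all
  of the cross-covariance, so that fraction is uninformative).
* Gene lists: two-sided normal p from the bootstrap ratio, BH-adjusted,
  split by sign at q < 0.05, ordered by |Z|.  The BH step-up itself is
  delegated to statsmodels.
* Behavioral term selection uses **Fisher's z** of the Pearson r over
  the non-zero overlap, `z = atanh(r)·√(n−3)`, threshold |z| > 2.1
  (asymptotically P < 0.05 for the correlation); terms with < 4 overlap
  voxels are skipped since the transform's variance is undefined.
* Macroscale coupling corrects across the family {whole mask, 12
  networks} per index with BH; network-restricted inference rebuilds the
  weight matrix on the network's voxels.

## Leave-one-session-out validation and its leakage

`predictive_validation` rotates each session out, refits PLS1 on the
mean of the remaining sessions' maps, and correlates predicted scores
with the held-out map.  Because the same expression matrix serves for
training and prediction, the predicted scores are a projection of the
training map onto the column space of X; when session maps are reliable
this yields fold correlations of roughly √(G/V) · reliability even for
expression with no voxel-wise signal.  Permutation baselines must
therefore break the voxel correspondence of the held-out maps (as the
test suite does), not merely shuffle gene columns or expression rows.
At gene counts comparable to or exceeding the voxel count, a high fold
r mostly certifies session reliability, not transcriptomic specificity
— a caveat inherited by any analysis of this design.

## Problem sizes used in the checks

Pair-count identities run at 45 subjects / 4 sessions over a 6-voxel
toy; the naive-reference equivalence uses 10 voxels × 3 subjects × 2
sessions × 2 runs of 30 timepoints; variability recovery uses the
default 20 × 4 × 300 cohort; decoding recovery uses 500 voxels × 1000
genes with 20 signal genes at effect 0.8 and 500 bootstraps; surrogate
fidelity and calibration use 100-voxel maps with 199–200 surrogates and
200 replicates.  These sizes were chosen as the smallest at which each
property is sharply testable (hundreds of pairs per voxel, binomial
bands that are informative at 200 replicates) while the whole suite
runs in well under a minute of compute per module.

## Known limitations

* The additive FC-space model cannot represent heteroscedastic
  measurement noise across voxels or non-linear profile distortions.
* The variance-component scales are unitless FC perturbations; they are
  not calibrated against empirical test-retest reliabilities.
* Clipping to [−1, 1] slightly biases planted components at extreme
  parameter settings (negligible at the defaults).
* MSR surrogates preserve only second-order spatial structure; maps
  with strong anisotropy or long-range structure not captured by the
  k-NN graph are randomized more than real data would warrant.
* The permutation enrichment null resamples gene lists from the
  background universe; it does not model gene-gene co-expression, so
  its p-values are anti-conservative when the tested list is internally
  correlated with set membership beyond chance.
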