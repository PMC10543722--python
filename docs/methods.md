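# Methods

This note documents the models and conventions implemented in `msihet`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Scope and data model

The pipeline operates on three plain-text tables (see `msihet.dataio`):
ROI pixels with spatial coordinates and F intensity channels, a per-patient
clinical table (survival time in months, death indicator, ordinal stage 1–4,
age, sex), and a feature catalog (m/z per channel, optional metabolite names
and pathway / drug-pathway memberships). Vendor formats (imzML, SCiLS),
peak picking and metabolite annotation are out of scope: the pipeline starts
from already-resolved feature channels, and pathway memberships are
user-supplied annotation tables rather than live database queries.

## Normalization and segmentation

Each pixel spectrum is divided by its root-mean-square intensity computed
over **all** F channels, zero channels included (whether vendor RMS excludes
zeros is not standardized; including them is the plain reading of the
formula). Normalization is per-pixel and idempotent; an all-zero spectrum is
an error, not a silent drop.

Segmentation is plain Lloyd k-means on the normalized spectra with squared
Euclidean distance:

- distance-weighted (k-means++) random seeding, best of `n_init` restarts
  (default 10), `max_iter` 300, convergence at relative WCSS change ≤ 1e-4;
- an empty cluster is re-seeded at the pixel farthest from its assigned
  centroid, deterministically;
- the within-cluster sum of squares is recorded after every iteration, so
  monotone descent is checkable, and the final WCSS is recomputable from
  labels and centroids;
- everything is deterministic given `(seed, n_init, max_iter)`.

Cluster ids are renumbered 1..k by decreasing overall pixel share, giving a
stable reporting order (no canonical ordering exists for k-means labels).
No spatial regularization is applied: subpopulations are spectrally similar
pixels that need not be adjacent. Exact reproduction of any particular
vendor tool's partition is not attempted (initialization and convergence
settings of such tools are unpublished).

## Simpson diversity

For per-cluster pixel counts c with shares p = c/Σc, the index is the
Gini–Simpson (with-replacement) form `D = 1 − Σ p_c²` — the probability
that two pixels drawn with replacement fall in different subpopulations,
0 iff one cluster holds all pixels, maximum 1 − 1/k. This form matches the
verbal definition "probability that two randomly chosen pixels are from
different types"; the without-replacement finite-sample form
`1 − Σ c(c−1)/(N(N−1))` is available via `finite_sample=True`. Merging two
clusters can never increase D (tested on random count vectors); the index is
invariant to cluster relabelling.

The low/high heterogeneity split scans the midpoints between consecutive
sorted unique index values, excludes candidates leaving either group below
`min_group_frac` (default 0.1, preventing degenerate 1-vs-rest splits — no
published minimum rule exists), and picks the candidate minimizing the
two-sided log-rank p, ties broken toward the more balanced split and then
the smaller cutoff. Because the cutoff is data-driven, the minimal p is
optimistically biased; the result carries an explicit `optimism_warning`
and no correction is applied (consistent with the unadjusted-p convention
used throughout).

## Presence threshold grid and model selection

For threshold τ, the binary covariates 1[p_ic ≥ τ] enter **one joint** Cox
proportional-hazards model per (k, τ) (the alternative of one model per
cluster is available through `cox_presence_aic` on single-column presence
matrices). Conventions:

- Efron tie handling (ties are likely with coarse follow-up times);
- constant and collinear indicators are dropped with a note (at k = 2 the
  two indicators are complementary, so one always drops);
- AIC = 2·(number of fitted indicators) − 2·(maximized partial
  log-likelihood); with no varying indicator the null model's −2ℓ₀ is
  reported with 0 parameters;
- a row is **degenerate** when no indicator varies, when an indicator
  coincides with the event status (it then completely determines who died),
  when the likelihood is monotone (|coef| > 8 on a binary indicator — the
  MLE diverges), or when the fit fails to converge;
- the τ grid is 2 %–50 % in 1 % steps (the step is a package convention;
  only the range is standard).

Selection: admissible rows are non-degenerate with global likelihood-ratio
p < 0.05; among them the minimal AIC wins, ties toward smaller k then
smaller τ; an empty admissible set is an explicit abstention, not an error.
A "stability" criterion sometimes described for such selections is not
quantifiable and is not implemented; selection is AIC + significance +
non-degeneracy only. Note that because the per-row tests are unadjusted,
scanning 49 correlated thresholds retains a substantial family-wise
false-positive rate under a null cohort (measured ≈ 45 % at k = 5,
n = 150); abstention under the null is therefore *not* guaranteed at the
1 − α level, which is an inherent property of the unadjusted selection rule
rather than an implementation artifact.

## Membership and survival models

At the chosen τ*, a patient joins every subpopulation with p_ic ≥ τ*
(possibly several, possibly none); memberless subpopulations are listed as
excluded. Between-subpopulation survival contrasts use the counting-process
layout: one row per (patient, subpopulation) membership with the patient's
time and event repeated, cluster dummies against a reference subpopulation
(default: the largest), and a patient-clustered robust sandwich variance
with Wald tests. When every patient has exactly one membership this
reproduces the ordinary Cox fit exactly (same estimating equation). The
robust variance was verified against an explicit score-residual sandwich
computed independently (agreement ~1e-15; no small-sample correction factor
is applied by either side). Terms with fewer than two members are dropped
with a note.

The multivariate model is patient-level: indicators for subpopulations with
more than one member (a patient may switch on several; the implicit
reference state is "no retained subpopulation"), stage as dummies against
stage 1 (ordinal coding available), age in years, sex as a male indicator.
Collinear columns are dropped greedily (later columns lose) with a note.

A caveat on the counting-process layout with overlapping membership: the
row-level model assumes each row's hazard follows its own subpopulation
coefficient, which cannot hold exactly for a patient carrying two
subpopulations with different true hazards. The coverage simulation in the
test suite therefore plants overlap between prognostically equivalent
subpopulations, where the marginal model is correctly specified (this is
the Lee–Wei–Amato setting); under hazard-discordant overlap the contrast
estimate attenuates toward zero, and results should be read accordingly.

## Differential features and pathways

The test unit is the patient (pixel-level testing would pseudo-replicate
thousands of correlated pixels): intensities are averaged per patient
before any test. The volcano uses fold change of group means of these
patient means plus a two-sided Welch t-test; a feature is discriminative at
|FC| ≥ 1.5-fold and p < 0.05 (both configurable). Features whose
denominator group mean is zero are flagged and excluded from fold-change
ranking. The presentation heatmap takes the top 50 features by ascending p,
autoscales rows to zero mean / unit variance, and orders rows and columns
by Ward/Euclidean hierarchical clustering — deterministic and exported, but
purely presentational.

Feature–subpopulation association is the Pearson correlation of per-patient
feature means with per-patient presence fractions; zero-variance pairs are
flagged rather than given a fabricated r. Pathway analysis is hypergeometric
over-representation of the significantly correlated feature sets (split by
correlation sign into up/down), with the universe restricted to annotated
features; topology-based "pathway impact" scores are out of scope. A
(subpopulation, drug-action pathway) association requires at least
`min_metabolites` (default 1) significantly correlated annotated features;
the edge list carries each feature's correlation sign. Nothing is adjusted
for multiple testing, and outputs say so.

## Two-cohort comparison

Pixels of both cohorts are normalized and clustered **in one run**, so
subpopulations live on a common spectral scale. A subpopulation is present
in a cohort when ≥ `min_patients` (default 1) of its patients carry it at
≥ `tau_presence` (default 0.05); present in both ⇒ shared, in one ⇒
cohort-specific, in neither ⇒ absent. The presence rule is a convention —
no standard numeric definition of "presented in a cohort" exists — and both
knobs are configurable.

## Synthetic cohorts

`msihet.synthdata` emulates a TMA cohort at the scale of the measurement
design the pipeline targets (defaults: 72 patients × 3 cores ×
333 pixels/core ≈ 10³ ROI pixels per patient, 100 feature channels tagged
with synthetic m/z in [50, 1000], 5 true subpopulations):

- each core is a disc of lattice pixels partitioned into
  `patches_per_core` contiguous patches (nearest-seed partition of random
  seed points — simpler and deterministic compared with Gaussian random
  fields, and sufficient to mimic patchy segmentation maps); each patch
  draws one subpopulation from the patient's Dirichlet composition
  (symmetric Dirichlet(1) by default);
- subpopulation centroids sit at exact pairwise distance
  `centroid_separation × noise_sd` (orthonormal offsets from a positive
  baseline; an absolute distance when `noise_sd = 0`); pixel spectra add
  i.i.d. Gaussian noise and truncate at zero — a mild distortion at low
  SNR, negligible at the defaults;
- survival is exponential with rate
  `baseline_hazard_rate · exp(Σ_c β_c·1[composition_c ≥ τ_true])`, where
  the composition is the **realized** pixel fraction (what a perfect
  segmentation recovers); censoring is independent exponential, with the
  default censoring rate 0.023/month chosen in closed form so that ≈ 40 %
  of patients are censored at the default hazards
  (baseline 0.02/month ⇒ median ≈ 35 months; β = 1.5 on subpopulation 1 at
  τ_true = 0.20);
- ordinal stage follows a proportional-odds model whose linear predictor
  increases with the patient's true Gini–Simpson diversity (slope
  `stage_diversity_link`, default 2), so the stage-association stage of the
  pipeline has a known positive target; stage is generated from *true*
  diversity, not the estimate;
- all randomness flows from one seed; identical configs are byte-identical
  after serialization.

What the generator does **not** emulate: mass-spectral peak shapes,
isotopes, m/z drift, intensity heteroscedasticity, core-to-core batch
effects, and any calibrated amount of spatial autocorrelation (patch
granularity is a free knob — no quantitative description of within-tumor
spatial correlation was available to calibrate it). Passing recovery tests
therefore demonstrates the statistical machinery under a clean generative
model, not robustness to real acquisition artifacts.

## Problem sizes used in the test suite

Recovery experiments run at deliberately modest sizes chosen as the
package's own test design: segmentation recovery at 50 patients × 3 cores ×
200 pixels × 100 features over 10 seeds; presence-threshold recovery at
150 patients (3 × 80 pixels, 60 features, k = 5) over 20 seeds;
counting-process coverage at 300 patients × 200 replicates; cutoff recovery
at 60 patients × 50 seeds. The cutoff-recovery fixture plants a
near-deterministic effect (log-HR 3.5, light censoring): the minimal-p
cutoff search is only pinpoint-accurate when the survival split is strong,
and the fixture is meant to test the search machinery, not power at
marginal effect sizes.

## Known limitations

- The minimal-p heterogeneity cutoff and the unadjusted threshold grid both
  inflate significance; outputs flag this but do not correct it.
- The Andersen–Gill layout duplicates identical survival times within a
  patient; see the misspecification caveat above.
- k-means with Euclidean distance on RMS-normalized spectra is one
  reasonable convention among several; no claim is made that it reproduces
  any specific vendor segmentation.
- Exponential survival and censoring in the generator are chosen for
  closed-form sanity checks, not realism.
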