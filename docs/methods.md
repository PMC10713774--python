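# Methods

This note documents the models, estimators and numerical choices behind
`dmnstrat`, the assumptions they make, and what the synthetic-data tests
do and do not establish about real EEG.

## Phase-lag-index connectivity

The unit of analysis is the epoch-averaged phase lag index between two
ROI signals in one frequency band. Per epoch,

    PLI = | (1/T) Σₜ sign( sin(φᵢ(t) − φⱼ(t)) ) |,

and the reported value is the plain mean over the first 40 epochs of
8 s, always taken from the start of the recording with trailing samples
discarded, so every participant contributes the same amount of data.
`sign(0)` contributes 0: exactly zero phase difference is treated as no
lag, which is what makes the index insensitive to instantaneous
(volume-conducted) mixing.

**Filtering.** Band-pass is an order-8 Butterworth applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with doubled
attenuation. Measured on tones: a mid-band tone is preserved to well
within 5% RMS, a 10 Hz tone leaks into the neighbouring beta band (edge
12 Hz) at ≈ 0.3% RMS, and attenuation one octave outside an edge
exceeds 30 dB by a wide margin. Band edges are delta 1.5–4, theta 4–8,
alpha 8–12, beta 12–30 Hz; gamma is excluded because scalp-EEG gamma is
too easily contaminated by muscle activity.

**Phase.** The instantaneous phase is the angle of the analytic signal
(Hilbert transform), computed per epoch independently, since epochs are
the unit of the PLI estimate. The first and last 5% of samples of each
epoch are excluded from the PLI average to suppress analytic-signal edge
effects; this default lives in `pli_matrix` and the primitive
`pli_pair` applies no trimming unless asked.

**Estimator bias.** Because the absolute value is taken per epoch
before averaging, the estimator has a positive noise floor even for
completely independent signals: approximately √(2/(π·T_eff)) per epoch,
where T_eff is the number of effectively independent phase samples
(duration × bandwidth, far fewer than the sample count for narrowband
signals). For theta at the default epoching this floor is ≈ 0.1, which
is why tests compare planted-null PLI against an *empirically
calibrated* independent-signal floor rather than an i.i.d.-theory bound;
the 3/√N half-normal bound is only valid for pooled i.i.d. phases and is
asserted in that regime.

**Feature layout.** ROIs are ordered (LP_L, MPFC_L, PCC_L, LP_R,
MPFC_R, PCC_R) and the 15-entry feature vector is the row-major strict
upper triangle of the symmetric PLI matrix, so columns line up with the
conventional "L LP vs L MPFC, L LP vs L PCC, …" table layout.

**PCA-flip.** The ROI-aggregation utility returns the first
principal-component score series of the within-ROI vertex signals,
sign-flipped to correlate non-negatively with the vertex mean; when that
correlation is exactly zero (perfectly cancelling vertices) the
largest-magnitude loading is made positive — an arbitrary but
deterministic tie-break.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not EEG physics. Per band, each configured ROI pair shares a latent
narrowband Gaussian process (white noise band-passed to the target band,
unit variance); ROI i receives κ·latent + (1−κ)·independent narrowband
noise, ROI j the same with the latent's analytic signal rotated by
e^{iδ}. ROI signals sum the band components plus broadband Gaussian
noise. Expected PLI increases monotonically in κ at δ = π/2 and stays at
(or below) the independent-signal floor at δ ∈ {0, π} — zero-lag
coupling is invisible to the PLI by construction, which the generator
makes testable.

Defaults are the study design: 37 patients in planted subgroups of
19/18, 97 controls, 6 ROIs, 256 Hz, 336 s (40 epochs of 8 s plus
margin). Subgroup structure is planted in theta and beta only
(subgroup 1 κ = 0.38, subgroup 2 κ = 0.22, controls κ = 0.30 on a few
pairs, δ = π/2, with one pair per band reversed so the subgroups differ
in the coupling *pattern*, not just its overall level). Two additive
Gaussian variability terms make the cohort covariance realistic rather
than rank-1: a participant-level offset shared by all couplings
(sd 0.02 on the κ scale — globally more- or less-synchronized
individuals, the dominant subgroup-independent variance axis) and
independent per-connection jitter (sd 0.03). Both terms only perturb
connections that are coupled at all (κ > 0 stays the hard zero). The κ
gap was calibrated once against the resulting within-group spread so
the planted subgroups sit a few SDs apart in the PCA score space the
clustering actually sees — recoverable, not degenerate. Both extremes
fail: gaps an order of magnitude larger make the clusters so tight that
held-out-likelihood selection is decided by within-cluster shape detail
and wavers between K and K+1, while gaps near the spread leave recovery
to cohort luck. Delta and alpha carry group-independent coupling only,
so a correct pipeline reports no subgroups there. The sampling rate is 256 Hz rather than a
hardware-typical 2048 Hz: sufficient for bands up to 30 Hz and much
faster; configurable.

Clinical scores are independent Gaussians per variable with reference
means/SDs typical of first-episode cohorts (PANSS positive 18.2 ± 4.3,
negative 18.1 ± 7.4, general 36.8 ± 9.7; five cognitive measures with
separate patient and control means). A standardized effect d on a
variable shifts subgroup 1 by +d/2 and subgroup 2 by −d/2 reference SDs.
Default effects (negative symptoms up and positive symptoms down in
subgroup 1; slower responses, more set-shifting errors but higher verbal
IQ in subgroup 2) are illustrative magnitudes (|d| 0.4–1.0), not
calibrated to any real cohort. PANSS is patient-only; controls carry
NaN there. Values are unbounded Gaussians and may leave the natural
range of a scale (e.g. a negative error count) — harmless for the
statistics exercised here, but worth knowing.

**What passing tests show.** That the pipeline recovers structure it
should recover, stays calibrated under nulls, and matches brute-force
definitions. The generator's signals are stationary, Gaussian,
artifact-free and exactly narrowband-coupled; real EEG is none of these,
so the tests validate the *machinery*, not the claim that any particular
real cohort contains subgroups.

## PCA order selection

PCA is fitted by SVD on mean-centered features; features are *not*
variance-standardized by default since all 15 are PLI values on a common
[0, 1] scale (a flag enables z-scoring). The model-selection criterion
uses the maximized probabilistic-PCA (PPCA) log-likelihood, which for
sample-covariance eigenvalues l₁ ≥ … ≥ l_d has the closed form

    LL(k) = −n/2 [ d ln 2π + Σ_{i≤k} ln lᵢ + (d−k) ln s²_k + d ],
    s²_k = mean(l_{k+1}, …, l_d),

with free-parameter count p(k) = dk − k(k−1)/2 + 1 + d (loadings modulo
rotation, residual variance, mean). The criterion is the small-sample
corrected AIC,

    AICc(k) = −2 LL(k) + 2 p(k) + 2 p(k)(p(k)+1)/(n − p(k) − 1),

with ranks whose parameter count leaves no residual degrees of freedom
(n − p − 1 ≤ 0) excluded. Two reasons: with d = 15 the parameter count
reaches the cohort size (p(14) = 135 vs n = 134), where uncorrected AIC
is ill-posed; and plain AIC's known tendency to over-select the rank is
material at these sizes (rank-3 recovery on n = 500 improves from 77%
to 96% of seeds with the correction). Ties take the smallest k. The
closed-form likelihood is verified in tests against an explicit
multivariate-normal density built from the PPCA parameters.

Clustering uses min(k_AIC, ⌊log₂ n_patients⌋) components — the 2^d
sample-size rule for mixture models, 5 dimensions for 37 patients — with
a config flag to lift the cap.

## Stability-gated mixture subgrouping

Only patients enter the clustering; controls shape the PCA but never the
mixture. The mixture is full-covariance Gaussian, fitted by EM with λ·I
added to every component covariance at each M-step (ridge
regularization, which keeps 36-point fits well conditioned).
Initialization assigns hard responsibilities to k-means++-seeded
centers; convergence is an absolute 1e-6 tolerance on the total
log-likelihood, at most 500 iterations; K = 1 is closed-form. A
component collapse under λ = 0 raises an error advising λ > 0.

(K, λ) are selected by leave-one-out cross-validated held-out
log-likelihood over K = 1..8 and a λ grid. The default grid is
{10⁻⁵, 10⁻⁴, 10⁻³, 10⁻²} × the mean per-dimension score variance. The
reference scale deliberately stays well below the *total* variance,
which for clustered data includes the between-cluster separation: a
ridge of order 10% of total variance is large enough that over-clustered
solutions (several heavily-ridged components per true cluster) beat the
true K on held-out likelihood, which defeats recovery even at 4σ
separation.

The selection is repeated (default 50×), each repeat re-seeding the EM
initializations — the only stochastic element. (An option runs several
EM restarts per fit and keeps the best by training likelihood; the
default is a single initialization, because averaging out optimizer
noise also makes *spurious* splits more repeatable, and the stability
gate is meant to see that noise.) Ties on the held-out
score go to the smaller K (parsimony), then to the larger λ. A cluster
count is reported only when the same K wins ≥ 90% of repeats; the model
is then refitted on all patients at the modal K and the modal winning λ,
and patients are assigned by posterior responsibility (ties to the lower
index). Subgroups are renumbered by decreasing size, with the lower mean
on PC1 first on size ties — a labeling convention, not a substantive
claim. An unstable outcome carries no labels at all.

For speed, the (repeat × λ × fold) fits of one K run as a single batched
weighted-EM computation in which each held-out row enters its problem
with sample weight 0; per-problem convergence is tracked and converged
problems retire from the batch. The batched path is verified in tests to
match an explicit fold-by-fold loop over the reference single-problem EM
to 1e-9.

LOOCV held-out log-likelihood is a *density*-based criterion, not a
consistent estimator of the number of clusters: on well-separated data
it is decisive, but on one-dimensional or marginal score spaces a K+1
split of one component can tie with the true K often enough to fail
the 90% gate — which is the gate doing its job (ambiguous structure is
reported as "no stable subgroups"). The converse failure also exists:
a mixture can *stably* out-score a single Gaussian on structureless
1-D data by modeling mild skew, so a stable K = 2 in a single band and
a single cohort is evidence, not proof, of subgroups — exactly why the
pipeline validates subgroups against independent clinical data rather
than trusting the clustering alone.

## Univariate validation

Dispatch rule per variable: categorical → χ², replaced by Fisher's
exact test when any expected cell count is below 5 and the table is
2×2 (larger sparse tables keep χ² with a warning; an exact test for
r×c tables is out of scope); continuous → Welch's t if a Shapiro–Wilk
screen accepts normality (p > 0.05) in both groups, else Mann–Whitney U
(exact null for combined n ≤ 20 without ties, mid-rank/tie-corrected
normal approximation otherwise). Zero variance in both groups falls
back to Mann–Whitney with a warning; identical constant groups return
p = 1. All tests are two-sided. Benjamini–Hochberg adjustment is applied
within each (comparison, modality) family and significance is declared
at p_FDR < 0.05. Post hoc subgroup-vs-control comparisons skip
variables with fewer than two observations in a group (PANSS for
controls).

## Multivariate validation

A linear soft-margin SVM (hinge loss, L2 penalty, C = 1 by default)
predicts subgroup labels from either the three PANSS sub-scores or the
five a-priori cognitive measures. Predictors are z-scored *inside* each
leave-one-out training fold and the held-out row is transformed with
the training statistics — a leakage guard that a dedicated test
enforces by constructing an outlier whose fold-wise and whole-data
scalings disagree. Rows with any missing predictor are dropped listwise
per predictor set, with the count recorded.

Significance is the Monte Carlo permutation p: the label vector is
shuffled m = 1000 times, the full LOOCV accuracy is recomputed each
time, and p = (b+1)/(m+1) with b counting permuted accuracies ≥ the
observed one — the conservative add-one estimator, floored at 1/(m+1).
Note that LOOCV accuracy under the null is slightly *pessimistic* (the
held-out class is always under-represented in training), which is
harmless here because the permutation reference distribution has the
same property.

The SVM is solved in-package by dual coordinate descent with an
augmented, weakly regularized bias (the liblinear formulation), run as
one batched computation over all (permutation, fold) problems; with
z-scored predictors the difference from an unregularized intercept is
negligible, and tests cross-check weights and predictions against an
independent reference solver. The weight vector reported for
interpretation comes from a fit on all rows of z-scored data; a positive
weight pushes the decision toward the higher-numbered subgroup.

## Orchestration and reproducibility

`RunConfig` holds every stage parameter; defaults are the study design
(8-s epochs, first 40; K = 1..8; 50 repeats; 90% stability; 1000
permutations; α = 0.05). All randomness flows from one master seed:
per-band clustering seeds and per-(band, predictor-set) permutation
seeds are derived by hashing the master seed with the stage name, so
runs are reproducible and stages are independent. Reports serialize
deterministically (sorted JSON keys); identical config + seed reproduce
the report byte-for-byte apart from the wall-clock field. A band whose
cluster solution is unstable, or stabilizes at K = 1, is reported as
"no stable subgroups" and skips validation; an error in one band is
caught and reported without aborting the others.

Problem sizes in the shipped tests and acceptance script are reduced
relative to the full design where the statistics allow it — e.g. 20
selection repeats instead of 50, K up to 6 instead of 8 in the
end-to-end run, two-decade λ grids in recovery tests — keeping each
suite's power for the property it checks while a complete run stays in
the minutes range on one core. The acceptance script states its grid in
its docstring and reports only quantities it computed in that run.

## Known limitations

- The generator's coupling model is pairwise and stationary; it cannot
  emulate cross-frequency coupling, nonstationarity, artifacts, or
  realistic source leakage beyond the zero-lag common-source case.
- The AICc-on-PPCA criterion is one defensible choice among several;
  with other formulations the selected k can differ by ±1 at cohort
  sizes, and nothing downstream assumes a particular k beyond the 2^d
  cap.
- Fisher's exact substitution is limited to 2×2 tables.
- LOOCV held-out likelihood selects the best *density* model; it is not
  a consistency-guaranteed estimator of the number of clusters, which
  is exactly why the stability gate exists.
- The clinical simulator draws independent Gaussians; correlated
  clinical profiles (which real PANSS items have) would make the
  multivariate validation harder than these tests suggest.
- At the design sample size (37 patients), whether a planted
  two-subgroup structure passes the 90% stability gate varies from one
  simulated cohort to the next: the per-repeat win rate of the true K
  sits near the gate, so some cohorts report recovery and others
  honestly report no stable subgroups. This mirrors the band-to-band
  variability the gate is designed to expose, and it is reported, not
  tuned away.
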