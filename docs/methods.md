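# Methods

## Strain definition and thresholds

Strain identity is defined operationally per SGB from the two empirical
distributions of normalized phylogenetic distances: related pairs (the
same recipient's pre/post samples, and donor/post pairs within a triad —
donor strains may replace native ones, which is what makes those pairs
informative) versus unrelated pairs (samples from different subjects with
no transplantation link). Distances are patristic distances on the SGB's
marker tree divided by the tree's total branch length; this normalizer is
recorded in each `DistanceSet`, and precomputed matrices are accepted as
already normalized. Profiles with fewer than 20 markers are dropped
(inclusive boundary: exactly 20 is kept), and when a sample × marker
presence table is supplied, markers present in at least 50% of retained
samples are kept (inclusive) before the sample filter is re-applied.

With at least `min_related = 50` related pairs the threshold is the
smaller — i.e. the more conservative with respect to declaring sharing —
of (a) the Youden-optimal cut for the classifier "related ⇔ d ≤ t" and
(b) the 5th percentile of the unrelated distances. With fewer related
pairs it is the 3rd percentile of the unrelated distances. Choices fixed
here because they are not forced by the definition:

* **Percentile convention** — linear interpolation between order
  statistics (`numpy.percentile` default). The interpolated percentile is
  slightly biased in small samples (the expected mass below the estimated
  3rd percentile is ≈ (k+γ)/(n+1), e.g. ≈ 3.2% at n = 500 unrelated
  pairs); at the cohort-scale pools of thousands of unrelated pairs per
  SGB the bias is negligible, which is what the calibration experiment
  measures.
* **Youden candidates** — the observed distances themselves. Because the
  sharing boundary is inclusive, J(t) changes only at observed values, so
  this scan attains the global maximum; ties break toward the smallest
  threshold. A property test checks agreement of max J with an exhaustive
  midpoint scan.
* **"50 related"** is counted in *pairs* passing filters; the count used
  is stored with each threshold row.
* **Donor–pre pairs within a triad** carry no transplant link and are
  placed in the unrelated set.
* **Sharing boundary** is inclusive (d ≤ t); ties at the threshold count
  as shared.
* Extra baseline-only samples (e.g. an external cohort added to enlarge
  the unrelated pool) enter the metadata table as donor-role rows that no
  recipient references. SGBs with no unrelated pairs, or fewer than two
  filtered samples, are flagged not estimable and excluded downstream.

## Origin assignment

For each (SGB, triad) with the SGB present post-FMT: shared only with the
donor → `donor` (or `novel_donor` when the SGB was absent pre-FMT — the
niche-filling pattern); shared only with pre-FMT → `recipient`; shared
with both → the side with the smaller distance; an exact distance tie goes
to the recipient (conservative against declaring engraftment — the tie is
a measure-zero event under continuous distances and the choice is
recorded here for reproducibility). Shared with neither →
`retained_unshared`, flagged *de novo* when neither donor nor pre-FMT
carried the SGB. Engraftment = origin ∈ {donor, novel_donor}.

## Cohort metrics

The strain-sharing rate divides shared strains by the SGBs strain-profiled
in both samples; the post-anchored fractions divide by the strains
profiled post-FMT, so f_donor + f_pre can exceed 1 (a strain shared with
both sides counts in both numerators). The dissimilarity model is OLS of
D = 1 − shared/max-shared on sample type (pre/post), true-donor status and
their interaction; the interaction coefficient is the quantity of
interest (the sample-type main effect alone cannot express "post samples
are specifically closer to *their own* donor"). A main-effects-only model
is available via `interaction=False`. The default pair universe is
recipient-sample × donor-sample within one sub-study, matching per-sub-study
reporting; cross-sub-study universes are a caller choice. Abundance
comparisons for engrafted strains use the paired two-sided Wilcoxon
signed-rank test (robust on compositional fractions; the exact null is
used at small n), and engraftment patterns are classified as novel
(pre-absent), expansion (significant abundance increase among engrafted
recipients at α = 0.05), or replacement. Sharing networks use squared
shared-strain counts as edge weights and a seeded Fruchterman–Reingold
layout.

## Regularized CCA and pair selection

Columns of both matrices are centered and scaled (unit variance, ddof 1);
zero-variance columns are dropped with a warning and rows incomplete in
either matrix are removed. Directions come from the SVD of
(Cxx + λ₁I)^(−1/2) Cxy (Cyy + λ₂I)^(−1/2); an eigenvalue floor of 1e-12
guards the inverse square roots. Reported canonical correlations are the
Pearson correlations of the variates (signs aligned non-negative); the
singular values — the penalized canonical correlations that solve the
generalized eigenproblem — are kept separately and are what the oracle
test compares.

Tuning is leave-one-out over a grid of 21 log-spaced penalties in
[1e-4, 1] per axis (overridable). Each held-out subject is standardized
with the training fold's parameters and scored on the training fold's
first pair of directions; loading signs follow a deterministic convention
(largest-|entry| of the X direction positive) so pooled scores are
comparable across folds. The pooled score correlation selects the grid
point, ties toward larger penalties (more shrinkage under equal CV
score). Degenerate folds score −inf.

Correlation-circle coordinates are each feature's correlations with the
first two canonical variates of its own dataset; constant features sit at
the origin. The outer-ring radius defaults to 0.5 (the usual inner/outer
ring convention; exposed in config). Pair selection scores cross-dataset
pairs only, by |c1ˣc1ʸ + c2ˣc2ʸ|, keeping the top 10.

## Mixed model and Satterthwaite df

The confirmatory model per (SGB, clinical parameter) pair is a
random-intercept model, value ~ engrafted + time + engrafted:time +
(1 | subject), fitted by REML. The implementation profiles the criterion
over the variance ratio φ = τ²/σ² (closed Woodbury forms per subject
block; the residual variance has a closed form at fixed φ), which is
exact for this single-random-effect structure and fast enough for
thousand-replicate calibration. Degrees of freedom use Satterthwaite's
two-moment formula df = 2C²/(gᵀAg), with C the coefficient's variance, g
its finite-difference gradient in (σ², τ²) and A twice the inverse
finite-difference Hessian of the −2·REML criterion. On balanced complete
noiseless data the interaction estimate reduces to the
difference-in-differences of cell means (tested to 1e-8); on noisy data
the coefficients and variance components match an independent REML
implementation to numerical precision, and the interaction test's type-I
error is calibrated by simulation (1000 nulls). Groups with fewer than 2
subjects per engraftment arm are reported untestable. FDR is
Benjamini–Hochberg.

## Metabolites, correlations, Procrustes, multilevel split

Metabolite preprocessing imputes missing cells with half the lowest
observed value of that metabolite (distinguishing below-detection from
the lowest measured intensity), then scales the column by its median —
impute *then* scale, so imputed values influence the median. A fixed-point
rescale (at most 5 divisions) makes the output median bitwise 1.0 even
for even-length columns, where a single division can leave the median at
1 ± 1 ulp. All-missing metabolites are dropped with a warning.

Spearman links use pairwise-complete observations; below 10 pairs the
p-value is an exact permutation enumeration over all pairings of ranks,
otherwise the usual t approximation.

The Procrustes association reduces each subject × feature matrix to its
Euclidean principal coordinates (2 by default — the ordination fed to the
superposition is a package choice, as only "an ordination" is implied by
the procedure), centers and unit-norms both configurations, and takes
m² = 1 − (Σ singular values)² after the optimal rotation/scaling. The
permutation p-value uses 999 random row permutations of the second
configuration: p = (1 + #{m²perm ≤ m²obs})/(1 + 999), so the smallest
attainable p is 1/1000.

The multilevel split decomposes repeated measures into subject means
(between) and deviations from them (within); between + within
reconstructs the input exactly, and PCA of the within part isolates the
pre → post variation. Single-observation subjects get an all-zero within
row and are flagged. Only the decomposition (plus downstream PCA) is
provided; the choice of test against an outcome is left to the caller, as
no single convention exists.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the *structure* that the methods rely on:
triads across sub-studies (29/3 by default) with donors assigned
round-robin so several recipients share a donor; per-SGB bimodal distance
distributions — truncated normals at (0.01, 0.005) for same-strain and
(0.30, 0.10) for different-strain pairs, values chosen so the two modes
are well separated on the normalized-distance scale as in real
strain-profiling data; SGB presence/absence (donor 0.9, pre-FMT 0.8) so
novel engraftment occurs in recipients without a native strain;
per-SGB engraftment probability 0.35 (retention dominating engraftment,
as observed in non-infectious indications); a block of 10 recipients of
one sub-study with missing diastolic blood pressure (so integrations on
that parameter use 19 complete cases); marker counts of 25–150; and a
planted effect chain — engraftment of SGB0001 shifts diastolic blood
pressure by −16 mmHg and plasma 2-oxoarginine by −0.4, SGB0002 shifts
4-guanidinobutanoate by −0.3 — against clinical noise of 4 mmHg
(diastolic) and parameter-scaled noise otherwise. Randomness comes from
per-SGB sub-streams spawned deterministically from the run seed, so
enlarging the panel does not reshuffle earlier SGBs, and fixtures are
byte-identical across runs at the same seed.

Deliberately *not* emulated: sequence evolution and read-level noise
(distances are drawn, not computed from trees); cross-pair metric
consistency (two recipients of the same donor both carry its strain yet
their mutual distance is drawn from the different-strain mode);
compositional coupling between abundance and engraftment beyond the
novel-niche rule; batch effects and covariate structure in the clinical
and metabolite tables. Passing tests therefore demonstrate that the
*inference chain* is correct and calibrated under its own assumptions,
not that those assumptions hold in any particular real cohort.

## Validation experiments (sizes are package choices)

* Threshold calibration: 500 SGBs, 30 related / 4000 training unrelated
  pairs each, 200 held-out unrelated pairs each; pooled false-sharing
  rate compared with 3% at the binomial 95% CI.
* Youden boundary: 50 separable SGBs; the threshold must land in the gap
  between the distance modes.
* Engraftment recovery: 29 triads × 50 SGBs with zero-variance modes;
  exact equality with ground truth.
* rCCA oracle: 100 random 20×5/5 instances with uniform random penalties;
  agreement with a generalized-eigenvalue solve to 1e-8.
* Pair selection: 200 replicates at 19 subjects, 15 SGBs, 6 clinical
  parameters, planted −16 mmHg / 4 mmHg-noise effect (4 within-group SD);
  ≥90% top-10 recovery. Recovery is monotone in effect size and falls to
  ≈80% at a 1.5 SD effect with these feature counts — an intrinsic limit
  of ranking 90 candidate pairs at n = 19, not an implementation one.
* LMM: difference-in-differences identity to 1e-8; type-I error in
  [0.03, 0.07] over 1000 nulls at 29 subjects; ±2 SE coverage ≥ 93%.
* Procrustes: rotated copy → m² < 1e-10, p = 1/1000; independent inputs →
  approximately uniform p over 100 replicates.

## Known limitations

* The Satterthwaite implementation covers the random-intercept structure
  the pipeline uses, not arbitrary random-effect designs.
* Leave-one-out tuning refits the full grid per fold; for much larger
  panels a warm-started or coarser grid would be preferable.
* The dissimilarity model treats pairs as independent observations; pairs
  sharing a sample are correlated, so its p-values are anti-conservative
  and the coefficient (not the test) is the primary readout.
* `novel` classification takes abundance 0 (below the profiler's
  detection) as absence; low-abundance native strains below detection are
  indistinguishable from true absence.
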