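# Methods

This note documents the models and procedures implemented in `hemiconn`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Synthetic cohort model

No public generative model exists for the kind of cohort this analysis
targets, so the generator's defaults are explicit stand-ins anchored to
study-design quantities: a ~90% dextral population with a J-shaped EHI
distribution, hemispheric asymmetry concentrated in the
language↔default-mode (LN–DMN), language↔frontoparietal (LN–FPN) and
within-DMN network blocks, and asymmetry magnitude that increases with EHI
up to a breakpoint at EHI = 75 and is flat above it.  All defaults were
fixed before any downstream result was computed and are not tuned.

**EHI.** A two-component mixture: with probability `dextral_mass` (default
0.90) a truncated normal on (0, 100] centred at +80 (SD 18); otherwise a
broad truncated normal on [−100, 0] centred at −40 (SD 55).  Truncating
the components at 0 makes the expected dextral fraction equal the mass
parameter exactly, and the high-positive mode gives the J shape.
Handedness is dextral iff EHI > 0.

**Covariance.** Each hemisphere's parcel correlation matrix is
`Z B Zᵀ` with unit diagonal, where `Z` is the parcel→network indicator
and `B` a network-level Gram matrix (within-network correlation 0.35 on
the diagonal, 0.10 between networks).  Positive definiteness is
structural: the matrix equals a network-factor model plus a positive
diagonal, and `B` is checked for positive semidefiniteness at
construction (a low-rank `W Wᵀ + D` form with `W = Z chol(B)`).  For the
left hemisphere, each network pair named in the asymmetry map gets
`offset × s(EHI)` added to its block of `B` (defaults: +0.15 on LN–DMN
and LN–FPN, +0.10 within-DMN; Fisher-Z-scale correlation units).  Offsets
never touch raw matrix entries, so infeasible requests fail loudly rather
than producing a non-PD matrix.

**EHI→asymmetry link.** The piecewise-linear distance model
`raw(e) = 0.01·min(e, 75) + 0·max(e − 75, 0)` serves two roles: rescaled
to [0, 1] over the EHI range it is the (noiseless) asymmetry scale
`s(EHI)` used by the covariance builder, and `8.0 + raw(e) + N(0, 2.0²)`
is the direct EHI→distance sampler used in breakpoint-recovery
simulations (noise SD in distance units).  The default slope/noise encode
a deliberately *weak* effect — more sinistral individuals have only
somewhat more similar hemispheres — which matters for test design (below).

**Timeseries.** `T` (default 300) i.i.d. Gaussian samples via the
Cholesky factor.  Real BOLD autocorrelation, motion, physiological noise
and spatial geometry are *not* modelled; a passing test on these cohorts
shows the statistical machinery recovers what was planted, not that real
acquisitions carry such signal.  Default parcel counts follow a fixed
proportional allocation over the eight kept networks.

Determinism: the cohort seed feeds a `SeedSequence` that spawns one
stream for EHI and one per subject, so identical specs give byte-identical
cohorts and partial reruns match full runs.

## Feature conventions

Hemiconnectome features are the upper triangle (row-major, i < j) of the
within-hemisphere block, ordered identically for both hemispheres by
parcel index, so homologous connections share a feature index and LDA
scalings are comparable across runs.  The transconnectome excludes
homotopic pairs; the full connectome is the concatenation
HC-LH ‖ HC-RH ‖ TC, which at P = 180 yields 2·16,110 + (180² − 180) =
64,440 features.  Fisher-Z clips |r| at 1 − 1e−7 before atanh so unit
correlations stay finite without dropping data.  When homologous parcels
carry different network labels, both take the LH label; network merge and
drop rules (default: merge the two visual networks, drop the three
smallest networks) affect only enrichment grouping — dropped-network
parcels remain in every feature vector.

## Classification

Folds are built over subjects, stratified on handedness, so the two
hemisphere samples of a subject can never straddle a train/test split
(identity leakage).  LDA uses raw features, keeping its scalings
interpretable; SVC (linear kernel, suited to p ≫ n) and the
single-hidden-layer MLP standardize per feature on the training folds.
No hyperparameter search is performed.  Minority oversampling duplicates
rows with replacement until class counts match the majority; the
size-matched control subsamples training subjects to the size of the
minority cohort's training portion (e.g. 74 = ⅘ × 92).

MCC is computed from the confusion matrix with the convention that any
zero denominator factor yields 0 (so an all-majority classifier on a
90/10 split scores accuracy 0.90 but MCC 0); multiclass matrices use the
generalized covariance form, and four-way outcomes are reported after
decomposition into the chirality and handedness binary problems.  The
reported MCC is the mean of 1,000 joint bootstrap resamples of
(truth, prediction) pairs, with the 2.5th/97.5th percentiles as the CI;
degenerate replicates score 0 rather than being dropped.  The
`mcc_accuracy_calibration` simulation (per-class correct counts binomial,
errors spread uniformly over other classes — the allocation rule is a
parameter) grounds the MCC 0.4/0.6 ↔ 80%/90% per-class-accuracy
benchmarks at 875/92 class sizes.

## Enrichment

Stage 1 refits the LDA on hemisphere labels shuffled *within each
subject's pair of samples* — the shuffle unit is a documented choice; a
row-wise shuffle would break the two-samples-per-subject structure.  Each
feature's two-sided rank-proportion p is floored at 3/reps (at 10,000
reps, .0003), and the floor is a clamp: no reported p, including values
of 1/reps or 2/reps, falls below it.  Connections with p < .01 form the
mask.  Stage 2 shuffles the mask's significant flags uniformly over the
grouped upper-triangle positions (mirroring back onto the matrix keeps it
symmetric by construction) and tests each of the k(k+1)/2 network groups
one-sided for more significant connections than chance, followed by
Benjamini–Hochberg FDR.  LD1 is oriented so the LH class mean is
negative; positive scalings then read RH > LH.  Scalings are reported as
model scalings, not "feature importance" — a connection with a small
between-hemisphere difference can carry a large scaling.

A practical power note: the group-level p floor interacts with FDR.  With
36 groups and three enriched groups at the floor, adjusted values are
`floor × 36/3`; at 500 permutations (floor .006) that is .072, so
reduced-scale enrichment runs use 1,000 permutations (floor .003 →
adjusted .036) to leave the FDR threshold reachable.

Calibration of the group test is checked against an exact oracle: under
the uniform position shuffle, a group's significant-connection count is
hypergeometric, so the attainable rejection level of the discrete test at
nominal .05 (and the Monte-Carlo smoothing from 500-rep empirical
p-values) has a closed form.  On null cohorts the observed rejection
fraction is required to stay below the nominal binomial upper bound
(no inflation) and to match binomial bounds around that attainable level;
the attainable level is strictly below .05 at reduced scale because
counts are small integers — a property of any valid permutation test,
not of this implementation.

## Hemisphere space

LD1 scores come from the maximal model (trained on the full sample; the
four-way model's first discriminant in the handedness analysis), oriented
LH-negative.  LD1_dist = |LD1_LH| + |LD1_RH| is symmetric in the
hemispheres and invariant to the global LDA sign flip.  Z(LD1) uses the
sample (n − 1) SD within each hemisphere group; in group comparisons the
LH z-scores are sign-flipped so positive always means "farther out on the
hemisphere's own side".  The two-group comparison is a one-way ANOVA
(equal to the squared two-sample t, asserted in tests).

Segmented regression uses the continuous hinge basis `max(x − b, 0)`; the
breakpoint is profiled over a 50-point interior grid (5th–95th
percentiles) with golden-section refinement, and estimates at the search
boundary are flagged.  Breakpoint SEs come from a nonparametric bootstrap
(500 replicates by default).  Nested F-tests count coefficients plus
estimated breakpoints as parameters (linear 2, one-breakpoint 4,
two-breakpoint 6); AIC uses the Gaussian log-likelihood with the same
parameter counts, matching the statsmodels OLS convention for the
non-segmented fits.  The quadratic fit reports its vertex only together
with a sign check that the parabola opens downward.

Because the default EHI→distance effect is weak (slope .01/EHI-unit
against noise SD 2.0), single-cohort breakpoint estimates have wide
bootstrap SEs, and AIC model selection between linear and one-breakpoint
fits stabilises only at large simulated samples; the model-selection
consistency test therefore runs at n = 20,000 draws from the distance
sampler (cheap, as no timeseries are involved), while breakpoint recovery
is demonstrated at n = 900 within two bootstrap SEs.

## Scales used by the test suite

Reduced-scale study conditions, chosen as desk-scale defaults: the main
cohort is n = 200 subjects, P = 40 parcels per hemisphere, T = 300
timepoints (`CohortSpec.desk_scale()`); enrichment recovery uses 20
cohorts of 40 dextral subjects at P = 40 with 1,000 permutations; type-I
calibration uses 50 null cohorts of 24 subjects at P = 20 (four networks)
with 500 permutations; bootstrap-CI coverage uses 200 simulated
experiments.  The full 10,000-permutation, 16,110-feature refits are
supported but long-running.

## Known limitations

- Gaussian i.i.d. timeseries: no temporal autocorrelation, so Fisher-Z
  noise at a given T is optimistic relative to real BOLD.
- Constant-block covariances: within-block connectivity is homogeneous,
  unlike real connectomes; enrichment recovery is correspondingly cleaner.
- Handedness affects connectivity only through the EHI-scaled asymmetry
  magnitude; the generator plants no handedness-specific topology, which
  is precisely why handedness classification fails on these cohorts.
- Exact SVC/MLP configurations are library defaults (linear kernel, one
  hidden layer of 100 units, max 500 iterations) and are surfaced in
  `classify.build_model`.
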