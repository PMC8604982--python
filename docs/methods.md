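# Methods

This note documents the models, parameter choices and numerical decisions
behind `semadapt`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and shape

The package chains five stages — simulate → index → select → design →
analyze — as plain functions over pandas tables, NIfTI volumes and small
dataclass configs, orchestrated by `semadapt.pipeline` with one global seed
split into per-stage SHA-256 substreams (`semadapt._seed.stage_seed`). All
tabular I/O is schema-validated TSV; atlas volumes are NIfTI-1 via nibabel.

## Literature indexing

**Coordinate spaces.** Foci are millimetre coordinates in RAS+ MNI space;
Talairach-reported foci are converted with the Brett piecewise-affine
transform: a 0.05 rad rotation about x composed with zooms
diag(0.99, 0.97, 0.92) for z ≥ 0 and diag(0.99, 0.97, 0.84) for z < 0,
inverted for the Talairach → MNI direction. The branch is chosen on the input
z, so the forward and inverse maps are exact inverses away from the z = 0
plane and the transform is continuous but only approximately invertible on
it — the standard behavior of this transform.

**Focus merging.** Published contrasts often report several nearby peaks for
one activation. Within a contrast, foci are merged by single-linkage
clustering at a 10 mm Euclidean threshold and each cluster is replaced by its
componentwise mean; foci farther apart stay separate. Single linkage and
centroid replacement were chosen because the merging rule is stated only as a
distance criterion; foci are processed in lexicographic coordinate order so
the output is order-invariant and deterministic.

**Region formation.** Two modes exist. In the default *median* mode all foci
are clustered spatially (same 10 mm single linkage), each cluster's
componentwise median is assigned to an atlas parcel, and clusters landing in
the same parcel are collapsed; in *focus* mode every focus is assigned to a
parcel directly. Atlas lookup rounds the mm coordinate to the nearest voxel
via the image affine; a background hit is resolved to the nearest nonzero
label within a 6 mm search radius, otherwise the focus is reported as
unassigned (never silently dropped).

**Indexes.** Correction levels are coded voxel = 1, cluster = 0.5,
uncorrected = −1; contrasts with unknown correction are excluded from the
mean rather than coded, because no defensible numeric value exists for them.
Contrast classes are coded concrete semantic = 1, abstract semantic = 0.5,
control = −1. Both region indexes are plain means, hence bounded in [−1, 1]
with the bounds attained only by unanimous codes.

## Database indexing

The heterogeneity weight of a region active in `n_micro` of the taxonomy's
micro-domains and `n_macro` of its macro-domains is

    W = (n_micro/total_micro + n_macro/total_macro) / n_domains_region

where `n_domains_region` defaults to the region's own `n_micro + n_macro`
(an externally supplied count is accepted — the denominator's referent is
genuinely ambiguous, so both readings are available). The packaged default
taxonomy has 5 macro-domains (Action, Cognition, Emotion, Interoception,
Perception) with 6 micro-domains each (30 total); any two-column
micro→macro table can be substituted. Domain specificity is W × P per
domain, with P a user-supplied activation likelihood in [0, 1]; the
region-level summary is the maximum over the region's domains (most
selective), with the mean available as an option. Paradigm control types are
coded semantic = 1, mixed = 0.5, control = −1 and averaged into the
control-type mean.

## ROI selection

A candidate is classified semantic if its control-type mean exceeds 0.6 and
control if below −0.6 (strict inequalities; exact ±0.6 is excluded). The
secondary criteria are configurable filters with defaults: |semantic-control
differential| ≤ 0.5, domain specificity at or above the 0.5 quantile among
candidates passing the control-type gate, and sign concordance of the
sensitivity index with the candidate class. The specificity quantile is
computed on the gate-passing pool only, which keeps selection monotone:
loosening any one threshold can never shrink the selected set. The
correction-level index is carried through and reported; an optional hard
floor on it exists but is off by default, since the index's purpose is to
privilege stringent analyses, not to define a cut. Every exclusion is
recorded with its reasons in an audit table.

## Stimulus design

The default lexicon mirrors the study conditions: four abstract categories
(emotions, cognitions, attitudes, human actions) × 24 nouns and two concrete
categories (biological entities, artefacts) × 48 nouns, plus 6 + 6 held-out
baseline words per domain. Ten attributes (concreteness, imageability,
familiarity, age of acquisition, context availability, abstractness, mode of
acquisition, letter count, written and spoken log-frequency) are drawn from
identical distributions for all categories of a domain.

**Matching emulation.** A raw-p floor over dozens of pairwise tests is
essentially never satisfied by independent draws (with ~70 tests at a 0.055
floor the all-pass probability is below 2%), yet real stimulus sets *are*
matched — because experimenters select items until they are. The generator
reproduces that workflow: each (domain, attribute) is redrawn until all
pairwise Welch p-values exceed a 0.06 floor, and `matched_design` retries
deterministic sub-seeded pairings until the full report — including
relatedness homogeneity of the realized Same/Different-Category pairings —
passes (floors 0.055 abstract / 0.056 concrete). Consequently a passing
matching report certifies the construction procedure, not an unconditional
statistical property of random word samples.

**Pairs and runs.** Within each domain, each category's words are split once
into prime and target halves (primes and targets never swap roles), and each
half again into Same-Category and Different-Category uses — so per-category
counts must be divisible by 4. Different-Category targets come from another
category of the same domain via a seeded cyclic shift; abstract and concrete
words never share a pair. Runs hold 54 trials (24 + 24 + 6, half abstract)
with fixed event timing (1 s fixation, 0.5 s prime, 0.4 s blank, 0.5 s
target) and inter-trial intervals uniform on {3, 5, 7} s. Orders are
pseudo-randomized with at most three consecutive same-condition trials
(rejection sampling with a greedy fallback); the cap of three is this
package's choice of what "pseudo-randomized" enforces.

## BOLD simulation

`gen_bold` draws one beta per subject × ROI × condition cell:

    beta = grand_mean + subject_intercept + condition_shift
           + planted_adaptation + noise

Defaults: grand mean 12 000, Same/Different-Category shifts +1 500/+1 800,
residual SD 1 000, subject SD 100 (near-zero between-subject variability),
all in arbitrary BOLD units on the scale of first-level beta estimates; the
planted adaptation map moves Same-Category cells of designated
(ROI, category) pairs toward the baseline by −2 750…−3 400 units, emulating
selective adaptation of an anterior middle temporal region by
emotion/attitude words and of an anterior fusiform region by concrete words.
These magnitudes reproduce the contrast scale (~10³ units) qualitatively;
no quantitative effect sizes in raw beta units were available to calibrate
against. Noise is Gaussian everywhere — the simplest model consistent with a
linear analysis. The voxel-level variant emits rank-1 matrices
(positive voxel loadings × cell betas) plus independent voxel noise, making
the first singular component identifiable. What the generator does *not*
emulate: hemodynamics, HRF convolution, scanner noise spectra, motion — so
passing tests certify the statistical pipeline, not robustness to realistic
fMRI artifacts.

Two structural facts matter downstream. First, the subject intercept is
shared by every cell, so it cancels exactly in baseline-subtracted
contrasts; fitted ICCs on `gen_bold` output are therefore small regardless
of the planted subject SD. Second, all contrasts of a (subject, ROI, domain)
block subtract the *same* Same-Word draw, which induces a positive
within-block residual correlation and a small structural floor (~0.05–0.1 at
test scale) on the fitted ICC. For clean parameter-recovery studies the
package therefore provides `gen_lmm_contrasts`, which draws contrast values
directly from the mixed model (subject intercept variance = icc · total
variance, independent residuals, optional fixed cell effects).

## Adaptation analysis

**Eigenvariate.** For a voxels × observations matrix Y (optionally divided
by its grand mean first — the "grand_mean" scaling mode), the summary is
s₁·v₁/√n_voxels from the SVD: the first right singular vector scaled to the
amplitude of an average voxel, so an ROI of identical voxels returns exactly
their common series. The sign is aligned with the across-voxel mean series
(tie-broken by the uncentered projection). Degenerate inputs (all-zero, rank
0 after scaling, single observation) raise.

**Contrasts.** Same-Category and Different-Category values minus the
domain's Same-Word baseline, per subject and ROI, at category granularity,
with domain-level rows as within-domain means. Missing baseline cells raise
with the offending cell named.

**Mixed model.** `value ~ C(condition) * C(domain) * C(roi)` with a
participant random intercept, REML, via statsmodels MixedLM (default
optimizer, falling back to L-BFGS and Powell on linear-algebra failures).
Reported: joint Wald χ² tests for all seven factorial terms,
ICC = σ²_subject/(σ²_subject + σ²_residual), and a Wald Z for the subject
variance using the balanced-design asymptotic SE
√(2/n)·(σ²_u + σ²_e/k̄) — computed in closed form because the SE statsmodels
exposes for the variance parameter is on an internal scale (verified against
the empirical sampling SD in simulation). Boundary (zero) variance estimates
are expected under the near-zero between-subject design and are not treated
as failures. Empty factorial cells raise before fitting.

**ROI-specific interaction probe.** The omnibus 25-df Wald test of the
three-way term dilutes a one-ROI effect across the whole interaction
subspace and has roughly 70–85% power at an effect of one residual SD in a
single ROI (n = 36, 26 ROIs). Localized inference therefore follows the
probe logic: per (condition, ROI) cell a paired t-test between domains,
Bonferroni-corrected over the full family (conditions × ROIs). This is the
package's primary report of where a CONDITION × DOMAIN × ROI effect lives;
the omnibus test is reported alongside.

**Post hocs and flags.** Within a (ROI, domain), categories are compared by
one-way ANOVA (> 2 levels) or a paired t-test (2 levels), followed by all
pairwise paired t-tests with Bonferroni adjustment (family size recorded per
row), 95% confidence intervals, and Cohen's d = mean difference / pooled SD
of the two cells. A (ROI, category) cell is flagged *adapted* when its
Same-Category − Same-Word confidence interval excludes zero and its mean is
either negative or strictly the lowest among the domain's categories in that
ROI — the relative reading ("lowest signal increase from baseline") used for
interpreting adaptation, with the sign condition preventing a lone positive
(enhancement) cell from being flagged.

## Problem sizes used in validation

Simulation-based checks run at the study's scale where that is cheap
(36 subjects, 26 ROIs for ICC recovery — 50 replicates per planted fraction
{0, 0.006, 0.1, 0.3}, at domain granularity — and 100 simulations for
planted-effect detection) and at reduced scale for routine unit tests
(e.g. 12–20 subjects, 4–8 ROIs for the omnibus-test power check at a
stronger 1.5 SD effect). Each test states its own sizes.

## Known limitations

- The exact membership of the study's 15 + 11 ROI set is not reproducible:
  it depends on unreleased literature and database tables; the selection
  rule's secondary criteria ("highest specificity", "lowest differential")
  are exposed as thresholds rather than claimed to replicate that list.
- Matching verification certifies the generator's selection procedure (see
  above), not a property of unselected word norms.
- The mixed model assumes a single random intercept; random slopes and
  richer covariance structures (e.g. the within-block correlation induced by
  a shared baseline) are not modeled.
- The Brett transform is itself an approximation between template spaces;
  sub-millimetre agreement is asserted against the published matrices, not
  against anatomy.
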