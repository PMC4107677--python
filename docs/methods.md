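# Methods

This note documents the statistical model the package implements, the
synthetic-data model used to exercise it, the numerical choices that were
genuinely open, and what the package's tests do and do not establish.

## Per-subject signal conditioning

The per-subject chain runs in a fixed order: volume discard → spatial
smoothing → nuisance regression → band-pass. Reordering changes results
(band-passing before regression, for instance, reintroduces out-of-band
nuisance variance), so the orchestrator does not expose the order as a knob.

**Volume discard.** The first `n_discard` volumes (default 4) are dropped to
avoid T1 saturation; the motion table is truncated identically.

**Smoothing.** Separable Gaussian per volume, per-axis
`sigma_vox = fwhm_mm / (sqrt(8 ln 2) · voxel_size_mm)` (default FWHM 5 mm →
sigma ≈ 0.685 voxels at 3.1 mm). Boundary handling is reflect padding, which
preserves local means near the edges of the small synthetic grids; on a
whole-brain field of view surrounded by air the choice is immaterial.

**Nuisance model.** Sixteen nominal columns: intercept, the six realignment
parameters, their backward-difference derivatives (first element 0, the
usual realignment-derivative convention), and the GM/WM/CSF mean series
(averaging, per time point, over all voxels of the tissue class; tissue
means are computed from the smoothed, discard-truncated series that is
passed forward). Non-intercept columns are mean-centered; constant columns
(e.g. the derivative of a constant motion parameter) are dropped with a
warning, and a design still rank-deficient after dropping raises. Each voxel
series is replaced by its least-squares residual; because the intercept
stays in the design, residuals are mean-zero and orthogonal to every
retained column. The nuisance regressors are *not* themselves band-passed;
filtering follows regression. This matches the stated processing order of
the protocol the pipeline reproduces, without claiming equivalence to any
particular toolbox's internals.

**Band-pass.** An ideal DFT mask: coefficients with `low ≤ f ≤ high`
(default 0.01–0.08 Hz) are kept at unit gain, all others — including DC —
are zeroed, and the inverse transform returns a real series. The
realization is zero-phase, has an exactly flat passband, and is an
orthogonal projection (applying it twice equals once), which makes its
contracts exactly testable on DFT-bin sinusoids: unit gain in band, exact
zero out of band. For an *off-bin* sinusoid only a few bins from the band
edge, spectral leakage through any projection-type filter is unavoidable at
finite series length (an off-bin 0.005 Hz tone at T=246/TR 2.2 s retains
~15–20% RMS); the filter contracts are therefore stated and tested on the
DFT grid. A Butterworth realization was considered and rejected: its
passband ripple under zero-phase application with reflection padding is
larger than the ideal mask's, and it is not idempotent.

## Seed series and connectivity maps

A region's representative series is its **first eigenvariate**: the first
left singular vector of the time × voxel matrix of mean-centered voxel
series. The vector is rescaled to unit variance (scale conventions differ
between toolboxes; scale cancels in correlations, so unit variance is used)
and sign-aligned so it correlates non-negatively with the region's
spatial-mean series; in the measure-zero tie the first nonzero element is
made positive, for determinism. The bilateral seed is the eigenvariate of
the **union** of left and right seed voxels — not the average of two
per-hemisphere eigenvariates — since the underlying protocol computes one
eigenvariate over all seed voxels; by the Eckart–Young property the union
eigenvariate explains at least as much union variance as either single-side
series.

Connectivity maps: per gray-matter voxel, Pearson r between the seed series
and the voxel series, then Fisher's z = atanh(r), with |r| clipped at
1 − 1e-7 so maps stay finite (z ≈ 8.39 at the clip). Zero-variance voxels
get z = 0 and are removed from the map's mask. Seed voxels are retained in
the analysis mask (they trivially show high z; nothing in the analysis
excludes them).

## Group model and cluster inference

Per voxel, across subjects: OLS on `z ~ intercept + age_c + sex_c + site`,
with age mean-centered, sex coded ±0.5 and centered, and site sum-to-zero
(effect) coded and centered — so the intercept estimates the
covariate-adjusted grand mean of z, which serves as the FC main effect.
Degenerate covariates (single sex or site) are dropped with a warning.
t statistics use the residual variance at `df = N − rank`; degenerate
zero-residual fits are reported at a documented cap of ±1e6.

**Conjunctions.** All four age contrasts are one-sided and paired with a
one-sided FC main effect of consistent definition: age-related decrease or
increase of positive FC (main t > t_crit, age t below −t_crit or above
+t_crit) and of negative FC (main t < −t_crit; note that a *decrease of
anticorrelation* means the negative mean moves toward zero, i.e. a positive
age slope). A voxel enters a cluster only if both tests pass the
cluster-forming threshold (one-sided voxel p < 0.001 by default); connected
components are labeled under 26-connectivity (6/18 configurable).

**Cluster-level FWE.** The reference protocol used parametric random-field
cluster correction; this package substitutes a permutation max-cluster-size
test, which is exactly specified, assumption-light, and whose calibration
can itself be tested. The scheme is Freedman–Lane on the age covariate: fit
the reduced model (all columns but age), permute its residual rows, refit
the full model, recompute the age t-map, intersect with the **fixed**
observed main-effect pass-mask, and record the maximum cluster size. The
main-effect mask is held fixed because the conjunction's inferential target
is the age effect — permuting age cannot break the main effect, whose role
is only to restrict where age effects may be declared. Cluster
`p_fwe = (1 + #{perm max ≥ observed size}) / (1 + n_perm)` (add-one
estimator, so p is never 0 and is floored at 1/(n_perm+1)). Clusters with
p_fwe below 0.05 are significant; a liberal 0.1 level is flagged
separately. Empirical FWE measured over 200 independent null cohorts is
0.025 at the nominal 0.05 level (conservative, as expected for a
conjunction whose second leg is never permuted).

## Per-cluster aging statistics

Subject-level cluster coupling is the mean Fisher-z over cluster voxels,
back-transformed (`r = tanh(mean z)`). An alternative reading — correlating
the cluster-mean time series with the seed — is deliberately not the
default: mean-z is linear in the quantities the group GLM models. The
cohort is split at the age median into equal halves (ties broken by subject
id; for odd N the median subject is excluded — the rule that yields 180/180
from 361). The young−old difference is a Welch (unequal-variance) t on the
subject-level z values, signed young minus old so that a decline with age
is positive — matching the sign convention of the reported statistics the
schema mirrors, where the interhemispheric coupling that *rises* with age
carries a negative t. The age association is a Spearman rank correlation
(average ranks on ties) over all subjects. Clusters are reported only if
|mean r| > 0.1 (strict) in at least one half — a small effect by Cohen's
convention.

The hemispheric supplement fits the same covariate model to per-subject
paired differences D = z_left − z_right (both directions of the main and
age effects, inference as above), and the interhemispheric analysis
correlates the left and right seed eigenvariates per subject and applies
the same split-half/Spearman statistics to their Fisher-z.

## Synthetic cohort model

The generator reproduces the *statistical* structure the analysis assumes,
not BOLD biophysics. Per subject: unit-variance Gaussian latents band-limited
to 0.01–0.08 Hz (so planted couplings survive the pipeline's own filter) —
one per hemispheric seed, sharing a common component so the interhemispheric
correlation is controllable and may drift with age (default 0.43 at the
cohort mean age, +0.0013/yr) — and one per effect region. An effect region
with target coupling ρ carries `ρ·s(t) + sqrt(1−ρ²)·ε(t)` against its seed
latent, with `ρ = baseline_r + slope·(age − mean_age)` linear in age (the
analysis model is linear in age; no quadratic option). Defaults emulate the
target study: 361 subjects, ages uniform 18–85, 34.5% female, 3 sites
(round-robin), 250 volumes at TR 2.2 s, 3.1 mm voxels, and three planted
effects mirroring reported magnitudes (r ≈ 0.13 declining 0.002/yr;
r ≈ 0.08 rising 0.002/yr; r ≈ −0.05 rising 0.002/yr). The 16³ grid is a
desk-scale stand-in for a whole-brain field of view; regions are cuboids
(exact voxel counts for cluster tests), and one shared atlas serves the
whole cohort since spatial normalization is out of scope.

On top of the signal every voxel receives i.i.d. Gaussian noise (sd 1.0
against unit-variance latents), a site mean offset, a linear drift, a
motion-coupled component (random per-voxel mixture of the six simulated
AR(1) realignment series — removable exactly by the motion regressors), and
brain-wide WM/CSF components (removable by the tissue means). All
randomness derives from the root seed via per-subject streams keyed by a
hash of the subject id, so cohorts are bit-reproducible and independent of
generation order.

What the generator does **not** emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, motion spike artifacts,
spatially correlated noise, anatomical geometry, or scanner-specific
autocorrelation. Passing tests therefore demonstrate the *inference
machinery* is correct and calibrated under the assumed signal model — not
that the pipeline is robust to every artifact of real scanner data.

## Detection limits at desk scale

A useful consequence of the ideal band-pass: a subject-level Fisher-z
estimate carries sampling noise ≈ `1/sqrt(2B − 3)` where B is the number of
in-band DFT bins (B = 38 at T=246, TR 2.2 → σ_z ≈ 0.117; the package's
empirical residual sd matches this floor). An age slope of 0.002 z/yr over
ages 18–85 then yields an expected per-voxel age t of ≈ 2.9 at N=80 —
*below* the p<0.001 forming threshold (t_crit ≈ 3.2), so detection of an
effect of that magnitude at that cohort size is intrinsically unreliable
(measured ≈ 28% over 50 replicates); at N=361 the same effect is
comfortably detectable, which is consistent with the cohort size the
original study needed. The calibration studies in `stnfc.validation` use
N=40/T=120 null cohorts (error control does not require power) and report
detection rates honestly as measured.

## Numerical conventions

- Voxel indices are 0-based internally; only world-mm coordinates (via the
  grid affine) appear in output tables.
- Fisher-z clipping constant: |r| ≤ 1 − 1e-7. t cap: 1e6.
- All tables are TSV with '.' decimals, locale-independent; floats are
  written at 6 decimals.
- One root RNG seed per run; per-stage and per-subject streams are derived
  by stable hashing, so subject-level work is order-independent and two
  runs with the same config and seed produce byte-identical cluster tables.
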