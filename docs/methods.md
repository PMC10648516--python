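# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `netseg`.

## The segregation statistic and its decompositions

All statistics operate on a node×node matrix of Fisher z-transformed
Pearson correlations in which negative entries have been set to zero and
the diagonal is structurally excluded (no operation can ever pool a
self-correlation; the stored zero diagonal is a placeholder, not a value).

* **Global segregation** pools *node pairs*: `(Z̄_w − Z̄_b) / Z̄_w`, where
  `Z̄_w` averages the W within-system pairs and `Z̄_b` the B between-system
  pairs across all assigned systems (`W + B = N(N−1)/2`).
* **System-type segregation** (association vs sensory-motor) is a
  *mean-of-means*: per system S of the requested type, `W_s` is the mean
  over pairs inside S and `B_s` the mean over pairs from S to every other
  assigned system of either type; the statistic is
  `(mean_S W_s − mean_S B_s) / mean_S W_s`. The pooled and mean-of-means
  readings coincide only for equal-sized systems with block-constant
  connectivity, so they are kept as separate, separately tested code paths.
* Systems typed `unassigned` are excluded from every pool. Systems with a
  single node have no within pairs; their within block is carried as
  missing (NaN), never as zero, and such systems are excluded from the
  mean-of-means.
* Degenerate input (pooled within mean of zero) raises an explicit
  undefined-segregation error rather than returning an infinity.

## Denoising sequence

The resting-state-specific processing order is fixed and enforced by a
stage marker on the time-series object; calling a stage out of order raises
an error. The order is: (1) per-node demeaning and linear detrending;
(2) multiple regression against the nuisance set — global signal (mean over
all nodes), white-matter and CSF surrogate channels, the first backward
differences of all three, and the Friston-24 motion expansion (6 rigid-body
parameters, their one-frame differences, and the squares of both);
(3) scrubbing at framewise displacement FD > 0.3 mm with temporary linear
interpolation between flanking clean frames; (4) zero-phase band-pass
0.009–0.08 Hz; (5) removal of the interpolated frames. Subjects with fewer
than 100 clean frames are excluded; survivors contribute exactly their
first 100 clean frames.

Choices where the procedure is under-determined:

* **FD** uses backward differences with rotations converted to arc length
  on a 50 mm sphere (the standard Power-style formula).
* **Nuisance coefficients are fit on low-motion frames only** (FD below the
  scrubbing threshold) and the fitted component is subtracted from *all*
  frames, so frames destined for censoring remain consistent through
  interpolation and filtering. The printed step order (regression before
  scrubbing) is preserved; only the estimation sample is restricted.
* **Interpolation** is linear between flanking clean frames; edge gaps take
  the nearest clean value. Spectral interpolation would be an alternative
  but is out of scope.
* **Filter**: second-order Butterworth applied forward–backward
  (`filtfilt`), giving zero phase. One octave outside the band the measured
  gain is below 0.1; in mid-band it exceeds 0.9.
* Degenerate nuisance columns (all-zero, or exact duplicates — e.g. with a
  motionless synthetic subject) are dropped with a logged warning rather
  than failing the run; a genuinely collinear design still raises an error
  naming the offending columns.

## Synthetic cohort generator

The generator emulates a cross-sectional aging/dementia cohort at the level
of node time series; it does not synthesize images.

**Covariates.** CDR is drawn from {0, 0.5, 1, 2} with probabilities
(0.5424, 0.3661, 0.0749, 0.0166) — the 326/220/55 split of a ~600-person
sample with the rare moderate-dementia level a small fraction of the
combined mild-and-moderate group. Age (truncated normal, 55–96) and
education are drawn conditional on CDR with group means (age 73.96 / 74.98
/ 77.95 / 77.95, SD ≈ 8; education 16.97 / 16.08 / 15.42), reproducing the
usual confounding of age and severity; the marginal age mean is 74.70.
Gender is Bernoulli (53.2% F); pulse and respiration are optional normal
covariates. Scan length is 140, 197 or 200 frames (20/20/60%), mirroring a
multi-protocol study; the interaction of a fixed 100-clean-frame rule with
variable acquisition length is what makes high-motion subjects on short
protocols fail QC.

**Covariance model.** Each subject's generating correlation matrix is
block-constant on the Fisher-z scale: per-system within-z baselines
(0.48–0.70), between-z 0.12 for association–association pairs and 0.04 for
pairs involving a sensory-motor system (sensory systems couple weakly to
the rest of cortex). Effects are injected linearly in z:

| parameter | default | meaning |
| --- | --- | --- |
| `age_slope_within_assoc` | −0.002 z/year | within-system decline of association systems, relative to age 75 |
| `cdr_slope_within` | −0.05 z/CDR-unit | within-system decline, both system types |
| `cdr_slope_between` | +0.10 z/CDR-unit | between-system increase on blocks involving the default or frontoparietal system |
| `noise_sd` | 0.5 | white measurement noise (signal SD 1) |
| `ar_coef` | 0.5 | temporal AR(1) of the neural signal |
| `spike_rate_base`, `spike_rate_cdr` | 0.05, 0.08 | per-frame motion-spike probability, baseline and per CDR unit |

The z-matrix is mapped to correlations, clipped to |r| ≤ 0.99 (with a log
message) and, if indefinite, repaired by eigenvalue clipping at zero with
renormalized unit diagonal. Time series are stationary AR(1) draws whose
marginal spatial covariance equals the generating matrix exactly; white
noise and, at spike frames, a global additive artifact are superimposed.
Motion is a slow random walk (mean FD ≈ 0.1 mm) plus 1 mm single-frame
translation excursions at spike frames, so each spike unambiguously censors
two frames at the 0.3 mm threshold.

**Why the between-system effect is targeted, and why AR(1).** Two features
of the denoising sequence constrain what an injectable effect can look
like. First, global signal regression removes the projection on the mean
signal, which makes the total off-diagonal correlation mass essentially
invariant: a spatially *uniform* between-system increase is
indistinguishable from a global signal component and is regressed away.
Real dementia-related hyperconnectivity is not uniform — it concentrates on
interactions of hub-like association systems — so the generator injects the
CDR between-system effect on blocks involving the default and
frontoparietal systems, which survives GSR. Second, BOLD power is
concentrated at low frequencies; a white-spectrum surrogate loses more than
half its variance (and hence most of its effective degrees of freedom) to
the 0.009–0.08 Hz band-pass at TR = 3 s, drowning subtle between-system
effects in correlation sampling noise. The AR(1) coefficient of 0.5 gives
the surrogate a realistic low-frequency-weighted spectrum. Effect
magnitudes were chosen once for detectability at n = 300 through the full
pipeline and are documented as design values, not as empirical estimates
from any dataset.

**Reproducibility.** One master seed spawns an independent stream per
subject (`SeedSequence.spawn`), so enlarging a cohort never reshuffles
earlier subjects; time-series streams are spawned from `seed + 1` so the
covariate draw and the noise draw are independent. Identical seeds produce
bit-identical cohorts, time series and reports.

## Inference layer

* **OLS** with nuisance covariates (gender, post-scrubbing mean FD,
  education; extendable with pulse/respiration or any extra columns).
  Effect size per term is the partial correlation `t / sqrt(t² + df)`.
  CDR enters as a continuous predictor at its raw values; a categorical
  recoding {0, 0.5, 1&2} is provided for post hoc pairwise group tests
  (Welch t, Bonferroni-corrected).
* **Mixed models** for two-level within-subject factors (system type, or
  within- vs between-system interaction type): random intercept per subject
  — with two condition levels a random slope is not identifiable separately
  from the residual — and fixed effects for condition, the focal variables,
  their condition interactions, and the covariates; a three-way
  age×CDR×condition variant is available. Marginal and conditional R² use
  the Nakagawa–Schielzeth variance partition. For numerical stability the
  design and outcome are scaled to unit magnitude internally and estimates
  are rescaled; t and p are invariant to this. Approximate per-term p
  values use df = n_subjects − n_fixed − 1.
* **Block permutation test** (Freedman–Lane): the outcome is residualized
  on the covariates alone, residuals are permuted across participants, the
  covariate fit is added back and the focal coefficient refit; the
  two-sided p is `(1 + #{|β*| ≥ |β|}) / (n_perm + 1)`, never zero. All
  blocks share the same permutations, preserving cross-block dependence.
  The implementation uses the identity that the focal-coefficient row of
  the full-design pseudoinverse is orthogonal to the covariate columns, so
  the whole null distribution is two matrix products. The FDR family is all
  S(S+1)/2 unique blocks of one focal variable's test (configurable by
  passing a different outcome table); flags are reported uncorrected and
  Benjamini–Hochberg corrected at q = 0.05.

## Problem sizes used in the test suite

The cohort-level calibration tests use the sizes at which the behavioural
claims are stated: 500 replicate null cohorts of n = 150 with 200
permutations for type-I calibration, and 50 replicate default cohorts of
n = 300 for the dissociation recovery; together they account for most of
the suite's runtime. Unit and property tests use desk-scale fixtures
(≤ 12-node matrices, ≤ 300-subject single cohorts).

## What passing tests do and do not show

The generator produces Gaussian, block-constant-covariance, AR(1) signals
with Bernoulli motion spikes. Real BOLD data have spatially heterogeneous
within-block correlation, non-Gaussian artifacts, physiological rhythms
aliased into the band, scanner/site effects, and motion that is temporally
clustered rather than independent across frames. Passing the recovery tests
therefore shows that the *pipeline* is correct and adequately powered under
the stated generative model — not that effects of these magnitudes are
detectable in any particular real dataset. Site effects, amyloid/genotype
moderation and surface/image processing are out of scope; extra covariate
columns pass through the inference layer generically.

## Known limitations

* The default 120-node, 10-system partition is a desk-scale stand-in, not a
  published atlas; node and system counts are configurable.
* The mixed-model p values use a simple residual-df approximation rather
  than Satterthwaite/Kenward-Roger corrections; with ≥ 150 subjects the
  difference is negligible.
* The permutation test assumes exchangeable covariate-adjusted residuals;
  strong heteroscedasticity across CDR groups would weaken its exactness.
* Under the default generator the CDR effect on sensory-motor segregation
  is negative but weak relative to its association-system counterpart;
  cohorts emphasizing that component should raise `cdr_slope_within`.
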