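# Methods

`nirsnet` implements a resting-state fNIRS graph-theory pipeline for
developmental case-control studies, together with a synthetic cohort
generator that makes every stage testable against known ground truth.
This note documents the models, the defaults and why they were chosen,
the numerical conventions, and the limits of what the synthetic tests
demonstrate.

## The analysis model

Each subject contributes a 48-channel resting recording (HbO and HbR
chromophores, 8.7 Hz, 8 min by default). After cleaning, the pipeline:

1. computes the 48×48 Pearson correlation matrix per chromophore and
   Fisher-transforms it, `z = atanh(r)`;
2. keeps only positive z values and thresholds proportionally: at sparsity
   `S ∈ {0.01, …, 0.50}` the strongest `round(S · 1128)` edges form a
   binary, undirected network (1128 = 48·47/2). Rounding is
   half-away-from-zero; z ties break by the lower channel pair, so the
   stack is fully deterministic and nested along the grid;
3. computes global efficiency `E_glob = mean over ordered pairs of 1/d(i,j)`
   and local efficiency (mean neighbor-subgraph global efficiency), plus
   nodal degree and nodal efficiency per channel. Unreachable pairs
   contribute `1/∞ = 0`; nodal efficiency uses the harmonic form (mean of
   inverse distances), which remains finite on the fragmented networks
   that low sparsities produce. The alternative inverse-of-mean convention
   disagrees only on disconnected graphs and is intentionally not used;
4. normalizes the two global metrics against the mean of 100
   degree-preserving random networks per sparsity (double-edge swaps,
   10 × edge-count swap budget; networks for which no valid swap exists,
   e.g. complete graphs, are their own null). Nodal metrics enter the
   statistics as raw values;
5. integrates every metric curve over the sparsity grid by the trapezoid
   rule (AUC). Grid points with a zero null mean are marked missing and
   excluded; an AUC needs at least two valid points.

### Trajectory statistics

For each outcome (metric × channel × chromophore AUC) an OLS model

    Y = b0 + b1·group + b2·age + b3·age² + b4·age:group + b5·age²:group + e

is fit with age centered on the full-sample mean, the quadratic term as
the square of the centered age, and group coded TD = 0 / ASD = 1.
Standardized coefficients z-score the outcome and each *constructed*
column (including interactions); a switch (`zscore_age_first`) supports
the alternative convention of standardizing age before construction.
Either way t statistics and p-values equal those of the raw fit.
Benjamini–Hochberg FDR at q = 0.05 is applied within each
(metric, chromophore, term) family across the 48 channels. Brain-behavior
associations are age-controlled partial correlations (residual method)
between metric AUCs and ADOS communication/social scores, computed in the
ASD group only, since the scores exist only there. Demographic tables use
the pooled-variance two-sample t test, which reproduces the conventional
reporting for matched groups.

## Preprocessing

Fixed order: trim 30 s from both ends → motion detection → spline
correction → wavelet filtering → 0.009–0.08 Hz zero-phase band-pass →
3rd-order polynomial detrend → first-sample baseline correction. All
operators preserve shape and sampling metadata.

- **Motion detection** slides a 1 s window per channel and flags it when
  the excursion (max − min) exceeds an amplitude threshold or the moving
  SD exceeds 15 × the channel's median moving SD. On optical density the
  amplitude threshold is 0.1 (absolute OD). On hemoglobin input, where
  absolute units depend on conversion constants, the threshold is
  4 × the channel's *median windowed excursion* — a scale estimate chosen
  because it stays valid when baseline step artifacts inflate the global
  SD. Flagged windows are dilated to their full extent and merged.
- **Spline correction** fits a smoothing spline (MATLAB-style parameter
  p = 0.99, translated to `lam = (1−p)/p`) inside each flagged segment,
  subtracts it, and re-anchors the residual on the straight line between
  the neighboring unmasked samples, so segment endpoints join the
  surrounding signal exactly; unmasked samples are never modified.
- **Wavelet filtering** (db3) fits a Gaussian robustly (median/MAD) to
  each detail level and zeroes coefficients outside the central 90%
  (α = 0.1). The decomposition depth is capped so the approximation band
  still contains the 0–0.08 Hz hemodynamic band; only out-of-band detail
  levels are thresholded. Without this cap the α-tail rule removes ~44%
  of the variance of every in-band level and visibly erodes the signal;
  with it, a 0.05 Hz tone passes with r ≥ 0.99 while isolated spikes lose
  > 90% of their amplitude.
- **Band-pass** is a 3rd-order Butterworth applied forward-backward
  (zero phase). Measured gains: ≥ 0.94 at 0.05 Hz, ≤ 0.01 at 0.2 Hz, 0 at
  DC.
- **MBLL conversion** (for intensity input) solves the 3-wavelength ×
  2-chromophore system by least squares per sample. Extinction
  coefficients are tabulated approximations at 780/805/830 nm in
  1/(mM·cm); DPF defaults to 6.0 per wavelength and the pathlength to
  3 cm. All constants are configurable; round-trip forward/inverse tests
  pin the algebra rather than the constants. When the input is already
  hemoglobin (the simulator's native output), the OD steps are skipped
  and detection runs on the hemoglobin series.

Artifact fractions are reported per subject as the channel-mean masked
percentage; corrected segments are retained in the correlation window
rather than excluded (the conservative reading of the cleaning-then-
correlating workflow).

## The synthetic cohort generator

The generator emulates the study design the pipeline targets: 77 ASD and
40 TD males aged 6–16.6 years (uniform), IQ drawn from the groups'
reported means/SDs, ADOS communication (2.21 ± 1.50) and social
(6.79 ± 2.15) scores for ASD subjects only, 48 channels at 8.7 Hz for
8 min.

Each subject carries a latent 48×48 correlation matrix: Fisher-z
within-region coupling atanh(0.45), cross-hemisphere same-region
atanh(0.30), between-region atanh(0.12), plus symmetric subject-level
jitter (SD 0.05 on the z scale), projected to the nearest unit-diagonal
PSD matrix. The block structure gives non-trivial topology at
intermediate sparsity. The "neural" signal is white noise low-passed
below 0.08 Hz and mixed through the Cholesky factor, so the band-limited
sample correlation is an unbiased estimate of the latent matrix. HbR is
generated anti-correlated with HbO (r = −0.7, configurable) with its own
latent-structured residual at 0.4 relative amplitude. Nuisance terms:
1/f noise (0.5), cardiac ~1.1 Hz (0.4), respiratory ~0.25 Hz (0.3),
Mayer ~0.1 Hz (0.35), white noise (0.1), amplitudes relative to unit
signal SD. Motion artifacts hit all channels at once (head motion moves
the whole probe array): 60% brief half-sine spikes at 10 × channel SD,
40% persistent baseline shifts at 5 × SD, Poisson-arriving at 4
events/min — chosen a priori so that, with ~2 s masked per detected
event, roughly 15% of samples are flagged, the regime typical of
pediatric resting recordings. All randomness derives from a single seed;
identical configurations reproduce cohorts bit-for-bit.

**Injected effects** modify one channel's z-couplings by `δ · x`, where
`x` is the z-scored design term (group, age, age², or an interaction).
The ADOS scores can be negatively linked to the injected nodal shift so
brain-behavior recovery is testable.

### Effect calibration (recovery harness)

A target effect is specified on the *outcome* scale — e.g. "standardized
β5 = 0.4 on nodal-efficiency AUC" — but injected on the latent z scale.
The harness calibrates the mapping with two pilot measurements through
the actual pipeline: (i) outcome noise σ_ε, the SD of the target
channel's AUC across pilot subjects with no effect; (ii) the slope of the
latent→AUC response, measured as a paired difference between recordings
generated from ±probe-shifted covariances with identical noise draws
(which cancels nearly all sampling noise), re-measured once at the shift
amplitude the regression effectively samples. Then
`δ = (β/√(1−β²)) · σ_ε / slope`, which also pins the model R² near β²
(~0.15–0.16, the range typical of developmental cohort effects). The
recovery experiment uses 2 minutes of analyzed signal per subject
(150 s simulated, 15 s trimmed per edge) and skips spline/wavelet on the
artifact-free input — sizes chosen so the 20-replicate experiment runs on
a laptop while the AUC sampling noise still dominates, as it would in
real data.

Measured behavior at these conditions: the 20-replicate mean standardized
β5 lands within ±0.1 of the 0.4 target (with a small upward bias from the
mild nonlinearity of the latent→AUC response under a collinear design).
The affected channel ranks first by β5 p-value in only ~60% of
replicates: with n = 117, uniform ages and a 2:1 group ratio, the
age²:group column is strongly collinear with the group and age² main
effects (VIF ≈ 4), so a true standardized effect of 0.4 yields t ≈ 2.3 —
not reliably the minimum p among 48 correlated channels. This is a
property of the design, not of the estimator; the corresponding
acceptance test documents it by failing.

## What the synthetic tests do and do not show

The generator produces Gaussian, stationary signals with block-structured
covariance and idealized artifacts. Passing tests demonstrate that the
estimators recover what the generator encodes — correlation structure,
degree-sequence-preserving nulls, injected developmental effects, FDR
control — under realistic sampling noise. They do not validate optical
physics (no photon transport), scalp/systemic physiology shared across
channels, non-Gaussian or non-stationary dynamics, or registration error;
conclusions about real cohorts still require real data.

## Numerical conventions and edge cases

- Zero-variance channels: correlations set to 0 with a warning.
- Fisher z clips |r| at 1 − 1e−7.
- Graph distances via level-synchronous BFS (boolean matrix products);
  betweenness (optional, excluded from the default pipeline for its
  known poor retest reliability) via Brandes accumulation in unordered
  pair units.
- Rewiring randomness is drawn in advance and consumed by a jitted swap
  kernel; null ensembles are seeded per (subject, chromophore, sparsity).
- OLS via `statsmodels` for single outcomes; a vectorized least-squares
  path handles 48-channel families and is tested to agree with
  `statsmodels` term by term.
- Partial correlation is undefined (flagged, NaN) when a variable is an
  exact affine function of the covariate (residual SD below 1e−10 of the
  variable's scale).
- Pooled t with zero pooled variance: t = 0 for equal means, ±∞ with a
  warning otherwise.
- All tables are TSV with 10-significant-digit floats, which makes
  identically seeded pipeline runs byte-identical; TSV is the package's
  interchange format throughout.

## Known limitations

- The montage ships synthetic MNI coordinates (region/hemisphere labels
  are the meaningful part); no probe registration is modeled.
- The spline corrector replaces the in-segment waveform with an anchored
  residual; genuine neural signal inside long masked segments is lost.
- Null-model normalization is only defined per sparsity point; very
  sparse graphs whose null mean efficiency is 0 yield missing normalized
  points.
- The mean recovered standardized coefficient carries a small
  (+0.05–0.08) finite-sample bias at effect 0.4 under the default
  design's collinearity; applications estimating effect sizes from small
  cohorts inherit this.
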