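# Methods

This note documents the models, parameter defaults and design choices behind
`affectphysio`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Experimental design model

A session is a pseudorandomized block design: 90 trials (50 facial-emotion
videos — 10 each of anger, disgust, fear, happiness, surprise — 20 dynamic
mosaics, 20 fixation crosses) grouped into condition-homogeneous blocks of
five. Trials are scanner-triggered at volume onsets (TR = 2.93 s), so onsets
are exact volume multiples; onset-to-onset spacing is 11.72 s (4 TR) for
video trials and 8.79 s (3 TR) for fixation trials, giving
4·70 + 3·20 = 340 volumes. Video durations are drawn from 4 + 4·Beta(0.9, 3.1) s,
a distribution on [4, 8] s with mean 4.9 s matching the stimulus set's stated
range and mean. Block order is a seeded permutation re-drawn (≤1000 attempts)
until no two consecutive blocks share a condition; whether emotions were
intermixed or blocked within facial blocks is not knowable from the study
description, so both orders are available behind `emotion_order`
(default `mixed`).

The mosaic baseline operator partitions every frame into an `r × c` grid
(20 × 20 = 400 tiles in the study) and applies one seeded tile permutation
per stimulus, identical across frames. It is a bijection on tile positions:
applying the inverse permutation restores the input bit-exactly, and
per-frame pixel multisets are untouched (luminance/contrast/colour matched).

## Cardiac pipeline

* **Peak detection** uses local-maximum search (`scipy.signal.find_peaks`)
  with a refractory distance of `min_ibi_s` (default 0.33 s ≈ 180 bpm
  ceiling) and prominence ≥ 10 % of the waveform range. Flat signals and
  recordings with < 3 peaks are rejected as quality errors. These defaults
  are physiological bounds; the original study's in-house script is
  unpublished, so they are explicit parameters.
* **Rate trace**: each output sample takes 60/IBI bpm of the covering
  interval, then a centred 1-s moving average (window truncated at the trace
  edges; for even window lengths the window is left-biased by one sample —
  the convention the tests' hand-computed values use).
* **Trial scoring**: baseline = mean rate over the 1 s before onset (the
  study never defines "baseline heart rate for that trial"; 1 s mirrors the
  pupil baseline for cross-modality symmetry and is a parameter);
  `pct(t) = 100·(HR(t) − baseline)/baseline` over (0, 4] s; eight 500-ms bin
  means (half-open-left, closed-right, ending at 0.5 … 4.0 s); `at_3s` is the
  smoothed trace at the sample nearest 3.000 s (ties to the earlier sample).
  Percentage normalisation makes scores invariant to rescaling the trace.
* **Screening**: HRV = Var(IBI); the arrhythmia proxy flags recordings whose
  IBI coefficient of variation exceeds 0.25 (the original exclusions were by
  visual inspection; a reproducible rule replaces them).

A planted deceleration is *attenuated* by this pipeline: the 1-s sliding
filter and the piecewise-constant rate conversion act as ~1-s and ~IBI-wide
box filters on the dip, so a 4 % planted nadir reads back slightly shallower
at 3 s. The recovery tests measure through the full pipeline and accept the
planted value within ±0.5 percentage points; the residual shortfall is this
filtering, not an estimation bias.

## Pupil pipeline

Reactivity is the ratio `100 × max post-onset (5 s) / mean baseline (1 s)`,
computed over valid samples only. Tracker dropouts (sentinel-valued runs) are
invalidated together with 50 ms padding on each side (lid closure distorts
neighbouring samples). Exclusion rules: (1) ratios more than 2 population SDs
above the pooled all-participant mean (one pass, high side only — low ratios
are not blink artefacts); (2) capture fraction < 0.5 over the 6-s analysis
window ("insufficient capture" is undefined in the study; 0.5 is exposed as
config). Flags are non-destructive, so exclusion is idempotent. Fixation
trials are never scored (luminance mismatch with the video conditions).
Participant covariates for the second-level GLM are means over retained
trials; participants with no retained trials are dropped from covariate
analyses with a logged warning. The ratio is unit-invariant (diameter vs
area) and scale-invariant.

## BOLD GLM

First-level designs are built on a fine grid (dt = TR/16): per-condition
boxcars over each trial's own duration, convolved with the canonical
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions,
undershoot ratio 1/6, unit-peak scaled; kernel mode ≈ 5 s), scaled by dt
(making regressor amplitude grid-independent) and sampled at volume onsets.
Six motion covariates are mean-centred; an intercept closes the design.
Fitting is OLS per voxel inside a liberal mask (mean signal > 0.1 × global
mean — chosen so atrophic regions survive to the second level); optional
single-ρ AR(1) prewhitening (Cochrane–Orcutt) is available because the
first-level noise model of the original analysis package is unspecified.
Rank-deficient designs fall back to the pseudoinverse with reduced effective
degrees of freedom and a logged warning.

Contrast helpers are balanced within sides and zero-sum across condition
columns: facial>fixation, facial>mosaic, and the valence pair
positive(happiness, surprise) vs negative(anger, disgust, fear), which are
exact negations of each other.

Second level: subject contrast maps are stacked under a majority mask
(voxels defined in > 50 % of subjects). Group structure is cell-means coded;
the group map is a one-way fixed-effects F across diagnostic-group means
(voxels with zero residual variance carry no information and are masked
out). Covariate slope maps fit `map ~ 1 + covariate (+ nuisance)` within one
group (≥ 4 complete subjects; constant or collinear covariates rejected);
both slope signs are meaningful — negative heart-rate-change slopes index
parasympathetic engagement, positive sympathetic. Whether the original
analysis used one model per group or group × covariate interactions is
ambiguous; per-group models are the default here.

### Cluster-level FWE

Inference is by permutation rather than random-field theory: RFT needs a
smoothness estimate and stronger assumptions, while permutation is exact
under exchangeability; the cluster-defining threshold (p < 0.005) and alpha
(0.05) match the study's settings. Clusters are 26-connected components
above the CDT-equivalent statistic (connectivity is config: 6/18/26). The
null is the distribution of the maximum cluster size under: sign-flipping of
subject maps (one-sample condition effects), permutation of group labels
(group F), or permutation of covariate entries with nuisance columns fixed
(Manly-style; Freedman–Lane is not implemented). Cluster
`p_FWE = (1 + #{null max ≥ size}) / (1 + n_perm)`, monotone in cluster size;
`n_perm ≥ 100` is enforced (default 1000). ROI analyses use the sign-flip
max-statistic at peak level within a user-supplied mask. Sign-flip t nulls
exploit the sign-invariance of Σx² per voxel, so an entire null is one
matrix product plus connected-component labelling.

## Synthetic cohorts

The generators define the test-bed conditions; all are pure functions of
(parameters, seed) and byte-reproducible.

* **PPG**: instantaneous rate = base (default 70 bpm) minus a causal
  Gaussian dip per trial (depth in % of base, nadir 3 s, σ = 1.5 s,
  truncated to start at onset — the orienting response cannot precede the
  stimulus), scaled 1.0/0.6/0.5 for facial/mosaic/fixation. Beats are placed
  by integrating the rate; per-beat timing jitter has SD jitter/√2 so IBI
  variance equals jitter² (20 ms default, an elderly-cohort-scale SDNN)
  without drift against the schedule clock. The waveform is an asymmetric
  raised-cosine pulse train (fast systolic upstroke) plus white noise — only
  peak locations matter downstream.
* **Pupil**: baseline 4.0 units plus a gamma-shaped dilation bump per trial
  (unit peak at the latency, default 1.5 s) with amplitude in % of baseline;
  measurement noise is 120-ms-smoothed (temporally correlated, 0.5 % of
  baseline — video-tracker scale) because the Eq.-1 max operator is
  max-biased under white noise; blinks are Poisson (4/min) sentinel runs of
  100–300 ms.
* **BOLD**: 24 × 24 × 12 voxels at a nominal 2 mm (desk-scale but genuinely
  3-D), ellipsoidal brain mask at baseline 100 (keeping brain voxels above
  the 0.1 mask threshold), boxcar⊗HRF responses summed over planted spheres,
  AR(1) noise (ρ = 0.3, marginal SD 1), six random-walk motion traces
  (optionally leaked into the data, default off). Null-calibration
  simulations use second-level noise maps smoothed with σ = 1.27 voxels —
  the FWHM-6-mm kernel of the acquisition pipeline at 2-mm voxels — since
  real subject maps are spatially smooth and cluster-size inference is
  sensitive to smoothness.
* **Behaviour**: responses drawn from per-group 5 × 5 confusion matrices
  (uniform off-diagonal). Default diagonal accuracies 0.72 / 0.53 / 0.48 /
  0.50 for control / bvFTD / svPPA / nfvPPA reproduce the qualitative group
  ordering of identification totals; default group sizes 22/17/12/9 follow
  the cohort. Patient cardiac dips are attenuated (1.5 % vs 4 %) and pupil
  dilation is reduced mainly in nfvPPA (12 % vs 25 %) — encoded as
  parameters, never asserted as results.

What the generators do **not** emulate: photorealistic faces, luminance
coupling between stimulus and pupil, respiratory/cardiac aliasing in BOLD,
scanner drift, atrophy-dependent masks, or between-subject anatomical
variability. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated noise models, not robustness to every
artefact of real recordings.

## Statistics module

ANOVAs are fixed-effects with Type-III sums of squares under sum-to-zero
coding (group sizes are unbalanced, so the convention must be explicit);
degenerate inputs (zero response variance, saturated layouts, empty cells)
are flagged or rejected rather than silently reported. Post-hocs are
pairwise pooled-variance t tests with Bonferroni multiplication
(p_adj = min(1, m·p), monotone). Missing behavioural responses score as
incorrect (forced-choice task; conservative). Correlations are Pearson,
pairwise-complete, ≥ 4 pairs.

## Problem sizes and numerical choices

Recovery and calibration runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the stated tolerances: 200 trials for cardiac recovery
(±0.5 points), 100 for pupil (±1 point), 12 subjects for cluster recovery
(Dice > 0.5), and 500 null simulations × 500 permutations for the FWE
type-I rate. Voxel indices are 0-based; world coordinates come from the
affine; all times are seconds from scan start; writes are atomic
(temp-file + rename) and gzip members carry no timestamp or filename, so
identical inputs give byte-identical outputs.

## Known limitations

* The AR(1) prewhitening option uses a single global ρ, not voxel-wise or
  ARMA noise models.
* Slope-map permutation is Manly-style; with strong nuisance effects a
  Freedman–Lane scheme would have better small-sample control.
* The second-level F handles missing voxels NaN-aware but assumes homogeneous
  variance across groups (as the original full-factorial model does).
* Cluster-size inference on nearly unsmoothed maps is conservative (discrete
  small cluster sizes); cluster mass would be less granular but is not the
  statistic used here.
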