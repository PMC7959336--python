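# affectphysio

Multimodal analysis of dynamic facial-emotion processing for
frontotemporal-dementia research: stimulus/design generation, cardiac and
pupillary reactivity scoring from raw physiological traces, behavioural
emotion-identification statistics, and a mass-univariate BOLD GLM with
permutation cluster-level FWE inference — plus a synthetic-data module that
generates complete multimodal cohorts with known ground truth, so every
stage of the pipeline is testable without access to patient data.

## The problem

Passive-viewing fMRI experiments of naturalistic facial expressions pair a
block design of dynamic face videos, scrambled "mosaic" baselines and
fixation crosses (TR = 2.93 s; video trials span 4 volumes, fixation trials
3) with simultaneous pulse-oximetry and pupillometry, and a post-scan
five-alternative emotion-identification task. Cohorts span behavioural-variant
FTD (bvFTD), semantic and non-fluent variant primary progressive aphasia
(svPPA, nfvPPA) and healthy controls. The analysis must combine:

* **Cardiac reactivity.** Pulse peaks are detected in the oximetry waveform;
  each sample is converted to the instantaneous rate 60/IBI of its inter-beat
  interval; the trace is smoothed with a 1-s sliding filter and normalised per
  trial to the pre-onset baseline, so every value is a percent change in heart
  rate. The event-locked orienting deceleration is summarised over eight
  500-ms bins (0.5–4 s) and at its nadir, 3 s post onset. Heart-rate
  variability is indexed as Var(IBI) and screens out arrhythmic recordings.
* **Pupil reactivity.** Per trial,
  `R = 100 × max pupil size in (t₀, t₀+5 s] / mean pupil size in [t₀−1 s, t₀)`,
  over blink-free samples only; trials more than 2 SD above the pooled
  experimental mean, or with insufficient pupil capture, are excluded.
* **Behaviour.** Per-emotion identification scores (0–10; total /50), compared
  with group × emotion fixed-effects ANOVA and Bonferroni post-hocs.
* **BOLD GLM.** First level: each condition (five emotions, mosaic, fixation)
  as a boxcar over each trial's duration convolved with the canonical
  double-gamma HRF, six motion covariates, a liberal 0.1 masking threshold.
  Second level: group factor (cell-means coded) under a majority mask, one-way
  group F maps, condition t maps and within-group covariate slope maps
  (reactivity or identification score, with vocabulary score as nuisance),
  thresholded at a cluster-defining p < 0.005 and assessed at cluster-level
  p_FWE < 0.05 by sign-flip / label-permutation of the subject maps.

## Worked example

Generate a small synthetic cohort (two participants per diagnostic group) and
run the physiological and behavioural stages:

```bash
affectphysio simulate --seed 7 --n-per-group 2 --out cohort
affectphysio cardiac  --physio cohort/sub-000/ppg.tsv.gz   --events cohort/sub-000/events.tsv --out cardiac.tsv
affectphysio pupil    --physio cohort/sub-000/pupil.tsv.gz --events cohort/sub-000/events.tsv --out pupil.tsv
affectphysio behaviour --responses cohort/responses.tsv --out beh
```

```
cohort of 8 participants -> cohort
90 trials scored (mean HR 69.3 bpm, usable=True) -> cardiac.tsv
70 trials scored -> pupil.tsv
8 participants scored -> beh
```

`sub-000` is a control. Averaging its per-trial scores by condition:

```
at_3s (% HR change)        ratio_pct (pupil, %)
facial     -3.27           facial    125.5
fixation   -2.16           mosaic    115.8
mosaic     -1.50
```

The planted control physiology (4 % cardiac deceleration at the 3-s nadir,
larger for facial than scrambled stimuli; 25 % pupil dilation, scaled down
for mosaics) is recovered: heart rate decelerates ~3–4 % for faces, less for
the control conditions, and pupil ratios sit near 125 % for faces. The
behavioural ANOVA on this cohort (patient groups generated with lower
identification accuracy) gives:

```
       effect  sum_sq  df     F  PR(>F)
        group  35.275   3 4.237   0.018
      emotion  19.250   4 1.734   0.182
group:emotion  31.350  12 0.941   0.528
```

i.e. a group main effect on identification scores, no emotion or interaction
effect at this tiny cohort size. First- and second-level GLM stages run the
same way (`affectphysio glm first-level ...`, `affectphysio glm group ...`)
and write NIfTI effect maps and cluster tables with FWE-corrected p-values.

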