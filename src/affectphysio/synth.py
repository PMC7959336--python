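"""Synthetic multimodal cohorts with known ground truth.

The study's raw data are not deposited, so every pipeline stage is exercised
on simulated recordings that share one trial schedule per session (one
clock) and carry their generating parameters alongside as ground truth:

* pulse-oximetry waveforms whose instantaneous heart rate carries an
  event-locked Gaussian-shaped deceleration (nadir 3 s post onset), with
  beat-timing jitter and additive waveform noise;
* pupil traces with an event-locked smooth dilation, correlated measurement
  noise and blink dropouts (sentinel-valued runs of 100-300 ms);
* 4-D BOLD runs built as boxcar-convolved-HRF responses in planted spherical
  clusters over AR(1)-correlated Gaussian noise, plus random-walk motion
  regressors;
* five-alternative emotion-identification responses drawn from per-group
  confusion matrices.

Default cohort parameters encode the qualitative study pattern as
configuration, never as assertions: controls show the deepest cardiac
deceleration, larger for facial than scrambled stimuli; patient groups are
attenuated; pupil dilation is reduced mainly in the non-fluent group; and
identification accuracy is ordered controls > patients.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import EMOTIONS, TrialSchedule, build_trial_schedule
from .glm import BoldDataset, condition_regressor
from .trace import PhysioTrace

PUPIL_SENTINEL = 0.0
DEFAULT_BOLD_SHAPE = (24, 24, 12)
DEFAULT_VOXEL_MM = 2.0


@dataclass
class GroupParams:
    """Per-diagnostic-group generating parameters."""

    n: int
    cardiac_dip_pct: float = 4.0  # HR deceleration depth at the nadir, % of base
    pupil_dilation_pct: float = 25.0  # facial-trial dilation over baseline, %
    pupil_latency_s: float = 1.5
    accuracy: float = 0.7  # diagonal of the emotion confusion matrix
    bold_amplitude: float = 1.0  # scales planted facial-condition response


def _confusion_from_accuracy(acc: float) -> np.ndarray:
    k = len(EMOTIONS)
    off = (1.0 - acc) / (k - 1)
    return np.full((k, k), off) + np.eye(k) * (acc - off)


@dataclass
class CohortSpec:
    """Full cohort description: groups, physiology, BOLD geometry, seed."""

    groups: dict[str, GroupParams] = field(default_factory=lambda: {
        "control": GroupParams(n=22, cardiac_dip_pct=4.0,
                               pupil_dilation_pct=25.0, accuracy=0.72),
        "bvFTD": GroupParams(n=17, cardiac_dip_pct=1.5,
                             pupil_dilation_pct=24.0, accuracy=0.53),
        "svPPA": GroupParams(n=12, cardiac_dip_pct=1.5,
                             pupil_dilation_pct=20.0, accuracy=0.48),
        "nfvPPA": GroupParams(n=9, cardiac_dip_pct=1.5,
                              pupil_dilation_pct=12.0, accuracy=0.50),
    })
    n_facial: int = 50
    n_mosaic: int = 20
    n_fixation: int = 20
    base_hr_bpm: float = 70.0
    hr_jitter_ms: float = 20.0
    ppg_fs_hz: float = 50.0
    ppg_noise_sd: float = 0.02
    pupil_fs_hz: float = 50.0
    pupil_baseline_units: float = 4.0
    pupil_noise_sd: float = 0.02
    blink_rate_per_min: float = 4.0
    mosaic_condition_scale: float = 0.6  # autonomic response scale vs facial
    fixation_condition_scale: float = 0.5
    bold_shape: tuple[int, int, int] = DEFAULT_BOLD_SHAPE
    bold_noise_sd: float = 1.0
    ar1_rho: float = 0.3
    motion_sd: float = 0.05
    planted_effects: dict = field(default_factory=lambda: {
        "facial": [{"center": (8, 14, 6), "radius": 3.0, "amplitude": 1.0}],
        "mosaic": [{"center": (16, 8, 6), "radius": 2.5, "amplitude": 0.6}],
    })
    seed: int = 0

    def validate(self) -> None:
        for name, g in self.groups.items():
            if g.n < 0:
                raise ValueError(f"group {name}: n must be >= 0")
            if not (0 < g.accuracy <= 1):
                raise ValueError(f"group {name}: accuracy must be in (0, 1]")
        for cond, spheres in self.planted_effects.items():
            for s in spheres:
                c, r = s["center"], s["radius"]
                if any(not (r <= ci <= dim - 1 - r + 1e-9)
                       for ci, dim in zip(c, self.bold_shape)):
                    raise ValueError(
                        f"planted sphere for {cond!r} at {c} (r={r}) leaves the grid")


def _pulse_template(fs_hz: float) -> np.ndarray:
    """Asymmetric raised-cosine pulse: fast systolic upstroke, slow decay."""
    rise = max(2, int(round(0.10 * fs_hz)))
    fall = max(3, int(round(0.30 * fs_hz)))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(rise) / rise))
    down = 0.5 * (1 + np.cos(np.pi * np.arange(fall + 1) / fall))
    return np.concatenate([up, down])


def gen_ppg(
    schedule: TrialSchedule,
    base_hr_bpm: float = 70.0,
    deceleration_depth_pct: float = 4.0,
    nadir_s: float = 3.0,
    width_s: float = 1.5,
    fs_hz: float = 50.0,
    jitter_ms: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition_scales: dict | None = None,
) -> tuple[PhysioTrace, np.ndarray]:
    """Simulate a pulse waveform with event-locked heart-rate deceleration.

    The instantaneous rate is the base rate minus a Gaussian-shaped dip
    (depth ``deceleration_depth_pct`` percent, nadir ``nadir_s`` after every
    trial onset, standard deviation ``width_s``), truncated to start at
    onset (the orienting response is causal) and scaled per condition by
    ``condition_scales`` (facial/mosaic/fixation; facial defaults to 1).
    Beats are placed by integrating the rate; timing jitter is applied per
    beat with SD ``jitter_ms / sqrt(2)`` so the inter-beat intervals carry
    variance ``(jitter_ms/1000)**2`` without any drift against the schedule
    clock.  Returns the waveform trace and the ground-truth beat times
    (post-jitter).
    """
    if not 40 <= base_hr_bpm <= 120:
        raise ValueError("base_hr_bpm must be within [40, 120]")
    if fs_hz < 25:
        raise ValueError("fs_hz must be >= 25 Hz for pulse morphology")
    if deceleration_depth_pct >= 100:
        raise ValueError("deceleration depth would drive heart rate <= 0")
    rng = np.random.default_rng(seed)
    scales = {"mosaic": 1.0, "fixation": 1.0}
    if condition_scales:
        scales.update(condition_scales)
    # Pre-roll before scan start so the first trial's baseline window and
    # the peak detector's warm-up are covered.
    pre_roll = 8.0
    duration = schedule.total_duration_s + 10.0 if schedule.trials else 60.0
    dt = 1.0 / fs_hz
    t = -pre_roll + np.arange(int((duration + pre_roll) * fs_hz)) * dt
    rate = np.full(t.size, float(base_hr_bpm))
    for tr in schedule.trials:
        sc = 1.0 if tr.condition == "facial" else scales[tr.condition]
        dip = sc * deceleration_depth_pct / 100.0 * base_hr_bpm
        # Causal response: the orienting deceleration starts at stimulus
        # onset, so the Gaussian is truncated to t >= onset.
        rel = t - tr.onset_s
        rate -= np.where(rel >= 0,
                         dip * np.exp(-0.5 * ((rel - nadir_s) / width_s) ** 2),
                         0.0)
    # Integrate the rate to place beats: the k-th beat falls where the
    # accumulated beat count crosses k.
    phase = np.concatenate(([0.0], np.cumsum(rate / 60.0) * dt))
    tgrid = np.concatenate((t, [t[-1] + dt])) + pre_roll
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, tgrid) - pre_roll
    if jitter_ms > 0:
        # Per-beat timing noise with SD jitter/sqrt(2), so successive
        # differences (the IBIs) carry variance jitter^2 without the beat
        # times drifting against the schedule clock.
        beat_times = np.sort(
            beat_times + rng.normal(0, jitter_ms / 1000.0 / np.sqrt(2.0),
                                    beat_times.size))
    # Render the waveform: one pulse template per beat plus white noise.
    wave = np.zeros(t.size)
    tmpl = _pulse_template(fs_hz)
    for bt in beat_times:
        i0 = int(round((bt + pre_roll) * fs_hz))
        if i0 < 0:
            continue
        seg = tmpl[: max(0, min(tmpl.size, t.size - i0))]
        if seg.size:
            wave[i0:i0 + seg.size] += seg
    if noise_sd > 0:
        wave = wave + rng.normal(0, noise_sd, wave.size)
    trace = PhysioTrace(wave, fs_hz, channel="ppg", start_time_s=-pre_roll)
    return trace, beat_times


def gen_pupil(
    schedule: TrialSchedule,
    baseline_units: float = 4.0,
    dilation_pct: float = 25.0,
    latency_s: float = 1.5,
    blink_rate_per_min: float = 4.0,
    fs_hz: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition_scales: dict | None = None,
) -> PhysioTrace:
    """Simulate a pupil-diameter trace with event-locked dilation and blinks.

    Each trial adds a smooth gamma-shaped dilation peaking ``latency_s`` after
    onset with amplitude ``dilation_pct`` percent of baseline (scaled per
    condition).  Measurement noise is temporally correlated (120-ms smoothed
    white noise), emulating tracker noise rather than white pixel noise.
    Blinks arrive as a Poisson process at ``blink_rate_per_min`` and replace
    100-300 ms runs with the sentinel value 0.
    """
    if baseline_units <= 0:
        raise ValueError("baseline_units must be positive")
    rng = np.random.default_rng(seed)
    scales = {"mosaic": 1.0, "fixation": 1.0}
    if condition_scales:
        scales.update(condition_scales)
    pre_roll = 8.0
    duration = schedule.total_duration_s + 10.0 if schedule.trials else 60.0
    dt = 1.0 / fs_hz
    t = -pre_roll + np.arange(int((duration + pre_roll) * fs_hz)) * dt
    x = np.full(t.size, float(baseline_units))
    k = 2.0  # gamma shape of the dilation bump (unit peak at latency)
    for tr in schedule.trials:
        sc = 1.0 if tr.condition == "facial" else scales[tr.condition]
        amp = sc * dilation_pct / 100.0 * baseline_units
        rel = np.clip((t - tr.onset_s) / latency_s, 0.0, 50.0)
        x += amp * rel ** k * np.exp(k * (1.0 - rel))  # zero at onset, peak 1 at latency
    if noise_sd > 0:
        w = max(1, int(round(0.12 * fs_hz)))
        noise = np.convolve(rng.normal(0, 1.0, t.size), np.ones(w) / w, mode="same")
        x = x + noise_sd * noise / max(noise.std(), 1e-12)
    if blink_rate_per_min > 0:
        total = duration + pre_roll
        n_blinks = rng.poisson(blink_rate_per_min * total / 60.0)
        for _ in range(n_blinks):
            b0 = rng.uniform(0, total)
            blen = rng.uniform(0.1, 0.3)
            i0, i1 = int(b0 * fs_hz), int((b0 + blen) * fs_hz)
            x[i0:i1] = PUPIL_SENTINEL
    return PhysioTrace(x, fs_hz, channel="pupil", start_time_s=-pre_roll)


def gen_motion(n_vols: int, motion_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Six random-walk motion parameter traces (3 translations, 3 rotations)."""
    steps = rng.normal(0, motion_sd, size=(n_vols, 6))
    return np.cumsum(steps, axis=0)


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    c = [(d - 1) / 2 for d in shape]
    r = [d / 2 - 0.5 for d in shape]
    dist = sum(((grid[i] - c[i]) / max(r[i], 1e-9)) ** 2 for i in range(3))
    return dist <= 1.0


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    dist = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return dist <= radius ** 2


def gen_bold(
    schedule: TrialSchedule,
    grid_shape: tuple[int, int, int] = DEFAULT_BOLD_SHAPE,
    planted_effects: dict | None = None,
    ar1_rho: float = 0.3,
    noise_sd: float = 1.0,
    motion_sd: float = 0.05,
    seed: int = 0,
    baseline: float = 100.0,
    motion_leak: float = 0.0,
    participant_id: str = "",
) -> tuple[BoldDataset, dict[str, np.ndarray], np.ndarray]:
    """Simulate a preprocessed 4-D BOLD run with planted condition effects.

    Signal = baseline + sum over conditions of amplitude x (boxcar (x) HRF)
    inside each planted sphere, plus AR(1) Gaussian noise (marginal SD
    ``noise_sd``).  Overlapping spheres sum.  The in-brain baseline keeps all
    brain voxels above the first-level 0.1 masking threshold.  Returns the
    dataset, boolean truth masks per condition, and the motion table (which
    leaks into the data with coefficient ``motion_leak``, default 0).
    """
    from .design import schedule_volume_count

    n_vols = schedule_volume_count(schedule) if schedule.trials else 40
    rng = np.random.default_rng(seed)
    shape = tuple(grid_shape)
    brain = _brain_mask(shape)
    data = np.zeros(shape + (n_vols,))
    data[brain] = baseline
    truth: dict[str, np.ndarray] = {}
    planted = planted_effects or {}
    for cond, spheres in planted.items():
        reg = condition_regressor(schedule, n_vols, cond) if schedule.trials else 0
        cond_mask = np.zeros(shape, dtype=bool)
        for s in spheres:
            m = _sphere_mask(shape, s["center"], s["radius"]) & brain
            cond_mask |= m
            data[m] += s["amplitude"] * reg
        truth[cond] = cond_mask
    # AR(1) noise with marginal SD noise_sd inside the brain.
    if noise_sd > 0:
        from scipy.signal import lfilter

        eps = rng.normal(0, noise_sd * np.sqrt(1 - ar1_rho ** 2),
                         size=(int(brain.sum()), n_vols))
        noise = lfilter([1.0], [1.0, -ar1_rho], eps, axis=1)
        data[brain] += noise
    motion = gen_motion(n_vols, motion_sd, rng)
    if motion_leak:
        weights = rng.normal(0, 1.0, size=(int(brain.sum()), 6))
        data[brain] += motion_leak * weights @ motion.T
    vox = DEFAULT_VOXEL_MM
    affine = np.diag([vox, vox, vox, 1.0])
    ds = BoldDataset(data, tr_s=schedule.tr_s, affine=affine,
                     participant_id=participant_id)
    return ds, truth, motion


def gen_behaviour(
    confusion_by_group: dict[str, np.ndarray],
    n_per_group: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Sample emotion-identification responses from group confusion matrices.

    Each participant answers 10 trials per emotion (50 total); row ``i`` of a
    group's 5x5 matrix gives the response distribution when the true emotion
    is ``EMOTIONS[i]``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sub = 0
    for group, n in n_per_group.items():
        M = np.asarray(confusion_by_group[group], dtype=float)
        if M.shape != (len(EMOTIONS), len(EMOTIONS)):
            raise ValueError(f"group {group}: confusion matrix must be 5x5")
        if np.any(M < 0) or not np.allclose(M.sum(axis=1), 1.0):
            raise ValueError(f"group {group}: confusion rows must sum to 1")
        for _ in range(n):
            pid = f"sub-{sub:03d}"
            sub += 1
            trial = 0
            for ei, emo in enumerate(EMOTIONS):
                picks = rng.choice(len(EMOTIONS), size=10, p=M[ei])
                for p in picks:
                    rows.append({"participant": pid, "group": group,
                                 "trial": trial, "true_emotion": emo,
                                 "response_emotion": EMOTIONS[p]})
                    trial += 1
    return pd.DataFrame(rows)


def gen_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Write a complete synthetic cohort to disk in the pipeline's formats.

    One directory per participant (events TSV, PPG and pupil TSV+JSON, BOLD
    NIfTI, motion TSV), plus ``participants.tsv``, ``responses.tsv`` and a
    ground-truth manifest ``truth.json``.  Every derived seed is a pure
    function of ``spec.seed`` and the participant index.  Returns the
    manifest.
    """
    from . import io as io_mod

    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(spec.seed)
    manifest: dict = {"seed": spec.seed, "groups": {}, "participants": {},
                      "planted_effects": {
                          c: [{**s, "center": list(s["center"])} for s in sp]
                          for c, sp in spec.planted_effects.items()},
                      }
    part_rows = []
    sub = 0
    cond_scales = {"mosaic": spec.mosaic_condition_scale,
                   "fixation": spec.fixation_condition_scale}
    for gname, g in spec.groups.items():
        manifest["groups"][gname] = asdict(g)
        for _ in range(g.n):
            pid = f"sub-{sub:03d}"
            pseed = int(root_rng.integers(0, 2 ** 31 - 1))
            pdir = out / pid
            pdir.mkdir(exist_ok=True)
            schedule = build_trial_schedule(
                spec.n_facial, spec.n_mosaic, spec.n_fixation, seed=pseed)
            io_mod.write_events(schedule, pdir / "events.tsv")
            ppg, beats = gen_ppg(
                schedule, spec.base_hr_bpm, g.cardiac_dip_pct,
                fs_hz=spec.ppg_fs_hz, jitter_ms=spec.hr_jitter_ms,
                noise_sd=spec.ppg_noise_sd, seed=pseed + 1,
                condition_scales=cond_scales)
            io_mod.write_physio(ppg, pdir / "ppg.tsv.gz")
            pupil = gen_pupil(
                schedule, spec.pupil_baseline_units, g.pupil_dilation_pct,
                g.pupil_latency_s, spec.blink_rate_per_min,
                fs_hz=spec.pupil_fs_hz, noise_sd=spec.pupil_noise_sd,
                seed=pseed + 2, condition_scales=cond_scales)
            io_mod.write_physio(pupil, pdir / "pupil.tsv.gz")
            planted = {
                cond: [{**s, "amplitude": s["amplitude"] * g.bold_amplitude}
                       for s in spheres]
                for cond, spheres in spec.planted_effects.items()}
            bold, truth, motion = gen_bold(
                schedule, spec.bold_shape, planted, spec.ar1_rho,
                spec.bold_noise_sd, spec.motion_sd, seed=pseed + 3,
                participant_id=pid)
            io_mod.write_nifti(bold, pdir / "bold.nii.gz")
            io_mod.write_table(
                pd.DataFrame(motion, columns=[f"motion_{i+1}" for i in range(6)]),
                pdir / "motion.tsv")
            manifest["participants"][pid] = {
                "group": gname, "seed": pseed,
                "n_beats": int(beats.size),
                "planted_amplitudes": {
                    c: [s["amplitude"] for s in sp] for c, sp in planted.items()},
            }
            part_rows.append({"participant": pid, "group": gname})
            sub += 1
    confusions = {g: _confusion_from_accuracy(p.accuracy)
                  for g, p in spec.groups.items()}
    responses = gen_behaviour(confusions, {g: p.n for g, p in spec.groups.items()},
                              seed=spec.seed + 99)
    io_mod.write_table(responses, out / "responses.tsv")
    io_mod.write_table(pd.DataFrame(part_rows), out / "participants.tsv")
    io_mod.write_json(manifest, out / "truth.json")
    return manifest
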