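"""Pupillary reactivity scoring with blink handling and trial exclusion.

Pupil reactivity for a trial is the ratio

    100 * max pupil size during 5 s post stimulus onset
        / mean pupil size during 1 s prior to stimulus onset

computed over valid samples only (tracker dropouts and their padded
neighbourhoods are invalid).  Trials whose ratio exceeds the experimental
(all-participants pooled) mean by more than 2 SD are flagged as likely
blink-contaminated, and trials with insufficient pupil capture are flagged
separately; flags are non-destructive.  Fixation trials are never scored:
their luminance differs too much from the video conditions for a direct
comparison.  The ratio is unit-invariant, so diameter vs area conventions do
not matter.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .trace import PhysioTrace

logger = logging.getLogger(__name__)

BASELINE_WINDOW_S = 1.0
POST_WINDOW_S = 5.0

REASON_OUTLIER = "outlier_2sd"
REASON_CAPTURE = "insufficient_capture"
REASON_COVERAGE = "insufficient_coverage"


@dataclass
class PupilReactivity:
    """Per-trial pupil reactivity ratio (percent) with exclusion bookkeeping."""

    trial_index: int
    ratio_pct: float = np.nan
    capture_fraction: float = 0.0
    excluded: bool = False
    reason: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ratio_pct)


def mark_valid_samples(
    trace: PhysioTrace,
    dropout_value: float = 0.0,
    pad_s: float = 0.05,
) -> PhysioTrace:
    """Mark tracker dropouts (sentinel-valued samples) invalid, with padding.

    Samples equal to ``dropout_value`` (NaN sentinels are matched with isnan)
    are invalidated together with ``pad_s`` seconds on each side of every
    dropout run, since pupil estimates immediately around a blink are
    distorted by the closing/opening lid.  Sample values are left untouched.
    """
    if trace.channel != "pupil":
        raise ValueError("mark_valid_samples expects a pupil trace")
    x = trace.samples
    if np.isnan(dropout_value):
        dropped = np.isnan(x)
    else:
        dropped = x == dropout_value
    invalid = dropped.copy()
    pad_n = int(round(pad_s * trace.fs_hz))
    if pad_n > 0 and dropped.any():
        idx = np.nonzero(dropped)[0]
        for i in idx:  # runs are short; simple dilation
            invalid[max(0, i - pad_n): i + pad_n + 1] = True
    return replace(trace, valid=trace.valid & ~invalid)


def pupil_reactivity(trace: PhysioTrace, onset_s: float) -> PupilReactivity:
    """Score one trial with the max-post / mean-baseline ratio (percent).

    Requires the trace to cover ``[onset - 1 s, onset + 5 s]``.  The ratio
    uses valid samples only; ``capture_fraction`` is the valid fraction over
    the whole analysis window.  A zero or negative baseline mean raises
    (degenerate baseline); an empty valid baseline or post window yields an
    excluded record instead.
    """
    if trace.channel != "pupil":
        raise ValueError("pupil_reactivity expects a pupil trace")
    rec = PupilReactivity(trial_index=-1)
    if (onset_s - BASELINE_WINDOW_S < trace.start_time_s - 0.5 / trace.fs_hz
            or onset_s + POST_WINDOW_S > trace.end_time_s + 0.5 / trace.fs_hz):
        rec.excluded = True
        rec.reason = REASON_COVERAGE
        return rec
    base_idx = trace.window_indices(onset_s - BASELINE_WINDOW_S, onset_s, closed="left")
    post_idx = trace.window_indices(onset_s, onset_s + POST_WINDOW_S, closed="right")
    window_idx = np.concatenate([base_idx, post_idx])
    rec.capture_fraction = float(trace.valid[window_idx].mean()) if window_idx.size else 0.0
    base_valid = base_idx[trace.valid[base_idx]]
    post_valid = post_idx[trace.valid[post_idx]]
    if base_valid.size == 0 or post_valid.size == 0:
        rec.excluded = True
        rec.reason = REASON_CAPTURE
        return rec
    baseline = float(trace.samples[base_valid].mean())
    if baseline <= 0:
        raise ValueError("degenerate baseline: mean pupil size <= 0")
    rec.ratio_pct = 100.0 * float(trace.samples[post_valid].max()) / baseline
    return rec


def score_schedule_pupil(trace: PhysioTrace, schedule) -> list[PupilReactivity]:
    """Score facial and mosaic trials of a schedule (fixation is never scored)."""
    out = []
    for tr in schedule.trials:
        if tr.condition == "fixation":
            continue
        rec = pupil_reactivity(trace, tr.onset_s)
        rec.trial_index = tr.index
        out.append(rec)
    return out


def exclude_pupil_trials(
    records: list[PupilReactivity],
    sd_mult: float = 2.0,
    min_capture: float = 0.5,
) -> list[PupilReactivity]:
    """Apply the experiment-wide exclusion rules (non-destructively).

    The outlier rule flags ratios more than ``sd_mult`` population SDs above
    the pooled mean of all defined ratios in the experiment (one pass, high
    side only -- low ratios are not artefactual in the same way).  The capture
    rule flags records with ``capture_fraction < min_capture``.  Values are
    retained on flagged records, so re-running on the output is a no-op.
    """
    ratios = np.array([r.ratio_pct for r in records if r.defined])
    use_sd_rule = ratios.size >= 2
    if use_sd_rule:
        mean, sd = float(ratios.mean()), float(ratios.std())  # population SD
        cutoff = mean + sd_mult * sd
    out: list[PupilReactivity] = []
    n_out, n_cap = 0, 0
    for r in records:
        r2 = replace(r)
        if r2.capture_fraction < min_capture and r2.reason != REASON_COVERAGE:
            r2.excluded = True
            r2.reason = REASON_CAPTURE
            n_cap += 1
        elif use_sd_rule and r2.defined and r2.ratio_pct > cutoff:
            r2.excluded = True
            r2.reason = REASON_OUTLIER
            n_out += 1
        out.append(r2)
    n_total = len(records)
    n_excluded = sum(r.excluded for r in out)
    logger.info(
        "pupil exclusion: %d/%d trials excluded (%.1f%%): %d outlier_2sd, "
        "%d insufficient_capture",
        n_excluded, n_total, 100.0 * n_excluded / max(n_total, 1), n_out, n_cap,
    )
    return out


def participant_mean_pupil(records: list[PupilReactivity]) -> float | None:
    """Mean ratio over a participant's retained (non-excluded) trials.

    Returns ``None`` when no trials survive exclusion, in which case the
    participant is dropped from covariate analyses (a warning is logged).
    """
    kept = [r.ratio_pct for r in records if not r.excluded and r.defined]
    if not kept:
        logger.warning("participant has no retained pupil trials; dropped from covariates")
        return None
    return float(np.mean(kept))
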