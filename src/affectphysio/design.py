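"""Stimulus schedule construction and the dynamic-mosaic baseline operator.

The experiment presents short videos of dynamic facial expressions (five
emotions: anger, disgust, fear, happiness, surprise), scrambled "mosaic"
versions of the same videos as a complex visual baseline, and fixation-cross
trials, in a pseudorandomized block design of five stimuli per block.  Every
trial is triggered at the onset of an EPI volume (TR = 2.93 s), so trial
onsets are exact volume multiples; video trials span 4 volumes (onset-to-onset
11.72 s) and fixation trials 3 volumes (8.79 s).

The mosaic operator divides every video frame into a fixed grid of equal
rectangles (20 x 20 = 400 in the study) and applies one random tile
permutation per stimulus, identical across all frames, preserving luminance,
colour, contrast and motion statistics while destroying facial configuration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

TR_S = 2.93
"""Repetition time of the EPI acquisition, seconds."""

EMOTIONS = ("anger", "disgust", "fear", "happiness", "surprise")
POSITIVE_EMOTIONS = frozenset({"happiness", "surprise"})
NEGATIVE_EMOTIONS = frozenset({"anger", "disgust", "fear"})

VIDEO_VOLUMES = 4
FIXATION_VOLUMES = 3

_ONSET_TOL = 1e-6


def valence_of(emotion: str) -> str:
    """Map an emotion label to its valence class.

    Happiness and surprise are positive; anger, disgust and fear are negative.
    Sadness is not part of the stimulus set (its diffuse time course sets it
    apart from the other dynamic expressions) and is rejected like any other
    unknown label.
    """
    if emotion in POSITIVE_EMOTIONS:
        return "positive"
    if emotion in NEGATIVE_EMOTIONS:
        return "negative"
    raise ValueError(
        f"unknown emotion {emotion!r}: expected one of {sorted(EMOTIONS)}"
    )


@dataclass(frozen=True)
class Trial:
    """One scheduled trial."""

    index: int
    condition: str  # facial | mosaic | fixation
    emotion: str  # one of EMOTIONS for facial trials, "none" otherwise
    onset_s: float
    duration_s: float
    n_volumes: int


@dataclass
class TrialSchedule:
    """Ordered trial list plus the scanner TR; the shared temporal backbone.

    Invariants (checked by :meth:`validate`): onsets strictly increasing and
    volume-locked (integer multiples of ``tr_s``); video trials span 4 volumes
    and fixation trials 3; ``emotion == "none"`` exactly for non-facial trials.
    """

    trials: list[Trial] = field(default_factory=list)
    tr_s: float = TR_S

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        prev = -math.inf
        for t in self.trials:
            if t.onset_s <= prev:
                raise ValueError(f"trial {t.index}: onsets must be strictly increasing")
            prev = t.onset_s
            ratio = t.onset_s / self.tr_s
            if abs(ratio - round(ratio)) > _ONSET_TOL:
                raise ValueError(
                    f"trial {t.index}: onset {t.onset_s} is not a multiple of tr_s"
                )
            if t.condition in ("facial", "mosaic"):
                if t.n_volumes != VIDEO_VOLUMES:
                    raise ValueError(f"trial {t.index}: video trials span 4 volumes")
            elif t.condition == "fixation":
                if t.n_volumes != FIXATION_VOLUMES:
                    raise ValueError(f"trial {t.index}: fixation trials span 3 volumes")
            else:
                raise ValueError(f"trial {t.index}: unknown condition {t.condition!r}")
            if (t.condition == "facial") != (t.emotion != "none"):
                raise ValueError(
                    f"trial {t.index}: emotion must be 'none' iff condition != facial"
                )
            if t.condition == "facial" and t.emotion not in EMOTIONS:
                raise ValueError(f"trial {t.index}: unknown emotion {t.emotion!r}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        """Scan time implied by the schedule: total volume count times TR."""
        return schedule_volume_count(self) * self.tr_s

    def facial_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.condition == "facial"]


def schedule_volume_count(schedule: TrialSchedule) -> int:
    """Total EPI volumes spanned: 4 per video trial, 3 per fixation trial."""
    return sum(t.n_volumes for t in schedule.trials)


def _draw_video_duration(rng: np.random.Generator) -> float:
    # Videos last 4-8 s; beta(0.9, 3.1) on that range has mean 4.9 s, matching
    # the stated range and mean of the stimulus set.
    return 4.0 + 4.0 * rng.beta(0.9, 3.1)


def build_trial_schedule(
    n_facial: int,
    n_mosaic: int,
    n_fixation: int,
    block_size: int = 5,
    isi_video_s: float = 11.72,
    isi_fixation_s: float = 8.79,
    seed: int = 0,
    *,
    tr_s: float = TR_S,
    emotion_order: str = "mixed",
) -> TrialSchedule:
    """Build a pseudorandomized block schedule.

    Trials are grouped into condition-homogeneous blocks of ``block_size``;
    block order is a seeded permutation re-drawn (up to 1000 attempts) until no
    two consecutive blocks share a condition, falling back to the best effort
    when unavoidable.  Onsets advance by the condition-specific onset-to-onset
    ISI, which must be a positive multiple of the TR (trials are
    scanner-triggered at volume onsets).

    Parameters
    ----------
    emotion_order:
        ``"mixed"`` deals the five emotions across facial blocks (shuffled
        pool, equal counts when divisible); ``"blocked"`` gives each facial
        block a single emotion.  Which arrangement the original experiment
        used is not knowable from its description, so both are offered.
    """
    for name, v in (("n_facial", n_facial), ("n_mosaic", n_mosaic),
                    ("n_fixation", n_fixation)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if block_size <= 0:
        raise ValueError(f"block_size must be > 0, got {block_size}")
    for name, isi in (("isi_video_s", isi_video_s), ("isi_fixation_s", isi_fixation_s)):
        if isi <= 0:
            raise ValueError(f"{name} must be positive, got {isi}")
        ratio = isi / tr_s
        if abs(ratio - round(ratio)) > _ONSET_TOL or round(ratio) < 1:
            raise ValueError(
                f"{name}={isi} is not a positive multiple of tr_s={tr_s}"
            )
    for name, v in (("n_facial", n_facial), ("n_mosaic", n_mosaic),
                    ("n_fixation", n_fixation)):
        if v > 0 and v % block_size:
            raise ValueError(
                f"{name}={v} is not divisible by block_size={block_size}; "
                "blocks are condition-homogeneous"
            )
    if emotion_order not in ("mixed", "blocked"):
        raise ValueError(f"emotion_order must be 'mixed' or 'blocked', got {emotion_order!r}")

    rng = np.random.default_rng(seed)

    blocks = (["facial"] * (n_facial // block_size)
              + ["mosaic"] * (n_mosaic // block_size)
              + ["fixation"] * (n_fixation // block_size))

    def n_adjacent(order: list[str]) -> int:
        return sum(a == b for a, b in zip(order, order[1:]))

    best: list[str] = list(blocks)
    if blocks:
        best_score = math.inf
        for _ in range(1000):
            cand = [blocks[i] for i in rng.permutation(len(blocks))]
            score = n_adjacent(cand)
            if score < best_score:
                best, best_score = cand, score
            if score == 0:
                break

    # Emotion assignment for facial trials.
    n_fblocks = n_facial // block_size
    emo_pool: list[str] = []
    if emotion_order == "mixed":
        emo_pool = [EMOTIONS[i % len(EMOTIONS)] for i in range(n_facial)]
        rng.shuffle(emo_pool)
    else:
        block_emos = [EMOTIONS[i % len(EMOTIONS)] for i in range(n_fblocks)]
        rng.shuffle(block_emos)
        for e in block_emos:
            emo_pool.extend([e] * block_size)
    emo_iter = iter(emo_pool)

    trials: list[Trial] = []
    t = 0.0
    idx = 0
    for cond in best:
        for _ in range(block_size):
            if cond == "fixation":
                n_vol, isi = FIXATION_VOLUMES, isi_fixation_s
                emotion, dur = "none", isi_fixation_s
            else:
                n_vol, isi = VIDEO_VOLUMES, isi_video_s
                dur = min(_draw_video_duration(rng), isi_video_s)
                emotion = next(emo_iter) if cond == "facial" else "none"
            trials.append(Trial(idx, cond, emotion, round(t, 6), dur, n_vol))
            t += isi
            idx += 1
    return TrialSchedule(trials, tr_s=tr_s)


@dataclass
class FrameStack:
    """An ordered stack of equal-shape 2-D frames (one video stimulus)."""

    frames: np.ndarray  # (n_frames, height, width)
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (n_frames, height, width)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("pixel values must be finite")


def tile_permutation(n_tiles: int, seed: int) -> np.ndarray:
    """The seeded tile permutation used by :func:`scramble_frames`."""
    return np.random.default_rng(seed).permutation(n_tiles)


def scramble_frames(
    stack: FrameStack,
    grid_rows: int = 20,
    grid_cols: int = 20,
    seed: int = 0,
    *,
    inverse: bool = False,
) -> FrameStack:
    """Scramble every frame by one shared random permutation of grid tiles.

    Each frame is divided into ``grid_rows x grid_cols`` equal rectangles and
    the same seeded permutation of tile positions is applied to all frames, so
    the per-frame pixel multiset is preserved and motion energy stays locally
    coherent within tiles.  ``inverse=True`` applies the inverse permutation,
    restoring an earlier scramble with the same seed bit-exactly.
    """
    n, h, w = stack.frames.shape
    if grid_rows <= 0 or grid_cols <= 0:
        raise ValueError("grid_rows and grid_cols must be positive")
    if h % grid_rows or w % grid_cols:
        raise ValueError(
            f"frame shape ({h}, {w}) must be divisible by grid ({grid_rows}, {grid_cols})"
        )
    th, tw = h // grid_rows, w // grid_cols
    perm = tile_permutation(grid_rows * grid_cols, seed)
    if inverse:
        perm = np.argsort(perm)
    tiles = (stack.frames
             .reshape(n, grid_rows, th, grid_cols, tw)
             .transpose(0, 1, 3, 2, 4)
             .reshape(n, grid_rows * grid_cols, th, tw))
    out = (tiles[:, perm]
           .reshape(n, grid_rows, grid_cols, th, tw)
           .transpose(0, 1, 3, 2, 4)
           .reshape(n, h, w))
    return FrameStack(out, frame_rate_hz=stack.frame_rate_hz)
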