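"""Mass-univariate BOLD GLM: first-level designs, OLS fits, contrasts, group models.

First level
-----------
Each experimental condition (facial trials split by emotion, mosaic,
fixation) is modelled as a boxcar over the duration of each individual trial
on a fine time grid (dt = TR/16), convolved with the canonical double-gamma
haemodynamic response function, and sampled at volume onsets.  Six head
motion parameters enter as mean-centred covariates of no interest plus an
intercept.  Voxels are analysed inside a liberal mask (mean signal above 0.1
of the global mean) so that atrophic regions are not excluded before the
second level.  Fitting is ordinary least squares; an optional single-rho
AR(1) prewhitening (Cochrane-Orcutt) is available since event-related BOLD
noise is serially correlated.

Second level
------------
Subject contrast maps enter a one-factor layout with diagnostic group
(control, bvFTD, svPPA, nfvPPA) as the level variable, cell-means coded, over
a study-specific majority mask (voxels defined in more than half of
subjects).  Group differences are assessed with a one-way F across group
means; per-participant covariates (emotion identification score, cardiac or
pupil reactivity) are tested as within-group slope maps with an optional
nuisance covariate (e.g. BPVS vocabulary score).  Cluster-level FWE inference
lives in :mod:`affectphysio.cluster`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import gamma as gamma_dist

from .design import EMOTIONS, NEGATIVE_EMOTIONS, POSITIVE_EMOTIONS, TrialSchedule

logger = logging.getLogger(__name__)

GROUPS = ("control", "bvFTD", "svPPA", "nfvPPA")

HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
OVERSAMPLE = 16


@dataclass
class BoldDataset:
    """A preprocessed 4-D BOLD run on a common grid."""

    volumes: np.ndarray  # (x, y, z, t)
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, time)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[-1]


@dataclass
class DesignMatrix:
    """Named first-level regressors (time x columns)."""

    matrix: np.ndarray
    names: list[str]
    condition_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix columns must match names")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class StatMap:
    """A voxelwise statistic grid (NaN outside the analysis mask)."""

    values: np.ndarray  # 3-D
    df: tuple[float, float]  # (num, den); num = 1 for t
    stat_kind: str  # "t" | "f"
    mask: np.ndarray

    def __neg__(self) -> "StatMap":
        if self.stat_kind != "t":
            raise ValueError("only t maps can be negated")
        return StatMap(-self.values, self.df, self.stat_kind, self.mask)


@dataclass
class FirstLevelFit:
    """OLS results for one subject: betas, residual variance, mask, design."""

    betas: np.ndarray  # (p, n_mask_voxels)
    sigma2: np.ndarray  # (n_mask_voxels,)
    df_resid: float
    mask: np.ndarray  # 3-D bool
    design: DesignMatrix
    cov_unscaled: np.ndarray  # pinv(X'X)
    shape: tuple[int, int, int]

    def unmask(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.shape, np.nan)
        out[self.mask] = flat
        return out


def canonical_hrf(dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt_s``, scaled to unit peak.

    Peak delay 6 s, undershoot delay 16 s, dispersions 1, undershoot ratio
    1/6; with these parameters the kernel's mode sits near 5 s and the tail
    at 32 s is below 1% of the peak.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(int(np.floor(duration_s / dt_s)) + 1) * dt_s
    h = (gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
         - HRF_UNDERSHOOT_RATIO
         * gamma_dist.pdf(t, HRF_UNDERSHOOT_DELAY_S / HRF_UNDERSHOOT_DISP,
                          scale=HRF_UNDERSHOOT_DISP))
    return h / h.max()


def condition_of(trial) -> str:
    """First-level condition name of a trial (facial trials split by emotion)."""
    if trial.condition == "facial":
        return f"facial_{trial.emotion}"
    return trial.condition


def condition_regressor(
    schedule: TrialSchedule,
    n_vols: int,
    condition: str,
    oversample: int = OVERSAMPLE,
) -> np.ndarray:
    """Boxcar (x) HRF regressor for one condition, sampled at volume onsets.

    ``condition`` may be a split name (``facial_fear``), a raw condition
    (``mosaic``, ``fixation``) or ``facial`` (all facial trials pooled).
    """
    dt = schedule.tr_s / oversample
    n_fine = n_vols * oversample
    box = np.zeros(n_fine)
    for tr in schedule.trials:
        match = (condition_of(tr) == condition
                 or tr.condition == condition)
        if not match:
            continue
        end = tr.onset_s + tr.duration_s
        if end > n_vols * schedule.tr_s + 1e-9:
            raise ValueError(
                f"trial {tr.index} (onset {tr.onset_s}, duration {tr.duration_s}) "
                f"extends past scan end {n_vols * schedule.tr_s:.2f} s"
            )
        i0 = int(np.round(tr.onset_s / dt))
        i1 = min(int(np.ceil(end / dt)), n_fine)
        box[i0:i1] = 1.0
    hrf = canonical_hrf(dt)
    fine = np.convolve(box, hrf)[:n_fine] * dt
    return fine[::oversample][:n_vols]


def build_first_level_design(
    schedule: TrialSchedule,
    n_vols: int,
    motion: np.ndarray | None = None,
    oversample: int = OVERSAMPLE,
) -> DesignMatrix:
    """First-level design: per-condition boxcar (x) HRF columns + nuisance.

    Condition columns appear only for conditions with at least one trial
    (facial split by emotion in the fixed order anger, disgust, fear,
    happiness, surprise; then mosaic; then fixation).  Motion columns are
    mean-centred; an intercept is appended last.
    """
    present = {condition_of(t) for t in schedule.trials}
    cond_names = [f"facial_{e}" for e in EMOTIONS if f"facial_{e}" in present]
    cond_names += [c for c in ("mosaic", "fixation") if c in present]
    cols, names = [], []
    for c in cond_names:
        cols.append(condition_regressor(schedule, n_vols, c, oversample))
        names.append(c)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_vols:
            raise ValueError("motion rows must equal n_vols")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j] - motion[:, j].mean())
            names.append(f"motion_{j + 1}")
    cols.append(np.ones(n_vols))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, cond_names)


def _ar1_prewhiten(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Single global-rho Cochrane-Orcutt prewhitening of data and design."""
    b = np.linalg.pinv(X) @ Y
    r = Y - X @ b
    num = float((r[1:] * r[:-1]).sum())
    den = float((r[:-1] ** 2).sum())
    rho = 0.0 if den == 0 else np.clip(num / den, -0.99, 0.99)
    Yw = Y[1:] - rho * Y[:-1]
    Xw = X[1:] - rho * X[:-1]
    return Yw, Xw, rho


def fit_first_level(
    bold: BoldDataset,
    design: DesignMatrix,
    mask_frac: float = 0.1,
    ar1: bool = False,
) -> FirstLevelFit:
    """Per-voxel OLS over the liberal first-level mask.

    The analysis mask keeps voxels whose mean signal exceeds ``mask_frac``
    times the global mean signal (default 0.1).  Rank-deficient designs are
    fitted via the pseudoinverse with a logged warning and the effective rank
    reduces the residual degrees of freedom.
    """
    X = design.matrix
    if X.shape[0] != bold.n_volumes:
        raise ValueError("design rows must equal number of volumes")
    data = bold.volumes
    vox_mean = data.mean(axis=-1)
    global_mean = float(data.mean())
    mask = vox_mean > mask_frac * global_mean
    Y = data[mask].T  # time x voxels
    rho = 0.0
    if ar1:
        Y, X, rho = _ar1_prewhiten(Y, X)
        logger.info("AR(1) prewhitening with global rho=%.3f", rho)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "using pseudoinverse", rank, X.shape[1])
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    df = X.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / df
    return FirstLevelFit(
        betas=betas,
        sigma2=sigma2,
        df_resid=float(df),
        mask=mask,
        design=design,
        cov_unscaled=np.linalg.pinv(X.T @ X),
        shape=data.shape[:3],
    )


def contrast_weights(design: DesignMatrix, name: str) -> np.ndarray:
    """Standard contrast vectors, balanced within sides, zero-sum across conditions.

    Available: ``facial_gt_fixation``, ``facial_gt_mosaic``,
    ``positive_gt_negative``, ``negative_gt_positive``.
    """
    w = np.zeros(len(design.names))
    facial = [n for n in design.condition_names if n.startswith("facial_")]
    pos = [n for n in facial if n.removeprefix("facial_") in POSITIVE_EMOTIONS]
    neg = [n for n in facial if n.removeprefix("facial_") in NEGATIVE_EMOTIONS]

    def put(cols: list[str], value: float) -> None:
        if not cols:
            raise ValueError(f"contrast {name!r} needs condition columns that are absent")
        for c in cols:
            w[design.names.index(c)] = value

    if name == "facial_gt_fixation":
        put(facial, 1.0 / len(facial))
        put(["fixation"], -1.0)
    elif name == "facial_gt_mosaic":
        put(facial, 1.0 / len(facial))
        put(["mosaic"], -1.0)
    elif name == "positive_gt_negative":
        put(pos, 1.0 / len(pos))
        put(neg, -1.0 / len(neg))
    elif name == "negative_gt_positive":
        put(neg, 1.0 / len(neg))
        put(pos, -1.0 / len(pos))
    else:
        raise ValueError(f"unknown contrast {name!r}")
    return w


def t_contrast(fit: FirstLevelFit, weights: np.ndarray) -> StatMap:
    """Voxelwise t statistic for a contrast of first-level betas."""
    w = np.asarray(weights, dtype=float)
    if w.size != fit.betas.shape[0]:
        raise ValueError("weights length must equal number of design columns")
    if not np.any(w):
        raise ValueError("all-zero t contrast weights")
    effect = w @ fit.betas
    var = fit.sigma2 * float(w @ fit.cov_unscaled @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(var)
    return StatMap(fit.unmask(t), (1.0, fit.df_resid), "t", fit.mask)


def f_contrast(fit: FirstLevelFit, weight_rows: np.ndarray) -> StatMap:
    """Voxelwise F statistic for a multi-row contrast matrix."""
    C = np.atleast_2d(np.asarray(weight_rows, dtype=float))
    q = C.shape[0]
    B = C @ fit.betas  # q x V
    M = C @ fit.cov_unscaled @ C.T
    sol = np.linalg.solve(M, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (B * sol).sum(axis=0) / (q * fit.sigma2)
    return StatMap(fit.unmask(F), (float(q), fit.df_resid), "f", fit.mask)


def contrast_map_3d(fit: FirstLevelFit, weights: np.ndarray) -> np.ndarray:
    """Contrast-of-betas effect map (3-D, NaN outside mask) for second level."""
    w = np.asarray(weights, dtype=float)
    return fit.unmask(w @ fit.betas)


# --------------------------------------------------------------------------
# Second level
# --------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Second-level inputs: stacked subject maps, labels, covariates, mask.

    ``data`` is subjects x in-mask voxels (NaN where a subject is undefined
    at a retained voxel); the majority mask keeps voxels defined in more than
    ``majority_frac`` of subjects.
    """

    data: np.ndarray  # n_subjects x n_mask_voxels
    mask: np.ndarray  # 3-D bool
    subjects: list[str]
    groups: np.ndarray  # str array, len n_subjects
    covariates: "object" = None  # pandas DataFrame indexed by subject, optional
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    shape: tuple[int, int, int] = (0, 0, 0)

    def unmask(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.shape, np.nan)
        out[self.mask] = flat
        return out


def build_group_design(
    maps: list[np.ndarray],
    groups: list[str],
    covariates=None,
    majority_frac: float = 0.5,
    subjects: list[str] | None = None,
    affine: np.ndarray | None = None,
) -> GroupDesign:
    """Stack co-registered subject maps under the study majority mask.

    A voxel is retained when it is defined (finite) in strictly more than
    ``majority_frac`` of subjects.  Grid mismatches are rejected naming the
    offending subjects.  Group membership is cell-means coded downstream.
    """
    if len(maps) != len(groups):
        raise ValueError("one group label per subject map required")
    if subjects is None:
        subjects = [f"sub-{i:02d}" for i in range(len(maps))]
    shape = np.asarray(maps[0]).shape
    bad = [s for s, m in zip(subjects, maps) if np.asarray(m).shape != shape]
    if bad:
        raise ValueError(f"subject maps not co-registered (grid mismatch): {bad}")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    defined = np.isfinite(stack)
    mask = defined.sum(axis=0) > majority_frac * len(maps)
    data = stack[:, mask]
    return GroupDesign(
        data=data,
        mask=mask,
        subjects=list(subjects),
        groups=np.asarray(groups),
        covariates=covariates,
        affine=np.eye(4) if affine is None else affine,
        shape=tuple(shape),
    )


def _oneway_f(data: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Vectorised one-way fixed-effects F across group means, NaN-aware."""
    labels = np.unique(groups)
    k = labels.size
    n_tot = np.isfinite(data).sum(axis=0).astype(float)
    ssw = np.zeros(data.shape[1])
    ssb = np.zeros(data.shape[1])
    grand = np.nanmean(data, axis=0)
    ok = np.ones(data.shape[1], dtype=bool)
    for g in labels:
        sub = data[groups == g]
        n_g = np.isfinite(sub).sum(axis=0).astype(float)
        ok &= n_g >= 2
        m_g = np.nanmean(sub, axis=0)
        ssb += n_g * (m_g - grand) ** 2
        ssw += np.nansum((sub - m_g) ** 2, axis=0)
    df1 = float(k - 1)
    df2 = n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F[~ok | (ssw == 0)] = np.nan  # degenerate: no residual variance
    return F, df1, float(np.median(df2[ok])) if ok.any() else 0.0


def group_effect_map(design: GroupDesign) -> StatMap:
    """One-way F across diagnostic-group means at every in-mask voxel.

    Voxels with zero residual variance (all subjects identical) carry no
    information about group differences and are masked out (NaN).  Each group
    must contribute at least two subjects.
    """
    labels, counts = np.unique(design.groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups for an F test")
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"groups with < 2 subjects: {list(small)}")
    F, df1, df2 = _oneway_f(design.data, design.groups)
    return StatMap(design.unmask(F), (df1, df2), "f", design.mask)


def group_cluster_betas(design: GroupDesign, cluster_mask: np.ndarray):
    """Per-group summary of subject responses over a cluster ("beta plot" data).

    Returns a pandas DataFrame with one row per subject: group and the mean
    map value over all voxels of the cluster.
    """
    import pandas as pd

    flat = cluster_mask[design.mask]
    vals = np.nanmean(design.data[:, flat], axis=1)
    return pd.DataFrame({
        "subject": design.subjects,
        "group": design.groups,
        "cluster_mean": vals,
    })


def condition_effect_map(design: GroupDesign) -> StatMap:
    """One-sample t across all subjects for the condition effect."""
    X = design.data
    n = np.isfinite(X).sum(axis=0).astype(float)
    mean = np.nanmean(X, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.nanvar(X, axis=0, ddof=1)
        t = mean / np.sqrt(var / n)
    t[n < 2] = np.nan
    return StatMap(design.unmask(t), (1.0, float(np.median(n) - 1)), "t", design.mask)


def covariate_slope_map(
    design: GroupDesign,
    covariate_name: str,
    within_group: str | None = None,
    nuisance: str | list[str] | None = None,
) -> StatMap:
    """Voxelwise t for a per-participant covariate slope within one group.

    Fits ``map ~ 1 + covariate (+ nuisance)`` over the selected subjects and
    returns the t map of the covariate slope (both signs meaningful: negative
    slopes of heart-rate change index parasympathetic engagement, positive
    slopes sympathetic).  Subjects missing the covariate are dropped from
    this analysis only; at least four complete subjects are required and a
    constant or collinear covariate is rejected.
    """
    if design.covariates is None:
        raise ValueError("GroupDesign has no covariates table")
    cov = design.covariates
    nuis = [nuisance] if isinstance(nuisance, str) else list(nuisance or [])
    cols = [covariate_name] + nuis
    sel = np.ones(len(design.subjects), dtype=bool)
    if within_group is not None:
        sel &= design.groups == within_group
    values = cov.loc[design.subjects, cols].to_numpy(dtype=float)
    sel &= np.isfinite(values).all(axis=1)
    n = int(sel.sum())
    if n < 4:
        raise ValueError(f"need >= 4 subjects with non-missing covariate, got {n}")
    Z = np.column_stack([np.ones(n), values[sel]])
    if np.ptp(values[sel, 0]) == 0:
        raise ValueError(f"constant covariate {covariate_name!r}")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError(f"collinear second-level design ({cols})")
    Y = design.data[sel]
    ok = np.isfinite(Y).all(axis=0)
    pinv = np.linalg.pinv(Z)
    cov_un = np.linalg.inv(Z.T @ Z)
    b = pinv @ np.where(ok, Y, 0.0)
    resid = np.where(ok, Y, 0.0) - Z @ b
    df = n - Z.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b[1] / np.sqrt(sigma2 * cov_un[1, 1])
    t[~ok] = np.nan
    return StatMap(design.unmask(t), (1.0, float(df)), "t", design.mask)


def stat_threshold(df: tuple[float, float], stat_kind: str, cdt_p: float,
                   tail: str = "pos") -> float:
    """Statistic value equivalent to an uncorrected cluster-defining p."""
    if stat_kind == "f":
        return float(stats.f.ppf(1 - cdt_p, df[0], df[1]))
    if tail == "two":
        return float(stats.t.ppf(1 - cdt_p / 2, df[1]))
    return float(stats.t.ppf(1 - cdt_p, df[1]))
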