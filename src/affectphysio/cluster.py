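"""Cluster-level family-wise-error inference by permutation.

Suprathreshold clusters are formed at a cluster-defining threshold
(voxelwise uncorrected p, default 0.005) with 26-neighbour connectivity, and
the FWE-corrected cluster p-value is the rank of the observed cluster size in
the permutation null distribution of the *maximum* cluster size:

    p_fwe = (1 + #{null max size >= observed size}) / (1 + n_perm)

The permutation scheme matches the second-level model: sign-flipping of
subject maps for one-sample (condition-effect) t tests, permutation of
diagnostic-group labels for the group F, and permutation of covariate
entries (nuisance columns held fixed) for slope maps.  Permutation is exact
under exchangeability and needs no smoothness estimate, unlike random-field
theory; the cluster-defining threshold and alpha follow the study settings.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .glm import GroupDesign, StatMap, stat_threshold

_CONN_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None


@dataclass
class ClusterTable:
    """Suprathreshold clusters with FWE-corrected p-values.

    ``clusters`` is sorted by size descending; each entry has ``size_voxels``,
    ``peak_value``, ``peak_ijk`` and ``p_fwe_cluster``.  ``labels`` is the
    3-D integer label image (0 = background).
    """

    clusters: list[dict]
    cdt_p: float
    n_perm: int
    threshold: float
    labels: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["p_fwe_cluster"] < alpha]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in self.significant(alpha):
            out |= self.labels == c["label"]
        return out

    def to_frame(self, affine: np.ndarray | None = None):
        """Cluster table as a DataFrame (with world mm coordinates if given)."""
        import pandas as pd

        rows = []
        for i, c in enumerate(self.clusters, start=1):
            row = {
                "cluster_id": i,
                "size_voxels": c["size_voxels"],
                "peak_stat": c["peak_value"],
                "peak_i": c["peak_ijk"][0],
                "peak_j": c["peak_ijk"][1],
                "peak_k": c["peak_ijk"][2],
                "p_fwe": c["p_fwe_cluster"],
            }
            if affine is not None:
                xyz = affine @ np.array([*c["peak_ijk"], 1.0])
                row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"] = xyz[:3]
            rows.append(row)
        return pd.DataFrame(rows)


def _exceed_mask(stat3d: np.ndarray, thresh: float, tail: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if tail == "two":
            return np.abs(stat3d) > thresh
        return stat3d > thresh


def _cluster_sizes(mask3d: np.ndarray, structure: np.ndarray):
    labels, n = ndimage.label(mask3d, structure=structure)
    if n == 0:
        return labels, np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def _max_cluster_size(stat_flat: np.ndarray, mask: np.ndarray, thresh: float,
                      tail: str, structure: np.ndarray, shape) -> int:
    m3 = np.zeros(shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        if tail == "two":
            m3[mask] = np.abs(stat_flat) > thresh
        else:
            m3[mask] = stat_flat > thresh
    if not m3.any():
        return 0
    _, sizes = _cluster_sizes(m3, structure)
    return int(sizes.max())


def _assemble_table(stat3d, mask, thresh, tail, structure, null_max, n_perm, cdt_p):
    work = np.where(np.isfinite(stat3d), stat3d, -np.inf if tail != "two" else 0.0)
    m3 = _exceed_mask(work, thresh, tail) & mask
    labels, sizes = _cluster_sizes(m3, structure)
    null_max = np.asarray(null_max)
    clusters = []
    order = np.argsort(sizes)[::-1]
    for li in order:
        lab = li + 1
        sz = int(sizes[li])
        in_cl = labels == lab
        vals = np.where(in_cl, np.abs(work) if tail == "two" else work, -np.inf)
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        clusters.append({
            "label": int(lab),
            "size_voxels": sz,
            "peak_value": float(stat3d[peak]),
            "peak_ijk": tuple(int(v) for v in peak),
            "p_fwe_cluster": float((1 + (null_max >= sz).sum()) / (1 + n_perm)),
        })
    return ClusterTable(clusters, cdt_p, n_perm, thresh, labels)


def cluster_fwe_one_sample(
    maps: np.ndarray,
    mask: np.ndarray,
    *,
    cdt_p: float = 0.005,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    tail: str = "pos",
) -> tuple[StatMap, ClusterTable]:
    """Sign-flip cluster FWE for a one-sample (condition-effect) t test.

    ``maps`` is subjects x voxels (flattened over ``mask``) or a stack of 3-D
    maps.  Under the null the subject effect maps are sign-symmetric, so the
    max-cluster-size null is built from seeded random sign flips.  The t
    statistic for every permutation reuses the sign-invariant sum of squares,
    making the whole null a single matrix product.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (inference unstable below)")
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 4:
        X = maps[:, mask]
    else:
        X = maps
    n, V = X.shape
    structure = _structure(connectivity)
    meansq = (X ** 2).mean(axis=0)
    df = n - 1
    thresh = stat_threshold((1.0, df), "t", cdt_p, tail)

    def t_from_mean(m):
        var = np.maximum(meansq - m ** 2, 0.0) * n / df
        with np.errstate(divide="ignore", invalid="ignore"):
            return m / np.sqrt(var / n)

    t_obs = t_from_mean(X.mean(axis=0))
    rng = np.random.default_rng(seed)
    S = rng.choice([-1.0, 1.0], size=(n_perm, n))
    Tm = (S @ X) / n
    null_max = np.empty(n_perm, dtype=int)
    shape = mask.shape
    for i in range(n_perm):
        null_max[i] = _max_cluster_size(t_from_mean(Tm[i]), mask, thresh,
                                        tail, structure, shape)
    stat3d = np.full(shape, np.nan)
    stat3d[mask] = t_obs
    table = _assemble_table(stat3d, mask, thresh, tail, structure,
                            null_max, n_perm, cdt_p)
    return StatMap(stat3d, (1.0, float(df)), "t", mask), table


def cluster_fwe_group_f(
    design: GroupDesign,
    *,
    cdt_p: float = 0.005,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> tuple[StatMap, ClusterTable]:
    """Group-label permutation cluster FWE for the one-way group F."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (inference unstable below)")
    X = design.data
    if not np.isfinite(X).all():
        raise ValueError("group permutation requires complete data at in-mask voxels")
    n, V = X.shape
    labels = design.groups
    uniq, counts = np.unique(labels, return_counts=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    onehot = (labels[:, None] == uniq[None, :]).astype(float)  # n x k
    structure = _structure(connectivity)
    df1, df2 = float(k - 1), float(n - k)
    thresh = stat_threshold((df1, df2), "f", cdt_p)
    sumsq = (X ** 2).sum(axis=0)
    total = X.sum(axis=0)

    def f_from_order(order):
        G = onehot[order].T  # k x n
        s = G @ X  # per-group sums
        between = (s ** 2 / counts[:, None]).sum(axis=0)
        ssb = between - total ** 2 / n
        ssw = sumsq - between
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / df1) / (ssw / df2)

    rng = np.random.default_rng(seed)
    F_obs = f_from_order(np.arange(n))
    null_max = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null_max[i] = _max_cluster_size(f_from_order(rng.permutation(n)),
                                        design.mask, thresh, "pos",
                                        structure, design.mask.shape)
    stat3d = design.unmask(F_obs)
    table = _assemble_table(stat3d, design.mask, thresh, "pos", structure,
                            null_max, n_perm, cdt_p)
    return StatMap(stat3d, (df1, df2), "f", design.mask), table


def cluster_fwe_slope(
    design: GroupDesign,
    covariate_name: str,
    within_group: str | None = None,
    nuisance: str | list[str] | None = None,
    *,
    cdt_p: float = 0.005,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    tail: str = "pos",
) -> tuple[StatMap, ClusterTable]:
    """Covariate-permutation cluster FWE for a within-group slope map.

    The covariate entries are permuted among the selected subjects while the
    nuisance columns stay attached to their subjects (Manly-style
    permutation).  ``tail="pos"`` tests positive slopes; negate the covariate
    (or pass ``tail="two"``) for the opposite association.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (inference unstable below)")
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
    Y = design.data[sel]
    if not np.isfinite(Y).all():
        raise ValueError("slope permutation requires complete data at in-mask voxels")
    c = values[sel, 0]
    Znuis = values[sel, 1:]
    if np.ptp(c) == 0:
        raise ValueError(f"constant covariate {covariate_name!r}")
    structure = _structure(connectivity)
    p = 2 + Znuis.shape[1]
    df = n - p
    thresh = stat_threshold((1.0, float(df)), "t", cdt_p, tail)

    def slope_t(cvec):
        Z = np.column_stack([np.ones(n), cvec, Znuis])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("collinear second-level design")
        cov_un = np.linalg.inv(Z.T @ Z)
        b = np.linalg.pinv(Z) @ Y
        resid = Y - Z @ b
        sigma2 = (resid ** 2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            return b[1] / np.sqrt(sigma2 * cov_un[1, 1])

    rng = np.random.default_rng(seed)
    t_obs = slope_t(c)
    null_max = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null_max[i] = _max_cluster_size(slope_t(c[rng.permutation(n)]),
                                        design.mask, thresh, tail,
                                        structure, design.mask.shape)
    stat3d = design.unmask(t_obs)
    table = _assemble_table(stat3d, design.mask, thresh, tail, structure,
                            null_max, n_perm, cdt_p)
    return StatMap(stat3d, (1.0, float(df)), "t", design.mask), table


def cluster_fwe(
    statmap: StatMap | None,
    inputs,
    *,
    cdt_p: float = 0.005,
    n_perm: int = 1000,
    seed: int = 0,
    exchangeability: str = "sign_flip",
    connectivity: int = 26,
    **kwargs,
) -> ClusterTable:
    """Cluster-level FWE inference dispatcher.

    ``exchangeability="sign_flip"`` treats ``inputs`` as stacked subject maps
    (plus a ``mask`` kwarg or a GroupDesign) and runs the one-sample engine;
    ``"group_permute"`` expects a GroupDesign and runs the group-F engine.
    The recomputed observed statistic replaces ``statmap`` (which may be
    ``None``); passing a statmap of the wrong kind is rejected.
    """
    if exchangeability == "sign_flip":
        if isinstance(inputs, GroupDesign):
            maps, mask = inputs.data, inputs.mask
        else:
            maps, mask = inputs, kwargs.pop("mask")
        if statmap is not None and statmap.stat_kind != "t":
            raise ValueError("sign_flip exchangeability implies a t statmap")
        _, table = cluster_fwe_one_sample(
            maps, mask, cdt_p=cdt_p, n_perm=n_perm, seed=seed,
            connectivity=connectivity, **kwargs)
    elif exchangeability == "group_permute":
        if statmap is not None and statmap.stat_kind != "f":
            raise ValueError("group_permute exchangeability implies an F statmap")
        _, table = cluster_fwe_group_f(
            inputs, cdt_p=cdt_p, n_perm=n_perm, seed=seed,
            connectivity=connectivity, **kwargs)
    else:
        raise ValueError("exchangeability must be 'sign_flip' or 'group_permute'")
    return table


def roi_peak_fwe(
    maps: np.ndarray,
    roi_mask: np.ndarray,
    *,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Peak-level FWE within a user-supplied region of interest.

    Sign-flip max-statistic test of the one-sample t over the ROI voxels;
    returns the observed t values (flattened over the ROI) and the FWE
    p-value of the ROI peak.
    """
    X = np.asarray(maps, dtype=float)
    if X.ndim == 4:
        X = X[:, roi_mask]
    n = X.shape[0]
    meansq = (X ** 2).mean(axis=0)
    df = n - 1

    def t_of(m):
        var = np.maximum(meansq - m ** 2, 0.0) * n / df
        with np.errstate(divide="ignore", invalid="ignore"):
            return m / np.sqrt(var / n)

    t_obs = t_of(X.mean(axis=0))
    rng = np.random.default_rng(seed)
    S = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_peak = np.nanmax(t_of((S @ X) / n), axis=1)
    p = (1 + (null_peak >= np.nanmax(t_obs)).sum()) / (1 + n_perm)
    return t_obs, float(p)
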