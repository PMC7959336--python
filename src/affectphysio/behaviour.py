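"""Behavioural scoring and group-level statistics.

The post-scan task shows each of the 50 facial-expression videos again and
asks the participant to pick the emotion from the five used (10 trials per
emotion, total score /50).  Group statistics follow the study's approach:
fixed-effects ANOVA models (group x emotion for identification scores,
group x stimulus type for autonomic reactivity) with Bonferroni-corrected
pairwise post-hoc t tests, and Pearson correlations between summary measures
and neuropsychological scores.  Unbalanced group sizes are handled with
Type-III sums of squares under sum-to-zero coding.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .design import EMOTIONS

N_TRIALS_PER_EMOTION = 10


def score_identification(responses: pd.DataFrame) -> pd.DataFrame:
    """Score the five-alternative emotion-identification task per participant.

    ``responses`` needs columns ``participant``, ``trial``, ``true_emotion``,
    ``response_emotion`` (missing responses = NaN/None, scored incorrect --
    the task is forced choice, so an omission is a failure to identify).
    Returns one row per participant with per-emotion correct counts (0-10
    each), ``total`` (0-50) and ``percent_correct``.
    """
    req = {"participant", "trial", "true_emotion", "response_emotion"}
    missing = req - set(responses.columns)
    if missing:
        raise ValueError(f"responses table missing columns: {sorted(missing)}")
    dup = responses.duplicated(subset=["participant", "trial"])
    if dup.any():
        raise ValueError("duplicate (participant, trial) rows in responses")
    bad = set(responses["true_emotion"]) - set(EMOTIONS)
    if bad:
        raise ValueError(f"unknown true_emotion labels: {sorted(bad)}")
    df = responses.copy()
    df["correct"] = (df["response_emotion"] == df["true_emotion"]).astype(int)
    per = (df.pivot_table(index="participant", columns="true_emotion",
                          values="correct", aggfunc="sum", fill_value=0)
             .reindex(columns=list(EMOTIONS), fill_value=0))
    counts = df.groupby("participant")["trial"].count()
    over = df.groupby(["participant", "true_emotion"])["trial"].count()
    if (over > N_TRIALS_PER_EMOTION).any():
        raise ValueError("more than 10 trials for an emotion within a participant")
    out = per.copy()
    out["total"] = per.sum(axis=1)
    out["percent_correct"] = 100.0 * out["total"] / counts.reindex(out.index)
    return out.reset_index()


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA with Bonferroni post-hocs."""

    table: pd.DataFrame  # index: effects; columns: sum_sq, df, F, PR(>F)
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    degenerate: bool = False


def _check_cells(df: pd.DataFrame, a: str, b: str) -> None:
    cells = df.groupby([a, b], observed=True).size().unstack()
    if cells.isna().any().any() or (cells == 0).any().any():
        raise ValueError(f"empty cell in {a} x {b} layout")
    if len(df) <= cells.size:
        raise ValueError(
            "saturated design: no residual degrees of freedom "
            f"({len(df)} observations for {cells.size} cells)")


def posthoc_pairwise(df: pd.DataFrame, dv: str, factor: str) -> pd.DataFrame:
    """All pairwise two-sample t tests on a factor, Bonferroni-multiplied."""
    levels = sorted(df[factor].unique())
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa = df.loc[df[factor] == a, dv].to_numpy(dtype=float)
        xb = df.loc[df[factor] == b, dv].to_numpy(dtype=float)
        t, p = stats.ttest_ind(xa, xb)
        rows.append({
            "level_a": a, "level_b": b,
            "mean_a": xa.mean(), "mean_b": xb.mean(),
            "t": float(t), "p_raw": float(p),
            "p_bonf": float(min(1.0, m * p)),
        })
    return pd.DataFrame(rows)


def two_way_anova(df: pd.DataFrame, dv: str, factor_a: str, factor_b: str) -> AnovaResult:
    """Two-way fixed-effects ANOVA (A, B, A x B), Type-III SS, sum coding.

    If the response has zero variance the design is degenerate (no
    within-cell variance to test against): all F are reported as 0 with
    ``degenerate=True``.
    """
    for col in (dv, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    _check_cells(df, factor_a, factor_b)
    y = df[dv].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        effects = [f"C({factor_a}, Sum)", f"C({factor_b}, Sum)",
                   f"C({factor_a}, Sum):C({factor_b}, Sum)", "Residual"]
        table = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": [0.0, 0.0, 0.0, np.nan],
             "PR(>F)": np.nan}, index=effects)
        return AnovaResult(table=table, degenerate=True)
    work = pd.DataFrame({"_y": y, "_A": df[factor_a].to_numpy(),
                         "_B": df[factor_b].to_numpy()})
    model = ols("_y ~ C(_A, Sum) * C(_B, Sum)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=3)
    rename = {
        "C(_A, Sum)": factor_a,
        "C(_B, Sum)": factor_b,
        "C(_A, Sum):C(_B, Sum)": f"{factor_a}:{factor_b}",
    }
    table = table.rename(index=rename).drop(index="Intercept")
    result = AnovaResult(table=table)
    for factor in (factor_a, factor_b):
        if table.loc[factor, "PR(>F)"] < 0.05:
            result.posthoc[factor] = posthoc_pairwise(df, dv, factor)
    return result


def group_emotion_anova(scores: pd.DataFrame, groups: pd.DataFrame | None = None) -> AnovaResult:
    """Group x emotion ANOVA on per-emotion identification scores (0-10).

    ``scores`` is either long format (columns ``participant``, ``group``,
    ``emotion``, ``score``) or the wide output of
    :func:`score_identification`, in which case ``groups`` must map
    ``participant`` to ``group``.
    """
    if "score" not in scores.columns:
        if groups is None:
            raise ValueError("wide scores need a participant->group table")
        long = scores.melt(id_vars=["participant"], value_vars=list(EMOTIONS),
                           var_name="emotion", value_name="score")
        long = long.merge(groups[["participant", "group"]], on="participant")
    else:
        long = scores
    return two_way_anova(long, "score", "group", "emotion")


def reactivity_anova(reactivities: pd.DataFrame) -> AnovaResult:
    """Group x stimulus-type ANOVA on trial (or participant-mean) reactivity.

    Expects long format with columns ``group``, ``stimulus_type`` and
    ``value`` -- heart-rate change from baseline or pupil ratio.
    """
    return two_way_anova(reactivities, "value", "group", "stimulus_type")


def bonferroni(p_raw: float | np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), monotone in p."""
    return np.minimum(1.0, m * np.asarray(p_raw, dtype=float))


def correlate_measures(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pairwise-complete correlation between two summary measures.

    Returns ``(r, p)`` with a two-sided p-value; requires at least 4 complete
    pairs and non-zero variance in both vectors.
    """
    if method != "pearson":
        raise ValueError("only pearson correlation is provided")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 paired complete observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
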