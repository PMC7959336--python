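"""Emotion-identification scoring and group statistics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affectphysio import (
    correlate_measures,
    gen_behaviour,
    group_emotion_anova,
    reactivity_anova,
    score_identification,
)
from affectphysio.behaviour import bonferroni, posthoc_pairwise, two_way_anova
from affectphysio.design import EMOTIONS


def make_responses(responder, participant="p0"):
    rows = []
    trial = 0
    for emo in EMOTIONS:
        for _ in range(10):
            rows.append({"participant": participant, "trial": trial,
                         "true_emotion": emo,
                         "response_emotion": responder(emo)})
            trial += 1
    return pd.DataFrame(rows)


class TestScoring:
    def test_perfect_responder_scores_50(self):
        out = score_identification(make_responses(lambda e: e))
        assert out["total"].iloc[0] == 50
        assert all(out[e].iloc[0] == 10 for e in EMOTIONS)
        assert out["percent_correct"].iloc[0] == 100.0

    def test_always_happiness(self):
        out = score_identification(make_responses(lambda e: "happiness"))
        assert out["happiness"].iloc[0] == 10
        assert out["total"].iloc[0] == 10

    def test_missing_response_counts_incorrect(self):
        df = make_responses(lambda e: e)
        df.loc[0, "response_emotion"] = None
        out = score_identification(df)
        assert out["total"].iloc[0] == 49

    def test_duplicate_trial_rows_rejected(self):
        df = make_responses(lambda e: e)
        with pytest.raises(ValueError, match="duplicate"):
            score_identification(pd.concat([df, df.iloc[:1]]))

    def test_scoring_invariant_to_trial_order(self):
        df = make_responses(lambda e: np.random.choice(EMOTIONS))
        a = score_identification(df)
        b = score_identification(df.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_random_responder_expectation(self):
        # 10,000 simulated responders, p(correct)=0.2, n=50 -> mean total 10
        uniform = np.full((5, 5), 0.2)
        resp = gen_behaviour({"g": uniform}, {"g": 10_000}, seed=3)
        out = score_identification(resp)
        assert out["total"].mean() == pytest.approx(10.0, abs=0.1)


class TestAnova:
    def test_identical_scores_degenerate(self):
        rows = [{"group": g, "emotion": e, "score": 7.0}
                for g in "ab" for e in "xy" for _ in range(4)]
        res = two_way_anova(pd.DataFrame(rows), "score", "group", "emotion")
        assert res.degenerate
        assert (res.table["F"].dropna() == 0).all()

    def test_balanced_layout_matches_closed_form(self, rng):
        rows = []
        for g in ("a", "b"):
            for e in ("x", "y"):
                for _ in range(8):
                    rows.append({"group": g, "emotion": e,
                                 "score": rng.normal((g == "a") + 0.5 * (e == "x"), 1)})
        df = pd.DataFrame(rows)
        res = two_way_anova(df, "score", "group", "emotion")
        y = df["score"].to_numpy()
        gm = y.mean()
        A = df.groupby("group")["score"].mean().to_numpy()
        B = df.groupby("emotion")["score"].mean().to_numpy()
        cells = df.groupby(["group", "emotion"])["score"].mean().unstack().to_numpy()
        ssa = 16 * ((A - gm) ** 2).sum()
        ssb = 16 * ((B - gm) ** 2).sum()
        ssab = 8 * ((cells - np.add.outer(A - gm, B - gm) - gm) ** 2).sum()
        sse = ((y - df.groupby(["group", "emotion"])["score"]
                .transform("mean")) ** 2).sum()
        mse = sse / 28
        assert res.table.loc["group", "F"] == pytest.approx(ssa / mse, rel=1e-10)
        assert res.table.loc["emotion", "F"] == pytest.approx(ssb / mse, rel=1e-10)
        assert res.table.loc["group:emotion", "F"] == pytest.approx(ssab / mse,
                                                                    rel=1e-10)
        # sums of squares partition exactly in the balanced case
        total = ((y - gm) ** 2).sum()
        parts = ssa + ssb + ssab + sse
        assert abs(parts - total) / total < 1e-10

    def test_empty_cell_rejected(self):
        rows = [{"group": "a", "emotion": "x", "score": 1.0}] * 3 + \
               [{"group": "a", "emotion": "y", "score": 2.0}] * 3 + \
               [{"group": "b", "emotion": "x", "score": 3.0}] * 3
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(pd.DataFrame(rows), "score", "group", "emotion")

    def test_planted_group_effect_power_matches_analytic(self, rng):
        # 2 groups x 2 emotions, 15 per cell, group effect d = 1 SD
        n_rep, hits = 300, 0
        m = 15
        for _ in range(n_rep):
            rows = []
            for g in (0, 1):
                for e in ("x", "y"):
                    for _ in range(m):
                        rows.append({"group": f"g{g}", "emotion": e,
                                     "score": rng.normal(g * 1.0, 1)})
            res = two_way_anova(pd.DataFrame(rows), "score", "group", "emotion")
            hits += res.table.loc["group", "PR(>F)"] < 0.05
        n_tot = 4 * m
        lam = n_tot * 0.25  # sum-coded effect +-d/2, lambda = N * (d/2)^2
        crit = stats.f.ppf(0.95, 1, n_tot - 4)
        power = 1 - stats.ncf.cdf(crit, 1, n_tot - 4, lam)
        assert abs(hits / n_rep - power) < 0.05

    def test_group_emotion_anova_wide_input(self, rng):
        from affectphysio.synth import _confusion_from_accuracy
        resp = gen_behaviour(
            {"control": _confusion_from_accuracy(0.8),
             "bvFTD": _confusion_from_accuracy(0.4)},
            {"control": 8, "bvFTD": 8}, seed=1)
        scores = score_identification(resp)
        groups = resp[["participant", "group"]].drop_duplicates()
        res = group_emotion_anova(scores, groups)
        assert res.table.loc["group", "PR(>F)"] < 0.001
        assert "group" in res.posthoc

    def test_reactivity_anova_relabelling_symmetry(self, rng):
        rows = []
        for g in ("control", "bvFTD"):
            for s in ("facial", "mosaic"):
                for _ in range(10):
                    rows.append({"group": g, "stimulus_type": s,
                                 "value": rng.normal(-2 if g == "control" else -1, 1)})
        df = pd.DataFrame(rows)
        res = reactivity_anova(df)
        swapped = df.assign(group=df["group"].map(
            {"control": "bvFTD", "bvFTD": "control"}))
        res2 = reactivity_anova(swapped)
        assert res.table.loc["group", "F"] == pytest.approx(
            res2.table.loc["group", "F"], rel=1e-10)
        if "group" in res.posthoc and "group" in res2.posthoc:
            assert res.posthoc["group"]["t"].iloc[0] == pytest.approx(
                -res2.posthoc["group"]["t"].iloc[0], rel=1e-10)


class TestBonferroniAndCorrelation:
    def test_bonferroni_monotone_and_capped(self):
        p = np.array([0.001, 0.02, 0.2, 0.9])
        adj = bonferroni(p, 6)
        assert np.all(np.diff(adj) >= 0)
        assert adj.max() <= 1.0
        assert adj[0] == pytest.approx(0.006)

    def test_posthoc_bonferroni_multiplies_raw(self, rng):
        df = pd.DataFrame({
            "g": np.repeat(list("abc"), 10),
            "v": rng.normal(size=30) + np.repeat([0, 1, 2], 10),
        })
        ph = posthoc_pairwise(df, "v", "g")
        assert len(ph) == 3
        assert np.allclose(ph["p_bonf"], np.minimum(1, 3 * ph["p_raw"]))

    def test_perfect_linear_relation(self):
        r, p = correlate_measures([1, 2, 3, 4, 5], [5, 7, 9, 11, 13])
        assert r == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r1, _ = correlate_measures(x, y)
        r2, _ = correlate_measures(x, -y)
        assert r1 == pytest.approx(-r2)

    def test_pairwise_complete_missing_handling(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        x[3] = np.nan
        y[7] = np.nan
        ok = np.isfinite(x) & np.isfinite(y)
        r, _ = correlate_measures(x, y)
        expect, _ = stats.pearsonr(x[ok], y[ok])
        assert r == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_measures([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            correlate_measures([1, 2, 3], [4, 5, 6])
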