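"""ROC/AUC, DeLong variance and tests, tails strategy, control matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from ribobench import (
    ScoreSet,
    TailThresholds,
    apply_tails,
    delong_compare,
    delong_sd,
    match_controls,
    roc,
    run_benchmark,
    tail_thresholds,
)
from ribobench.bench import benjamini_hochberg


def scoreset(pos, neg):
    return ScoreSet(
        positives=[(f"p{i}", float(s)) for i, s in enumerate(pos)],
        negatives=[(f"n{i}", float(s)) for i, s in enumerate(neg)],
    )


def rank_sum_auc(pos, neg):
    """Independent AUC: U/(n1*n2) from the rank-sum statistic."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc(scoreset([2, 3], [0, 1]))
        assert r.auc == 1.0

    def test_identical_multisets_half(self):
        r = roc(scoreset([1, 2, 3], [1, 2, 3]))
        assert r.auc == pytest.approx(0.5)

    def test_exhaustive_pair_counting(self):
        # positives {1, 3}, negatives {2, 4}: one concordant of four pairs
        assert roc(scoreset([1, 3], [2, 4])).auc == pytest.approx(0.25)

    def test_matches_rank_sum_on_random_sets(self, rng):
        for _ in range(200):
            m, n = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            pos = rng.choice(np.arange(10), size=m).astype(float)  # with ties
            neg = rng.choice(np.arange(10), size=n).astype(float)
            assert roc(scoreset(pos, neg)).auc == pytest.approx(
                rank_sum_auc(pos, neg), rel=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(1, 1, 50)
        neg = rng.normal(0, 1, 40)
        y = np.r_[np.ones(50), np.zeros(40)]
        assert roc(scoreset(pos, neg)).auc == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), rel=1e-12
        )

    def test_best_point_top_left(self):
        r = roc(scoreset([5, 6, 7], [1, 2, 8]))
        t, sens, spec = r.best_point
        # threshold between 2 and 8 captures all positives, one false positive
        assert sens == 1.0 and spec == pytest.approx(2 / 3)

    def test_curve_endpoints_and_monotonicity(self, rng):
        r = roc(scoreset(rng.normal(1, 1, 20), rng.normal(0, 1, 20)))
        sens = [p[1] for p in r.points]
        spec = [p[2] for p in r.points]
        assert sens[0] == 0.0 and spec[0] == 1.0
        assert sens[-1] == 1.0 and spec[-1] == 0.0
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))

    def test_empty_side_error(self):
        with pytest.raises(ValueError):
            roc(ScoreSet(positives=[("p", 1.0)], negatives=[]))


class TestDelongSd:
    def test_zero_under_perfect_separation(self):
        assert delong_sd(scoreset([3, 4, 5], [0, 1, 2])) == 0.0
        r = roc(scoreset([3, 4, 5], [0, 1, 2]))
        assert r.ci95 == (1.0, 1.0)

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 25)
        s1 = delong_sd(scoreset(pos, neg))
        s2 = delong_sd(scoreset(np.exp(pos), np.exp(neg)))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_matches_bootstrap(self, rng):
        pos = rng.normal(1.0, 1, 60)
        neg = rng.normal(0.0, 1, 50)
        s = delong_sd(scoreset(pos, neg))
        B = 4000
        aucs = np.array([
            rank_sum_auc(rng.choice(pos, 60), rng.choice(neg, 50))
            for _ in range(B)
        ])
        boot = aucs.std(ddof=1)
        assert s == pytest.approx(boot, rel=0.15)

    def test_requires_two_per_side(self):
        with pytest.raises(ValueError):
            delong_sd(scoreset([1.0], [0.0, 0.5]))


class TestDelongCompare:
    def test_identical_sets_p_half(self, rng):
        pos = rng.normal(1, 1, 20)
        neg = rng.normal(0, 1, 20)
        a, b = scoreset(pos, neg), scoreset(pos, neg)
        res = delong_compare(a, b)
        assert res["z"] == 0.0 and res["p_value"] == pytest.approx(0.5)
        assert res["paired"]

    def test_unpaired_variance_adds(self, rng):
        a = scoreset(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        b = scoreset(rng.normal(0.5, 1, 25), rng.normal(0, 1, 25))
        res = delong_compare(a, b)
        assert not res["paired"]
        var = delong_sd(a) ** 2 + delong_sd(b) ** 2
        z_expected = (res["auc_a"] - res["auc_b"]) / math.sqrt(var)
        assert res["z"] == pytest.approx(z_expected, rel=1e-12)

    def test_matches_permutation_test(self, rng):
        # unpaired comparison against a label-permutation oracle
        a_pos, a_neg = rng.normal(1.2, 1, 25), rng.normal(0, 1, 25)
        b_pos, b_neg = rng.normal(0.3, 1, 25), rng.normal(0, 1, 25)
        res = delong_compare(scoreset(a_pos, a_neg), scoreset(b_pos, b_neg))
        obs = res["auc_a"] - res["auc_b"]
        pool_pos = np.r_[a_pos, b_pos]
        pool_neg = np.r_[a_neg, b_neg]
        B = 2000
        count = 0
        for _ in range(B):
            pp = rng.permutation(pool_pos)
            pn = rng.permutation(pool_neg)
            d = rank_sum_auc(pp[:25], pn[:25]) - rank_sum_auc(pp[25:], pn[25:])
            if d >= obs:
                count += 1
        p_perm = count / B
        # agree within Monte-Carlo error
        se = math.sqrt(p_perm * (1 - p_perm) / B) + 1e-3
        assert abs(res["p_value"] - p_perm) < max(4 * se, 0.02)

    def test_matches_r_proc_paired(self, rng, tmp_path):
        # independent cross-check against pROC's paired DeLong test
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        n = 40
        base = rng.normal(0, 1, 2 * n)
        s1 = base + rng.normal(0, 0.5, 2 * n) + np.r_[np.ones(n), np.zeros(n)]
        s2 = base + rng.normal(0, 0.8, 2 * n) + 0.6 * np.r_[np.ones(n), np.zeros(n)]
        a = ScoreSet([(f"w{i}", s1[i]) for i in range(n)],
                     [(f"w{i+n}", s1[n + i]) for i in range(n)])
        b = ScoreSet([(f"w{i}", s2[i]) for i in range(n)],
                     [(f"w{i+n}", s2[n + i]) for i in range(n)])
        res = delong_compare(a, b, alternative="greater")
        np.savetxt(tmp_path / "s1.txt", s1)
        np.savetxt(tmp_path / "s2.txt", s2)
        script = (
            'suppressMessages(library(pROC));'
            f'n <- {n};'
            f's1 <- scan("{tmp_path}/s1.txt", quiet=TRUE);'
            f's2 <- scan("{tmp_path}/s2.txt", quiet=TRUE);'
            'y <- c(rep(1, n), rep(0, n));'
            'r1 <- roc(y, s1, direction="<", quiet=TRUE);'
            'r2 <- roc(y, s2, direction="<", quiet=TRUE);'
            't <- roc.test(r1, r2, method="delong", alternative="greater",'
            ' paired=TRUE);'
            'cat(t$p.value, "\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        p_ref = float(out.stdout.strip().split()[-1])
        assert res["p_value"] == pytest.approx(p_ref, rel=1e-6, abs=1e-9)
        assert res["paired"]


class TestTails:
    def test_thresholds_bracket_extremes(self):
        scores = np.arange(1, 21, dtype=float)
        th = tail_thresholds(scores, 10)
        # linear-interpolation quantiles at 5% and 95% of 1..20
        assert th.theta_low == pytest.approx(1.95)
        assert th.theta_high == pytest.approx(19.05)
        ss = scoreset(scores[:10], scores[10:])
        kept = apply_tails(ss, th)
        kept_scores = sorted(
            [s for _, s in kept.positives] + [s for _, s in kept.negatives]
        )
        assert kept_scores == [1.0, 20.0]

    def test_n100_is_identity(self, rng):
        ss = scoreset(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        th = tail_thresholds(
            np.r_[ss.pos_scores, ss.neg_scores], 100
        )
        out = apply_tails(ss, th)
        assert out.positives == ss.positives and out.negatives == ss.negatives

    def test_shift_equivariance(self, rng):
        x = rng.normal(0, 1, 200)
        th1 = tail_thresholds(x, 25)
        th2 = tail_thresholds(x + 7.5, 25)
        assert th2.theta_low == pytest.approx(th1.theta_low + 7.5)
        assert th2.theta_high == pytest.approx(th1.theta_high + 7.5)

    def test_retained_fraction_on_continuous_scores(self, rng):
        x = rng.normal(0, 1, 10000)
        ss = scoreset(x[:5000], x[5000:])
        for n_pct in (25, 5):
            th = tail_thresholds(x, n_pct)
            kept = apply_tails(ss, th)
            frac = (len(kept.positives) + len(kept.negatives)) / 10000
            assert frac == pytest.approx(n_pct / 100, abs=0.01)

    def test_ties_retained_inclusively(self):
        # degenerate, zero-heavy multiset as MFE distances produce
        pos = [0.0] * 10 + [3.0]
        neg = [0.0] * 10 + [1.0]
        ss = scoreset(pos, neg)
        th = tail_thresholds(np.r_[pos, neg], 5)
        kept = apply_tails(ss, th)
        # theta_low falls on the tied zeros: all of them stay
        assert sum(1 for _, s in kept.positives if s == 0.0) == 10
        assert sum(1 for _, s in kept.negatives if s == 0.0) == 10

    def test_zero_percent_rejected(self):
        with pytest.raises(ValueError):
            tail_thresholds([1.0, 2.0], 0)

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            TailThresholds(n_percent=5, theta_low=2.0, theta_high=1.0)


_score_lists = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=2, max_size=40
)


class TestRankInvariance:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(_score_lists, _score_lists)
    def test_auc_invariant_under_increasing_transform(self, pos, neg):
        a = roc(scoreset(pos, neg)).auc
        f = lambda xs: [math.atan(x) + 0.1 * x for x in xs]
        b = roc(scoreset(f(pos), f(neg))).auc
        assert a == pytest.approx(b, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=1,
                    max_size=60),
           st.floats(0.5, 100))
    def test_tail_thresholds_ordered_and_within_range(self, xs, n_pct):
        th = tail_thresholds(xs, n_pct)
        assert min(xs) <= th.theta_low <= th.theta_high <= max(xs)


class _Cand:
    def __init__(self, window_id, mean_fdr_p):
        self.window_id = window_id
        self.mean_fdr_p = mean_fdr_p


class TestMatchControls:
    def test_hand_ranked_direction(self):
        cands = [_Cand("a", 0.9), _Cand("b", 0.2), _Cand("c", 0.99)]
        top2 = match_controls(cands, 2)
        assert [c.window_id for c in top2] == ["c", "a"]

    def test_whole_pool_and_overflow_warns(self):
        cands = [_Cand("a", 0.9), _Cand("b", 0.2)]
        assert match_controls(cands, 2) == sorted(
            cands, key=lambda c: -c.mean_fdr_p
        )
        with pytest.warns(UserWarning, match="returning all"):
            assert len(match_controls(cands, 5)) == 2

    def test_n_zero_empty(self):
        assert match_controls([_Cand("a", 0.5)], 0) == []

    def test_tie_break_deterministic(self):
        cands = [_Cand("b", 0.5), _Cand("a", 0.5), _Cand("c", 0.5)]
        assert [c.window_id for c in match_controls(cands, 2)] == ["a", "b"]

    def test_ascending_flag_inverts(self):
        cands = [_Cand("a", 0.9), _Cand("b", 0.2)]
        assert match_controls(cands, 1, ascending=True)[0].window_id == "b"


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 50)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), ref)


class _W:
    def __init__(self, window_id, label, categories, mean_fdr_p):
        self.window_id = window_id
        self.label = label
        self.categories = categories
        self.mean_fdr_p = mean_fdr_p


class TestRunBenchmark:
    def _windows_scores(self, rng, n=40, separable=True):
        wins, scores = [], {}
        for i in range(n):
            wid = f"pos{i}"
            cats = {"symmetric" if i % 2 else "asymmetric"}
            if i % 5 == 0:
                cats.add("validated")
            wins.append(_W(wid, "riboSNitch", cats, float(rng.uniform(0, 0.1))))
            scores[wid] = float(rng.uniform(2, 3) if separable else rng.normal())
        for i in range(n):
            wid = f"neg{i}"
            wins.append(_W(wid, "non-riboSNitch", set(), float(rng.uniform(0.5, 1))))
            scores[wid] = float(rng.uniform(0, 1) if separable else rng.normal())
        return wins, {"bppm_profile": scores}

    def test_separable_scores_auc_one_everywhere(self, rng):
        wins, scores = self._windows_scores(rng, separable=True)
        rows = run_benchmark(wins, scores, tails=(25, 5))
        assert rows  # probed row present as NA
        for row in rows:
            if row.auc is not None:
                assert row.auc == 1.0
        cats = {r.category for r in rows}
        assert {"probed", "validated", "symmetric", "asymmetric", "all",
                "25% tails", "5% tails"} <= cats

    def test_small_category_reported_na(self, rng):
        wins, scores = self._windows_scores(rng)
        rows = run_benchmark(wins, scores, tails=())
        probed = [r for r in rows if r.category == "probed"]
        assert len(probed) == 1
        assert probed[0].auc is None and "NA" in probed[0].note

    def test_label_permuted_auc_near_half(self, rng):
        wins, scores = self._windows_scores(rng, n=100, separable=False)
        rows = run_benchmark(wins, scores, tails=())
        all_row = next(r for r in rows if r.category == "all")
        # null scores: AUC within the 95% band around 0.5
        sd = delong_sd(ScoreSet(
            positives=[(w.window_id, scores["bppm_profile"][w.window_id])
                       for w in wins if w.label == "riboSNitch"],
            negatives=[(w.window_id, scores["bppm_profile"][w.window_id])
                       for w in wins if w.label == "non-riboSNitch"],
        ))
        assert abs(all_row.auc - 0.5) < 1.96 * sd + 0.05

    def test_tails_improve_auc_with_heavy_tailed_effects(self, rng):
        wins, scores = [], {}
        n = 400
        for i in range(n):
            wid = f"pos{i}"
            eff = abs(rng.standard_cauchy())
            wins.append(_W(wid, "riboSNitch", {"symmetric"}, 0.01))
            scores[wid] = float(abs(rng.normal(0, 1) + eff))
        for i in range(n):
            wid = f"neg{i}"
            wins.append(_W(wid, "non-riboSNitch", set(), 0.9))
            scores[wid] = float(abs(rng.normal(0, 1)))
        rows = run_benchmark(wins, {"m": scores}, tails=(25, 5))
        by_cat = {r.category: r for r in rows}
        assert by_cat["5% tails"].auc >= by_cat["all"].auc
        assert by_cat["25% tails"].auc >= by_cat["all"].auc
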