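import math

import numpy as np
import pytest
from scipy import stats

from aevnet.metrics import (
    DecoySet,
    MetricsReport,
    ScoredSet,
    ScreeningSet,
    bootstrap_ci,
    docking_power,
    enrichment_factor,
    pearson_r,
    predictive_index,
    ranking_power,
    scoring_power,
    screening_power,
)


def scored(y, yhat, classes=None):
    ids = [f"c{i}" for i in range(len(y))]
    return ScoredSet(ids, np.asarray(y, float), np.asarray(yhat, float), classes)


class TestScoringPower:
    def test_perfect(self):
        r, rmse = scoring_power(scored([1, 2, 3], [1, 2, 3]))
        assert r == pytest.approx(1.0)
        assert rmse == 0.0

    def test_anti_correlated(self):
        r, _ = scoring_power(scored([1, 2, 3], [4, 3, 2]))
        assert r == pytest.approx(-1.0)

    def test_four_point_hand_case(self):
        # y=(1,2,3,4), yhat=(1.5,1.5,3.5,3.5):
        # r = 4/sqrt(4*5) = 0.894..., rmse = 0.5
        r, rmse = scoring_power(scored([1, 2, 3, 4], [1.5, 1.5, 3.5, 3.5]))
        assert r == pytest.approx(4.0 / math.sqrt(20.0), abs=1e-12)
        assert r == pytest.approx(0.894, abs=1e-3)
        assert rmse == pytest.approx(0.5, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        y = rng.normal(size=40)
        yhat = y + rng.normal(size=40)
        r, _ = scoring_power(scored(y, yhat))
        assert r == pytest.approx(stats.pearsonr(y, yhat).statistic, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            scoring_power(scored([1, 1, 1], [1, 2, 3]))

    def test_r_affine_invariant_rmse_not(self, rng):
        y = rng.normal(size=20)
        yhat = y + rng.normal(size=20) * 0.5
        r1, rmse1 = scoring_power(scored(y, yhat))
        r2, rmse2 = scoring_power(scored(y, 2.0 * yhat + 3.0))
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert rmse1 != pytest.approx(rmse2)


class TestRankingPower:
    def test_perfect_ordering(self):
        y = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        classes = ["a"] * 5 + ["b"] * 5
        rho, tau, pi = ranking_power(scored(y, y, classes))
        assert rho == pytest.approx(1.0)
        assert tau == pytest.approx(1.0)
        assert pi == pytest.approx(1.0)

    def test_reversed_ordering(self):
        y = [1.0, 2, 3, 4, 5]
        yhat = [5.0, 4, 3, 2, 1]
        rho, tau, pi = ranking_power(scored(y, yhat, ["a"] * 5))
        assert rho == pytest.approx(-1.0)
        assert tau == pytest.approx(-1.0)
        assert pi == pytest.approx(-1.0)

    def test_adjacent_swap_hand_case(self):
        # 5 items, predicted order swaps ranks of items 1 and 2:
        # kendall = (9-1)/10 = 0.8, spearman = 1 - 6*2/(5*24) = 0.9
        y = [1.0, 2, 3, 4, 5]
        yhat = [2.0, 1, 3, 4, 5]
        rho, tau, pi = ranking_power(scored(y, yhat, ["a"] * 5))
        assert tau == pytest.approx(0.8, abs=1e-12)
        assert rho == pytest.approx(0.9, abs=1e-12)
        # PI by direct enumeration: sum|dy| = 20, one discordant pair w=1
        assert pi == pytest.approx((20.0 - 2.0) / 20.0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.normal(size=10)
        yhat = rng.normal(size=10)
        s1 = ranking_power(scored(y, yhat, ["a"] * 10))
        s2 = ranking_power(scored(y, np.exp(yhat), ["a"] * 10))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_singleton_class_excluded(self):
        y = [1.0, 2, 3, 9]
        yhat = [1.0, 2, 3, 9]
        with pytest.warns(UserWarning, match="single member"):
            rho, tau, pi = ranking_power(scored(y, yhat, ["a", "a", "a", "b"]))
        assert rho == 1.0

    def test_requires_classes(self):
        with pytest.raises(ValueError):
            ranking_power(scored([1, 2], [1, 2]))


class TestPredictiveIndex:
    def test_weights_matter(self):
        # mis-ranking the widely separated pair hurts more
        y = np.array([0.0, 1.0, 10.0])
        swap_small = predictive_index(y, np.array([1.0, 0.0, 10.0]))
        swap_large = predictive_index(y, np.array([10.0, 1.0, 0.0]))
        assert swap_small > swap_large

    def test_all_equal_y_undefined(self):
        with pytest.raises(ValueError):
            predictive_index(np.array([2.0, 2.0]), np.array([1.0, 2.0]))


class TestDockingPower:
    def _sets(self, ranks_of_good):
        """One good (rmsd 1.0) pose per target, ranked at the given position."""
        sets = []
        for t, rank in enumerate(ranks_of_good):
            poses = []
            for k in range(5):
                rmsd = 1.0 if k == rank else 5.0
                poses.append((f"p{k}", rmsd, 10.0 - k))  # scores decreasing
            sets.append(DecoySet(f"t{t}", poses))
        return sets

    def test_all_good_top1(self):
        rates = docking_power(self._sets([0, 0, 0]))
        assert rates == {1: 100.0, 2: 100.0, 3: 100.0}

    def test_no_good_poses(self):
        sets = [DecoySet("t", [(f"p{k}", 8.0, -k) for k in range(4)])]
        assert docking_power(sets) == {1: 0.0, 2: 0.0, 3: 0.0}

    def test_three_target_enumeration(self):
        # good poses at ranks 1, 2, 4 -> top1 33.3%, top2 66.7%, top3 66.7%
        rates = docking_power(self._sets([0, 1, 3]))
        assert rates[1] == pytest.approx(100.0 / 3)
        assert rates[2] == pytest.approx(200.0 / 3)
        assert rates[3] == pytest.approx(200.0 / 3)

    def test_monotone_in_k(self, rng):
        sets = []
        for t in range(10):
            poses = [(f"p{k}", float(rng.uniform(0, 5)), float(rng.normal()))
                     for k in range(6)]
            sets.append(DecoySet(f"t{t}", poses))
        rates = docking_power(sets)
        assert rates[1] <= rates[2] <= rates[3]

    def test_tie_broken_by_pose_id(self):
        poses = [("b", 5.0, 1.0), ("a", 1.0, 1.0), ("c", 5.0, 0.0)]
        rates = docking_power([DecoySet("t", poses)], top_ks=(1,))
        assert rates[1] == 100.0  # 'a' sorts before 'b' on equal score

    def test_too_few_poses(self):
        with pytest.raises(ValueError):
            docking_power([DecoySet("t", [("p", 1.0, 0.0)])])


class TestScreeningPower:
    def test_ef_printed_formula_toy(self):
        # 200 candidates, TB_tot = 10, both top-1% slots are true binders
        cands = []
        for k in range(200):
            is_tb = k < 10
            score = 100.0 - k if k < 2 else 50.0 - k  # top 2 are binders
            cands.append((f"l{k}", score, is_tb, k == 0))
        ef = enrichment_factor(cands, 0.01)
        assert ef == pytest.approx(2.0 / (0.01 * 10.0))  # = 20

    def test_binders_ranked_last(self):
        cands = [(f"l{k}", float(-k), k >= 90, k == 99) for k in range(100)]
        assert enrichment_factor(cands, 0.01) == 0.0

    def test_random_null_mean_ef_near_one(self, rng):
        efs = []
        for _ in range(60):
            scores = rng.normal(size=400)
            tb = rng.permutation(400) < 40
            cands = [(f"l{k}", float(scores[k]), bool(tb[k]), False)
                     for k in range(400)]
            efs.append(enrichment_factor(cands, 0.10))
        assert np.mean(efs) == pytest.approx(1.0, abs=0.15)

    def test_forward_and_reverse_success(self):
        sets = []
        for t in range(4):
            cands = []
            for k in range(100):
                score = 100.0 - k
                # best binder at top for even targets, bottom for odd
                best_at = 0 if t % 2 == 0 else 99
                cands.append((f"l{t}-{k}", score, k == best_at, k == best_at))
            sets.append(ScreeningSet(f"t{t}", cands))
        res = screening_power(sets, alphas=(0.01,))
        assert res["forward_success"][0.01] == pytest.approx(50.0)
        # each ligand binds one target only; with 4 targets top-1% = 1 target
        assert 0.0 <= res["reverse_success"][0.01] <= 100.0

    def test_zero_binder_target_skipped(self):
        ok = ScreeningSet("t0", [("a", 1.0, True, True), ("b", 0.0, False, False)])
        empty = ScreeningSet("t1", [("c", 1.0, False, False)])
        with pytest.warns(UserWarning, match="zero true binders"):
            res = screening_power([ok, empty], alphas=(0.5,))
        assert res["forward_success"][0.5] == 100.0

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            enrichment_factor([("a", 1.0, True, True)], 1.5)


class TestBootstrap:
    def test_perfect_agreement_degenerate_interval(self):
        s = scored([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        lo, hi = bootstrap_ci(lambda ss: scoring_power(ss)[0], s,
                              n_rep=200, seed=0)
        assert lo == hi == pytest.approx(1.0)

    def test_seed_determinism(self, rng):
        y = rng.normal(size=30)
        s = scored(y, y + rng.normal(size=30))
        f = lambda ss: scoring_power(ss)[0]
        assert bootstrap_ci(f, s, 200, seed=4) == bootstrap_ci(f, s, 200, seed=4)
        assert bootstrap_ci(f, s, 200, seed=4) != bootstrap_ci(f, s, 200, seed=5)

    def test_interval_contains_point_typically(self, rng):
        y = rng.normal(size=80)
        s = scored(y, y + 0.5 * rng.normal(size=80))
        r, _ = scoring_power(s)
        lo, hi = bootstrap_ci(lambda ss: scoring_power(ss)[0], s, 1000, seed=0)
        assert lo <= r <= hi

    def test_coverage_simulation(self):
        # nominal 90% percentile interval: check empirical coverage loosely
        true_rho = 0.8
        cov = np.array([[1.0, true_rho], [true_rho, 1.0]])
        hits = 0
        outer = 40
        for k in range(outer):
            rng = np.random.default_rng(1000 + k)
            xy = rng.multivariate_normal([0, 0], cov, size=150)
            s = scored(xy[:, 0], xy[:, 1])
            lo, hi = bootstrap_ci(lambda ss: scoring_power(ss)[0], s,
                                  n_rep=400, level=0.90, seed=k)
            hits += lo <= true_rho <= hi
        assert hits / outer >= 0.70  # loose lower bound at these sizes

    def test_shrinks_with_n(self, rng):
        y_small = rng.normal(size=20)
        y_big = rng.normal(size=400)
        f = lambda ss: scoring_power(ss)[0]
        s_small = scored(y_small, y_small + rng.normal(size=20))
        s_big = scored(y_big, y_big + rng.normal(size=400))
        lo1, hi1 = bootstrap_ci(f, s_small, 500, seed=1)
        lo2, hi2 = bootstrap_ci(f, s_big, 500, seed=1)
        assert (hi2 - lo2) < (hi1 - lo1)


class TestMetricsReport:
    def test_json_and_csv(self, tmp_path):
        rep = MetricsReport()
        rep.add("pearson_r", 0.8, (0.7, 0.9))
        rep.add("rmse", 1.3)
        out = tmp_path / "rep.json"
        rep.to_json(out)
        rep.to_csv(tmp_path / "rep.csv")
        import json
        data = json.loads(out.read_text())
        assert data["metrics"]["pearson_r"]["ci"] == [0.7, 0.9]

    def test_ci_ordering_warning(self):
        rep = MetricsReport()
        with pytest.warns(UserWarning):
            rep.add("m", 5.0, (0.0, 1.0))
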