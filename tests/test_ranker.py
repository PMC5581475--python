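import numpy as np
import pytest
from scipy import optimize, stats

from contactrank.ranker import (
    RankExample,
    build_rank_examples,
    cross_validate_C,
    hinge_objective,
    pairwise_differences,
    predictions_from_scores,
    rank_score,
    relevance_from_distance,
    train_rank_svm,
)


def oracle_objective(diffs, C, dim):
    """Independent convex oracle: the explicit slack-variable QP via SLSQP.

    Variables are (w, xi); minimize 1/2 ||w||^2 + C sum(xi) subject to
    D w >= 1 - xi and xi >= 0.  Smooth problem, so a generic constrained
    solver nails it without touching the hinge formulation under test.
    """
    n = diffs.shape[0]

    def obj(z):
        w, xi = z[:dim], z[dim:]
        return 0.5 * w @ w + C * xi.sum()

    def jac(z):
        return np.concatenate([z[:dim], C * np.ones(n)])

    cons = [{
        "type": "ineq",
        "fun": lambda z: diffs @ z[:dim] - 1 + z[dim:],
        "jac": lambda z: np.hstack([diffs, np.eye(n)]),
    }]
    bounds = [(None, None)] * dim + [(0, None)] * n
    z0 = np.zeros(dim + n)
    z0[dim:] = 1.0
    res = optimize.minimize(obj, z0, jac=jac, constraints=cons, bounds=bounds,
                            method="SLSQP",
                            options={"maxiter": 1000, "ftol": 1e-14})
    return obj(res.x)


class TestRelevance:
    def test_closer_pair_ranks_higher(self):
        assert relevance_from_distance(5.0) > relevance_from_distance(20.0)

    def test_default_bins(self):
        for d, r in [(7.99, 4), (8.0, 3), (11.99, 3), (12.0, 2),
                     (16.0, 1), (19.99, 1), (20.0, 0), (40.0, 0)]:
            assert relevance_from_distance(d) == r

    def test_undefined_distance_raises(self):
        with pytest.raises(ValueError):
            relevance_from_distance(float("nan"))


class TestBuildExamples:
    def _inputs(self, n, seed=0):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(size=(n, 4))
        pairs = [(1, 7 + k) for k in range(n)]
        dists = rng.uniform(4, 30, size=n)
        return phi, pairs, dists

    def test_groups_and_relevance(self):
        phi, pairs, _ = self._inputs(2)
        ex = build_rank_examples("q", phi, pairs, np.array([5.0, 20.0]))
        assert ex[0].relevance > ex[1].relevance

    def test_identical_distances_no_constraints(self):
        phi, pairs, _ = self._inputs(3)
        ex = build_rank_examples("q", phi, pairs, np.full(3, 9.0))
        assert pairwise_differences(ex).shape[0] == 0

    def test_pair_cap_deterministic(self):
        phi, pairs, dists = self._inputs(50)
        a = build_rank_examples("q", phi, pairs, dists, pair_cap=10, seed=3)
        b = build_rank_examples("q", phi, pairs, dists, pair_cap=10, seed=3)
        assert len(a) == 10
        assert [e.pair for e in a] == [e.pair for e in b]

    def test_empty_group_warns(self):
        phi, pairs, _ = self._inputs(2)
        with pytest.warns(UserWarning):
            out = build_rank_examples("q", phi, pairs, np.full(2, np.nan))
        assert out == []


class TestPairwiseDifferences:
    def _example(self, rel, phi, qid="q"):
        return RankExample(qid=qid, pair=(1, 10), phi=np.asarray(phi, float),
                           relevance=rel)

    def test_three_distinct_levels_give_three_constraints(self):
        ex = [self._example(r, [r, 0.0]) for r in (2, 1, 0)]
        assert pairwise_differences(ex).shape == (3, 2)

    def test_two_levels_sizes_2_and_3_give_6(self):
        ex = [self._example(1, [1.0, 0.0])] * 2 + [self._example(0, [0.0, 1.0])] * 3
        diffs = pairwise_differences(ex)
        assert diffs.shape == (6, 2)
        assert np.allclose(diffs, [[1.0, -1.0]] * 6)

    def test_single_example_empty(self):
        assert pairwise_differences([self._example(1, [0.5])]).shape[0] == 0

    def test_cross_qid_raises(self):
        ex = [self._example(1, [1.0], "a"), self._example(0, [0.0], "b")]
        with pytest.raises(ValueError, match="qid"):
            pairwise_differences(ex)

    def test_count_formula_random(self):
        rng = np.random.default_rng(5)
        rels = rng.integers(0, 4, size=12)
        ex = [self._example(int(r), rng.uniform(size=3)) for r in rels]
        diffs = pairwise_differences(ex)
        # brute-force count of ordered cross-level pairs
        expected = sum(
            1 for a in range(12) for b in range(12) if rels[a] > rels[b]
        )
        assert diffs.shape[0] == expected


class TestTrainRankSVM:
    def test_1d_closed_form(self):
        # all differences equal (+1): objective n*C*max(0,1-w) + w^2/2,
        # minimized at w* = min(1, C*n)
        for C, n in [(10.0, 3), (0.1, 2), (0.05, 4), (1.0, 1)]:
            diffs = np.ones((n, 1))
            model = train_rank_svm(diffs, C=C, tol=1e-12)
            assert model.weights[0] == pytest.approx(min(1.0, C * n), abs=1e-9)

    def test_separable_2d_kkt(self):
        diffs = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = train_rank_svm(diffs, C=100.0, tol=1e-12)
        assert np.all(model.weights >= 1.0 - 1e-9)
        assert np.allclose(model.weights, [1.0, 1.0], atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_objective_matches_convex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 31)
        dim = rng.integers(1, 6)
        diffs = rng.normal(size=(n, dim))
        C = float(rng.choice([0.05, 0.5, 1.0, 5.0]))
        model = train_rank_svm(diffs, C=C, tol=1e-12)
        ours = model.diagnostics["objective"]
        oracle = oracle_objective(diffs, C, dim)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_zero_difference_rows_handled(self):
        diffs = np.array([[0.0, 0.0], [1.0, 0.0]])
        model = train_rank_svm(diffs, C=2.0, tol=1e-12)
        # the zero row always costs C*1; weight solves the 1-D problem
        assert model.weights[0] == pytest.approx(1.0, abs=1e-8)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            train_rank_svm(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            train_rank_svm(np.ones((2, 2)), C=0.0)

    def test_nonconvergence_raises(self):
        diffs = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(RuntimeError, match="converge"):
            train_rank_svm(diffs, C=50.0, tol=1e-14, max_iter=1)


class TestRankScore:
    def test_projection_weight(self):
        model = train_rank_svm(np.array([[1.0, 0.0, 0.0]]), C=5.0)
        phi = np.random.default_rng(0).uniform(size=(10, 3))
        s = rank_score(model, phi)
        assert stats.kendalltau(s, phi[:, 0]).statistic == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        model = train_rank_svm(np.ones((1, 2)), C=1.0)
        with pytest.raises(ValueError, match="dimension"):
            rank_score(model, np.ones(3))

    def test_monotone_in_positive_weight(self):
        model = train_rank_svm(np.array([[1.0, 0.5]]), C=10.0)
        lo = rank_score(model, np.array([0.2, 0.5]))[0]
        hi = rank_score(model, np.array([0.9, 0.5]))[0]
        assert hi >= lo

    def test_scale_invariance_of_order(self):
        rng = np.random.default_rng(2)
        model = train_rank_svm(rng.normal(size=(10, 4)), C=1.0)
        phi = rng.uniform(size=(30, 4))
        s1 = rank_score(model, phi)
        s2 = rank_score(model, 3.7 * phi)
        assert np.array_equal(np.argsort(-s1), np.argsort(-s2))


class TestRankingRecovery:
    @pytest.mark.parametrize("seed", range(4))
    def test_kendall_tau_one_on_noiseless_linear_groups(self, seed):
        # relevance is the rank of a noiseless linear score; the trained
        # model must reproduce the exact ordering per qid
        rng = np.random.default_rng(seed)
        w_true = rng.uniform(0.5, 2.0, size=3)
        groups = {}
        phis = {}
        for q in range(4):
            phi = rng.uniform(size=(8, 3))
            scores = phi @ w_true
            rel = np.argsort(np.argsort(scores))  # 0..7, distinct
            ex = [
                RankExample(qid=f"q{q}", pair=(1, k + 10), phi=phi[k],
                            relevance=int(rel[k]))
                for k in range(8)
            ]
            groups[f"q{q}"] = pairwise_differences(ex)
            phis[f"q{q}"] = (phi, scores)
        # separable constraints can have tiny margins: a hard-margin-sized C
        # is needed for an exact ordering fit
        model = train_rank_svm(np.vstack(list(groups.values())), C=1e5,
                               tol=1e-10, max_iter=500_000)
        for q, (phi, scores) in phis.items():
            tau = stats.kendalltau(rank_score(model, phi), scores).statistic
            assert tau == pytest.approx(1.0)


class TestCrossValidation:
    def test_picks_reasonable_C_and_is_deterministic(self):
        rng = np.random.default_rng(1)
        w_true = np.array([1.0, 0.5])
        groups = {}
        for q in range(6):
            phi = rng.uniform(size=(10, 2))
            scores = phi @ w_true + rng.normal(scale=0.01, size=10)
            ex = [
                RankExample(qid=f"q{q}", pair=(1, k + 10), phi=phi[k],
                            relevance=int(r))
                for k, r in enumerate(np.argsort(np.argsort(scores)))
            ]
            groups[f"q{q}"] = pairwise_differences(ex)
        c1 = cross_validate_C(groups, seed=0)
        c2 = cross_validate_C(groups, seed=0)
        assert c1 == c2
        assert c1 in (0.01, 0.1, 1.0, 10.0, 100.0)


class TestPredictionsFromScores:
    def test_minmax_and_order(self):
        pairs = [(1, 10), (2, 11), (3, 12)]
        plist = predictions_from_scores("T", pairs, np.array([3.0, -1.0, 5.0]))
        assert plist.records[0][:2] == (3, 12)
        assert plist.records[0][2] == 1.0
        assert plist.records[-1][2] == 0.0

    def test_constant_scores_tie_rule(self):
        pairs = [(5, 20), (1, 30), (1, 8)]
        plist = predictions_from_scores("T", pairs, np.zeros(3))
        assert [r[:2] for r in plist.records] == [(1, 8), (1, 30), (5, 20)]
        assert all(r[2] == 0.5 for r in plist.records)

    def test_empty(self):
        assert len(predictions_from_scores("T", [], np.zeros(0))) == 0
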