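"""Model zoo, LOOCV selection, greedy acquisition, loop, final selection."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from alfe import chemlib, synth
from alfe.al import (
    ALConfig,
    ALError,
    TrainingSet,
    automl_select,
    greedy_acquire,
    loocv_predictions,
    loocv_r2,
    project_chemical_space,
    run_al_loop,
    select_candidates,
)
from alfe.models import RidgeOnBits, TanimotoGP, make_model, tanimoto_kernel


def random_bits(rng, n, d=64, density=0.2):
    return (rng.random((n, d)) < density).astype(np.uint8)


class TestTanimotoKernel:
    def test_matches_pairwise_tanimoto_similarity(self):
        rng = np.random.default_rng(0)
        x = random_bits(rng, 10)
        k = tanimoto_kernel(x, x)
        for i in range(10):
            for j in range(10):
                inter = int(np.sum(x[i] & x[j]))
                union = int(np.sum(x[i] | x[j]))
                expected = 1.0 if union == 0 else inter / union
                assert k[i, j] == pytest.approx(expected)

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        x = random_bits(rng, 30)
        k = tanimoto_kernel(x, x)
        eigs = np.linalg.eigvalsh(k)
        assert eigs.min() > -1e-8


class TestModels:
    def test_gp_interpolates_at_low_noise(self):
        rng = np.random.default_rng(2)
        x = random_bits(rng, 20)
        y = rng.normal(size=20)
        gp = TanimotoGP(noise=1e-8).fit(x, y)
        assert np.allclose(gp.predict(x), y, atol=1e-4)

    def test_gp_loo_closed_form_matches_explicit_loop(self):
        rng = np.random.default_rng(3)
        x = random_bits(rng, 15)
        y = rng.normal(size=15)
        fast = TanimotoGP(noise=1e-2).loo_predictions(x, y)
        slow = np.empty(15)
        idx = np.arange(15)
        for i in range(15):
            m = TanimotoGP(noise=1e-2).fit(x[idx != i], y[idx != i])
            slow[i] = m.predict(x[i : i + 1])[0]
        assert np.allclose(fast, slow, atol=1e-8)

    def test_ridge_loo_closed_form_matches_explicit_loop(self):
        rng = np.random.default_rng(4)
        x = random_bits(rng, 12, d=8)
        y = rng.normal(size=12)
        fast = RidgeOnBits(alpha=1.0).loo_predictions(x, y)
        slow = np.empty(12)
        idx = np.arange(12)
        for i in range(12):
            m = RidgeOnBits(alpha=1.0).fit(x[idx != i], y[idx != i])
            slow[i] = m.predict(x[i : i + 1])[0]
        assert np.allclose(fast, slow, atol=1e-6)


class TestLOOCV:
    def test_perfect_linear_labels_score_one(self):
        rng = np.random.default_rng(5)
        x = random_bits(rng, 25, d=16)
        beta = rng.normal(size=16)
        y = x @ beta
        # plain least squares (alpha=0) goes through the explicit refit loop
        r2 = loocv_r2(lambda: RidgeOnBits(alpha=0.0), x, y)
        assert r2 > 0.99

    def test_constant_prediction_scores_nonpositive(self):
        class ConstantModel:
            def fit(self, x, y):
                self.c = float(np.mean(y))
                return self

            def predict(self, x):
                return np.full(len(x), self.c)

        rng = np.random.default_rng(6)
        x = random_bits(rng, 20)
        y = rng.normal(size=20)
        assert loocv_r2(lambda: ConstantModel(), x, y) <= 0.0

    def test_random_forest_matches_manual_loo_loop(self):
        rng = np.random.default_rng(7)
        x = random_bits(rng, 5, d=10)
        y = rng.normal(size=5)
        factory = lambda: make_model("random_forest", {"n_estimators": 20}, seed=0)
        fast = loocv_predictions(factory, x, y)
        manual = np.empty(5)
        idx = np.arange(5)
        for i in range(5):
            model = factory()
            model.fit(x[idx != i], y[idx != i])
            manual[i] = model.predict(x[i : i + 1])[0]
        assert np.allclose(fast, manual)

    def test_zero_variance_labels_sentinel(self):
        rng = np.random.default_rng(8)
        x = random_bits(rng, 10)
        assert loocv_r2(lambda: RidgeOnBits(1.0), x, np.ones(10)) == float("-inf")

    def test_too_few_entries_rejected(self):
        with pytest.raises(ALError):
            loocv_r2(lambda: RidgeOnBits(1.0), np.zeros((2, 4)), np.array([1.0, 2.0]))


def make_training(ids, labels):
    train = TrainingSet()
    for i, y in zip(ids, labels):
        train.add(i, y, "pre_AL")
    return train


class TestAutomlSelect:
    def test_single_cell_grid_returns_it(self):
        rng = np.random.default_rng(9)
        ids = [f"m{i}" for i in range(10)]
        feats = {"ecfp6_2048": {i: random_bits(rng, 1)[0] for i in ids}}
        train = make_training(ids, rng.normal(size=10))
        spec, model = automl_select(train, feats, ["ecfp6_2048"], ["gp_tanimoto"])
        assert spec.representation == "ecfp6_2048"
        assert spec.algorithm == "gp_tanimoto"

    def test_gp_draw_prefers_gp(self):
        # labels drawn from a Tanimoto-kernel GP should favor the GP cell
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            x = random_bits(rng, n, d=24)
            k = tanimoto_kernel(x, x) + 1e-6 * np.eye(n)
            y = np.linalg.cholesky(k) @ rng.normal(size=n)
            ids = [f"m{i}" for i in range(n)]
            feats = {"fp": dict(zip(ids, x))}
            spec, _ = automl_select(
                make_training(ids, y), feats, ["fp"],
                ["linear_regression", "gp_tanimoto"], seed=seed,
            )
            wins += spec.algorithm == "gp_tanimoto"
        assert wins >= 16  # >= 80% of seeds

    def test_linear_labels_reach_high_r2(self):
        rng = np.random.default_rng(10)
        x = random_bits(rng, 40, d=32)
        y = x.sum(axis=1).astype(float)  # linear in bit count
        ids = [f"m{i}" for i in range(40)]
        feats = {"fp": dict(zip(ids, x))}
        spec, _ = automl_select(
            make_training(ids, y), feats, ["fp"], ["linear_regression"], seed=0
        )
        assert spec.cv_r2 >= 0.9

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(11)
        x = random_bits(rng, 20)
        y = rng.normal(size=20)
        ids = [f"m{i}" for i in range(20)]
        feats = {"fp": dict(zip(ids, x))}
        args = (make_training(ids, y), feats, ["fp"], ["linear_regression", "gp_tanimoto"])
        spec1, _ = automl_select(*args, seed=3)
        spec2, _ = automl_select(*args, seed=3)
        assert spec1 == spec2


class TestGreedyAcquire:
    def test_most_negative_first(self):
        preds = {"a": -3.0, "b": -5.0, "c": -1.0}
        assert greedy_acquire(preds, 2) == ["b", "a"]

    def test_exclusion(self):
        preds = {"a": -3.0, "b": -5.0, "c": -1.0}
        assert greedy_acquire(preds, 2, exclude={"b"}) == ["a", "c"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(12)
        preds = {f"m{i:03d}": float(rng.normal()) for i in range(100)}
        chosen = greedy_acquire(preds, 10)
        expected = [k for _, k in sorted((v, k) for k, v in preds.items())[:10]]
        assert chosen == expected

    def test_tie_break_lexicographic(self):
        preds = {"z": -1.0, "a": -1.0, "m": -1.0}
        assert greedy_acquire(preds, 2) == ["a", "m"]

    def test_oversized_batch_returns_all(self):
        assert greedy_acquire({"a": -1.0}, 5) == ["a"]


class TestRunALLoop:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"m{i:03d}" for i in range(n)]
        feats = {"ecfp6_2048": {i: random_bits(rng, 1, d=32)[0] for i in ids}}
        labels = {i: float(rng.normal(-6, 1)) for i in ids}
        return ids, feats, labels

    def test_constant_oracle_completes_with_tiebreak_order(self):
        ids, feats, _ = self._setup()
        train = make_training(ids[:5], np.random.default_rng(0).normal(size=5))
        config = ALConfig(batch_schedule=(3, 3), seed=0, scope_switch_iteration=1)
        state = run_al_loop(ids, {i: "hit1" for i in ids}, feats,
                            lambda m: -5.0, train, config)
        assert len(state.history) == 2
        assert len(state.acquired_ids) == 6

    def test_never_requeries_and_conserves(self):
        ids, feats, labels = self._setup(n=20)
        train = make_training(ids[:5], [labels[i] for i in ids[:5]])
        config = ALConfig(batch_schedule=(5, 5, 5), seed=0, scope_switch_iteration=1)
        state = run_al_loop(ids, {i: "hit1" for i in ids}, feats,
                            lambda m: labels[m], train, config)
        acquired = state.acquired_ids
        assert len(acquired) == len(set(acquired)) == 15
        # batch schedule summing to the pool: every molecule labelled once
        assert set(state.training.ids) == set(ids)

    def test_oracle_failure_marks_failed_not_retried(self):
        ids, feats, labels = self._setup(n=20)
        bad = ids[10]

        def oracle(m):
            if m == bad:
                raise RuntimeError("simulation failed")
            return labels[m]

        train = make_training(ids[:5], [labels[i] for i in ids[:5]])
        config = ALConfig(batch_schedule=(14, 1), seed=0, scope_switch_iteration=1)
        state = run_al_loop(ids, {i: "hit1" for i in ids}, feats, oracle, train, config)
        assert state.failed_ids == [bad]
        assert bad not in state.training.ids

    def test_scope_switch_restricts_then_widens(self):
        ids, feats, labels = self._setup(n=30)
        groups = {i: ("hit1" if idx < 20 else "hit2") for idx, i in enumerate(ids)}
        train = make_training(ids[:5], [labels[i] for i in ids[:5]])
        config = ALConfig(batch_schedule=(5, 5), seed=0, scope_switch_iteration=2)
        state = run_al_loop(ids, groups, feats, lambda m: labels[m], train, config)
        first, second = state.history
        assert all(groups[m] == "hit1" for m in first.acquired_ids)
        assert first.pool_scope == "hit1_only"
        assert second.pool_scope == "both_hits"

    def test_deterministic_under_seed(self):
        ids, feats, labels = self._setup(n=30, seed=5)
        config = ALConfig(batch_schedule=(5, 5), seed=9, scope_switch_iteration=1)
        runs = []
        for _ in range(2):
            train = make_training(ids[:5], [labels[i] for i in ids[:5]])
            state = run_al_loop(ids, {i: "hit1" for i in ids}, feats,
                                lambda m: labels[m], train, config)
            runs.append(state.acquired_ids)
        assert runs[0] == runs[1]


class TestSelectCandidates:
    def test_budget_sums(self):
        rng = np.random.default_rng(13)
        ids = [f"m{i:03d}" for i in range(120)]
        scores = {i: float(rng.normal(-6, 1)) for i in ids}
        fps = {i: random_bits(rng, 1)[0] for i in ids}
        chosen = select_candidates(scores, fps, budget_total=75, greedy_n=70, diverse_n=5)
        assert len(chosen) == 75
        assert len(set(chosen)) == 75

    def test_identical_fingerprints_reduce_to_greedy(self):
        rng = np.random.default_rng(14)
        ids = [f"m{i:03d}" for i in range(30)]
        scores = {i: float(-1 - rng.random()) for i in ids}
        fps = {i: np.ones(16, dtype=np.uint8) for i in ids}
        chosen = select_candidates(scores, fps, budget_total=10, greedy_n=7, diverse_n=3)
        greedy_all = [k for _, k in sorted((v, k) for k, v in scores.items())][:10]
        assert set(chosen) == set(greedy_all)

    def test_two_cluster_toy_alternates_clusters(self):
        # cluster A shares bits 0..7, cluster B bits 8..15
        fps = {}
        scores = {}
        for i in range(5):
            a = np.zeros(16, dtype=np.uint8); a[:8] = 1; a[i % 3] = 0
            fps[f"a{i}"] = a
            scores[f"a{i}"] = -2.0 - 0.01 * i
            b = np.zeros(16, dtype=np.uint8); b[8:] = 1; b[8 + i % 3] = 0
            fps[f"b{i}"] = b
            scores[f"b{i}"] = -1.0 - 0.01 * i
        chosen = select_candidates(scores, fps, budget_total=2, greedy_n=0, diverse_n=2)
        # max-min picking after the most negative (an 'a') must jump clusters
        assert chosen[0].startswith("a")
        assert chosen[1].startswith("b")

    def test_shortfall_filled_greedily(self):
        rng = np.random.default_rng(15)
        ids = [f"m{i}" for i in range(10)]
        scores = {i: float(rng.normal(-3, 0.5)) for i in ids}
        fps = {i: random_bits(rng, 1, d=16)[0] for i in ids}
        chosen = select_candidates(
            scores, fps, budget_total=6, greedy_n=3, diverse_n=3,
            diverse_filter=lambda m: False,
        )
        assert len(chosen) == 6

    def test_bad_budget_split(self):
        with pytest.raises(ALError):
            select_candidates({}, {}, budget_total=10, greedy_n=5, diverse_n=3)


class TestChemicalSpaceProjection:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(16)
        x = random_bits(rng, 60, d=128)
        a = project_chemical_space(x, seed=1, perplexity=10)
        b = project_chemical_space(x, seed=1, perplexity=10)
        assert a.shape == (60, 2)
        assert np.array_equal(a, b)

    def test_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(17)
        a = np.zeros((40, 64), dtype=np.uint8); a[:, :24] = 1
        b = np.zeros((40, 64), dtype=np.uint8); b[:, 40:] = 1
        a ^= (rng.random((40, 64)) < 0.05).astype(np.uint8)
        b ^= (rng.random((40, 64)) < 0.05).astype(np.uint8)
        x = np.vstack([a, b])
        coords = project_chemical_space(x, seed=0, perplexity=15)
        labels = [0] * 40 + [1] * 40
        assert silhouette_score(coords, labels) > 0.5

    def test_perplexity_guard(self):
        with pytest.raises(ALError):
            project_chemical_space(np.zeros((10, 8)), seed=0, perplexity=10)
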