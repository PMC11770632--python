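"""Training-set construction, forests, the DNN, metrics, and ensembling."""

import numpy as np
import pandas as pd
import pytest

from delscreen import models
from delscreen.synthetic_del import FRAGMENT_POOL, assemble_member


def _toy_compounds(n, seed, fragments=None):
    rng = np.random.default_rng(seed)
    pool = fragments or FRAGMENT_POOL
    out = []
    for _ in range(n):
        out.append(assemble_member([pool[int(i)] for i in rng.integers(0, len(pool), 2)]))
    return out


@pytest.fixture(scope="module")
def separable_sets():
    """Aromatic positives vs aliphatic negatives: linearly separable."""
    aromatic = [f for f in FRAGMENT_POOL if "c1" in f][:20]
    aliphatic = [f for f in FRAGMENT_POOL if "c" not in f and "n" not in f][:20]
    pos = sorted({assemble_member([a, b]) for a in aromatic[:6] for b in aromatic[6:12]})
    neg = sorted({assemble_member([a, b]) for a in aliphatic[:6] for b in aliphatic[6:14]})
    neg = [s for s in neg if s not in set(pos)]
    return pos, neg


class TestBuildTrainingSets:
    def test_split_arithmetic(self):
        pos = [f"P{i}" for i in range(100)]
        neg = [f"N{i}" for i in range(1000)]
        sets = models.build_training_sets(pos, neg, n_models=1, n_negatives=500, seed=0)
        ts = sets[0]
        n_pos_train = int((ts.train_labels == 1).sum())
        assert n_pos_train == 180  # 90 sampled into train, doubled by oversampling
        assert int((ts.test_labels == 1).sum()) == 10
        assert int((ts.train_labels == 0).sum()) == 450
        assert int((ts.test_labels == 0).sum()) == 50

    def test_n_models_distinct_with_recorded_seeds(self):
        pos = [f"P{i}" for i in range(20)]
        neg = [f"N{i}" for i in range(100)]
        sets = models.build_training_sets(pos, neg, n_models=30, seed=1)
        assert len(sets) == 30
        assert len({ts.seed for ts in sets}) == 30
        assert len({tuple(ts.train_smiles) for ts in sets}) > 1

    def test_fixed_seed_reproducible(self):
        pos = [f"P{i}" for i in range(20)]
        neg = [f"N{i}" for i in range(100)]
        a = models.build_training_sets(pos, neg, n_models=3, seed=7)
        b = models.build_training_sets(pos, neg, n_models=3, seed=7)
        for x, y in zip(a, b):
            assert x.train_smiles == y.train_smiles and x.test_smiles == y.test_smiles

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            models.build_training_sets(["A"], ["A"] + [f"N{i}" for i in range(10)])

    def test_too_few_positives_for_holdout(self):
        with pytest.raises(ValueError):
            models.build_training_sets(["A"], [f"N{i}" for i in range(20)])


class TestForest:
    def test_separable_fixture_perfect_holdout(self, separable_sets):
        pos, neg = separable_sets
        sets = models.build_training_sets(pos, neg, n_models=1, seed=3)
        scorer, acc = models.train_forest(sets[0], n_trees=50, seed=3)
        assert acc == 1.0
        assert np.all(scorer.score(pos[:5]) > scorer.score(neg[:5]))

    def test_label_shuffle_gives_chance_accuracy(self, separable_sets):
        pos, neg = separable_sets
        sets = models.build_training_sets(pos, neg, n_models=1, seed=4)
        ts = sets[0]
        rng = np.random.default_rng(0)
        ts.train_labels = rng.permutation(ts.train_labels)
        ts.test_labels = rng.permutation(ts.test_labels)
        _, acc = models.train_forest(ts, n_trees=50, seed=4)
        # accuracy within a binomial CI of the majority-class rate
        p_major = max(ts.test_labels.mean(), 1 - ts.test_labels.mean())
        sigma = np.sqrt(p_major * (1 - p_major) / len(ts.test_labels))
        assert acc <= p_major + 4 * sigma

    def test_fixed_seed_identical_predictions(self, separable_sets):
        pos, neg = separable_sets
        sets = models.build_training_sets(pos, neg, n_models=1, seed=5)
        s1, _ = models.train_forest(sets[0], n_trees=20, seed=5)
        s2, _ = models.train_forest(sets[0], n_trees=20, seed=5)
        probe = pos[:3] + neg[:3]
        assert np.array_equal(s1.score(probe), s2.score(probe))

    def test_degenerate_single_class_raises(self):
        ts = models.TrainingSet(["CCO", "CCN"], np.array([1, 1]), ["CCC"], np.array([1]))
        with pytest.raises(ValueError, match="single-class"):
            models.train_forest(ts)

    def test_select_best_forest(self):
        dummies = [(object(), 0.7), (object(), 0.9), (object(), 0.8)]
        assert models.select_best_forest(dummies) is dummies[1][0]
        ties = [(object(), 0.8), (object(), 0.8)]
        assert models.select_best_forest(ties) is ties[0][0]
        single = [(object(), 0.5)]
        assert models.select_best_forest(single) is single[0][0]


class TestTop100Actives:
    def test_all_actives_ranked_first(self):
        scores = np.concatenate([np.linspace(1, 0.9, 150), np.linspace(0.5, 0, 300)])
        labels = np.concatenate([np.ones(150), np.zeros(300)])
        assert models.top_100_actives(scores, labels) == 100

    def test_fewer_items_than_n_warns_and_caps(self):
        with pytest.warns(UserWarning):
            assert models.top_100_actives([0.1] * 50, [1] * 50, n=100) == 50

    def test_matches_sort_and_count_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 200))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            k = int(rng.integers(1, n + 1))
            order = sorted(range(n), key=lambda i: (-scores[i], i))
            oracle = sum(labels[i] for i in order[:k])
            assert models.top_100_actives(scores, labels, n=k) == oracle

    def test_random_scores_match_hypergeometric_expectation(self, rng):
        n, n_pos, k = 400, 80, 100
        labels = np.array([1] * n_pos + [0] * (n - n_pos))
        counts = [
            models.top_100_actives(rng.random(n), labels, n=k) for _ in range(1000)
        ]
        expectation = k * n_pos / n
        sigma = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expectation) < 3 * max(sigma, 1e-9)


class TestDnn:
    def test_separable_fixture_checkpoint_selection(self, separable_sets):
        pos, neg = separable_sets
        scorer = models.train_dnn(
            pos[:20], neg[:30], pos[20:30], neg[30:45],
            layers=(32, 8), n_steps=400, checkpoint_every=100, batch_size=16,
            learning_rate=0.05, seed=0, top_n=100,
        )
        tune = pos[20:30] + neg[30:45]
        labels = np.array([1] * 10 + [0] * 15)
        # with fewer than 100 tuning items the metric counts over all of
        # them; a separating checkpoint recovers every tuning positive
        with pytest.warns(UserWarning):
            assert models.top_100_actives(scorer.score(tune), labels, n=100) == 10

    def test_zero_steps_returns_initialization(self, separable_sets):
        pos, neg = separable_sets
        scorer = models.train_dnn(
            pos[:10], neg[:10], pos[10:14], neg[10:16],
            layers=(8,), n_steps=0, checkpoint_every=100, seed=1,
        )
        assert scorer.checkpoint_step == 0

    def test_fixed_seed_reproducible_choice(self, separable_sets):
        pos, neg = separable_sets
        kw = dict(
            layers=(16,), n_steps=200, checkpoint_every=100, batch_size=8,
            learning_rate=0.05, seed=2,
        )
        s1 = models.train_dnn(pos[:10], neg[:15], pos[10:14], neg[15:20], **kw)
        s2 = models.train_dnn(pos[:10], neg[:15], pos[10:14], neg[15:20], **kw)
        probe = pos[14:16] + neg[20:22]
        assert np.allclose(s1.score(probe), s2.score(probe))
        assert s1.checkpoint_step == s2.checkpoint_step

    def test_tuning_overlap_rejected(self, separable_sets):
        pos, neg = separable_sets
        with pytest.raises(ValueError, match="disjoint"):
            models.train_dnn(pos[:10], neg[:10], pos[:2], neg[10:12], n_steps=0)


class _Const:
    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def score(self, smiles_list):
        return self.values[: len(smiles_list)]


class TestEnsemble:
    def _compounds(self, n=3):
        return pd.DataFrame(
            {"id": [f"c{i}" for i in range(n)], "smiles": ["CCO", "CCN", "CCC"][:n]}
        )

    def test_identical_members_equal_single_model(self):
        comp = self._compounds()
        single = _Const([0.3, 0.9, 0.1])
        ens = models.ScorerEnsemble(runs=[[single, single], [single]])
        ranked = models.ensemble_score(ens, comp)
        assert dict(zip(ranked["id"], ranked["score"])) == {"c1": 0.9, "c0": 0.3, "c2": 0.1}

    def test_within_run_median(self):
        comp = self._compounds(1)
        ens = models.ScorerEnsemble(
            runs=[[_Const([0.1]), _Const([0.2]), _Const([0.9])]]
        )
        assert models.ensemble_score(ens, comp)["score"].iloc[0] == pytest.approx(0.2)

    def test_replica_permutation_invariance(self):
        comp = self._compounds()
        replicas = [_Const([0.1, 0.5, 0.3]), _Const([0.7, 0.2, 0.4]), _Const([0.4, 0.9, 0.8])]
        a = models.ensemble_score(models.ScorerEnsemble(runs=[replicas]), comp)
        b = models.ensemble_score(models.ScorerEnsemble(runs=[replicas[::-1]]), comp)
        pd.testing.assert_frame_equal(a, b)

    def test_bounded_by_member_scores(self, rng):
        comp = self._compounds()
        reps = [[_Const(rng.random(3)) for _ in range(3)] for _ in range(2)]
        ens = models.ScorerEnsemble(runs=reps)
        scores = ens.score(comp["smiles"].tolist())
        all_scores = np.vstack([c.values for run in reps for c in run])
        assert np.all(scores >= all_scores.min(axis=0) - 1e-12)
        assert np.all(scores <= all_scores.max(axis=0) + 1e-12)

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            models.ensemble_score(models.ScorerEnsemble(runs=[]), self._compounds())


class TestV21Filter:
    def _ranked(self, scores):
        n = len(scores)
        df = pd.DataFrame(
            {"id": [f"c{i}" for i in range(n)], "smiles": [f"S{i}" for i in range(n)],
             "score": scores}
        )
        return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)

    def test_secondary_equals_primary_keeps_top_half(self):
        primary = self._ranked([0.9, 0.8, 0.7, 0.6])

        class Echo:
            def score(self_inner, smiles):
                return primary.set_index("smiles").loc[smiles, "score"].to_numpy()

        out = models.v21_filter(primary, Echo(), top_k=4, keep_fraction=0.5)
        assert out["id"].tolist() == ["c0", "c1"]

    def test_hand_evaluated_example(self):
        primary = self._ranked([0.9, 0.8, 0.7, 0.6])
        out = models.v21_filter(primary, _Const([0.9, 0.1, 0.8, 0.2]), top_k=4, keep_fraction=0.5)
        # secondary keeps items ranked 1 and 3 by primary; re-ranked by primary
        assert out["id"].tolist() == ["c0", "c2"]
        assert out["rank"].tolist() == [1, 2]

    def test_keep_fraction_one_is_identity_on_slice(self):
        primary = self._ranked([0.5, 0.4, 0.3, 0.2, 0.1])
        out = models.v21_filter(primary, _Const([0.1] * 5), top_k=3, keep_fraction=1.0)
        assert out["id"].tolist() == primary["id"].tolist()[:3]

    def test_top_k_capped_with_warning(self):
        primary = self._ranked([0.5, 0.4])
        with pytest.warns(UserWarning, match="capping"):
            out = models.v21_filter(primary, _Const([0.9, 0.1]), top_k=10, keep_fraction=0.5)
        assert len(out) == 1
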