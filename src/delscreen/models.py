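"""Model training and ensembling for DEL-based virtual screening.

The screening protocol implemented here:

* Random-forest ensemble: many forests are trained on independently
  resampled (positives, negatives) sets with fingerprint features (Morgan
  radius 2, 1024 bits); the forest with the highest holdout accuracy is
  used for catalog inference.  Forest scores are the fraction of trees
  voting positive.
* Fingerprint DNN: a two-hidden-layer (2000, 100) ReLU network on Morgan
  radius-3 / 2048-bit features, trained by SGD on log-loss with periodic
  checkpoints; the checkpoint with the highest ``top_100_actives`` on a
  disjoint tuning set is kept.
* Ensembling: the final score per compound is the median over replica
  models within a run, then the median over runs.
* Two-model filter: rank the catalog with the primary model, keep the top
  k, drop the half with the lowest secondary (DNN) scores, and re-rank the
  survivors by the primary score.

Graph-convolutional scorers are deliberately not re-implemented; any object
with a ``score(smiles_list) -> array`` method plugs into the ensembling and
filtering stages, and the fingerprint DNN plays that role in the tests.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .chemfeat import fingerprint_matrix

logger = logging.getLogger("delscreen.models")

RF_RADIUS, RF_NBITS = 2, 1024
DNN_RADIUS, DNN_NBITS = 3, 2048


@dataclass
class TrainingSet:
    """One resampled train/test split with its feature specification."""

    train_smiles: list[str]
    train_labels: np.ndarray
    test_smiles: list[str]
    test_labels: np.ndarray
    radius: int = RF_RADIUS
    nbits: int = RF_NBITS
    seed: int = 0


def build_training_sets(
    positives: list[str],
    negatives: list[str],
    n_models: int = 30,
    n_negatives: int | None = None,
    pos_fraction: float = 0.9,
    oversample_pos: int = 2,
    seed: int = 0,
    radius: int = RF_RADIUS,
    nbits: int = RF_NBITS,
) -> list[TrainingSet]:
    """Independently resampled training sets, one per model.

    Each model draws ``n_negatives`` negatives (without replacement when
    possible) and splits both classes ``pos_fraction`` / ``1-pos_fraction``
    into train / holdout, stratified by label.  Positives are oversampled
    (duplicated ``oversample_pos`` times) in the training partition only.
    """
    if len(positives) < 1:
        raise ValueError("need at least one positive example")
    if len(negatives) < 10:
        raise ValueError("need at least 10 negative examples")
    if set(positives) & set(negatives):
        raise ValueError("positives and negatives overlap")
    n_pos_train = int(round(len(positives) * pos_fraction))
    if n_pos_train < 1 or n_pos_train >= len(positives) + 1:
        raise ValueError("pos_fraction leaves no positives for train or holdout")
    if len(positives) - n_pos_train < 1:
        raise ValueError("too few positives for a stratified holdout")
    n_neg = n_negatives if n_negatives is not None else len(negatives)

    root = np.random.default_rng(seed)
    sets = []
    for m in range(n_models):
        child_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(child_seed)
        pos_perm = rng.permutation(len(positives))
        pos_train = [positives[i] for i in pos_perm[:n_pos_train]]
        pos_test = [positives[i] for i in pos_perm[n_pos_train:]]
        neg_pool = rng.choice(len(negatives), size=n_neg, replace=n_neg > len(negatives))
        n_neg_train = int(round(n_neg * pos_fraction))
        neg_train = [negatives[int(i)] for i in neg_pool[:n_neg_train]]
        neg_test = [negatives[int(i)] for i in neg_pool[n_neg_train:]]
        train = pos_train * oversample_pos + neg_train
        train_labels = np.array([1] * len(pos_train) * oversample_pos + [0] * len(neg_train))
        test = pos_test + neg_test
        test_labels = np.array([1] * len(pos_test) + [0] * len(neg_test))
        sets.append(
            TrainingSet(
                train_smiles=train,
                train_labels=train_labels,
                test_smiles=test,
                test_labels=test_labels,
                radius=radius,
                nbits=nbits,
                seed=child_seed,
            )
        )
    return sets


class ForestScorer:
    """Random-forest scorer; score = fraction of trees voting positive."""

    def __init__(self, clf: RandomForestClassifier, radius: int, nbits: int):
        self.clf = clf
        self.radius = radius
        self.nbits = nbits

    def score(self, smiles_list: list[str]) -> np.ndarray:
        X = fingerprint_matrix(smiles_list, self.radius, self.nbits)
        return self.score_features(X)

    def score_features(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(X)
        pos_col = list(self.clf.classes_).index(1)
        return proba[:, pos_col]


def train_forest(
    ts: TrainingSet,
    n_trees: int = 2000,
    min_split: int = 5,
    seed: int = 0,
) -> tuple[ForestScorer, float]:
    """Train one random forest and report its holdout accuracy."""
    if len(set(ts.train_labels.tolist())) < 2:
        raise ValueError("degenerate single-class training set")
    X = fingerprint_matrix(ts.train_smiles, ts.radius, ts.nbits)
    clf = RandomForestClassifier(
        n_estimators=n_trees, min_samples_split=min_split, random_state=seed, n_jobs=1
    )
    clf.fit(X, ts.train_labels)
    scorer = ForestScorer(clf, ts.radius, ts.nbits)
    X_test = fingerprint_matrix(ts.test_smiles, ts.radius, ts.nbits)
    acc = float((clf.predict(X_test) == ts.test_labels).mean())
    return scorer, acc


def select_best_forest(scored: list[tuple[ForestScorer, float]]) -> ForestScorer:
    """The forest with the highest holdout accuracy; ties keep the lowest index."""
    if not scored:
        raise ValueError("no scorers to select from")
    accs = [a for _, a in scored]
    best = int(np.argmax(accs))  # argmax returns the first maximum
    logger.info("selected forest %d of %d (accuracy %.4f)", best, len(scored), accs[best])
    return scored[best][0]


def top_100_actives(scores, labels, n: int = 100) -> int:
    """Number of true actives among the top-``n`` ranked predictions.

    Ties at the boundary are broken by stable input order.  With fewer than
    ``n`` items the count is taken over all of them (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have equal length")
    if scores.shape[0] < n:
        warnings.warn(f"only {scores.shape[0]} items for top-{n}; using all")
        n = scores.shape[0]
    order = np.argsort(-scores, kind="stable")[:n]
    return int(labels[order].sum())


class DnnScorer:
    """Fingerprint MLP scorer wrapping the selected checkpoint."""

    def __init__(self, clf: MLPClassifier, radius: int, nbits: int, checkpoint_step: int):
        self.clf = clf
        self.radius = radius
        self.nbits = nbits
        self.checkpoint_step = checkpoint_step

    def score(self, smiles_list: list[str]) -> np.ndarray:
        X = fingerprint_matrix(smiles_list, self.radius, self.nbits).astype(np.float32)
        return self.score_features(X)

    def score_features(self, X: np.ndarray) -> np.ndarray:
        pos_col = list(self.clf.classes_).index(1)
        return self.clf.predict_proba(X)[:, pos_col]


def train_dnn(
    train_pos: list[str],
    train_neg: list[str],
    tune_pos: list[str],
    tune_neg: list[str],
    layers: tuple[int, ...] = (2000, 100),
    radius: int = DNN_RADIUS,
    nbits: int = DNN_NBITS,
    n_steps: int = 1_000_000,
    checkpoint_every: int = 100_000,
    batch_size: int = 128,
    learning_rate: float = 0.01,
    seed: int = 0,
    top_n: int = 100,
) -> DnnScorer:
    """Train the fingerprint DNN with checkpoint selection.

    A ReLU MLP on Morgan radius-3 / 2048-bit features, optimized by
    mini-batch SGD on log-loss.  Every ``checkpoint_every`` gradient steps
    the ``top_100_actives`` metric is evaluated on the disjoint tuning set
    and the best checkpoint wins.  The defaults mirror production-scale
    training step counts; tests scale ``n_steps`` down.
    """
    if set(tune_pos) & set(train_pos) or set(tune_neg) & set(train_neg):
        raise ValueError("tuning set must be disjoint from training set")
    rng = np.random.default_rng(seed)
    X_train = np.vstack(
        [
            fingerprint_matrix(train_pos, radius, nbits),
            fingerprint_matrix(train_neg, radius, nbits),
        ]
    ).astype(np.float32)
    y_train = np.array([1] * len(train_pos) + [0] * len(train_neg))
    X_tune = np.vstack(
        [
            fingerprint_matrix(tune_pos, radius, nbits),
            fingerprint_matrix(tune_neg, radius, nbits),
        ]
    ).astype(np.float32)
    y_tune = np.array([1] * len(tune_pos) + [0] * len(tune_neg))

    clf = MLPClassifier(
        hidden_layer_sizes=layers,
        activation="relu",
        solver="sgd",
        learning_rate_init=learning_rate,
        batch_size=batch_size,
        random_state=int(rng.integers(0, 2**31 - 1)),
        max_iter=1,
        warm_start=False,
    )
    # initialize weights with one tiny partial_fit bootstrap
    clf.partial_fit(X_train[:1], y_train[:1], classes=np.array([0, 1]))

    def tune_metric() -> int:
        pos_col = list(clf.classes_).index(1)
        return top_100_actives(clf.predict_proba(X_tune)[:, pos_col], y_tune, n=top_n)

    best_metric = tune_metric()  # initialization baseline
    best_clf = copy.deepcopy(clf)
    best_step = 0
    improved = False
    step = 0
    while step < n_steps:
        chunk = min(checkpoint_every, n_steps - step)
        for _ in range(chunk):
            idx = rng.integers(0, X_train.shape[0], size=min(batch_size, X_train.shape[0]))
            clf.partial_fit(X_train[idx], y_train[idx])
        step += chunk
        m = tune_metric()
        logger.info("dnn checkpoint at step %d: top_%d_actives=%d", step, top_n, m)
        if m > best_metric:
            best_metric, best_clf, best_step = m, copy.deepcopy(clf), step
            improved = True
    if not improved and n_steps > 0:
        warnings.warn("no checkpoint improved over initialization; returning last checkpoint")
        best_clf, best_step = clf, step
    return DnnScorer(best_clf, radius, nbits, best_step)


@dataclass
class ScorerEnsemble:
    """Scorers grouped as runs x replicas; aggregation is median at each level."""

    runs: list[list]  # runs[r] = list of replica scorers
    metadata: dict = field(default_factory=dict)

    def score(self, smiles_list: list[str]) -> np.ndarray:
        if not self.runs or not all(self.runs):
            raise ValueError("ensemble has no scorers")
        # fingerprints are computed once per feature spec, not once per scorer
        feature_cache: dict[tuple[int, int], np.ndarray] = {}

        def member_score(s) -> np.ndarray:
            spec = (getattr(s, "radius", None), getattr(s, "nbits", None))
            if spec[0] is not None and hasattr(s, "score_features"):
                if spec not in feature_cache:
                    feature_cache[spec] = fingerprint_matrix(smiles_list, *spec)
                return s.score_features(feature_cache[spec])
            return np.asarray(s.score(smiles_list), dtype=float)

        run_medians = []
        for replicas in self.runs:
            rep_scores = np.vstack([member_score(s) for s in replicas])
            run_medians.append(np.median(rep_scores, axis=0))
        return np.median(np.vstack(run_medians), axis=0)


def ensemble_score(
    ensemble: ScorerEnsemble,
    compounds: pd.DataFrame,
) -> pd.DataFrame:
    """Score a catalog and return ranked predictions.

    ``compounds`` needs ``id`` and ``smiles`` columns.  Output is sorted by
    descending score with stable order for ties; scores lie in [0, 1].
    """
    scores = ensemble.score(compounds["smiles"].tolist())
    out = compounds[["id", "smiles"]].copy()
    out["score"] = scores
    out = out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def v21_filter(
    primary: pd.DataFrame,
    secondary_scorer,
    top_k: int = 100_000,
    keep_fraction: float = 0.5,
) -> pd.DataFrame:
    """Two-model consensus filter.

    Take the ``top_k`` compounds by primary score, drop the
    ``1 - keep_fraction`` tail with the lowest secondary scores, and
    re-rank the survivors by the primary score.
    """
    if top_k > len(primary):
        warnings.warn(f"top_k={top_k} exceeds catalog size {len(primary)}; capping")
        top_k = len(primary)
    head = primary.sort_values("score", ascending=False, kind="stable").head(top_k).copy()
    n_keep = int(round(top_k * keep_fraction))
    sec = np.asarray(secondary_scorer.score(head["smiles"].tolist()), dtype=float)
    head["_secondary"] = sec
    keep_idx = np.argsort(-sec, kind="stable")[:n_keep]
    survivors = head.iloc[np.sort(keep_idx)].copy()  # preserve primary order
    survivors = survivors.sort_values("score", ascending=False, kind="stable")
    survivors = survivors.drop(columns=["_secondary"]).reset_index(drop=True)
    survivors["rank"] = np.arange(1, len(survivors) + 1)
    return survivors
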