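"""AutoML active-learning loop for affinity-guided acquisition.

Each iteration trains the full (representation x algorithm) grid on all
currently labelled molecules, tunes hyperparameters per cell by an inner
5-fold grid search, scores each tuned cell by leave-one-out cross-validated
R^2, refits the winner on everything, predicts the unlabelled pool, and
greedily acquires the molecules with the most negative predicted binding
free energy for expensive labelling (here, an oracle function standing in
for TI simulation).  Pool scope can be restricted to one hit series for the
early iterations and widened for the last.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.manifold import TSNE
from sklearn.model_selection import KFold

from .chemlib import FingerprintKind, tanimoto_distance_matrix
from .models import HYPERPARAMETER_GRIDS, ModelSpec, make_model

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


class ALError(ValueError):
    """Raised for invalid active-learning configuration or state."""


@dataclass
class TrainingSet:
    """Labelled molecules: (id, absolute binding free energy, iteration tag)."""

    ids: list[str] = field(default_factory=list)
    labels: list[float] = field(default_factory=list)
    iteration_added: list[str] = field(default_factory=list)

    def add(self, mol_id: str, label: float, iteration: str) -> None:
        if mol_id in self.ids:
            raise ALError(f"molecule {mol_id} already labelled")
        if not np.isfinite(label):
            raise ALError(f"label for {mol_id} is not finite")
        self.ids.append(mol_id)
        self.labels.append(float(label))
        self.iteration_added.append(iteration)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ALConfig:
    """Loop settings: grid, batch schedule, scope switching, seed."""

    representations: tuple[str, ...] = (FingerprintKind.ECFP6_2048.value,)
    algorithms: tuple[str, ...] = ("linear_regression", "gp_tanimoto")
    batch_schedule: tuple[int, ...] = (20,) * 7
    scope_switch_iteration: int = 7  # iterations >= this screen both hit series
    seed: int = 0


@dataclass
class IterationRecord:
    iteration: int
    model_spec: ModelSpec
    acquired_ids: list[str]
    acquired_labels: list[float]
    pool_scope: str


@dataclass
class ALState:
    """Full history of one active-learning campaign."""

    training: TrainingSet
    history: list[IterationRecord] = field(default_factory=list)
    failed_ids: list[str] = field(default_factory=list)

    @property
    def acquired_ids(self) -> list[str]:
        return [i for rec in self.history for i in rec.acquired_ids]

    def to_json(self, path) -> None:
        payload = {
            "iterations": [
                {
                    "iteration": rec.iteration,
                    "pool_scope": rec.pool_scope,
                    "model": {
                        "representation": rec.model_spec.representation,
                        "algorithm": rec.model_spec.algorithm,
                        "hyperparameters": rec.model_spec.hyperparameters,
                        "loocv_r2": rec.model_spec.cv_r2,
                    },
                    "acquired_ids": rec.acquired_ids,
                    "acquired_labels": rec.acquired_labels,
                }
                for rec in self.history
            ],
            "failed_ids": self.failed_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def loocv_predictions(model_factory: Callable[[], object], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Held-out prediction for every entry: closed form when the model offers
    one, else an explicit leave-one-out refit loop."""
    probe = model_factory()
    if hasattr(probe, "loo_predictions") and getattr(probe, "supports_fast_loo", True):
        return np.asarray(probe.loo_predictions(x, y), float)
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = model_factory()
        model.fit(x[mask], y[mask])
        preds[i] = float(np.asarray(model.predict(x[i : i + 1])).ravel()[0])
    return preds


def loocv_r2(model_factory: Callable[[], object], x: np.ndarray, y: np.ndarray) -> float:
    """LOOCV R^2 = 1 - SSE/SST over held-out predictions.

    Zero label variance makes R^2 undefined; the -inf sentinel guarantees a
    degenerate cell can never win model selection.
    """
    y = np.asarray(y, float)
    if len(y) < 3:
        raise ALError("LOOCV needs at least 3 training entries")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        logger.warning("zero label variance: LOOCV R^2 undefined")
        return NEG_INF
    preds = loocv_predictions(model_factory, np.asarray(x, float), y)
    sse = float(np.sum((y - preds) ** 2))
    return 1.0 - sse / sst


def _kfold_r2(model_factory, x, y, n_splits: int, seed: int) -> float:
    y = np.asarray(y, float)
    n_splits = min(n_splits, len(y))
    if n_splits < 2:
        return NEG_INF
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    preds = np.empty(len(y))
    for train_idx, test_idx in kf.split(x):
        model = model_factory()
        model.fit(x[train_idx], y[train_idx])
        preds[test_idx] = np.asarray(model.predict(x[test_idx])).ravel()
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return NEG_INF
    return 1.0 - float(np.sum((y - preds) ** 2)) / sst


def tune_cell(
    algorithm: str, x: np.ndarray, y: np.ndarray, seed: int = 0
) -> dict:
    """Inner 5-fold grid search over the algorithm's hyperparameter grid;
    ties keep the earliest grid entry."""
    best_params, best_score = None, NEG_INF
    for params in HYPERPARAMETER_GRIDS[algorithm]:
        score = _kfold_r2(lambda: make_model(algorithm, params, seed), x, y, 5, seed)
        if score > best_score:
            best_params, best_score = params, score
    return dict(best_params if best_params is not None else HYPERPARAMETER_GRIDS[algorithm][0])


def automl_select(
    train: TrainingSet,
    features_by_representation: Mapping[str, Mapping[str, np.ndarray]],
    representations: Sequence[str],
    algorithms: Sequence[str],
    seed: int = 0,
) -> tuple[ModelSpec, object]:
    """Pick the (representation, algorithm) cell with the best LOOCV R^2.

    ``features_by_representation[rep][mol_id]`` is the fingerprint vector.
    Each cell is hyperparameter-tuned by inner 5-fold CV, then scored by
    LOOCV with the tuned parameters; the winning cell is refit on all data.
    Ties go to the first cell in declared grid order.
    """
    y = np.asarray(train.labels, float)
    best: tuple[ModelSpec, object] | None = None
    for rep in representations:
        feats = features_by_representation[rep]
        try:
            x = np.vstack([feats[i] for i in train.ids]).astype(float)
        except KeyError as exc:
            raise ALError(f"missing features for representation {rep}: {exc}") from exc
        for algo in algorithms:
            try:
                params = tune_cell(algo, x, y, seed=seed)
                r2 = loocv_r2(lambda: make_model(algo, params, seed), x, y)
            except Exception as exc:  # a failing cell must not sink the grid
                logger.warning("cell (%s, %s) failed: %s", rep, algo, exc)
                continue
            spec = ModelSpec(representation=rep, algorithm=algo,
                             hyperparameters=params, cv_r2=r2)
            if best is None or spec.cv_r2 > best[0].cv_r2:
                model = make_model(algo, params, seed)
                model.fit(x, y)
                best = (spec, model)
    if best is None:
        raise ALError("every AutoML grid cell failed")
    return best


def greedy_acquire(
    predictions: Mapping[str, float], batch: int, exclude: set[str] | Sequence[str] = ()
) -> list[str]:
    """The ``batch`` ids with most negative predictions; ties lexicographic."""
    if batch < 1:
        raise ALError("batch must be >= 1")
    excluded = set(exclude)
    ranked = sorted(
        ((v, k) for k, v in predictions.items() if k not in excluded),
        key=lambda t: (t[0], t[1]),
    )
    if batch > len(ranked):
        logger.warning("batch %d exceeds %d available; returning all", batch, len(ranked))
    return [k for _, k in ranked[:batch]]


def run_al_loop(
    pool_ids: Sequence[str],
    pool_groups: Mapping[str, str],
    features_by_representation: Mapping[str, Mapping[str, np.ndarray]],
    oracle: Callable[[str], float],
    init_train: TrainingSet,
    config: ALConfig,
) -> ALState:
    """Run the full acquisition campaign.

    ``pool_groups`` maps molecule id to its hit series ("hit1"/"hit2");
    iterations below ``config.scope_switch_iteration`` train and screen the
    hit1 series only, later iterations use everything.  Oracle failures mark
    the id failed (never retried), mirroring failed simulations.  The loop is
    deterministic for a fixed config seed.
    """
    if len(init_train) == 0:
        raise ALError("initial training set must be nonempty")
    state = ALState(training=init_train)
    labelled = set(init_train.ids)
    for it, batch in enumerate(config.batch_schedule, start=1):
        scope = "hit1_only" if it < config.scope_switch_iteration else "both_hits"
        if scope == "hit1_only":
            train_idx = [
                i for i, mol in enumerate(state.training.ids)
                if pool_groups.get(mol, "hit1") == "hit1"
            ]
            screen_ids = [m for m in pool_ids if pool_groups.get(m, "hit1") == "hit1"]
        else:
            train_idx = list(range(len(state.training.ids)))
            screen_ids = list(pool_ids)
        sub = TrainingSet(
            ids=[state.training.ids[i] for i in train_idx],
            labels=[state.training.labels[i] for i in train_idx],
            iteration_added=[state.training.iteration_added[i] for i in train_idx],
        )
        spec, model = automl_select(
            sub, features_by_representation, config.representations,
            config.algorithms, seed=config.seed,
        )
        feats = features_by_representation[spec.representation]
        candidates = [
            m for m in screen_ids
            if m not in labelled and m not in state.failed_ids and m in feats
        ]
        if not candidates:
            logger.warning("iteration %d: empty candidate pool, stopping", it)
            break
        xc = np.vstack([feats[m] for m in candidates]).astype(float)
        preds = dict(zip(candidates, np.asarray(model.predict(xc)).ravel()))
        chosen = greedy_acquire(preds, batch)
        acquired, labels = [], []
        for mol in chosen:
            try:
                label = float(oracle(mol))
            except Exception as exc:
                logger.warning("oracle failed for %s: %s", mol, exc)
                state.failed_ids.append(mol)
                continue
            state.training.add(mol, label, f"AL_{it}")
            labelled.add(mol)
            acquired.append(mol)
            labels.append(label)
        state.history.append(
            IterationRecord(
                iteration=it, model_spec=spec, acquired_ids=acquired,
                acquired_labels=labels, pool_scope=scope,
            )
        )
        assert len(set(state.acquired_ids)) == len(state.acquired_ids), \
            "an id was acquired twice"
    return state


def select_candidates(
    scores: Mapping[str, float],
    fingerprints: Mapping[str, np.ndarray],
    budget_total: int = 75,
    greedy_n: int = 70,
    diverse_n: int = 5,
    diverse_filter: Callable[[str], bool] | None = None,
) -> list[str]:
    """Budgeted final selection: greedy block plus a diversity block.

    The first ``greedy_n`` are the most negative scores overall; the
    remaining ``diverse_n`` come from molecules passing ``diverse_filter``
    (and having negative score, not already chosen), picked by max-min
    Tanimoto distance seeded with the most negative eligible molecule.
    Shortfalls are filled greedily with a warning.
    """
    if greedy_n + diverse_n != budget_total:
        raise ALError("greedy_n + diverse_n must equal budget_total")
    ranked = sorted(scores.items(), key=lambda t: (t[1], t[0]))
    chosen = [k for k, _ in ranked[:greedy_n]]
    chosen_set = set(chosen)

    eligible = [
        k for k, v in ranked
        if k not in chosen_set and v < 0 and (diverse_filter is None or diverse_filter(k))
    ]
    diverse: list[str] = []
    if eligible and diverse_n > 0:
        fps = np.vstack([fingerprints[k] for k in eligible]).astype(float)
        dist = tanimoto_distance_matrix(fps, fps)
        picked = [0]  # most negative eligible seeds the max-min picking
        while len(picked) < min(diverse_n, len(eligible)):
            min_dist = dist[:, picked].min(axis=1)
            min_dist[picked] = -1.0
            picked.append(int(np.argmax(min_dist)))
        diverse = [eligible[i] for i in picked[: diverse_n]]
    if len(diverse) < diverse_n:
        logger.warning(
            "only %d diverse candidates eligible; filling greedily", len(diverse)
        )
        fillers = [
            k for k, _ in ranked if k not in chosen_set and k not in diverse
        ][: diverse_n - len(diverse)]
        diverse.extend(fillers)
    return chosen + diverse


def project_chemical_space(
    features: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2D t-SNE embedding of a fingerprint matrix (reporting only)."""
    features = np.asarray(features, float)
    n = features.shape[0]
    if n <= perplexity * 3:
        raise ALError(
            f"perplexity {perplexity} too large for {n} molecules (need n > 3*perplexity)"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        max_iter=500,
    )
    return tsne.fit_transform(features)
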