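"""Random-forest tissue classification with nested cross-validation.

Regions are classified into 14 categories: tumor (T), composed tumor plus
non-tumor volumes (T+NT), brain, skeleton (SK), head-and-neck region (HN),
heart (HT), right/left kidney (RK/LK), liver (LI), gastrointestinal tract
(GI), genital organs (G), urinary bladder (BL), activated brown fat (BF) and
composed non-tumor volumes (NT+NT).  For the binary tumor/non-tumor decision,
T and T+NT both count as tumor so that no tumor lesion is lost.

Model selection uses a nested scheme: the data are split at patient level
into three parts which rotate through the roles of training, validation and
test set, so each region is a test case exactly once per repetition; the
inner step picks the hyperparameter pair (maximum tree depth, features per
split) with the best validation accuracy, and that model predicts the test
part.  Ten repetitions with fresh random partitions are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

#: canonical class order; ties in majority votes resolve to the earliest entry
CLASS_ORDER = ["T", "T+NT", "BRAIN", "SK", "HN", "HT", "RK", "LK", "LI",
               "GI", "G", "BL", "BF", "NT+NT"]
TUMOR_CLASSES = frozenset({"T", "T+NT"})

_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass
class CVConfig:
    """Nested cross-validation configuration.

    ``depth_grid`` and ``mtry_grid`` span the hyperparameter search (``None``
    depth means unlimited); ``patient_level=True`` partitions whole patients
    into the three parts so no patient leaks between them.
    """

    n_parts: int = 3
    repetitions: int = 10
    depth_grid: tuple = (4, 8, 16, None)
    mtry_grid: tuple = (6, 10, 16)
    n_trees: int = 500
    seed: int = 0
    patient_level: bool = True
    stratified: bool = False

    def __post_init__(self) -> None:
        self.depth_grid = tuple(self.depth_grid)
        self.mtry_grid = tuple(self.mtry_grid)
        if self.n_parts < 3:
            raise ValueError("n_parts must be at least 3 (train/validation/test)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be at least 1")
        if not self.depth_grid or not self.mtry_grid:
            raise ValueError("hyperparameter grid must be nonempty")


def train_forest(X: np.ndarray, y: np.ndarray, depth: int | None, mtry: int,
                 n_trees: int = 500, seed: int = 0) -> RandomForestClassifier:
    """Train a random forest of independently bootstrapped, depth-capped trees."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training set; forest degenerates to a "
                      "constant classifier", stacklevel=2)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=depth,
        max_features=min(mtry, X.shape[1]),
        random_state=seed,
        bootstrap=True,
    )
    forest.fit(np.asarray(X, dtype=float), y)
    return forest


def _count_votes(canon_votes: np.ndarray) -> np.ndarray:
    """Per-sample vote counts in canonical class order from ``(n_trees, n_samples)`` indices."""
    n_trees, n_samples = canon_votes.shape
    counts = np.zeros((len(CLASS_ORDER), n_samples), dtype=np.int64)
    sample_idx = np.tile(np.arange(n_samples), n_trees)
    np.add.at(counts, (canon_votes.ravel(), sample_idx), 1)
    return counts


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Resolve per-tree votes (class names, shape ``(n_trees, n_samples)``).

    Ties break toward the earliest class in :data:`CLASS_ORDER` (argmax over
    canonical-order counts takes the first maximum).
    """
    votes = np.asarray(votes, dtype=object)
    canon = np.vectorize(_CLASS_INDEX.__getitem__, otypes=[np.int64])(votes)
    winners = _count_votes(canon).argmax(axis=0)
    return np.array([CLASS_ORDER[w] for w in winners], dtype=object)


def predict(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Majority vote of all trees with the canonical-order tie-break."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing or non-finite entries")
    if len(forest.classes_) == 1:
        return np.full(X.shape[0], forest.classes_[0], dtype=object)
    canon_of_forest = np.array([_CLASS_INDEX[c] for c in forest.classes_])
    votes = np.stack([
        canon_of_forest[tree.predict(X).astype(np.int64)]
        for tree in forest.estimators_
    ])
    winners = _count_votes(votes).argmax(axis=0)
    return np.array([CLASS_ORDER[w] for w in winners], dtype=object)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class CVResult:
    """Outputs of :func:`nested_cv`.

    ``predictions`` has one row per region with the per-repetition predicted
    labels (columns ``rep0..repN``) and the modal label across repetitions;
    ``mean_confusion`` is the repetition-averaged 14x14 count matrix rounded
    to integers (rows automatic, columns manual); ``chosen_params`` logs the
    selected hyperparameters per repetition and rotation; ``partitions``
    holds, per repetition, the part index assigned to each region.
    """

    predictions: pd.DataFrame
    mean_confusion: pd.DataFrame
    chosen_params: list = field(default_factory=list)
    partitions: list = field(default_factory=list)

    @property
    def modal_labels(self) -> pd.Series:
        return self.predictions["modal"]


def _partition(units: np.ndarray, n_parts: int, rng: np.random.Generator) -> list[np.ndarray]:
    units = np.array(units)
    order = rng.permutation(len(units))
    return [units[part] for part in np.array_split(order, n_parts)]


def _confusion_counts(manual, predicted) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=CLASS_ORDER, columns=CLASS_ORDER, dtype=float)
    for m, p in zip(manual, predicted):
        cm.loc[p, m] += 1
    return cm


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def nested_cv(data: pd.DataFrame, cfg: CVConfig,
              feature_columns: list[str] | None = None) -> CVResult:
    """Nested cross-validation over a labeled region table.

    ``data`` must carry ``patient_id``, ``region_id``, ``label`` and the
    feature columns (default: every other numeric column).  Classes missing
    from a training part simply cannot be predicted in that rotation; this is
    logged, not fatal (singleton classes are expected in clinical data).
    """
    from .features import FEATURE_NAMES
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_NAMES if c in data.columns]
        if not feature_columns:
            feature_columns = [c for c in data.columns
                               if c not in ("patient_id", "region_id", "label")
                               and np.issubdtype(data[c].dtype, np.number)]
    unknown = set(data["label"]) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"labels outside the class vocabulary: {sorted(unknown)}")
    X = data[feature_columns].to_numpy(dtype=float)
    y = data["label"].to_numpy(dtype=object)
    patients = data["patient_id"].to_numpy()
    n = len(data)

    rep_preds = np.empty((cfg.repetitions, n), dtype=object)
    rep_confusions = []
    chosen = []
    partitions = []
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = ss.spawn(cfg.repetitions)
    for rep in range(cfg.repetitions):
        rng = np.random.default_rng(rep_seeds[rep])
        fit_seed = int(rng.integers(0, 2 ** 31 - 1))
        if cfg.patient_level:
            units = np.unique(patients)
            parts_units = _partition(units, cfg.n_parts, rng)
            parts = [np.nonzero(np.isin(patients, pu))[0] for pu in parts_units]
        else:
            parts = _partition(np.arange(n), cfg.n_parts, rng)
        part_of = np.full(n, -1, dtype=int)
        for pi, idx in enumerate(parts):
            part_of[idx] = pi
        partitions.append(part_of)
        covered = np.zeros(n, dtype=bool)
        for rot in range(cfg.n_parts):
            test_idx = parts[rot]
            val_idx = parts[(rot + 1) % cfg.n_parts]
            train_idx = np.concatenate([parts[r] for r in range(cfg.n_parts)
                                        if r not in (rot, (rot + 1) % cfg.n_parts)])
            best = None
            for depth in cfg.depth_grid:
                for mtry in cfg.mtry_grid:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        forest = train_forest(X[train_idx], y[train_idx], depth,
                                              mtry, cfg.n_trees, fit_seed)
                    acc = float(np.mean(predict(forest, X[val_idx]) == y[val_idx])) \
                        if len(val_idx) else 0.0
                    if best is None or acc > best[0]:
                        best = (acc, depth, mtry, forest)
            _, depth, mtry, forest = best
            chosen.append({"repetition": rep, "rotation": rot,
                           "max_depth": depth, "mtry": mtry,
                           "validation_accuracy": best[0]})
            if len(test_idx):
                rep_preds[rep, test_idx] = predict(forest, X[test_idx])
                covered[test_idx] = True
        assert covered.all(), "every region must be a test case exactly once"
        rep_confusions.append(_confusion_counts(y, rep_preds[rep]))

    mean_cm = sum(rep_confusions) / cfg.repetitions
    mean_cm = pd.DataFrame(_round_half_up(mean_cm.to_numpy()),
                           index=CLASS_ORDER, columns=CLASS_ORDER)

    pred_df = data[["patient_id", "region_id", "label"]].copy().reset_index(drop=True)
    for rep in range(cfg.repetitions):
        pred_df[f"rep{rep}"] = rep_preds[rep]
    modal = []
    for s in range(n):
        labels, counts = np.unique(rep_preds[:, s], return_counts=True)
        top = counts.max()
        cands = sorted((l for l, c in zip(labels, counts) if c == top),
                       key=lambda l: _CLASS_INDEX[l])
        modal.append(cands[0])
    pred_df["modal"] = modal
    return CVResult(predictions=pred_df, mean_confusion=mean_cm,
                    chosen_params=chosen, partitions=partitions)
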