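"""Per-beat contractile phenotype classification.

Reproduces the supervised protocol used to probe tracker robustness: a
labelled per-beat dataset of six kinematic features (four intervals + the
two speed-peak magnitudes), class rebalancing by subsampling the
overrepresented class, a stratified 0.80 train/test split, and three
classifiers — random forest and support vector machines with linear and
polynomial kernels — scored by true positive rate TPR = TP/(TP+FN) and
accuracy = (TP+TN)/(TP+TN+FP+FN) from the binary confusion matrix
(treated = positive = 1, control = negative = 0).

Hyperparameters (unstated in the protocol, recorded here for
reproducibility): RF 200 trees with default feature subsampling; SVM C = 1,
polynomial degree 3, features standardized on the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ClassMissingError, StratificationError, TrainingError

__all__ = [
    "FEATURES",
    "CLASSIFIERS",
    "BeatDataset",
    "ConfusionMatrix",
    "assemble_dataset",
    "assemble_datasets",
    "rebalance",
    "split",
    "train_and_evaluate",
    "evaluate_datasets",
]

FEATURES = (
    "beat_duration_ms",
    "t_theta_c_ms",
    "t_theta_r_ms",
    "t_theta_cr_ms",
    "contraction_peak",
    "relaxation_peak",
)

CLASSIFIERS = ("svm_linear", "svm_poly", "random_forest")

TRAIN_FRACTION = 0.80


@dataclass
class BeatDataset:
    """Labelled per-beat feature table for one (tracker, frequency, ...) key."""

    frame: pd.DataFrame  # FEATURES columns + 'label'
    key: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self):
        missing = [c for c in (*FEATURES, "label") if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame.loc[:, list(FEATURES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def class_counts(self) -> dict[int, int]:
        vc = self.frame["label"].value_counts()
        return {int(k): int(v) for k, v in vc.items()}


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; treated (1) is the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def assemble_dataset(per_beat: pd.DataFrame, key: dict | None = None) -> BeatDataset:
    """Build one dataset from a labelled per-beat table.

    Rows with a missing feature or label are dropped; the count of dropped
    rows is kept on the dataset.
    """
    cols = [*FEATURES, "label"]
    missing = [c for c in cols if c not in per_beat.columns]
    if missing:
        raise ValueError(f"per-beat table lacks columns: {missing}")
    sub = per_beat.loc[:, cols]
    clean = sub.dropna()
    return BeatDataset(
        frame=clean.reset_index(drop=True),
        key=dict(key or {}),
        n_dropped=len(sub) - len(clean),
    )


def assemble_datasets(
    per_beat: pd.DataFrame,
    by: tuple[str, ...] = ("tracker", "frequency", "sample_type"),
) -> dict[tuple, BeatDataset]:
    """One dataset per grouping key (default: tracker x frequency x sample type).

    A full benchmark — three trackers, three pacing frequencies, two sample
    types — yields the 18-dataset structure.
    """
    out = {}
    for key_vals, grp in per_beat.groupby(list(by)):
        key = dict(zip(by, key_vals))
        out[tuple(key_vals)] = assemble_dataset(grp, key=key)
    return out


def rebalance(dataset: BeatDataset, seed: int | None = None) -> BeatDataset:
    """Equalize class sizes by subsampling the overrepresented class.

    Sampling is without replacement under the given seed; the smaller class
    is untouched.  Both classes must be present.
    """
    counts = dataset.class_counts()
    if set(counts) != {0, 1}:
        raise ClassMissingError(f"need both classes, got labels {sorted(counts)}")
    if counts[0] == counts[1]:
        return BeatDataset(dataset.frame.copy(), key=dict(dataset.key),
                           n_dropped=dataset.n_dropped)
    big = max(counts, key=counts.get)
    small = 1 - big
    n_small = counts[small]
    rng = np.random.default_rng(seed)
    big_rows = dataset.frame[dataset.frame["label"] == big]
    keep = rng.choice(big_rows.index.to_numpy(), size=n_small, replace=False)
    frame = pd.concat(
        [dataset.frame[dataset.frame["label"] == small], dataset.frame.loc[sorted(keep)]]
    ).reset_index(drop=True)
    return BeatDataset(frame, key=dict(dataset.key), n_dropped=dataset.n_dropped)


def split(
    dataset: BeatDataset,
    train_fraction: float = TRAIN_FRACTION,
    seed: int | None = None,
) -> tuple[BeatDataset, BeatDataset]:
    """Stratified train/test split; train size = round(fraction x n)."""
    n = len(dataset)
    if n < 5:
        raise StratificationError(f"need >= 5 rows to split, got {n}")
    counts = dataset.class_counts()
    if min(counts.values(), default=0) < 2 or len(counts) < 2:
        raise StratificationError(f"class counts too small to stratify: {counts}")
    n_train = int(round(train_fraction * n))
    tr, te = train_test_split(
        dataset.frame,
        train_size=n_train,
        stratify=dataset.frame["label"],
        random_state=(None if seed is None else int(seed) % (2**32)),
    )
    return (
        BeatDataset(tr.reset_index(drop=True), key=dict(dataset.key)),
        BeatDataset(te.reset_index(drop=True), key=dict(dataset.key)),
    )


def _build_classifier(name: str, seed: int | None):
    state = None if seed is None else int(seed) % (2**32)
    if name == "svm_linear":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if name == "svm_poly":
        return make_pipeline(StandardScaler(), SVC(kernel="poly", degree=3, C=1.0))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=state)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def train_and_evaluate(
    train: BeatDataset,
    test: BeatDataset,
    classifier: str,
    seed: int | None = None,
) -> dict:
    """Fit one classifier on the train split and score it on the test split.

    Returns a report entry: confusion matrix counts, TPR, accuracy, the
    classifier tag, the dataset key and the seed.
    """
    if len(np.unique(train.y)) < 2:
        raise TrainingError("training set holds a single class")
    model = _build_classifier(classifier, seed)
    model.fit(train.X, train.y)
    pred = model.predict(test.X)
    y = test.y
    cm = ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
    )
    return {
        "classifier": classifier,
        "key": dict(train.key),
        "seed": seed,
        "confusion": {"TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn},
        "tpr": cm.tpr,
        "accuracy": cm.accuracy,
        "n_train": len(train),
        "n_test": len(test),
    }


def evaluate_datasets(
    datasets: dict[tuple, BeatDataset],
    classifiers: tuple[str, ...] = CLASSIFIERS,
    seed: int = 0,
) -> pd.DataFrame:
    """Rebalance, split and score every dataset with every classifier.

    Follows the protocol order — rebalance first, then the stratified 0.80
    split — with all randomness derived from one master seed.  Returns a
    tidy report (one row per dataset x classifier).
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(datasets))
    for (key_vals, ds), child in zip(sorted(datasets.items()), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        balanced = rebalance(ds, seed=sub_seed)
        train, test = split(balanced, seed=sub_seed)
        for clf in classifiers:
            rep = train_and_evaluate(train, test, clf, seed=sub_seed)
            row = dict(ds.key)
            row.update(
                {
                    "classifier": clf,
                    "tpr": rep["tpr"],
                    "accuracy": rep["accuracy"],
                    **rep["confusion"],
                    "n_train": rep["n_train"],
                    "n_test": rep["n_test"],
                    "seed": sub_seed,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
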