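"""Evaluation protocols: offline leave-one-out and online incremental.

Six prediction methods share these protocols — three Venn predictors
(``vm-svm``, ``vm-sr``, ``vm-nb``) and their underlying point-
probability methods (``platt``, ``sr``, ``nb``).  Point methods report
the probability they assign to their predicted label; Venn methods
report a probability interval.

* :func:`offline_loo` — every sample is predicted once by a model
  trained on the remaining n−1; feature scaling, when enabled, is
  refit inside each fold so no test information leaks into the scaler.
* :func:`online_run` — a small seeded initial training set (a fixed
  number of samples per class) is grown one sample at a time: predict,
  reveal the true label, add to the training set, refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import (GaussianNaiveBayes, SoftmaxRegression, SVMPlatt,
                          tune_svm)
from .datasets import Dataset
from .errors import InvalidInputError
from .signal_features import FeatureScaler
from .validity import PredictionRecord, ValidityReport, evaluate_records
from .venn import venn_predict

__all__ = [
    "METHODS",
    "ExperimentConfig",
    "ConfusionTable",
    "ProtocolResult",
    "offline_loo",
    "online_run",
    "sensitivity_specificity",
]

#: method name -> (is_venn, underlying classifier kind)
METHODS = {
    "vm-svm": (True, "svm"),
    "vm-sr": (True, "softmax"),
    "vm-nb": (True, "nb"),
    "platt": (False, "svm"),
    "sr": (False, "softmax"),
    "nb": (False, "nb"),
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run.

    Attributes
    ----------
    method : one of ``METHODS``.
    mode : Venn taxonomy mode, ``"loo"`` (faithful, O(K·n) fits per
        prediction) or ``"induct"`` (O(K) fits).
    seed : drives every random choice (online ordering, tuning folds).
    online_init_per_class : initial training samples per class online.
    scale : min-max scale features, refit per training set.
    tune : grid-search SVM (C, γ) before predicting (offline: once on
        the full set, then frozen; online: every ``retune_interval``
        steps).  When off, ``svm_c``/``svm_gamma`` are used as-is.
    """

    method: str
    mode: str = "loo"
    seed: int = 0
    online_init_per_class: int = 3
    scale: bool = True
    tune: bool = False
    retune_interval: int = 25
    svm_c: float = 10.0
    svm_gamma: object = "scale"
    l2: float = 1e-4
    var_smoothing: float = 1e-9

    def __post_init__(self):
        if self.method not in METHODS:
            raise InvalidInputError(
                f"unknown method {self.method!r}; valid methods: {sorted(METHODS)}")
        if self.mode not in ("loo", "induct"):
            raise InvalidInputError("mode must be 'loo' or 'induct'")
        if self.online_init_per_class < 1:
            raise InvalidInputError("online_init_per_class must be >= 1")

    @property
    def is_venn(self) -> bool:
        return METHODS[self.method][0]

    @property
    def base_kind(self) -> str:
        return METHODS[self.method][1]

    def classifier_hyper(self) -> dict:
        if self.base_kind == "svm":
            return {"C": self.svm_c, "gamma": self.svm_gamma}
        if self.base_kind == "softmax":
            return {"l2": self.l2}
        return {"var_smoothing": self.var_smoothing}

    def build_classifier(self, labels):
        kind = self.base_kind
        if kind == "svm":
            return SVMPlatt(labels, **self.classifier_hyper())
        if kind == "softmax":
            return SoftmaxRegression(labels, seed=self.seed, **self.classifier_hyper())
        return GaussianNaiveBayes(labels, **self.classifier_hyper())


@dataclass
class ConfusionTable:
    """K×K count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.labels)
        if self.counts.shape != (K, K) or np.any(self.counts < 0):
            raise InvalidInputError("confusion table must be K×K with counts >= 0")

    @classmethod
    def from_records(cls, true_labels, predicted_labels, labels) -> "ConfusionTable":
        labels = tuple(labels)
        lut = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true_labels, predicted_labels):
            counts[lut[t], lut[p]] += 1
        return cls(counts, labels)


@dataclass
class ProtocolResult:
    """Records, headline classification rate, validity report, confusion."""

    records: list
    classification_rate: float
    report: ValidityReport
    confusion: ConfusionTable
    config: ExperimentConfig
    fit_count: int = 0
    tuned: dict | None = None
    test_order: list = field(default_factory=list)


def _resolve_tuning(config: ExperimentConfig, data: Dataset) -> ExperimentConfig:
    """Grid-search (C, γ) once and freeze it into the config copy."""
    res = tune_svm(data, seed=config.seed)
    return replace(config, svm_c=res.C, svm_gamma=res.gamma, tune=False)


class _FitCounter:
    """Counts classifier fits (cost transparency for Venn-LOO runs)."""

    def __init__(self, config: ExperimentConfig, labels):
        self.config = config
        self.labels = labels
        self.count = 0

    def __call__(self):
        self.count += 1
        return self.config.build_classifier(self.labels)


def _predict_one(config: ExperimentConfig, train: Dataset, x, counter):
    """One prediction (interval or point) with a freshly trained model."""
    if config.is_venn:
        pred = venn_predict(train, x, taxonomy=counter, mode=config.mode)
        return pred.label, pred.p_lower, pred.p_upper
    clf = counter().fit(train.X, train.y)
    probs = clf.predict_proba(x)[0]
    j = int(np.argmax(probs))
    p = float(probs[j])
    return train.labels[j], p, p


def offline_loo(data: Dataset, config: ExperimentConfig) -> ProtocolResult:
    """Leave-one-out evaluation: each sample predicted by a model
    trained on the other n−1 (scaler refit per fold)."""
    if data.n < data.K + 1:
        raise InvalidInputError("need at least K+1 samples for leave-one-out")
    if config.tune and config.base_kind == "svm":
        scaled = data
        if config.scale:
            scaler = FeatureScaler.fit(data.X)
            scaled = Dataset(scaler.transform(data.X), data.y, data.labels,
                             data.sample_ids)
        config = _resolve_tuning(config, scaled)
    counter = _FitCounter(config, data.labels)
    records = []
    true_all, pred_all = [], []
    for i in range(data.n):
        train = data.without(i)
        x = data.X[i]
        if config.scale:
            scaler = FeatureScaler.fit(train.X)
            train = Dataset(scaler.transform(train.X), train.y, train.labels,
                            train.sample_ids)
            x = scaler.transform(x[None, :])[0]
        label, pl, pu = _predict_one(config, train, x, counter)
        correct = label == data.y[i]
        records.append(PredictionRecord(p_lower=pl, p_upper=pu, correct=bool(correct),
                                        sample_id=str(data.sample_ids[i]),
                                        true_label=data.y[i], predicted_label=label,
                                        step=i))
        true_all.append(data.y[i])
        pred_all.append(label)
    rate = float(np.mean([r.correct for r in records]))
    confusion = ConfusionTable.from_records(true_all, pred_all, data.labels)
    return ProtocolResult(records=records, classification_rate=rate,
                          report=evaluate_records(records), confusion=confusion,
                          config=config, fit_count=counter.count,
                          test_order=list(range(data.n)))


def online_run(data: Dataset, config: ExperimentConfig) -> ProtocolResult:
    """Online incremental evaluation.

    A seeded random initial training set (``online_init_per_class``
    samples per class) is grown by consuming the remaining samples in
    seeded random order: predict each, then add it with its true label
    and refit.  Records are returned in test order, so cumulative
    validity series can be read straight off the result.
    """
    yi = data.label_indices()
    rng = np.random.default_rng(config.seed)
    init_idx = []
    for k in range(data.K):
        members = np.flatnonzero(yi == k)
        if members.size <= config.online_init_per_class:
            raise InvalidInputError(
                f"class {data.labels[k]!r} needs more than "
                f"{config.online_init_per_class} samples for an online run")
        init_idx.extend(rng.choice(members, size=config.online_init_per_class,
                                   replace=False).tolist())
    rest = np.setdiff1d(np.arange(data.n), np.array(init_idx))
    order = rng.permutation(rest)

    retune = config.tune and config.base_kind == "svm"
    config = replace(config, tune=False)
    counter = _FitCounter(config, data.labels)

    train = data.subset(np.array(init_idx))
    records = []
    true_all, pred_all = [], []
    for step, i in enumerate(order):
        if retune and step % config.retune_interval == 0:
            # re-tune periodically on the current training set, when every
            # class is large enough for stratified folds
            yi_train = train.label_indices()
            if np.bincount(yi_train, minlength=data.K).min() >= 5:
                tuned = tune_svm(train, seed=config.seed)
                config = replace(config, svm_c=tuned.C, svm_gamma=tuned.gamma)
                counter.config = config
        x = data.X[i]
        fold_train = train
        if config.scale:
            scaler = FeatureScaler.fit(train.X)
            fold_train = Dataset(scaler.transform(train.X), train.y, train.labels,
                                 train.sample_ids)
            x = scaler.transform(x[None, :])[0]
        label, pl, pu = _predict_one(config, fold_train, x, counter)
        correct = label == data.y[i]
        records.append(PredictionRecord(p_lower=pl, p_upper=pu, correct=bool(correct),
                                        sample_id=str(data.sample_ids[i]),
                                        true_label=data.y[i], predicted_label=label,
                                        step=step))
        true_all.append(data.y[i])
        pred_all.append(label)
        train = train.append(data.X[i], data.y[i], str(data.sample_ids[i]))
    assert train.n == data.n
    rate = float(np.mean([r.correct for r in records]))
    confusion = ConfusionTable.from_records(true_all, pred_all, data.labels)
    return ProtocolResult(records=records, classification_rate=rate,
                          report=evaluate_records(records), confusion=confusion,
                          config=config, fit_count=counter.count,
                          test_order=[int(i) for i in order])


def sensitivity_specificity(confusion: ConfusionTable):
    """Per-class sensitivity and specificity.

    For class k: sensitivity is the fraction of class-k samples
    classified as k; specificity is one minus the fraction of
    other-class samples wrongly classified as k.  A class with no true
    samples has undefined sensitivity, reported as NaN (never a silent
    zero).

    Returns
    -------
    (sensitivity, specificity) : two arrays of length K.
    """
    C = confusion.counts
    row_sums = C.sum(axis=1)
    col_sums = C.sum(axis=0)
    n = C.sum()
    K = len(confusion.labels)
    sens = np.full(K, np.nan)
    spec = np.full(K, np.nan)
    for k in range(K):
        if row_sums[k] > 0:
            sens[k] = C[k, k] / row_sums[k]
        others = n - row_sums[k]
        if others > 0:
            spec[k] = 1.0 - (col_sums[k] - C[k, k]) / others
    return sens, spec
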