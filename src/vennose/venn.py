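"""The Venn machine: multiprobability prediction with validity guarantees.

A Venn predictor turns any classifier into a *multiprobability*
predictor.  To predict for a new object x given training examples
z_1..z_{n-1}:

1. hypothesize each possible label y, forming the augmented set
   {z_1, .., z_{n-1}, (x, y)};
2. assign every example in the augmented set to a *category* with a
   taxonomy — here, the label predicted for it by a classifier trained
   on the remaining examples (leave-one-out) or on the whole augmented
   set ("induct" shortcut);
3. take the empirical label distribution of the category containing
   (x, y) as row p_y of a K×K matrix P;
4. define the quality of a column as its minimum entry; predict the
   label whose column has the highest quality and report that column's
   (min, max) as the probability interval [P_l, P_u].

Under the sole assumption that examples are i.i.d., the reported
intervals are valid: cumulative correct-prediction counts track the
cumulative interval bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .classifiers import ProbabilisticClassifier, make_classifier
from .datasets import Dataset
from .errors import InvalidInputError

__all__ = [
    "VennPrediction",
    "assign_categories",
    "empirical_distribution",
    "select_from_matrix",
    "venn_predict",
    "taxonomy_factory",
]

TaxonomyFactory = Callable[[], ProbabilisticClassifier]


@dataclass(frozen=True)
class VennPrediction:
    """Outcome of one Venn prediction.

    Attributes
    ----------
    label : predicted class (the best-quality column).
    p_lower, p_upper : probability interval for the prediction.
    matrix : (K, K) array; row y is the empirical label distribution of
        the test example's category under hypothesis y; columns follow
        ``labels``.
    labels : the ordered label alphabet.
    """

    label: object
    p_lower: float
    p_upper: float
    matrix: np.ndarray
    labels: tuple

    def __post_init__(self):
        if not (0.0 <= self.p_lower <= self.p_upper <= 1.0):
            raise InvalidInputError("interval must satisfy 0 <= P_l <= P_u <= 1")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.p_lower, self.p_upper)


def taxonomy_factory(spec, labels, seed: int = 0, **hyper) -> TaxonomyFactory:
    """Turn a taxonomy spec (name or factory) into a zero-arg factory."""
    if callable(spec):
        return spec
    return lambda: make_classifier(spec, labels, seed=seed, **hyper)


def assign_categories(X: np.ndarray, y: np.ndarray, factory: TaxonomyFactory,
                      mode: str = "loo") -> np.ndarray:
    """Assign every example of the (augmented) set to a category.

    Categories are the labels predicted by the taxonomy classifier.  In
    ``"loo"`` mode the classifier is re-trained on the other n-1
    examples for each example (the taxonomy of the worked protocol, at
    O(n) fits); in ``"induct"`` mode it is trained once on all n
    examples and applied to each (O(1) fits — still a symmetric
    function of the set, so Venn validity is preserved).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if mode == "induct":
        clf = factory().fit(X, y)
        return clf.predict(X)
    if mode != "loo":
        raise InvalidInputError(f"unknown taxonomy mode {mode!r}; expected 'loo' or 'induct'")
    cats = np.empty(n, dtype=object)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        clf = factory().fit(X[keep], y[keep])
        cats[i] = clf.predict(X[i:i + 1])[0]
        keep[i] = True
    return cats


def empirical_distribution(categories: np.ndarray, y: np.ndarray,
                           target_category, labels) -> np.ndarray:
    """Label frequencies within one category (a row of the Venn matrix).

    ``p[y'] = #{examples in the target category with label y'} / |category|``.
    The hypothesized example counts with its hypothesized label.
    """
    categories = np.asarray(categories)
    y = np.asarray(y)
    member = categories == target_category
    size = int(member.sum())
    if size == 0:
        raise InvalidInputError("target category is empty")
    row = np.array([(y[member] == lab).sum() for lab in labels], dtype=float)
    return row / size


def select_from_matrix(P: np.ndarray, labels=None):
    """Apply the Venn column-selection rule to a probability matrix.

    The quality of column j is its minimum entry; the prediction is the
    column of highest quality (ties broken toward the smallest alphabet
    index) and the interval is the (min, max) of that column.

    Returns ``(label, (p_lower, p_upper))``; ``label`` is the column
    index when ``labels`` is None.
    """
    P = np.asarray(P, dtype=float)
    K = P.shape[0]
    if P.shape != (K, K):
        raise InvalidInputError("P must be square (one row per hypothesized label)")
    if np.any(P < -1e-9) or np.any(P > 1 + 1e-9):
        raise InvalidInputError("matrix entries must be probabilities")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidInputError("each row of P must sum to 1")
    quality = P.min(axis=0)
    j_best = int(np.argmax(quality))  # argmax takes the first maximum: smallest index
    col = P[:, j_best]
    label = j_best if labels is None else tuple(labels)[j_best]
    return label, (float(col.min()), float(col.max()))


def venn_predict(train: Dataset, x: np.ndarray, taxonomy="nb",
                 mode: str = "loo", seed: int = 0, **hyper) -> VennPrediction:
    """Venn multiprobability prediction for one test object.

    Parameters
    ----------
    train : Dataset
        Training examples with a label alphabet of size K >= 2.
    x : array of shape (d,)
        Test feature vector.
    taxonomy : str or factory
        ``"nb"``, ``"softmax"``, ``"svm"``, or a zero-argument callable
        returning a fresh classifier over ``train.labels``.
    mode : {"loo", "induct"}
        Taxonomy construction mode (see :func:`assign_categories`).
    """
    if train.n == 0:
        raise InvalidInputError("training set must be nonempty")
    if train.K < 2:
        raise InvalidInputError("label alphabet must have at least two classes")
    factory = taxonomy_factory(taxonomy, train.labels, seed=seed, **hyper)
    x = np.asarray(x, dtype=float).reshape(-1)
    Xa = np.vstack([train.X, x[None, :]])
    K = train.K
    P = np.empty((K, K))
    for k, y_hyp in enumerate(train.labels):
        ya = np.append(train.y, y_hyp)
        cats = assign_categories(Xa, ya, factory, mode=mode)
        P[k] = empirical_distribution(cats, ya, cats[-1], train.labels)
    label, (pl, pu) = select_from_matrix(P, train.labels)
    return VennPrediction(label=label, p_lower=pl, p_upper=pu,
                          matrix=P, labels=train.labels)
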