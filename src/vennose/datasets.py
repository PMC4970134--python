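"""Core in-memory containers: labelled feature datasets.

A :class:`Dataset` is an ordered, i.i.d.-sampled collection of feature
vectors with class labels drawn from a finite, ordered alphabet.  The
alphabet order is load-bearing throughout the package: probability
distributions, Venn probability matrices and confusion tables are all
aligned with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Feature matrix plus labels over a fixed, ordered label alphabet.

    Parameters
    ----------
    X : ndarray of shape (n, d)
        Feature matrix, one row per example.
    y : ndarray of shape (n,)
        Class labels; every value must belong to ``labels``.
    labels : tuple
        Ordered label alphabet.  May include classes not present in ``y``
        (e.g. a training fold missing one class).
    sample_ids : ndarray of shape (n,), optional
        Opaque per-example identifiers; defaults to ``"s0" .. "s{n-1}"``.
    """

    X: np.ndarray
    y: np.ndarray
    labels: tuple
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be a 2-D (n_samples, n_features) array")
        self.y = np.asarray(self.y)
        if self.y.shape != (self.X.shape[0],):
            raise InvalidInputError("y must have one label per row of X")
        self.labels = tuple(self.labels)
        known = set(self.labels)
        bad = [lab for lab in self.y.tolist() if lab not in known]
        if bad:
            raise InvalidInputError(f"labels outside the alphabet: {sorted(set(map(str, bad)))}")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(self.n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape != (self.n,):
                raise InvalidInputError("sample_ids must have one entry per row of X")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return len(self.labels)

    def label_indices(self) -> np.ndarray:
        """Labels encoded as alphabet indices (0 .. K-1)."""
        lut = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([lut[lab] for lab in self.y.tolist()], dtype=int)

    # -- structural operations -------------------------------------------
    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.X[idx], self.y[idx], self.labels, self.sample_ids[idx])

    def without(self, i: int) -> "Dataset":
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return self.subset(np.flatnonzero(keep))

    def append(self, x: np.ndarray, label, sample_id: str = "new") -> "Dataset":
        """Return a new dataset with one extra example appended."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        return Dataset(
            np.vstack([self.X, x]),
            np.append(self.y, label),
            self.labels,
            np.append(self.sample_ids, sample_id),
        )

    # -- pandas bridge ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "Dataset":
        if label_column not in df.columns:
            raise InvalidInputError(f"feature table is missing the {label_column!r} column")
        y = df[label_column].to_numpy()
        X = df.drop(columns=[label_column]).to_numpy(dtype=float)
        labels = tuple(sorted(set(y.tolist()), key=str))
        ids = df.index.astype(str).to_numpy(dtype=object)
        return cls(X, y, labels, ids)

    def to_dataframe(self, feature_names=None) -> pd.DataFrame:
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=list(feature_names))
        df["label"] = self.y
        df.index = pd.Index(self.sample_ids.tolist())
        return df
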