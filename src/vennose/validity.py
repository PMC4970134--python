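"""Validity assessment for probabilistic predictions.

Validity means the probabilities a predictor reports match the
frequencies with which it is actually correct.  Two families of
criteria are provided:

* loss-based — mean log loss ``d_ln`` and root-mean-square loss
  ``d_sq`` of the probability assigned to the predicted label, with
  interval predictions first collapsed to the minimax point
  probability for the relevant loss;
* cumulative — the running count of correct predictions CN compared
  with the running sums of the reported probability bounds (CP), and
  the end-point discrepancy ``d1``.

For a point predictor d1 = |CN/N − ΣP/N|.  For an interval predictor
the discrepancy is measured against both bounds, d11 (lower) and d12
(upper), and d1 = max(d11, d12).  Smaller is better for all three
criteria; a single wrong prediction issued with probability 1 makes
``d_ln`` infinite, which is propagated, not clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "PredictionRecord",
    "ValidityReport",
    "log_loss",
    "square_loss",
    "minimax_log",
    "minimax_square",
    "mean_losses",
    "cumulative_validity",
    "evaluate_records",
    "plot_cumulative_validity",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One prediction: probability interval (degenerate for point
    predictors), correctness, and optional bookkeeping fields."""

    p_lower: float
    p_upper: float
    correct: bool
    sample_id: str = ""
    true_label: object = None
    predicted_label: object = None
    step: int = -1

    def __post_init__(self):
        if not (0.0 <= self.p_lower <= self.p_upper <= 1.0):
            raise InvalidInputError("record must satisfy 0 <= p_lower <= p_upper <= 1")

    @classmethod
    def point(cls, p: float, correct: bool, **kw) -> "PredictionRecord":
        return cls(p_lower=p, p_upper=p, correct=correct, **kw)

    @property
    def is_interval(self) -> bool:
        return self.p_upper > self.p_lower


def log_loss(p: float, q) -> float:
    """−ln p if the prediction was correct (q=1), −ln(1−p) otherwise.

    Returns ``+inf`` at the degenerate endpoints (p=0 with q=1, or
    p=1 with q=0): a categorical claim that turned out wrong.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("p must lie in [0, 1]")
    if q:
        return -math.log(p) if p > 0.0 else math.inf
    return -math.log1p(-p) if p < 1.0 else math.inf


def square_loss(p: float, q) -> float:
    """Squared difference between reported probability and outcome, (p − q)²."""
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("p must lie in [0, 1]")
    return (p - float(bool(q))) ** 2


def minimax_log(p_l: float, p_u: float) -> float:
    """Minimax point probability of an interval under log loss:
    ``p = p_u / (1 − p_l + p_u)``.  Always lies within [p_l, p_u]."""
    _check_interval(p_l, p_u)
    return p_u / (1.0 - p_l + p_u)


def minimax_square(p_l: float, p_u: float) -> float:
    """Minimax point probability of an interval under square loss:
    ``p = p_u + p_l²/2 − p_u²/2``.  Always lies within [p_l, p_u]."""
    _check_interval(p_l, p_u)
    return p_u + 0.5 * p_l * p_l - 0.5 * p_u * p_u


def _check_interval(p_l: float, p_u: float) -> None:
    if not (0.0 <= p_l <= p_u <= 1.0):
        raise InvalidInputError("interval must satisfy 0 <= p_l <= p_u <= 1")


def mean_losses(records) -> tuple[float, float]:
    """Mean log error d_ln and root-mean-square error d_sq.

    Interval records are collapsed with the minimax conversion matched
    to each loss (log-minimax for d_ln, square-minimax for d_sq); point
    records pass through unchanged.  Any infinite log loss makes d_ln
    infinite.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("need at least one prediction record")
    lnlosses = [log_loss(minimax_log(r.p_lower, r.p_upper), r.correct) for r in records]
    sqlosses = [square_loss(minimax_square(r.p_lower, r.p_upper), r.correct)
                for r in records]
    d_ln = sum(lnlosses) / len(records)
    d_sq = math.sqrt(sum(sqlosses) / len(records))
    return d_ln, d_sq


@dataclass
class ValidityReport:
    """Validity criteria plus the cumulative series behind them."""

    d_ln: float
    d_sq: float
    d1: float
    d11: float
    d12: float
    cp_lower: np.ndarray = field(repr=False)
    cp_upper: np.ndarray = field(repr=False)
    cn: np.ndarray = field(repr=False)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "d_ln": self.d_ln, "d_sq": self.d_sq,
            "d1": self.d1, "d11": self.d11, "d12": self.d12,
            "n": self.n,
            "cp_lower": self.cp_lower.tolist(),
            "cp_upper": self.cp_upper.tolist(),
            "cn": self.cn.tolist(),
        }


def cumulative_validity(records) -> ValidityReport:
    """Cumulative calibration series and the d1 criterion.

    Records must be in test order.  Returns the running sums of the
    lower bounds (CP_lower), upper bounds (CP_upper) and correct
    predictions (CN), plus d11 = |CN/N − ΣP_l/N|, d12 = |CN/N − ΣP_u/N|
    and d1 = max(d11, d12); for point predictors the three d's
    coincide with |CN/N − ΣP/N|.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("need at least one prediction record")
    pl = np.array([r.p_lower for r in records])
    pu = np.array([r.p_upper for r in records])
    q = np.array([bool(r.correct) for r in records], dtype=float)
    cp_lower = np.cumsum(pl)
    cp_upper = np.cumsum(pu)
    cn = np.cumsum(q)
    N = len(records)
    d11 = abs(cn[-1] / N - cp_lower[-1] / N)
    d12 = abs(cn[-1] / N - cp_upper[-1] / N)
    d_ln, d_sq = mean_losses(records)
    return ValidityReport(d_ln=d_ln, d_sq=d_sq, d1=max(d11, d12),
                          d11=d11, d12=d12,
                          cp_lower=cp_lower, cp_upper=cp_upper, cn=cn, n=N)


# evaluate_records is the one-stop entry point used by the protocols
evaluate_records = cumulative_validity


def plot_cumulative_validity(report: ValidityReport, path, title: str = ""):
    """Plot CN against the cumulative probability bounds and save to ``path``.

    For point predictors the two bounds coincide and a single CP curve
    is drawn.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = np.arange(1, report.n + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(steps, report.cn, label="cumulative correct (CN)", color="k")
    if np.allclose(report.cp_lower, report.cp_upper):
        ax.plot(steps, report.cp_upper, label="cumulative probability (CP)",
                color="tab:blue")
    else:
        ax.plot(steps, report.cp_lower, label="cumulative lower bound", color="tab:blue")
        ax.plot(steps, report.cp_upper, label="cumulative upper bound", color="tab:red")
    ax.set_xlabel("prediction number")
    ax.set_ylabel("cumulative count / probability")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
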