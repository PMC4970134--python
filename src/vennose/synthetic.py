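"""Synthetic multi-class data generators.

Two levels of synthesis:

* :func:`generate_recordings` — raw sensor-array transients that mimic
  a headspace measurement cycle: a flat baseline, a saturating-
  exponential rise while the analyte is present, and an exponential
  recovery once clean air returns, with additive Gaussian read noise
  and per-sample amplitude jitter.  Class identity lives in the
  pattern of per-sensor response amplitudes and time constants.
  Defaults emulate a 16-sensor array measuring 9 sample categories, 35
  samples each, 340 s recorded at 2 Hz with a 20 s pre-injection
  baseline and a 180 s response phase.

* :func:`generate_feature_table` — class-conditional spherical
  Gaussian feature vectors, drawn i.i.d. within class.  Much cheaper,
  with a Bayes error controllable through the mean separation; used
  for calibration and validity experiments where the sensor physics is
  irrelevant.

Both are driven by a single seeded generator per call, so outputs are
reproducible bit-for-bit; within-class draws are i.i.d., which is
exactly the exchangeability assumption the Venn machine's validity
guarantee rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset
from .errors import InvalidInputError
from .signal_features import SensorRecording

__all__ = [
    "SyntheticRecordingSpec",
    "generate_recordings",
    "generate_feature_table",
    "default_class_means",
]


@dataclass
class SyntheticRecordingSpec:
    """Parameters of the simulated measurement campaign.

    Per-class, per-sensor response amplitudes (volts) and rise/decay
    time constants (seconds) are drawn once from ``seed`` unless
    supplied explicitly via ``amplitudes`` / ``rise_tau`` / ``decay_tau``
    (each of shape (n_classes, n_sensors)).
    """

    n_classes: int = 9
    n_sensors: int = 16
    samples_per_class: int = 35
    sampling_rate: float = 2.0        # Hz
    duration: float = 340.0           # s, total recorded span
    baseline_seconds: float = 20.0    # pre-injection segment
    response_seconds: float = 180.0   # analyte exposure
    baseline_level: float = 0.5       # V, clean-air output
    amplitude_range: tuple = (0.5, 4.0)   # V
    rise_tau_range: tuple = (5.0, 35.0)   # s
    decay_tau_range: tuple = (20.0, 80.0)  # s
    noise_sd: float = 0.02            # V, additive white read noise
    amplitude_jitter_sd: float = 0.05  # lognormal sd of per-sample gain
    seed: int = 0
    amplitudes: np.ndarray | None = field(default=None, repr=False)
    rise_tau: np.ndarray | None = field(default=None, repr=False)
    decay_tau: np.ndarray | None = field(default=None, repr=False)
    class_labels: tuple | None = None

    def __post_init__(self):
        for name in ("n_classes", "n_sensors", "samples_per_class"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")
        for name in ("sampling_rate", "duration", "baseline_seconds",
                     "response_seconds"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.baseline_seconds + self.response_seconds > self.duration:
            raise InvalidInputError("baseline + response must fit within duration")
        if self.noise_sd < 0 or self.amplitude_jitter_sd < 0:
            raise InvalidInputError("noise levels must be >= 0")
        if self.class_labels is None:
            self.class_labels = tuple(f"class_{k+1}" for k in range(self.n_classes))
        elif len(self.class_labels) != self.n_classes:
            raise InvalidInputError("one label per class required")

    def resolved_parameters(self, rng: np.random.Generator):
        shape = (self.n_classes, self.n_sensors)

        def draw(value, lohi):
            if value is not None:
                arr = np.asarray(value, dtype=float)
                if arr.shape != shape:
                    raise InvalidInputError(f"parameter array must have shape {shape}")
                return arr
            lo, hi = lohi
            return rng.uniform(lo, hi, size=shape)

        amp = draw(self.amplitudes, self.amplitude_range)
        rise = draw(self.rise_tau, self.rise_tau_range)
        decay = draw(self.decay_tau, self.decay_tau_range)
        return amp, rise, decay


def generate_recordings(spec: SyntheticRecordingSpec) -> list[SensorRecording]:
    """Simulate labelled sensor-array recordings, i.i.d. within class.

    Each trace is ``baseline + gain·A·r(t) + noise`` where r(t) is 0
    during the baseline, ``1 − exp(−(t−t0)/τ_rise)`` during the
    response phase and an exponential recovery afterwards; ``gain`` is
    a per-sample lognormal jitter shared across sensors (drift of the
    sample's volatile load), and ``noise`` is white Gaussian.
    """
    rng = np.random.default_rng(spec.seed)
    amp, rise, decay = spec.resolved_parameters(rng)
    t = np.arange(int(round(spec.duration * spec.sampling_rate)) + 1) / spec.sampling_rate
    t0 = spec.baseline_seconds
    t1 = spec.baseline_seconds + spec.response_seconds
    recordings = []
    for k, label in enumerate(spec.class_labels):
        for m in range(spec.samples_per_class):
            gain = rng.lognormal(mean=0.0, sigma=spec.amplitude_jitter_sd)
            traces = np.empty((t.size, spec.n_sensors))
            for s in range(spec.n_sensors):
                r = np.zeros_like(t)
                in_resp = (t >= t0) & (t < t1)
                r[in_resp] = 1.0 - np.exp(-(t[in_resp] - t0) / rise[k, s])
                peak = 1.0 - np.exp(-spec.response_seconds / rise[k, s])
                after = t >= t1
                r[after] = peak * np.exp(-(t[after] - t1) / decay[k, s])
                traces[:, s] = (spec.baseline_level + gain * amp[k, s] * r
                                + rng.normal(0.0, spec.noise_sd, size=t.size))
            recordings.append(SensorRecording(
                readings=traces,
                sampling_rate=spec.sampling_rate,
                baseline_window=(0, int(round(t0 * spec.sampling_rate))),
                sample_id=f"{label}_{m}",
                label=label,
            ))
    return recordings


def default_class_means(K: int, dims: int, separation: float) -> np.ndarray:
    """Well-spread class means: scaled one-hot directions (cycled when
    K > dims), pairwise distance ``separation·√2`` for distinct axes."""
    means = np.zeros((K, dims))
    for k in range(K):
        means[k, k % dims] = separation * (1 + k // dims)
    return means


def generate_feature_table(n_per_class, class_means, cov_scale: float = 1.0,
                           seed: int = 0, labels=None) -> Dataset:
    """Draw a labelled Gaussian-mixture feature dataset.

    Parameters
    ----------
    n_per_class : int or sequence of int
        Samples per class (scalar applies to every class).
    class_means : (K, d) array
        Class-conditional means.
    cov_scale : float
        Standard deviation of the shared spherical covariance.
    seed : int
    labels : optional sequence of K labels (default ``class_1..K``).

    The Bayes error is a closed-form function of the pairwise mean
    distances and ``cov_scale``, which makes the generator usable as a
    calibration ground truth.
    """
    class_means = np.atleast_2d(np.asarray(class_means, dtype=float))
    K, d = class_means.shape
    if labels is None:
        labels = tuple(f"class_{k+1}" for k in range(K))
    else:
        labels = tuple(labels)
        if len(labels) != K:
            raise InvalidInputError("one label per class mean required")
    if np.isscalar(n_per_class):
        counts = [int(n_per_class)] * K
    else:
        counts = [int(c) for c in n_per_class]
        if len(counts) != K:
            raise InvalidInputError("one count per class required")
    if min(counts) < 1:
        raise InvalidInputError("each class needs at least one sample")
    if not cov_scale > 0:
        raise InvalidInputError("cov_scale must be positive")

    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, cov_scale, size=(c, d)) + class_means[k]
                   for k, c in enumerate(counts)])
    y = np.concatenate([[labels[k]] * c for k, c in enumerate(counts)])
    # i.i.d. sampling means the order carries no information, but shuffle
    # anyway so sequential protocols never see class blocks
    order = rng.permutation(X.shape[0])
    return Dataset(X[order], y[order], labels)
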