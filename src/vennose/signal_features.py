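"""Feature extraction from metal-oxide gas-sensor array transients.

A measurement is a matrix of voltage readings, one column per sensor,
sampled uniformly.  Each sensor trace is first calibrated by
subtracting its baseline (the mean over a pre-injection window), then
summarised by eight features:

1. ``vmax`` — maximal absolute response, max_t |V(t)| (steady feature);
2. ``vint`` — area under the response curve, ∫ V(t) dt by the
   trapezoid rule (steady feature);
3-8. min and max of the exponential moving average (EMA) of the
   discrete derivative, for smoothing factors a = 1/(100·SR),
   1/(10·SR), 1/SR where SR is the sampling rate — six transient
   features capturing rise/decay dynamics.

With an S-sensor array this yields S × 8 features per sample (128 for
the 16-sensor array the defaults emulate).  Feature columns are
min-max scaled to [0, 1] with statistics fit on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "SensorRecording",
    "FeatureVector",
    "FeatureScaler",
    "calibrate",
    "feature_vmax",
    "feature_vint",
    "ema_derivative_features",
    "extract_features",
    "feature_names",
    "features_dataframe",
    "fit_scaler",
    "apply_scaler",
    "EMA_DIVISORS",
]

#: the EMA smoothing factors are 1/(divisor × SR) for these divisors
EMA_DIVISORS = (100.0, 10.0, 1.0)

_PER_SENSOR = ("vmax", "vint", "ema100_min", "ema100_max",
               "ema10_min", "ema10_max", "ema1_min", "ema1_max")


@dataclass
class SensorRecording:
    """One measurement: a time × sensor voltage matrix.

    Parameters
    ----------
    readings : ndarray (n_steps, n_sensors)
        Raw voltages V_s, one column per sensor.
    sampling_rate : float
        Samples per second (> 0).
    baseline_window : (start, stop)
        Half-open index range used to estimate the baseline V_o per
        sensor.  Defaults to the first 20 seconds of the trace.
    sample_id : str
    label : optional class label
    sensor_names : optional sequence of column names
    """

    readings: np.ndarray
    sampling_rate: float
    baseline_window: tuple[int, int] | None = None
    sample_id: str = ""
    label: object = None
    sensor_names: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 2 or self.readings.shape[0] < 2 or self.readings.shape[1] < 1:
            raise InvalidInputError("readings must be (>=2 time steps, >=1 sensors)")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")
        if self.baseline_window is None:
            stop = min(self.readings.shape[0], max(1, int(round(20.0 * self.sampling_rate))))
            self.baseline_window = (0, stop)
        start, stop = self.baseline_window
        if not (0 <= start < stop <= self.readings.shape[0]):
            raise InvalidInputError(
                f"baseline_window {self.baseline_window} invalid for "
                f"{self.readings.shape[0]} time steps")
        if self.sensor_names is None:
            self.sensor_names = tuple(f"sensor_{i+1}" for i in range(self.n_sensors))
        else:
            self.sensor_names = tuple(self.sensor_names)
            if len(self.sensor_names) != self.n_sensors:
                raise InvalidInputError("one sensor name per column required")

    @property
    def n_steps(self) -> int:
        return self.readings.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.readings.shape[1]

    @property
    def duration(self) -> float:
        """Total measurement time spanned by the trace, in seconds."""
        return (self.n_steps - 1) / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) / self.sampling_rate


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with stable, deterministic names."""

    values: np.ndarray
    names: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise InvalidInputError("one name per feature value required")


def calibrate(recording: SensorRecording) -> np.ndarray:
    """Baseline-corrected signal V = V_s − V_o, per sensor.

    V_o is each sensor's mean reading over the baseline window, so a
    constant offset present during the baseline is removed entirely.
    """
    start, stop = recording.baseline_window
    v_o = recording.readings[start:stop].mean(axis=0)
    return recording.readings - v_o


def feature_vmax(v: np.ndarray) -> float:
    """Maximal absolute response max_t |V(t)| of one sensor trace."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty signal")
    return float(np.max(np.abs(v)))


def feature_vint(v: np.ndarray, dt: float) -> float:
    """Area under the response curve, trapezoid approximation of ∫V(t)dt."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty signal")
    if not dt > 0:
        raise InvalidInputError("dt must be positive")
    return float(np.trapezoid(v, dx=dt))


def _ema_derivative(v: np.ndarray, a: float) -> np.ndarray:
    """EMA of the discrete derivative: y(1)=a·V(1),
    y(k)=(1−a)·y(k−1)+a·(V(k)−V(k−1))."""
    y = np.empty(v.size)
    y[0] = a * v[0]
    dv = np.diff(v)
    for k in range(1, v.size):
        y[k] = (1.0 - a) * y[k - 1] + a * dv[k - 1]
    return y


def ema_derivative_features(v: np.ndarray, sampling_rate: float,
                            divisors=EMA_DIVISORS) -> np.ndarray:
    """Six transient features: (min, max) of the EMA-of-derivative for
    each smoothing factor a = 1/(divisor × SR), in divisor order."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise InvalidInputError("need at least 2 time steps")
    if not sampling_rate > 0:
        raise InvalidInputError("sampling_rate must be positive")
    out = []
    for div in divisors:
        a = 1.0 / (div * sampling_rate)
        if not 0.0 < a <= 1.0:
            raise InvalidInputError(
                f"smoothing factor a=1/({div}×SR)={a:g} outside (0, 1]")
        y = _ema_derivative(v, a)
        out.extend((float(y.min()), float(y.max())))
    return np.array(out)


def feature_names(sensor_names) -> tuple:
    """Deterministic (sensor, feature) names, sensor-major order."""
    return tuple(f"{s}_{f}" for s in sensor_names for f in _PER_SENSOR)


def extract_features(recording: SensorRecording,
                     divisors=EMA_DIVISORS) -> FeatureVector:
    """Full feature vector of a recording: per sensor,
    [vmax, vint, six EMA features] — 8 × n_sensors values."""
    V = calibrate(recording)
    dt = 1.0 / recording.sampling_rate
    values = []
    for s in range(recording.n_sensors):
        v = V[:, s]
        values.append(feature_vmax(v))
        values.append(feature_vint(v, dt))
        values.extend(ema_derivative_features(v, recording.sampling_rate, divisors))
    return FeatureVector(np.array(values), feature_names(recording.sensor_names))


def features_dataframe(recordings, divisors=EMA_DIVISORS) -> pd.DataFrame:
    """Feature table for a collection of recordings (rows = samples).

    Includes a ``label`` column when any recording is labelled.  All
    recordings must share the sensor layout.
    """
    recordings = list(recordings)
    if not recordings:
        raise InvalidInputError("no recordings given")
    rows, names = [], None
    for rec in recordings:
        fv = extract_features(rec, divisors)
        if names is None:
            names = fv.names
        elif fv.names != names:
            raise InvalidInputError(
                f"recording {rec.sample_id!r} has a different sensor layout")
        rows.append(fv.values)
    df = pd.DataFrame(np.vstack(rows), columns=list(names),
                      index=[rec.sample_id for rec in recordings])
    if any(rec.label is not None for rec in recordings):
        df["label"] = [rec.label for rec in recordings]
    return df


# ---------------------------------------------------------------------------
# Min-max scaling
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature min-max scaling, (x − min)/(max − min), with
    statistics from the training set only.

    Training values map exactly onto [0, 1]; test values are clipped to
    [0, 1]; constant training columns map to 0 everywhere.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise InvalidInputError("need a 2-D table with at least one row")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.mins) / safe
        out = np.where(span > 0, out, 0.0)
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mins=np.asarray(d["mins"], dtype=float),
                   maxs=np.asarray(d["maxs"], dtype=float))


def fit_scaler(X) -> FeatureScaler:
    """Fit per-feature min/max on a training feature table."""
    return FeatureScaler.fit(X)


def apply_scaler(X, scaler: FeatureScaler) -> np.ndarray:
    """Scale a feature table with a fitted scaler (clipping to [0, 1])."""
    return scaler.transform(X)
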