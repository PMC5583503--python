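"""The 17-descriptor feature bank over the 18 signals (306 features).

Each repetition epoch is summarized per channel by time-domain moments
and order statistics, a signal-energy term, the mean-level crossing
rate, the Higuchi fractal dimension, and the variances of the
approximation and pooled detail coefficients of a Daubechies-5 discrete
wavelet decomposition to level 7.  Feature names are
``"<channel>__<descriptor>"`` in a fixed deterministic order.

Conventions (all documented because they matter for reproducibility):
variance and SD use the population denominator N; skewness and kurtosis
are moment-based, kurtosis as Fisher excess, both defined as 0 for a
constant epoch; energy is the sum of squares; percentiles interpolate
linearly; the crossing level is the epoch mean; the Higuchi estimate
uses kmax = 10; epochs too short for a level-7 decomposition use the
deepest feasible level (recorded in the vector's metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .preprocess import SIGNAL_NAMES
from .segment import Repetition

__all__ = [
    "DESCRIPTOR_NAMES",
    "FEATURE_NAMES",
    "FeatureVector",
    "descriptor",
    "higuchi_fd",
    "level_crossing_rate",
    "wavelet_variances",
    "compute_feature_vector",
    "build_feature_matrix",
]

#: the fixed 17-descriptor order
DESCRIPTOR_NAMES = (
    "mean", "rms", "std", "kurtosis", "median", "skewness", "range",
    "variance", "max", "min", "energy", "p25", "p75",
    "level_crossing_rate", "fractal_dimension",
    "wavelet_approx_var", "wavelet_detail_var",
)

#: the fixed 306-name feature order: channels x descriptors
FEATURE_NAMES = tuple(
    f"{channel}__{desc}" for channel in SIGNAL_NAMES for desc in DESCRIPTOR_NAMES
)

WAVELET = "db5"
WAVELET_LEVEL = 7
HIGUCHI_KMAX = 10


def level_crossing_rate(x: np.ndarray) -> float:
    """Sign changes of (x - mean(x)) per sample transition: count / (N - 1)."""
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    return float(np.count_nonzero(d[:-1] * d[1:] < 0) / (len(x) - 1))


def higuchi_fd(x: np.ndarray, kmax: int = HIGUCHI_KMAX) -> float:
    """Higuchi fractal dimension of a time series.

    Curve lengths ``L(k)`` are averaged over the k decimated sub-series
    for each delay ``k = 1..kmax`` and the dimension is the slope of
    ``log L(k)`` against ``log (1/k)``.  A straight line scores ~1 and
    white noise ~2.  A constant sequence (zero curve length) returns 1.0,
    the dimension of its degenerate graph.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        return 1.0
    kmax = min(kmax, (n - 1) // 2)
    ks, lengths = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lm.append(dist * norm / k)
        if lm:
            ks.append(k)
            lengths.append(np.mean(lm))
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        return 1.0
    slope = np.polyfit(np.log(1.0 / np.asarray(ks, dtype=float)), np.log(lengths), 1)[0]
    return float(slope)


def wavelet_variances(x: np.ndarray) -> tuple[float, float]:
    """Variances of DWT approximation and pooled detail coefficients.

    Daubechies-5 mother wavelet, symmetric extension, decomposed to level
    7 (or the deepest level the epoch length supports).  The first value
    is the population variance of the final approximation coefficients,
    the second that of all detail coefficients, levels 1..7 concatenated.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("wavelet descriptors need at least 2 samples")
    level = wavelet_depth(len(x))
    if level == 0:
        return float(np.var(x)), 0.0
    coeffs = pywt.wavedec(x, WAVELET, mode="symmetric", level=level)
    approx_var = float(np.var(coeffs[0]))
    details = np.concatenate(coeffs[1:])
    return approx_var, float(np.var(details))


def wavelet_depth(n: int) -> int:
    """Decomposition depth actually used for an epoch of length ``n``."""
    return min(WAVELET_LEVEL, pywt.dwt_max_level(n, pywt.Wavelet(WAVELET).dec_len))


def descriptor(name: str, x: np.ndarray) -> float:
    """One named descriptor of an epoch signal.

    Skewness and kurtosis of a (numerically) constant signal are defined
    as 0 rather than NaN so downstream feature matrices stay finite.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("descriptors need at least 2 samples")
    if name == "mean":
        return float(np.mean(x))
    if name == "rms":
        return float(np.sqrt(np.mean(x * x)))
    if name == "std":
        return float(np.std(x))
    if name == "kurtosis":
        return 0.0 if np.var(x) == 0 else float(stats.kurtosis(x, fisher=True, bias=True))
    if name == "median":
        return float(np.median(x))
    if name == "skewness":
        return 0.0 if np.var(x) == 0 else float(stats.skew(x, bias=True))
    if name == "range":
        return float(np.max(x) - np.min(x))
    if name == "variance":
        return float(np.var(x))
    if name == "max":
        return float(np.max(x))
    if name == "min":
        return float(np.min(x))
    if name == "energy":
        return float(np.sum(x * x))
    if name == "p25":
        return float(np.percentile(x, 25))
    if name == "p75":
        return float(np.percentile(x, 75))
    if name == "level_crossing_rate":
        return level_crossing_rate(x)
    if name == "fractal_dimension":
        return higuchi_fd(x)
    if name == "wavelet_approx_var":
        return wavelet_variances(x)[0]
    if name == "wavelet_detail_var":
        return wavelet_variances(x)[1]
    raise ValueError(f"unknown descriptor {name!r}")


@dataclass
class FeatureVector:
    """306 named descriptors of one repetition."""

    values: np.ndarray
    rep_key: tuple[str, str, int]
    names: tuple[str, ...] = FEATURE_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} values, got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=str(self.rep_key))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def compute_feature_vector(rep: Repetition) -> FeatureVector:
    """The full 306-dimensional feature vector of one repetition.

    A pure function of the epoch: channels in the fixed 18-name order,
    descriptors in the fixed 17-name order.  Raises for epochs shorter
    than 2 samples; all values are finite for epochs of length >= 16.
    """
    if len(rep.signals) < 2:
        raise ValueError("cannot compute features on an epoch shorter than 2 samples")
    values = np.empty(len(FEATURE_NAMES))
    i = 0
    for channel in SIGNAL_NAMES:
        x = np.asarray(rep.signals[channel], dtype=float)
        # the two wavelet descriptors share one decomposition
        approx_var, detail_var = wavelet_variances(x)
        for desc in DESCRIPTOR_NAMES:
            if desc == "wavelet_approx_var":
                values[i] = approx_var
            elif desc == "wavelet_detail_var":
                values[i] = detail_var
            else:
                values[i] = descriptor(desc, x)
            i += 1
    return FeatureVector(
        values=values,
        rep_key=rep.key,
        meta={"wavelet_depth": wavelet_depth(len(rep.signals)), "label": rep.label},
    )


def build_feature_matrix(db, exercise: str):
    """Feature matrix for one exercise: (n_reps x 306), labels, keys.

    Rows follow the database key order; the label vector is aligned.
    Raises ``KeyError`` when the database holds no repetitions of the
    exercise.
    """
    keys = [k for k in db.keys() if k[1] == exercise]
    if not keys:
        raise KeyError(f"no repetitions of exercise {exercise!r} in database")
    rows = [compute_feature_vector(db.get(key)).values for key in keys]
    labels = [db.get(key).label for key in keys]
    return np.vstack(rows), labels, keys
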