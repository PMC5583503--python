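"""Independent literal-definition oracles used only by the test suite.

Everything here is written directly from the defining formula — explicit
loops and sums, no reuse of the package's implementation — so that
agreement with the implementation is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pywt  # only for the db5 filter taps, which are published constants


def oracle_mean(x):
    return sum(x) / len(x)


def oracle_rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def oracle_variance(x):
    m = oracle_mean(x)
    return sum((v - m) ** 2 for v in x) / len(x)


def oracle_std(x):
    return math.sqrt(oracle_variance(x))


def oracle_skewness(x):
    m = oracle_mean(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    if m2 == 0:
        return 0.0
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return m3 / m2**1.5


def oracle_kurtosis(x):
    """Fisher (excess) kurtosis, population moments."""
    m = oracle_mean(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    if m2 == 0:
        return 0.0
    m4 = sum((v - m) ** 4 for v in x) / len(x)
    return m4 / m2**2 - 3.0


def oracle_median(x):
    s = sorted(x)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def oracle_percentile(x, p):
    """Linear interpolation between order statistics."""
    s = sorted(x)
    h = (len(s) - 1) * p / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def oracle_range(x):
    return max(x) - min(x)


def oracle_energy(x):
    return sum(v * v for v in x)


def oracle_level_crossing_rate(x):
    m = oracle_mean(x)
    d = [v - m for v in x]
    crossings = sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0)
    return crossings / (len(x) - 1)


def oracle_higuchi_fd(x, kmax=10):
    """Higuchi curve-length estimator, written from the definition."""
    x = list(x)
    n = len(x)
    kmax = min(kmax, (n - 1) // 2)
    log_inv_k, log_l = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            n_seg = (n - 1 - m) // k
            if n_seg < 1:
                continue
            dist = sum(abs(x[m + i * k] - x[m + (i - 1) * k]) for i in range(1, n_seg + 1))
            lengths.append(dist * (n - 1) / (n_seg * k) / k)
        if lengths:
            log_inv_k.append(math.log(1.0 / k))
            log_l.append(math.log(sum(lengths) / len(lengths)))
    # least-squares slope
    mx = sum(log_inv_k) / len(log_inv_k)
    my = sum(log_l) / len(log_l)
    num = sum((a - mx) * (b - my) for a, b in zip(log_inv_k, log_l))
    den = sum((a - mx) ** 2 for a in log_inv_k)
    return num / den


def _dwt_step_literal(x, taps):
    """One analysis-filter DWT step: half-sample symmetric extension,
    full convolution, downsample by 2 starting at the filter length."""
    x = np.asarray(x, dtype=float)
    f = len(taps)
    ext = np.array(
        [_reflect_index(x, i) for i in range(-(f - 1), len(x) + f - 1)], dtype=float
    )
    full = np.convolve(ext, taps, mode="full")
    n_out = (len(x) + f - 1) // 2
    return full[f::2][:n_out]


def _reflect_index(x, i):
    """Half-sample symmetric index: ...x1 x0 | x0 x1 ... xN-1 | xN-1 xN-2..."""
    n = len(x)
    period = 2 * n
    i = i % period
    return x[i] if i < n else x[period - 1 - i]


def oracle_wavelet_variances(x, level=7):
    """Literal pyramid: recursive low-pass/high-pass filtering with the
    published Daubechies-5 taps, then population variances of the final
    approximation and pooled detail coefficients."""
    wav = pywt.Wavelet("db5")
    lo = np.asarray(wav.dec_lo)
    hi = np.asarray(wav.dec_hi)
    # deepest level with len(x) >= (filter_len - 1) * 2^level
    max_level = 0
    while (len(lo) - 1) * 2 ** (max_level + 1) <= len(x):
        max_level += 1
    level = min(level, max_level)
    approx = np.asarray(x, dtype=float)
    details = []
    for _ in range(level):
        details.append(_dwt_step_literal(approx, hi))
        approx = _dwt_step_literal(approx, lo)
    if not details:
        return oracle_variance(list(approx)), 0.0
    pooled = np.concatenate(details)
    return oracle_variance(list(approx)), oracle_variance(list(pooled))


ORACLES = {
    "mean": oracle_mean,
    "rms": oracle_rms,
    "std": oracle_std,
    "kurtosis": oracle_kurtosis,
    "median": oracle_median,
    "skewness": oracle_skewness,
    "range": oracle_range,
    "variance": oracle_variance,
    "max": max,
    "min": min,
    "energy": oracle_energy,
    "p25": lambda x: oracle_percentile(x, 25),
    "p75": lambda x: oracle_percentile(x, 75),
    "level_crossing_rate": oracle_level_crossing_rate,
    "fractal_dimension": oracle_higuchi_fd,
    "wavelet_approx_var": lambda x: oracle_wavelet_variances(x)[0],
    "wavelet_detail_var": lambda x: oracle_wavelet_variances(x)[1],
}


def oracle_confusion(truth, predicted, positive="Acceptable"):
    """Four-branch literal counting."""
    tp = fn = tn = fp = 0
    for t, p in zip(truth, predicted):
        if t == positive and p == positive:
            tp += 1
        elif t == positive and p != positive:
            fn += 1
        elif t != positive and p != positive:
            tn += 1
        else:
            fp += 1
    return tp, fn, tn, fp
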