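"""Higuchi temporal fractal dimension of one-dimensional signals.

For a series ``x_1..x_N`` and a coarse-graining interval ``k``, Higuchi's
method forms the k subsampled series starting at offsets ``m = 1..k`` and
measures each one's normalized curve length

    L_m(k) = [ sum_i |x_{m+ik} - x_{m+(i-1)k}| * (N-1) / (floor((N-m)/k) k) ] / k.

The mean length ``<L(k)>`` over offsets scales as ``k^(-D)`` for a fractal
signal; ``D`` is minus the OLS slope of ``ln <L(k)>`` on ``ln k``. All
integers ``k = 1..k_max`` are used (k_max = 64 by default). For fractional
Brownian motion with Hurst exponent H the expected dimension is ``2 - H``;
a straight line gives exactly 1, white noise approaches 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

from fractalconn.exceptions import DegenerateSignalError

__all__ = [
    "HiguchiResult",
    "analytic_signal_magnitude",
    "higuchi_curve_lengths",
    "higuchi_fd",
    "truncate_series",
    "roi_higuchi_table",
]


@dataclass
class HiguchiResult:
    """Mean curve lengths per interval k and the log-log regression."""

    k_values: np.ndarray
    mean_lengths: np.ndarray
    slope_fit: tuple[float, float, float]  # slope, intercept, r_squared
    dimension: float
    k_max: int


def analytic_signal_magnitude(x: np.ndarray) -> np.ndarray:
    """Hilbert envelope: magnitude of the analytic signal.

    Offered as optional preprocessing of BOLD-like series; off by default
    throughout the pipeline.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    return np.abs(scipy.signal.hilbert(x))


def higuchi_curve_lengths(
    x: np.ndarray, k_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean normalized curve length <L(k)> for each k in 1..k_max.

    k values for which any offset series has no complete step
    (``floor((N-m)/k) = 0``) are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 4:
        raise ValueError("need at least 4 samples")
    ks, lengths = [], []
    dropped = []
    for k in range(1, k_max + 1):
        # worst offset is m = k: requires at least one full step of size k
        if (n - k) // k == 0:
            dropped.append(k)
            continue
        d = np.abs(x[k:] - x[:-k])  # d[j] = |x_{j+1+k} - x_{j+1}|, 0-based
        total = 0.0
        for m in range(1, k + 1):
            steps = (n - m) // k
            seg = d[m - 1 : m - 1 + steps * k : k]
            total += seg.sum() * (n - 1) / (steps * k) / k
        ks.append(k)
        lengths.append(total / k)
    if dropped:
        warnings.warn(
            f"dropped k values {dropped}: series too short for a full step",
            stacklevel=2,
        )
    return np.asarray(ks, dtype=int), np.asarray(lengths, dtype=float)


def higuchi_fd(x: np.ndarray, k_max: int = 64) -> HiguchiResult:
    """Higuchi fractal dimension: -slope of ln <L(k)> on ln k."""
    ks, lengths = higuchi_curve_lengths(x, k_max)
    if np.all(lengths == 0.0):
        raise DegenerateSignalError(
            "all curve lengths are zero (constant signal?)"
        )
    keep = lengths > 0.0
    if not keep.all():
        warnings.warn("dropping k values with zero curve length", stacklevel=2)
        ks, lengths = ks[keep], lengths[keep]
    if ks.size < 2:
        raise DegenerateSignalError("fewer than 2 usable k values")
    res = scipy.stats.linregress(np.log(ks), np.log(lengths))
    return HiguchiResult(
        k_values=ks,
        mean_lengths=lengths,
        slope_fit=(float(res.slope), float(res.intercept), float(res.rvalue) ** 2),
        dimension=-float(res.slope),
        k_max=k_max,
    )


def truncate_series(x: np.ndarray, n: int) -> np.ndarray:
    """First ``n`` samples of a series (length-matching control)."""
    x = np.asarray(x)
    if not 2 <= n <= x.size:
        raise ValueError(f"n must be in [2, {x.size}], got {n}")
    return x[:n].copy()


def roi_higuchi_table(
    samples: np.ndarray,
    roi_labels: list[str],
    k_max: int = 64,
    *,
    hilbert: bool = False,
    truncate: int | None = None,
) -> tuple[dict[str, float], float]:
    """Per-ROI Higuchi dimensions for a time x ROI array, plus their mean.

    The per-subject scalar is the mean over ROIs; the full per-ROI mapping
    is returned so other reductions remain possible.
    """
    samples = np.asarray(samples, dtype=float)
    per_roi = {}
    for j, label in enumerate(roi_labels):
        sig = samples[:, j]
        if truncate is not None:
            sig = truncate_series(sig, truncate)
        if hilbert:
            sig = analytic_signal_magnitude(sig)
        per_roi[label] = higuchi_fd(sig, k_max=k_max).dimension
    return per_roi, float(np.mean(list(per_roi.values())))
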