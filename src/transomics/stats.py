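"""Exact small-sample correlation statistics.

Everything the screening and mediation stages need with 3-6 samples per
factor pair: the product-moment coefficient on pairwise-complete values,
the t transform t = |r| sqrt(n-2) / sqrt(1 - r^2), inversion of the
two-sided Student quantile into a critical |r|, the first-order partial
correlation, and Dixon's Q outlier test with published two-tailed critical
values.

With n = 6 samples (4 degrees of freedom) a two-sided alpha of 0.01
requires |r| >= 0.91719; with n = 4 (2 df) it requires |r| >= 0.99. These
thresholds fall straight out of :func:`critical_thresholds` and are the
backbone of the whole screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .exceptions import (
    CollinearControlError,
    DegenerateDataError,
    InsufficientOverlapError,
    PerfectCorrelationError,
)

__all__ = [
    "CorrelationResult",
    "PartialCorrelationResult",
    "DixonResult",
    "pearson_r",
    "t_from_r",
    "critical_thresholds",
    "partial_r",
    "partial_r_from_data",
    "dixon_q",
    "DIXON_Q_CRIT",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """One factor pair's correlation with its exact significance threshold.

    ``r_crit`` is the minimum |r| reaching the two-sided ``alpha`` at this
    pair's own degrees of freedom (``df = n - 2``); ``significant`` is
    simply ``|r| >= r_crit``. Threshold fields are ``None`` when no alpha
    was requested.
    """

    factor_a: str
    layer_a: str
    factor_b: str
    layer_b: str
    n: int
    df: int
    r: float
    t: float
    alpha: Optional[float] = None
    r_crit: Optional[float] = None
    significant: Optional[bool] = None


@dataclass(frozen=True)
class PartialCorrelationResult:
    """First-order partial correlation of x and y controlling z."""

    x: str
    y: str
    z: str
    r_xy: float
    r_xz: float
    r_yz: float
    r_partial: float


@dataclass(frozen=True)
class DixonResult:
    """Dixon's Q verdict for one factor's values across samples.

    ``q_low``/``q_high`` are the r10 gap/range ratios for the smallest and
    largest value; the larger of the two is compared against the critical
    value, so at most one sample is flagged per call.
    """

    factor: str
    layer: str
    n: int
    q_low: float
    q_high: float
    q_crit: float
    outlier_sample: str
    is_outlier: bool


# ---------------------------------------------------------------------------
# Pearson r and the t transform
# ---------------------------------------------------------------------------

def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask], mask


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alpha: Optional[float] = None,
    factor_a: str = "x",
    layer_a: str = "",
    factor_b: str = "y",
    layer_b: str = "",
) -> CorrelationResult:
    """Product-moment correlation on pairwise-complete values.

    Positions missing (NaN) in either vector are dropped; at least 3
    complete pairs and nonzero variance in both vectors are required.
    When ``alpha`` is given the per-pair critical |r| at ``df = n - 2``
    and the significance flag are filled in.
    """
    xv, yv, _ = _complete_pairs(x, y)
    n = xv.size
    if n < 3:
        raise InsufficientOverlapError(
            f"{factor_a} vs {factor_b}: only {n} complete pairs (need >= 3)"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError(
            f"{factor_a} vs {factor_b}: zero variance in one factor"
        )
    r = float(scipy.stats.pearsonr(xv, yv).statistic)
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        t = math.inf
    else:
        t = t_from_r(r, n)
    r_crit = significant = None
    if alpha is not None:
        _, r_crit = critical_thresholds(alpha, df)
        significant = abs(r) >= r_crit
    return CorrelationResult(
        factor_a=factor_a, layer_a=layer_a, factor_b=factor_b, layer_b=layer_b,
        n=n, df=df, r=r, t=t, alpha=alpha, r_crit=r_crit, significant=significant,
    )


def t_from_r(r: float, n: int) -> float:
    """t statistic of a correlation coefficient: |r| sqrt(n-2) / sqrt(1-r^2).

    Nonnegative and monotone increasing in |r| at fixed n. |r| = 1 raises
    :class:`PerfectCorrelationError` (the statistic is infinite); |r| > 1
    is invalid input.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        raise PerfectCorrelationError("|r| = 1: t statistic is infinite")
    return abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def critical_thresholds(alpha: float, df: int) -> tuple[float, float]:
    """Two-sided critical t and the corresponding critical |r|.

    ``t_crit`` is the upper alpha/2 Student quantile at ``df`` degrees of
    freedom; inverting the t transform gives
    ``r_crit = t_crit / sqrt(t_crit^2 + df)``. At alpha = 0.01, df = 4
    this yields t = 4.604, r = 0.91719 — the screen's headline threshold.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError(f"df must be a positive integer, got {df!r}")
    t_crit = float(scipy.stats.t.isf(alpha / 2.0, df))
    r_crit = t_crit / math.sqrt(t_crit * t_crit + df)
    return t_crit, r_crit


# ---------------------------------------------------------------------------
# first-order partial correlation
# ---------------------------------------------------------------------------

def partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y after removing z:

        r_xy.z = (r_xy - r_xz r_yz) / (sqrt(1 - r_xz^2) sqrt(1 - r_yz^2))

    Symmetric in x and y (swap r_xz and r_yz). |r_xz| = 1 or |r_yz| = 1
    means z is collinear with one of the variables and the partial is
    undefined.
    """
    for name, v in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if abs(v) > 1:
            raise ValueError(f"{name} must be in [-1, 1], got {v}")
    if abs(r_xz) == 1 or abs(r_yz) == 1:
        raise CollinearControlError("controlled variable collinear with x or y")
    out = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    # consistent triples land in [-1, 1] up to rounding; trim the overshoot
    if -1.0 - 1e-12 <= out <= 1.0 + 1e-12:
        out = min(1.0, max(-1.0, out))
    return out


def partial_r_from_data(x, y, z) -> float:
    """Partial correlation computed from raw vectors (triple-complete)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    xv, yv, zv = x[mask], y[mask], z[mask]
    if xv.size < 4:
        raise InsufficientOverlapError(
            f"only {xv.size} triple-complete samples (need >= 4)"
        )
    c = np.corrcoef(np.vstack([xv, yv, zv]))
    return partial_r(c[0, 1], c[0, 2], c[1, 2])


# ---------------------------------------------------------------------------
# Dixon's Q test (r10 variant)
# ---------------------------------------------------------------------------

# Rorabacher (1991) two-tailed critical values for Dixon's r10 statistic,
# n = 3..30, at the 90 / 95 / 99 % confidence levels.
DIXON_Q_CRIT: dict[float, dict[int, float]] = {
    0.90: {
        3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468,
        9: 0.437, 10: 0.412, 11: 0.392, 12: 0.376, 13: 0.361, 14: 0.349,
        15: 0.338, 16: 0.329, 17: 0.320, 18: 0.313, 19: 0.306, 20: 0.300,
        21: 0.295, 22: 0.290, 23: 0.285, 24: 0.281, 25: 0.277, 26: 0.273,
        27: 0.269, 28: 0.266, 29: 0.263, 30: 0.260,
    },
    0.95: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526,
        9: 0.493, 10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396,
        15: 0.384, 16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342,
        21: 0.337, 22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312,
        27: 0.308, 28: 0.305, 29: 0.301, 30: 0.298,
    },
    0.99: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634,
        9: 0.598, 10: 0.568, 11: 0.542, 12: 0.522, 13: 0.503, 14: 0.488,
        15: 0.475, 16: 0.463, 17: 0.452, 18: 0.442, 19: 0.433, 20: 0.425,
        21: 0.418, 22: 0.411, 23: 0.404, 24: 0.399, 25: 0.393, 26: 0.388,
        27: 0.384, 28: 0.380, 29: 0.376, 30: 0.372,
    },
}


def dixon_q(
    values,
    sample_ids: Optional[Sequence[str]] = None,
    confidence: float = 0.99,
    *,
    factor: str = "",
    layer: str = "",
) -> DixonResult:
    """Dixon's Q test (classic r10 gap/range statistic) on 3-30 values.

    ``values`` may be a pandas Series (index used as sample IDs) or an
    array with ``sample_ids`` alongside. Missing values are dropped first.
    Ties sort stably by value then sample ID; if q_low equals q_high the
    high side is the one tested.
    """
    import pandas as pd

    if isinstance(values, pd.Series):  # a Series carries its own sample ids
        ids = list(values.index)
        vals = values.to_numpy(dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [
            str(i) for i in range(vals.size)
        ]
    if confidence not in DIXON_Q_CRIT:
        raise ValueError(
            f"confidence must be one of {sorted(DIXON_Q_CRIT)}, got {confidence}"
        )
    keep = np.isfinite(vals)
    vals, ids = vals[keep], [s for s, k in zip(ids, keep) if k]
    n = vals.size
    table = DIXON_Q_CRIT[confidence]
    if n < 3 or n > max(table):
        raise InsufficientOverlapError(f"n out of range for Dixon table: {n}")
    order = sorted(range(n), key=lambda i: (vals[i], str(ids[i])))
    s = vals[order]
    rng = s[-1] - s[0]
    if rng <= 0:
        raise DegenerateDataError("degenerate values: zero range")
    q_high = float((s[-1] - s[-2]) / rng)
    q_low = float((s[1] - s[0]) / rng)
    q_crit = table[n]
    if q_high >= q_low:
        q_max, candidate = q_high, ids[order[-1]]
    else:
        q_max, candidate = q_low, ids[order[0]]
    is_outlier = q_max >= q_crit
    return DixonResult(
        factor=factor, layer=layer, n=n, q_low=q_low, q_high=q_high,
        q_crit=q_crit, outlier_sample=str(candidate) if is_outlier else "",
        is_outlier=is_outlier,
    )
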