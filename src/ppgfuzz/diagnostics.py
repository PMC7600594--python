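"""Stream diagnostics: rhythmicity, Hurst exponent, summary statistics, CCA.

Rhythmicity R = C/D is the fraction of distinct code-word patterns (C)
among all patterns (D); an ideal singleton output has C = 1.  The Hurst
exponent is estimated by rescaled-range (R/S) analysis over dyadic block
sizes with, by default, the Anis–Lloyd/Peters small-sample correction
(the uncorrected slope is biased toward 0.5 at the series lengths used
here).  ``summarize`` reproduces the per-stream statistic battery (moment
statistics, geometric/harmonic means, lag-1 Pearson autocorrelation,
sample and approximate entropy), and ``cca_first`` the first canonical
correlation between two subject-by-feature value matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats
from scipy.special import gammaln

from .features import approximate_entropy, sample_entropy


@dataclass(frozen=True)
class RhythmicityReport:
    C: int  # number of distinct patterns
    D: int  # total number of patterns
    R: float  # C / D


def rhythmicity(words: Sequence[str]) -> RhythmicityReport:
    """Distinct-pattern fraction of a sequence of code-word strings."""
    if len(words) == 0:
        raise ValueError("words is empty")
    c = len(set(words))
    d = len(words)
    return RhythmicityReport(c, d, c / d)


def _expected_rs(n: int) -> float:
    """E[R/S] of an i.i.d. series of length n (Anis–Lloyd, Peters factor)."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        front = np.exp(gammaln((n - 1) / 2) - gammaln(n / 2)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2)
    return ((n - 0.5) / n) * front * s


def hurst_exponent(
    values: np.ndarray, min_window: int = 8, corrected: bool = True
) -> float:
    """Rescaled-range Hurst estimate over dyadic window sizes.

    Windows run 8, 16, ... up to n/2; within each size the series is cut
    into non-overlapping blocks and R/S averaged over blocks.  With
    ``corrected`` (default) the log deviation from the i.i.d. expectation
    is regressed on log window size and 0.5 added back, removing the
    small-sample bias of the plain slope.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("need at least 64 values")
    if np.ptp(x) == 0:
        raise ValueError("R/S is undefined for a constant series")

    sizes = []
    w = min_window
    while w <= n // 2:
        sizes.append(w)
        w *= 2

    log_w, log_rs = [], []
    for w in sizes:
        k = n // w
        blocks = x[: k * w].reshape(k, w)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = blocks.std(axis=1, ddof=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = (r[ok] / s[ok]).mean()
        if rs <= 0:
            continue
        val = np.log2(rs)
        if corrected:
            val -= np.log2(_expected_rs(w))
        log_w.append(np.log2(w))
        log_rs.append(val)
    if len(log_w) < 2:
        raise ValueError("not enough usable window sizes for a slope")
    slope = np.polyfit(log_w, log_rs, 1)[0]
    return float(slope + 0.5) if corrected else float(slope)


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact fGn sample via Davies–Harte circulant embedding (unit variance)."""
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    k = np.arange(0, n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eigs = np.fft.fft(row).real
    if eigs.min() < -1e-8:
        raise ValueError("circulant embedding failed (negative eigenvalue)")
    eigs = np.clip(eigs, 0, None)
    m = row.size
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(np.sqrt(eigs / (2 * m)) * w)
    return f.real[:n] * np.sqrt(2)


@dataclass(frozen=True)
class StatSummary:
    """Statistic battery of one optimized value stream."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    geometric_mean: float
    harmonic_mean: float
    pearson_cc: float
    sample_entropy: float
    approximate_entropy: float


def summarize(values: np.ndarray) -> StatSummary:
    """Moment statistics, means, lag-1 autocorrelation, and entropies.

    ``pearson_cc`` is the Pearson correlation between the stream and its
    one-step lag; degenerate (constant) streams report 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    var = float(v.var(ddof=1))
    if var > 0:
        skew = float(sp_stats.skew(v, bias=True))
        kurt = float(sp_stats.kurtosis(v, fisher=False, bias=True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lagged slices may be constant
            pcc = float(np.corrcoef(v[:-1], v[1:])[0, 1])
        if not np.isfinite(pcc):
            pcc = 0.0
    else:
        skew = kurt = pcc = 0.0
    gm = float(sp_stats.gmean(v)) if (v > 0).all() else float("nan")
    hm = float(sp_stats.hmean(v)) if (v > 0).all() else float("nan")
    return StatSummary(
        mean=float(v.mean()),
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        geometric_mean=gm,
        harmonic_mean=hm,
        pearson_cc=pcc,
        sample_entropy=sample_entropy(v),
        approximate_entropy=approximate_entropy(v),
    )


def summaries_to_frame(
    summaries: "dict[tuple[str, str], StatSummary]",
) -> "pd.DataFrame":
    """Flatten {(class, optimizer): StatSummary} into a report table."""
    import pandas as pd

    rows = []
    for (label, optimizer), s in summaries.items():
        rows.append({"class": label, "optimizer": optimizer, **vars(s)})
    return pd.DataFrame(rows)


def cca_first(
    normal_matrix: np.ndarray,
    cvd_matrix: np.ndarray,
    ridge: float = 1e-6,
) -> float:
    """First canonical correlation between two subjects-by-features matrices.

    Rows are truncated to the common count and columns to the common
    dimension.  Covariance blocks are ridge-regularized (eps on the
    diagonal); a warning is emitted when the inputs are rank-deficient.
    """
    x = np.asarray(normal_matrix, dtype=float)
    y = np.asarray(cvd_matrix, dtype=float)
    n = min(x.shape[0], y.shape[0])
    d = min(x.shape[1], y.shape[1])
    if n < 2:
        raise ValueError("need at least 2 rows in each matrix")
    x = x[:n, :d] - x[:n, :d].mean(axis=0)
    y = y[:n, :d] - y[:n, :d].mean(axis=0)

    cxx = x.T @ x / (n - 1) + ridge * np.eye(d)
    cyy = y.T @ y / (n - 1) + ridge * np.eye(d)
    cxy = x.T @ y / (n - 1)
    for name, c in (("first", cxx), ("second", cyy)):
        if np.linalg.matrix_rank(c - ridge * np.eye(d)) < d:
            warnings.warn(
                f"{name} matrix is rank-deficient; ridge regularization applied",
                stacklevel=2,
            )
    m = np.linalg.solve(cxx, cxy) @ np.linalg.solve(cyy, cxy.T)
    eigs = np.linalg.eigvals(m).real
    rho2 = float(np.clip(eigs.max(), 0.0, 1.0))
    return float(np.sqrt(rho2))
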