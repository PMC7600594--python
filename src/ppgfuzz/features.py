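"""Segmentation and the eight per-segment PPG parameters.

Every record is cut into non-overlapping 2-second windows (200 samples at
100 Hz; any trailing remainder is dropped) and each window is summarized
by eight features: Energy, Variance, Approximate Entropy (ApEn), Mean,
Standard Deviation, Skewness, Kurtosis and Peak Maximum.

Conventions
-----------
* Energy is the raw sum of squared amplitudes over the window.
* Variance / standard deviation use the unbiased (n-1) sample form.
* Skewness and kurtosis are the moment-based sample statistics; kurtosis
  is plain (non-excess, so a Gaussian gives ~3).
* ApEn follows Pincus: embedding m=2, tolerance r = 0.2 x sample SD,
  Chebyshev distance, self-matches included.
* A constant window is degenerate: skewness, kurtosis and ApEn are
  defined as 0 there.

Raw features are mapped into the linguistic domains of the fuzzy engine
by a per-feature affine calibration (``DEFAULT_CALIBRATION``); see
``apply_calibration``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .synthetic import PPGRecord

FEATURE_NAMES = (
    "energy",
    "variance",
    "apen",
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "peak_max",
)


@dataclass(frozen=True)
class SegmentFeatures:
    """The eight parameters of one 2-second segment."""

    energy: float
    variance: float
    apen: float
    mean: float
    std: float
    skewness: float
    kurtosis: float
    peak_max: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def segment(
    record: PPGRecord | np.ndarray,
    seg_seconds: float = 2.0,
    fs: float | None = None,
) -> np.ndarray:
    """Cut a record into consecutive windows; returns (n_windows, w) array.

    Accepts a :class:`PPGRecord` or a bare sample array (then ``fs`` is
    required).  The trailing remainder shorter than one window is dropped.
    """
    if isinstance(record, PPGRecord):
        samples, fs = record.samples, record.fs
    else:
        if fs is None:
            raise ValueError("fs is required when segmenting a bare array")
        samples = np.asarray(record, dtype=float)
    w = int(round(seg_seconds * fs))
    if w < 1:
        raise ValueError("segment length must be at least one sample")
    n = samples.size
    if n < w:
        raise ValueError(f"record has {n} samples, shorter than one {w}-sample segment")
    k = n // w
    return samples[: k * w].reshape(k, w)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy of a 1-D series (Chebyshev distance).

    ``r`` defaults to 0.2 x sample SD of ``x``.  Returns 0 for a constant
    series (tolerance zero, every template matches everything).
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0.0:
            return 0.0
        r = 0.2 * sd
    return float(_apen_windows(x[None, :], m, np.array([r]))[0])


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy (Richman–Moorman): self-matches excluded.

    Returns 0 for a constant series; +inf when no template matches at m+1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if r is None:
        sd = x.std(ddof=1) if n > 1 else 0.0
        if sd == 0.0:
            return 0.0
        r = 0.2 * sd

    # use the common n-m templates for both lengths
    k = n - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:k]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:k]
    dm = np.abs(emb_m[:, None, :] - emb_m[None, :, :]).max(axis=2)
    dm1 = np.abs(emb_m1[:, None, :] - emb_m1[None, :, :]).max(axis=2)
    bm = (dm <= r).sum() - k
    am = (dm1 <= r).sum() - k
    if bm == 0 or am == 0:
        return float("inf") if bm > 0 else 0.0
    return float(-np.log(am / bm))


def _apen_windows(
    windows: np.ndarray, m: int, r: np.ndarray, chunk: int = 32
) -> np.ndarray:
    """ApEn for a stack of equal-length windows (vectorized, chunked).

    windows : (k, n) array; r : (k,) per-window tolerance.  The Chebyshev
    distance matrix for embedding length m is built as a running maximum
    of per-offset absolute differences and extended in place to m+1.
    """
    windows = np.asarray(windows, dtype=float)
    k, n = windows.shape
    out = np.empty(k)
    k1 = n - m + 1  # templates at length m
    k2 = n - m  # templates at length m+1

    for lo in range(0, k, chunk):
        hi = min(k, lo + chunk)
        block = windows[lo:hi]
        rb = r[lo:hi, None, None]
        d = None
        for off in range(m):
            a = np.abs(block[:, off : off + k1, None] - block[:, None, off : off + k1])
            d = a if d is None else np.maximum(d, a, out=d)
        c1 = (d <= rb).mean(axis=2)
        phi1 = np.log(c1).mean(axis=1)
        d2 = np.maximum(
            d[:, :k2, :k2],
            np.abs(block[:, m : m + k2, None] - block[:, None, m : m + k2]),
        )
        c2 = (d2 <= rb).mean(axis=2)
        phi2 = np.log(c2).mean(axis=1)
        out[lo:hi] = phi1 - phi2
    return out


def extract_features(window: np.ndarray) -> SegmentFeatures:
    """Compute the eight parameters of one window (length >= 4)."""
    x = np.asarray(window, dtype=float)
    if x.size < 4:
        raise ValueError("window must contain at least 4 samples")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    std = float(np.sqrt(var))
    energy = float(np.sum(x * x))
    peak = float(x.max())
    if var == 0.0:
        return SegmentFeatures(energy, var, 0.0, mean, std, 0.0, 0.0, peak, True)
    skew = float(sp_stats.skew(x, bias=True))
    kurt = float(sp_stats.kurtosis(x, fisher=False, bias=True))
    apen = approximate_entropy(x)
    return SegmentFeatures(energy, var, apen, mean, std, skew, kurt, peak, False)


def features_for_record(record: PPGRecord, seg_seconds: float = 2.0) -> pd.DataFrame:
    """Feature table for every segment of one record (raw, uncalibrated)."""
    win = segment(record, seg_seconds)
    k, n = win.shape
    mean = win.mean(axis=1)
    var = win.var(axis=1, ddof=1)
    std = np.sqrt(var)
    energy = np.einsum("ij,ij->i", win, win)
    peak = win.max(axis=1)
    ok = var > 0

    skew = np.zeros(k)
    kurt = np.zeros(k)
    if ok.any():
        c = win[ok] - mean[ok, None]
        m2 = (c**2).mean(axis=1)
        m3 = (c**3).mean(axis=1)
        m4 = (c**4).mean(axis=1)
        skew[ok] = m3 / m2**1.5
        kurt[ok] = m4 / m2**2

    apen = np.zeros(k)
    if ok.any():
        apen[ok] = _apen_windows(win[ok], 2, 0.2 * std[ok])

    df = pd.DataFrame(
        {
            "subject_id": record.subject_id,
            "segment_index": np.arange(k),
            "energy": energy,
            "variance": var,
            "apen": apen,
            "mean": mean,
            "std": std,
            "skewness": skew,
            "kurtosis": kurt,
            "peak_max": peak,
            "label": record.label,
        }
    )
    return df


def preprocess(
    record: PPGRecord,
    detrend: bool = True,
    rescale: Tuple[float, float] | None = None,
) -> PPGRecord:
    """Linear detrend and optional amplitude rescale; no-op when disabled.

    Stands in for source separation that a single channel cannot support.
    """
    x = record.samples
    if not detrend and rescale is None:
        return record
    if detrend:
        x = sp_signal.detrend(x, type="linear")
    if rescale is not None:
        lo, hi = rescale
        xmin, xmax = x.min(), x.max()
        if xmax > xmin:
            x = lo + (x - xmin) * (hi - lo) / (xmax - xmin)
        else:
            x = np.full_like(x, (lo + hi) / 2)
    return PPGRecord(record.subject_id, record.label, record.fs, x)


# ---------------------------------------------------------------------------
# Calibration of raw features into the fuzzy linguistic domains.
#
# The eight linguistic ranges are mutually incompatible for any single raw
# waveform (a Mean of ~15 units over 200 samples forces an Energy far above
# its 0-30 domain), so each raw feature is mapped affinely,
# calibrated = offset + scale * raw, into its domain.  The constants below
# were fixed once from pilot quantiles of the default synthetic cohort so
# that normal-class segments populate the Very Low / Low sets and cvd-class
# segments the High / Very High sets of each feature.
# ---------------------------------------------------------------------------

#: feature -> (scale, offset); fixed once by mapping the pooled 0.5%-99.5%
#: quantile span of the default cohort's raw features onto a target
#: interval inside each feature's linguistic union.
DEFAULT_CALIBRATION: Dict[str, Tuple[float, float]] = {
    "energy": (0.0598, -0.4469),
    "variance": (7.1071, -0.4534),
    "apen": (8.4185, -1.3646),
    "mean": (26.651, -4.3248),
    "std": (18.3517, -4.3207),
    "skewness": (4.5328, -3.1378),
    "kurtosis": (0.356, -0.7591),
    "peak_max": (5.6287, -4.5245),
}

IDENTITY_CALIBRATION: Dict[str, Tuple[float, float]] = {
    n: (1.0, 0.0) for n in FEATURE_NAMES
}


def apply_calibration(
    features: pd.DataFrame,
    calibration: Dict[str, Tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Affinely map raw feature columns into the linguistic domains.

    ``calibration`` maps feature name -> (scale, offset); missing features
    pass through unchanged.  Defaults to ``DEFAULT_CALIBRATION``.
    """
    if calibration is None:
        calibration = DEFAULT_CALIBRATION
    out = features.copy()
    for name, (scale, offset) in calibration.items():
        if name in out.columns:
            out[name] = offset + scale * out[name]
    return out


def write_features(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
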