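"""Weighted binary code-word encoding of fuzzy risk levels.

Each 2-second segment yields seven output risk levels (Energy paired
with each of the seven other features, in the fixed order Variance,
ApEn, Mean, STD, Skewness, Kurtosis, Peak-Maximum).  Levels map to
letters N->A, L->B, M->C, H->D, VH->E; each letter carries a five-bit
one-hot binary string whose positional value over 31 gives its weight,
and weight/7 its probability.  A code word's numeric value is the sum of
its letters' probabilities, so values live in [7*p(A), 7*p(E)] =
[0.032256, 0.516124].

The canonical per-letter probabilities are the published six-decimal
constants (not the exact fractions) so worked examples reproduce
bit-for-bit; ``exact_probability`` exposes the fraction form, which
differs by < 1e-5 per word.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

LETTERS = "ABCDE"

LEVEL_TO_LETTER: Dict[str, str] = {"N": "A", "L": "B", "M": "C", "H": "D", "VH": "E"}
LETTER_TO_LEVEL: Dict[str, str] = {v: k for k, v in LEVEL_TO_LETTER.items()}

#: five-bit one-hot strings, A lowest position .. E highest
BINARY_STRING: Dict[str, str] = {
    "A": "00001",
    "B": "00010",
    "C": "00100",
    "D": "01000",
    "E": "10000",
}

#: positional value / 31
WEIGHT: Dict[str, float] = {
    "A": 1 / 31,
    "B": 2 / 31,
    "C": 4 / 31,
    "D": 8 / 31,
    "E": 16 / 31,
}

#: canonical printed six-decimal probabilities (weight / 7, rounded)
PROBABILITY: Dict[str, float] = {
    "A": 0.004608,
    "B": 0.009216,
    "C": 0.018433,
    "D": 0.036866,
    "E": 0.073732,
}

#: the fixed partner-feature order defining letter positions in a word
WORD_FEATURE_ORDER = (
    "variance",
    "apen",
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "peak_max",
)

WORD_LENGTH = 7
VALUE_MIN = 7 * PROBABILITY["A"]
VALUE_MAX = 7 * PROBABILITY["E"]


def exact_probability(letter: str) -> float:
    """Probability from exact fractions: (2^k / 31) / 7."""
    return WEIGHT[letter] / 7.0


def word_value(letters: str, exact: bool = False) -> float:
    """Numeric value of a letter string: sum of per-letter probabilities."""
    table = PROBABILITY if not exact else {l: exact_probability(l) for l in LETTERS}
    try:
        return float(sum(table[l] for l in letters))
    except KeyError as err:
        raise ValueError(f"unknown letter {err.args[0]!r}") from None


@dataclass(frozen=True)
class CodeWord:
    """A seven-letter code word with its numeric value."""

    letters: str
    value: float
    segment_index: int | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.letters) != WORD_LENGTH or any(
            l not in LETTERS for l in self.letters
        ):
            raise ValueError(
                f"letters must be {WORD_LENGTH} characters over {LETTERS!r}"
            )


def encode_segment(
    levels: Sequence[str],
    segment_index: int | None = None,
    subject_id: str | None = None,
) -> CodeWord:
    """Encode the seven subsystem output levels of one segment."""
    if len(levels) != WORD_LENGTH:
        raise ValueError(f"expected exactly {WORD_LENGTH} levels, got {len(levels)}")
    try:
        letters = "".join(LEVEL_TO_LETTER[lv] for lv in levels)
    except KeyError as err:
        raise ValueError(f"unknown output level {err.args[0]!r}") from None
    return CodeWord(letters, word_value(letters), segment_index, subject_id)


@dataclass
class PatientCodeStream:
    """Ordered per-segment code words of one subject."""

    subject_id: str
    label: str
    words: List[CodeWord] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return np.array([w.value for w in self.words])

    @property
    def letter_strings(self) -> List[str]:
        return [w.letters for w in self.words]


def target_code(
    stream: PatientCodeStream, window: slice | None = None
) -> CodeWord:
    """Position-wise modal letter over a window; modal ties -> higher risk."""
    words = stream.words if window is None else stream.words[window]
    if not words:
        raise ValueError("window is empty")
    letters = []
    for pos in range(WORD_LENGTH):
        counts = Counter(w.letters[pos] for w in words)
        top = max(counts.values())
        letters.append(max(l for l, c in counts.items() if c == top))
    s = "".join(letters)
    return CodeWord(s, word_value(s), subject_id=stream.subject_id)


def reduce_stream(stream: PatientCodeStream, L: int = 375) -> np.ndarray:
    """Deduplicated, fixed-length value vector for the optimizers.

    Duplicate letter strings are dropped keeping first occurrence (original
    segment order preserved); if more than ``L`` remain the ``L`` earliest
    are kept; if fewer, the deduplicated values are cycled to length ``L``.
    """
    if not stream.words:
        raise ValueError("stream is empty")
    if L < 1:
        raise ValueError("L must be >= 1")
    seen = set()
    values: List[float] = []
    for w in stream.words:
        if w.letters not in seen:
            seen.add(w.letters)
            values.append(w.value)
        if len(values) == L:
            break
    k = len(values)
    if k < L:
        reps = -(-L // k)
        values = (values * reps)[:L]
    return np.asarray(values)


@dataclass(frozen=True)
class DistributionPlotData:
    """Arrays behind a histogram / CDF / normal-probability plot."""

    bin_edges: np.ndarray
    counts: np.ndarray
    cdf_x: np.ndarray
    cdf_y: np.ndarray
    prob_quantiles: np.ndarray
    prob_order_stats: np.ndarray


def histogram_cdf(values: np.ndarray, bins: int = 20) -> DistributionPlotData:
    """Histogram, right-continuous empirical CDF, and probability-plot points.

    The CDF is evaluated at the sorted unique values; the probability plot
    pairs order statistics with standard-normal quantiles at (i-0.5)/n.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values is empty")
    counts, edges = np.histogram(v, bins=bins)
    xs = np.unique(v)
    cdf = np.searchsorted(np.sort(v), xs, side="right") / v.size
    n = v.size
    q = sp_stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return DistributionPlotData(edges, counts, xs, cdf, q, np.sort(v))


# ---------------------------------------------------------------------------
# CSV serialization of code-word streams
# ---------------------------------------------------------------------------


def streams_to_frame(streams: Iterable[PatientCodeStream]) -> pd.DataFrame:
    rows = []
    for s in streams:
        for i, w in enumerate(s.words):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "segment_index": i,
                    "letters": w.letters,
                    "value": w.value,
                    "label": s.label,
                }
            )
    return pd.DataFrame(rows)


def frame_to_streams(df: pd.DataFrame) -> List[PatientCodeStream]:
    streams = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("segment_index")
        words = [
            CodeWord(r.letters, float(r.value), int(r.segment_index), sid)
            for r in grp.itertuples(index=False)
        ]
        streams.append(PatientCodeStream(sid, grp["label"].iloc[0], words))
    return streams


def write_streams(
    streams: Iterable[PatientCodeStream], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        streams_to_frame(streams).to_csv(fh, index=False)


def read_streams(path: str | Path) -> List[PatientCodeStream]:
    return frame_to_streams(pd.read_csv(path, comment="#"))
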