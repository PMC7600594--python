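"""Type-1 Mamdani fuzzy inference over the eight PPG features.

Each feature carries five triangular linguistic sets, Very Low (VL) to
Very High (VH), built from the published numeric ranges: the triangle
spans the range with its peak at the midpoint, the VL set is extended to
a left shoulder (membership 1 below its peak) and VH to a right shoulder.
Energy is the prominent input: it is paired with each of the seven other
features through a 5x5 fuzzy associative matrix (FAM) whose 13 defined
cells form a band around the main diagonal; the remaining 12 cells are
don't-cares that never fire.  Conjunction is min, aggregation per output
level is max, and the "defuzzified" result is the linguistic risk level
itself (argmax, ties toward higher risk) — downstream encoding consumes
letters, not crisp numbers.

Gaps between adjacent ranges (e.g. Energy between 0.1 and 0.7) are closed
by a nearest-support fallback: a value with zero membership everywhere is
assigned membership 1 in the set whose support interval is nearest, ties
toward the higher set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

INPUT_LEVELS = ("VL", "L", "M", "H", "VH")
OUTPUT_LEVELS = ("N", "L", "M", "H", "VH")

#: Published linguistic ranges, feature -> five (lo, hi) pairs VL..VH.
TABLE_RANGES: Dict[str, List[Tuple[float, float]]] = {
    "energy": [(0, 0.1), (0.7, 3.6), (2.9, 8.2), (7.6, 11), (9.2, 30)],
    "variance": [(0, 0.3), (0.15, 0.45), (0.4, 2.2), (1.6, 4.3), (3.8, 15)],
    "apen": [(0, 1.8), (1, 2.2), (2, 3.6), (3.2, 5), (4.3, 12)],
    "mean": [(0, 2), (1, 5), (4, 10), (7, 16), (15, 28)],
    "std": [(0, 2), (1, 4.5), (4, 9), (7, 11.6), (10, 13)],
    "skewness": [(0, 0.3), (0.15, 0.45), (0.4, 2.4), (1.8, 4.6), (3.6, 10)],
    "kurtosis": [(0, 0.05), (0.025, 0.1), (0.09, 0.4), (0.28, 0.64), (0.54, 1)],
    "peak_max": [(0, 3), (1, 5.2), (4, 9.3), (7, 11.6), (10, 14.6)],
}

#: The published FAM band for Energy (rows) vs partner (columns); "x" cells
#: are don't-cares.  Reused for all seven feature pairs.
DEFAULT_FAM_GRID: List[List[str]] = [
    ["N", "L", "x", "x", "x"],
    ["L", "L", "M", "x", "x"],
    ["x", "M", "M", "H", "x"],
    ["x", "x", "H", "H", "VH"],
    ["x", "x", "x", "VH", "VH"],
]


@dataclass(frozen=True)
class LinguisticSet:
    """One triangular membership function, possibly shoulder-extended."""

    name: str
    lo: float
    peak: float
    hi: float
    shoulder: str = "none"  # left | none | right

    def membership(self, value: float) -> float:
        return float(self.memberships(np.asarray([value]))[0])

    def memberships(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        mu = np.zeros(x.shape)
        if self.peak > self.lo:
            rising = (x > self.lo) & (x <= self.peak)
            mu[rising] = (x[rising] - self.lo) / (self.peak - self.lo)
        else:
            mu[x == self.peak] = 1.0
        if self.hi > self.peak:
            falling = (x > self.peak) & (x < self.hi)
            mu[falling] = (self.hi - x[falling]) / (self.hi - self.peak)
        if self.shoulder == "left":
            mu[x <= self.peak] = 1.0
        elif self.shoulder == "right":
            mu[x >= self.peak] = 1.0
        return mu


@dataclass(frozen=True)
class FeatureFuzzifier:
    """The five ordered (VL..VH) linguistic sets of one feature."""

    feature_name: str
    sets: Tuple[LinguisticSet, ...]

    def __post_init__(self) -> None:
        if len(self.sets) != 5:
            raise ValueError("a fuzzifier needs exactly five linguistic sets")

    def memberships(self, values: np.ndarray) -> np.ndarray:
        """(n, 5) membership matrix with the nearest-support fallback."""
        x = np.asarray(values, dtype=float)
        if np.isnan(x).any():
            raise ValueError("cannot fuzzify NaN values")
        mu = np.stack([s.memberships(x) for s in self.sets], axis=-1)
        uncovered = mu.sum(axis=-1) == 0
        if uncovered.any():
            xu = x[uncovered]
            dists = np.stack(
                [
                    np.maximum.reduce([s.lo - xu, xu - s.hi, np.zeros_like(xu)])
                    for s in self.sets
                ],
                axis=-1,
            )
            # argmin with ties broken toward the higher set
            nearest = 4 - np.argmin(dists[:, ::-1], axis=-1)
            rows = np.where(uncovered)[0]
            mu[rows, nearest] = 1.0
        return mu


def build_set(name: str, lo: float, hi: float, shoulder: str = "none") -> LinguisticSet:
    """Triangle over a published range: peak at the range midpoint."""
    return LinguisticSet(name, float(lo), (float(lo) + float(hi)) / 2.0, float(hi), shoulder)


def build_fuzzifiers(
    ranges: Dict[str, List[Tuple[float, float]]] | None = None,
) -> Dict[str, FeatureFuzzifier]:
    """Fuzzifiers for all eight features from their published ranges."""
    if ranges is None:
        ranges = TABLE_RANGES
    out: Dict[str, FeatureFuzzifier] = {}
    for feature, pairs in ranges.items():
        if len(pairs) != 5:
            raise ValueError(f"{feature}: expected 5 ranges, got {len(pairs)}")
        sets = []
        for i, ((lo, hi), name) in enumerate(zip(pairs, INPUT_LEVELS)):
            if not lo <= hi:
                raise ValueError(f"{feature}/{name}: lo must be <= hi")
            shoulder = "left" if i == 0 else ("right" if i == 4 else "none")
            sets.append(build_set(name, lo, hi, shoulder))
        out[feature] = FeatureFuzzifier(feature, tuple(sets))
    return out


def fuzzify(value: float, fz: FeatureFuzzifier) -> Dict[str, float]:
    """Membership of one value in each of the five sets (with fallback)."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    mu = fz.memberships(np.asarray([value]))[0]
    return {name: float(m) for name, m in zip(INPUT_LEVELS, mu)}


@dataclass(frozen=True)
class FAM:
    """5x5 fuzzy associative matrix; cells hold output levels or None."""

    grid: Tuple[Tuple[str | None, ...], ...]

    @classmethod
    def from_strings(cls, rows: Sequence[Sequence[str]]) -> "FAM":
        grid = tuple(
            tuple(None if c.lower() == "x" else c for c in row) for row in rows
        )
        if len(grid) != 5 or any(len(r) != 5 for r in grid):
            raise ValueError("FAM must be a 5x5 grid")
        for row in grid:
            for c in row:
                if c is not None and c not in OUTPUT_LEVELS:
                    raise ValueError(f"unknown output level {c!r}")
        return cls(grid)

    def defined_cells(self) -> List[Tuple[int, int, int]]:
        """(energy_set, partner_set, output_level_index) of non-x cells."""
        cells = []
        for i, row in enumerate(self.grid):
            for j, c in enumerate(row):
                if c is not None:
                    cells.append((i, j, OUTPUT_LEVELS.index(c)))
        return cells


def default_fam() -> FAM:
    fam = FAM.from_strings(DEFAULT_FAM_GRID)
    assert count_active_rules(fam) == 13
    return fam


def count_active_rules(fam: FAM) -> int:
    """Number of defined (non-don't-care) cells in the FAM."""
    return len(fam.defined_cells())


def infer_levels(
    energy_values: np.ndarray,
    partner_values: np.ndarray,
    partner_fz: FeatureFuzzifier,
    fam: FAM | None = None,
    energy_fz: FeatureFuzzifier | None = None,
) -> np.ndarray:
    """Vectorized pair inference: output-level index (0..4) per segment.

    Firing of each defined FAM cell is min(energy membership, partner
    membership); levels aggregate by max; ties break toward higher risk.
    """
    if fam is None:
        fam = default_fam()
    if energy_fz is None:
        energy_fz = build_fuzzifiers()["energy"]
    e_mu = energy_fz.memberships(np.asarray(energy_values, dtype=float))
    p_mu = partner_fz.memberships(np.asarray(partner_values, dtype=float))
    n = e_mu.shape[0]
    agg = np.zeros((n, 5))
    cells = fam.defined_cells()
    for i, j, out in cells:
        firing = np.minimum(e_mu[:, i], p_mu[:, j])
        np.maximum(agg[:, out], firing, out=agg[:, out])
    # argmax with ties toward the higher level
    levels = 4 - np.argmax(agg[:, ::-1], axis=1)

    # A pair landing on a don't-care corner fires no rule at all.  Fall
    # back to the defined cell nearest (Manhattan) to the dominant
    # (energy-set, partner-set) pair, ties toward the higher output level,
    # which keeps the output monotone along the rule band.
    dead = agg.max(axis=1) == 0
    if dead.any():
        ei = 4 - np.argmax(e_mu[dead, ::-1], axis=1)
        pj = 4 - np.argmax(p_mu[dead, ::-1], axis=1)
        cell_arr = np.asarray(cells)  # (13, 3)
        dist = np.abs(ei[:, None] - cell_arr[None, :, 0]) + np.abs(
            pj[:, None] - cell_arr[None, :, 1]
        )
        best = dist.min(axis=1)
        # among minimal-distance cells take the highest output level
        out_masked = np.where(dist == best[:, None], cell_arr[None, :, 2], -1)
        levels[dead] = out_masked.max(axis=1)
    return levels


def infer_pair(
    energy_value: float,
    partner_value: float,
    partner_fz: FeatureFuzzifier,
    fam: FAM | None = None,
    energy_fz: FeatureFuzzifier | None = None,
) -> str:
    """Output risk level for one (energy, partner) pair of crisp values."""
    idx = infer_levels(
        np.asarray([energy_value]), np.asarray([partner_value]), partner_fz, fam, energy_fz
    )[0]
    return OUTPUT_LEVELS[idx]


# ---------------------------------------------------------------------------
# YAML round-trip so users can re-band rules without code changes.
# ---------------------------------------------------------------------------


def fuzzifiers_to_yaml(fuzzifiers: Dict[str, FeatureFuzzifier]) -> str:
    doc = {
        name: [[s.lo, s.hi] for s in fz.sets] for name, fz in fuzzifiers.items()
    }
    return yaml.safe_dump(doc, sort_keys=True)


def fuzzifiers_from_yaml(text: str) -> Dict[str, FeatureFuzzifier]:
    doc = yaml.safe_load(text)
    return build_fuzzifiers({k: [tuple(p) for p in v] for k, v in doc.items()})


def fam_to_yaml(fam: FAM) -> str:
    rows = [["x" if c is None else c for c in row] for row in fam.grid]
    return yaml.safe_dump({"fam": rows}, sort_keys=True)


def fam_from_yaml(text: str) -> FAM:
    doc = yaml.safe_load(text)
    return FAM.from_strings(doc["fam"])
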