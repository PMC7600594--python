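"""Two-class synthetic photoplethysmography (PPG) cohort generator.

Each subject is a single-channel pulsatile waveform sampled at ``fs`` Hz:
a train of beats, each beat the sum of a main systolic Gaussian and a
delayed, smaller dicrotic-notch Gaussian, plus a slow baseline-wander
sinusoid and additive white noise.  The ``cvd`` class differs from
``normal`` by a faster pulse rate, larger pulse amplitude, larger beat-to-
beat interval and amplitude jitter, and an attenuated dicrotic notch —
stylized contrasts that make the two classes separable in the eight
segment features consumed downstream, without claiming clinical realism.

The default cohort mirrors the benchmark framing the pipeline targets:
28 cvd + 14 normal subjects, 100 Hz, 750 two-second segments per subject
(150,000 samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

LABELS = ("normal", "cvd")
_LABEL_CODE = {"normal": 0, "cvd": 1}

# Stride separating per-class RNG streams; per-subject stream = seed +
# stride*label + subject_index (kept well below 2**31).
_STREAM_STRIDE = 100_003


class SynthSpecError(ValueError):
    """Raised when a SynthSpec field fails validation; names the field."""


@dataclass(frozen=True)
class ClassParams:
    """Per-class waveform parameters.

    heart_rate_bpm : mean pulse rate (beats/min)
    rr_jitter      : coefficient of variation of inter-beat intervals
    amp_scale      : mean systolic pulse amplitude (arbitrary units)
    amp_jitter     : coefficient of variation of per-beat amplitude
    notch_delay    : dicrotic-notch delay as a fraction of the beat period
    notch_amp      : notch amplitude relative to the systolic amplitude
    """

    heart_rate_bpm: float = 75.0
    rr_jitter: float = 0.03
    amp_scale: float = 1.0
    amp_jitter: float = 0.05
    notch_delay: float = 0.42
    notch_amp: float = 0.30


#: Study-condition defaults.  cvd: faster, larger, jitterier pulses with a
#: damped dicrotic notch (stiffer vasculature); normal: regular 75 bpm.
DEFAULT_CLASS_PARAMS: Dict[str, ClassParams] = {
    "normal": ClassParams(
        heart_rate_bpm=75.0,
        rr_jitter=0.03,
        amp_scale=1.0,
        amp_jitter=0.05,
        notch_delay=0.42,
        notch_amp=0.30,
    ),
    "cvd": ClassParams(
        heart_rate_bpm=90.0,
        rr_jitter=0.09,
        amp_scale=2.1,
        amp_jitter=0.14,
        notch_delay=0.36,
        notch_amp=0.12,
    ),
}


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic two-class PPG cohort."""

    n_normal: int = 14
    n_cvd: int = 28
    fs: float = 100.0
    n_segments: int = 750
    classes: Dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    noise_sd: float = 0.04
    baseline_amp: float = 0.10
    baseline_freq: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise SynthSpecError("fs must be > 0")
        if self.n_segments < 1:
            raise SynthSpecError("n_segments must be >= 1")
        if self.noise_sd < 0:
            raise SynthSpecError("noise_sd must be >= 0")
        if self.baseline_amp < 0:
            raise SynthSpecError("baseline_amp must be >= 0")
        for lab in LABELS:
            if lab not in self.classes:
                raise SynthSpecError(f"classes missing entry for '{lab}'")
            cp = self.classes[lab]
            if cp.heart_rate_bpm <= 0:
                raise SynthSpecError(f"classes[{lab}].heart_rate_bpm must be > 0")
            for fname in ("rr_jitter", "amp_jitter"):
                if getattr(cp, fname) < 0:
                    raise SynthSpecError(f"classes[{lab}].{fname} must be >= 0")
            if cp.amp_scale <= 0:
                raise SynthSpecError(f"classes[{lab}].amp_scale must be > 0")
            if not 0 < cp.notch_delay < 1:
                raise SynthSpecError(f"classes[{lab}].notch_delay must be in (0,1)")
            if cp.notch_amp < 0:
                raise SynthSpecError(f"classes[{lab}].notch_amp must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_segments * 2 * self.fs))

    def with_class(self, label: str, **kwargs) -> "SynthSpec":
        """Return a copy with one class's parameters overridden."""
        classes = dict(self.classes)
        classes[label] = replace(classes[label], **kwargs)
        return replace(self, classes=classes)


@dataclass(frozen=True)
class PPGRecord:
    """One subject's sampled PPG waveform with class label."""

    subject_id: str
    label: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        seg = int(round(2 * self.fs))
        if samples.size == 0 or samples.size % seg != 0:
            raise ValueError(
                f"record length {samples.size} is not a positive multiple of 2*fs={seg}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")


def _beat_train(
    rng: np.random.Generator, n: int, fs: float, cp: ClassParams
) -> np.ndarray:
    """Superpose systolic + dicrotic Gaussians for a jittered beat train."""
    period = fs * 60.0 / cp.heart_rate_bpm  # samples per beat (float)
    sigma_sys = 0.10 * period
    sigma_dic = 0.07 * period

    signal = np.zeros(n)
    t = 0.0
    # run a little past the end so boundary beats contribute their tails
    while t < n + 2 * period:
        ibi = period * max(0.3, 1.0 + cp.rr_jitter * rng.standard_normal())
        amp = cp.amp_scale * max(0.1, 1.0 + cp.amp_jitter * rng.standard_normal())
        for center, a, sigma in (
            (t, amp, sigma_sys),
            (t + cp.notch_delay * period, amp * cp.notch_amp, sigma_dic),
        ):
            lo = max(0, int(center - 5 * sigma))
            hi = min(n, int(center + 5 * sigma) + 1)
            if hi > lo:
                x = np.arange(lo, hi, dtype=float)
                signal[lo:hi] += a * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        t += ibi
    return signal


def generate_record(spec: SynthSpec, label: str, subject_index: int) -> PPGRecord:
    """Generate one subject's waveform; deterministic in (seed, label, index)."""
    spec.validate()
    if label not in LABELS:
        raise SynthSpecError(f"label must be one of {LABELS}, got {label!r}")
    seed = (spec.seed + _STREAM_STRIDE * _LABEL_CODE[label] + subject_index) % (2**31)
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    cp = spec.classes[label]

    signal = _beat_train(rng, n, spec.fs, cp)
    if spec.baseline_amp > 0:
        phase = 2 * math.pi * rng.random()
        tt = np.arange(n) / spec.fs
        signal += spec.baseline_amp * np.sin(
            2 * math.pi * spec.baseline_freq * tt + phase
        )
    if spec.noise_sd > 0:
        signal += spec.noise_sd * rng.standard_normal(n)

    sid = f"{label}{subject_index:03d}"
    return PPGRecord(subject_id=sid, label=label, fs=spec.fs, samples=signal)


def generate_cohort(spec: SynthSpec) -> Tuple[List[PPGRecord], pd.DataFrame]:
    """Generate the full cohort plus a manifest table (id, label, path, fs).

    Subject indices run over the whole cohort (cvd first, then normal) so
    every subject draws from a distinct RNG stream.
    """
    spec.validate()
    if spec.n_cvd < 1:
        raise SynthSpecError("n_cvd must be >= 1")
    if spec.n_normal < 1:
        raise SynthSpecError("n_normal must be >= 1")
    records: List[PPGRecord] = []
    idx = 0
    for label, count in (("cvd", spec.n_cvd), ("normal", spec.n_normal)):
        for _ in range(count):
            records.append(generate_record(spec, label, idx))
            idx += 1
    manifest = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "label": [r.label for r in records],
            "path": ["" for _ in records],
            "fs": [r.fs for r in records],
        }
    )
    return records, manifest


def write_cohort(
    records: Sequence[PPGRecord], out_dir: str | Path
) -> pd.DataFrame:
    """Write one amplitude-per-line text file per subject plus manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        path = out / f"{rec.subject_id}.txt"
        np.savetxt(path, rec.samples, fmt="%.6f")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "path": str(path),
                "fs": rec.fs,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_record(path: str | Path, subject_id: str, label: str, fs: float) -> PPGRecord:
    """Read a one-amplitude-per-line (or single-column delimited) file."""
    samples = np.loadtxt(path, ndmin=1)
    return PPGRecord(subject_id=subject_id, label=label, fs=fs, samples=samples)


def read_manifest(path: str | Path) -> List[PPGRecord]:
    """Read manifest.csv and load every referenced record."""
    manifest = pd.read_csv(path, comment="#")
    records = []
    for row in manifest.itertuples(index=False):
        records.append(read_record(row.path, row.subject_id, row.label, float(row.fs)))
    return records
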