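"""End-to-end orchestration: generate -> features -> fuzzy -> encode ->
optimize -> classify -> report.

These helpers hold the pipeline logic shared by the command-line
interface and by programmatic use.  All stages are deterministic given
the run seed; per-patient optimizer seeds are derived from it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classify, codewords, features, fuzzy, optimizers, synthetic


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    spec: synthetic.SynthSpec = field(default_factory=synthetic.SynthSpec)
    algorithms: Tuple[str, ...] = optimizers.ALGORITHMS
    classifiers: Tuple[str, ...] = classify.CLASSIFIERS
    folds: int = 10
    seed: int = 1
    np_size: int = 20
    max_iter: int = 40
    reduced_length: int = 375
    calibration: Dict[str, Tuple[float, float]] | None = None
    preprocess: bool = False

    def validate(self) -> None:
        self.spec.validate()
        for a in self.algorithms:
            if a not in optimizers.ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")
        for c in self.classifiers:
            if c not in classify.CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def hash(self) -> str:
        """Short stable hash of the configuration for output provenance."""
        doc = {
            "spec": {
                **{
                    k: getattr(self.spec, k)
                    for k in (
                        "n_normal",
                        "n_cvd",
                        "fs",
                        "n_segments",
                        "noise_sd",
                        "baseline_amp",
                        "baseline_freq",
                        "seed",
                    )
                },
                "classes": {
                    lab: vars(cp) for lab, cp in sorted(self.spec.classes.items())
                },
            },
            "algorithms": list(self.algorithms),
            "classifiers": list(self.classifiers),
            "folds": self.folds,
            "seed": self.seed,
            "np_size": self.np_size,
            "max_iter": self.max_iter,
            "reduced_length": self.reduced_length,
            "calibration": self.calibration,
            "preprocess": self.preprocess,
        }
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def extract_cohort_features(
    records: Sequence[synthetic.PPGRecord],
    calibration: Dict[str, Tuple[float, float]] | None = None,
    do_preprocess: bool = False,
) -> pd.DataFrame:
    """Calibrated per-segment feature table for a cohort."""
    frames = []
    for rec in records:
        if do_preprocess:
            rec = features.preprocess(rec)
        frames.append(features.features_for_record(rec))
    raw = pd.concat(frames, ignore_index=True)
    return features.apply_calibration(raw, calibration)


def encode_features(
    feature_table: pd.DataFrame,
    fuzzifiers: Dict[str, fuzzy.FeatureFuzzifier] | None = None,
    fam: fuzzy.FAM | None = None,
) -> List[codewords.PatientCodeStream]:
    """Fuzzy-infer the seven pair outputs per segment and encode code words."""
    if fuzzifiers is None:
        fuzzifiers = fuzzy.build_fuzzifiers()
    if fam is None:
        fam = fuzzy.default_fam()
    energy_fz = fuzzifiers["energy"]

    streams = []
    for sid, grp in feature_table.groupby("subject_id", sort=False):
        grp = grp.sort_values("segment_index")
        energy = grp["energy"].to_numpy()
        level_idx = np.stack(
            [
                fuzzy.infer_levels(
                    energy, grp[part].to_numpy(), fuzzifiers[part], fam, energy_fz
                )
                for part in codewords.WORD_FEATURE_ORDER
            ],
            axis=1,
        )  # (n_segments, 7)
        words = []
        for seg_i, row in enumerate(level_idx):
            levels = [fuzzy.OUTPUT_LEVELS[i] for i in row]
            words.append(codewords.encode_segment(levels, seg_i, sid))
        streams.append(
            codewords.PatientCodeStream(sid, grp["label"].iloc[0], words)
        )
    return streams


def class_target_values(
    streams: Sequence[codewords.PatientCodeStream],
) -> Dict[str, float]:
    """Per-class target-code values: modal target code over each class."""
    out: Dict[str, float] = {}
    for label in sorted({s.label for s in streams}):
        merged = codewords.PatientCodeStream(
            f"_class_{label}",
            label,
            [w for s in streams if s.label == label for w in s.words],
        )
        out[label] = codewords.target_code(merged).value
    return out


def optimize_cohort(
    streams: Sequence[codewords.PatientCodeStream],
    algorithm: str,
    seed: int,
    np_size: int = 20,
    max_iter: int = 40,
    L: int = 375,
) -> Dict[str, np.ndarray]:
    """Optimized value vector per patient; per-patient derived seeds."""
    out = {}
    for i, stream in enumerate(streams):
        cfg = optimizers.OptimizerConfig(
            algorithm=algorithm,
            np_size=np_size,
            max_iter=max_iter,
            seed=(seed + 131 * i + 7 * optimizers.ALGORITHMS.index(algorithm))
            % (2**31),
        )
        out[stream.subject_id] = optimizers.optimize_stream(stream, cfg, L=L)
    return out


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline and return the report table.

    One row per (optimizer, classifier, class) with class in
    {cvd, normal, average}.
    """
    config.validate()
    records, _ = synthetic.generate_cohort(config.spec)
    table = extract_cohort_features(
        records, config.calibration, config.preprocess
    )
    streams = encode_features(table)
    targets = class_target_values(streams)
    labels = {s.subject_id: s.label for s in streams}

    reports: Dict[Tuple[str, str], Dict[str, classify.ClassReport]] = {}
    for alg in config.algorithms:
        vectors = optimize_cohort(
            streams,
            alg,
            config.seed,
            np_size=config.np_size,
            max_iter=config.max_iter,
            L=config.reduced_length,
        )
        instances = classify.frame_instances(vectors, labels)
        for clf in config.classifiers:
            reports[(alg, clf)] = classify.cross_validate(
                instances,
                clf,
                folds=config.folds,
                seed=config.seed,
                targets=targets,
            )
    return classify.reports_to_frame(reports)


def write_report(
    report: pd.DataFrame, path, config: RunConfig | None = None
) -> None:
    """Write the report CSV with a provenance header comment."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        report.to_csv(fh, index=False, float_format="%.6f")
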