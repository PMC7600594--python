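from pathlib import Path

import numpy as np
import pytest

from ppgfuzz import fuzzy, pipeline, synthetic

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def example_window_words() -> list[str]:
    """The published two-minute example window of 60 code words."""
    return (DATA_DIR / "table5_codewords.txt").read_text().split()


@pytest.fixture(scope="session")
def fuzzifiers():
    return fuzzy.build_fuzzifiers()


@pytest.fixture(scope="session")
def fam():
    return fuzzy.default_fam()


@pytest.fixture(scope="session")
def small_spec() -> synthetic.SynthSpec:
    """A reduced cohort (full segment counts are exercised elsewhere)."""
    return synthetic.SynthSpec(n_normal=3, n_cvd=3, n_segments=60, seed=7)


@pytest.fixture(scope="session")
def small_streams(small_spec):
    records, _ = synthetic.generate_cohort(small_spec)
    table = pipeline.extract_cohort_features(records)
    return pipeline.encode_features(table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
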