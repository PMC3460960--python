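"""Shared fixtures: small synthetic datasets preprocessed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bloodmirna.preprocess import PreprocessConfig, run_preprocess
from bloodmirna.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale study: 200 probes, planted effects of every kind."""
    return SyntheticConfig(
        n_probes=200,
        n_empty_spots=100,
        n_de_probes=20,
        n_age_probes=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """(dataset, matrix, empty_summaries) after full pre-processing."""
    matrix, empty = run_preprocess(
        small_dataset.spot_tables, small_dataset.panel, PreprocessConfig()
    )
    return small_dataset, matrix, empty


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null study: no DE, no dye bias, no age effect, no pair."""
    cfg = SyntheticConfig(
        n_probes=150,
        n_empty_spots=80,
        n_de_probes=0,
        n_age_probes=0,
        planted_pair=False,
        dye_bias_amplitude=0.0,
        seed=21,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_pipeline(null_dataset):
    matrix, empty = run_preprocess(
        null_dataset.spot_tables, null_dataset.panel, PreprocessConfig()
    )
    return null_dataset, matrix, empty


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_log2_matrix(rng) -> pd.DataFrame:
    """30 probes × 24 samples of unstructured log2 signals."""
    probes = [f"p{i:03d}" for i in range(30)]
    samples = [f"s{i:02d}" for i in range(24)]
    return pd.DataFrame(
        rng.normal(7.0, 1.0, size=(30, 24)), index=probes, columns=samples
    )


@pytest.fixture()
def balanced_classes() -> np.ndarray:
    return np.array(["case"] * 12 + ["control"] * 12)
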