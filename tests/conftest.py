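"""Shared fixtures: a small synthetic benchmark, reused across the suite.

The benchmark fixture uses short trials (2 s short-term, 8 s endurance) so
the whole suite stays fast; the acceptance tests regenerate the full
default-length benchmark themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

import emgmodes as em


@pytest.fixture(scope="session")
def small_config() -> em.SynthConfig:
    return em.SynthConfig(seed=7, trial_s=2.0, endurance_trial_s=8.0)


@pytest.fixture(scope="session")
def small_benchmark(small_config) -> em.Benchmark:
    return em.generate_benchmark(small_config)


@pytest.fixture(scope="session")
def features_cache(small_benchmark):
    """Lazily extracted feature tables of the small benchmark, by
    (feature_set, session) key."""
    cache: dict[tuple[str, str], em.LabeledDataset] = {}

    def get(feature_set: str, session: str = "short_term") -> em.LabeledDataset:
        key = (feature_set, session)
        if key not in cache:
            trials = (
                small_benchmark.short_term
                if session == "short_term"
                else small_benchmark.endurance
            )
            cache[key] = em.extract_features(trials, feature_set=feature_set)
        return cache[key]

    return get


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_array() -> em.ElectrodeArray:
    return em.ElectrodeArray(
        name="test",
        n_rows=4,
        n_cols=5,
        muscle_masks={"m": {(r, c) for r in range(4) for c in range(5)}},
        diff_pairs={"m": ((1, 2), (1, 3))},
    )
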