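import warnings

import numpy as np
import pytest
from numpy.random import default_rng

from gigglekit.features import extract_dataset_features, individual_profile
from gigglekit.synth import (
    SynthesisConfig,
    make_population,
    population_frame,
    simulate_note_features,
    write_dataset,
)


@pytest.fixture(scope="session")
def default_config() -> SynthesisConfig:
    return SynthesisConfig(seed=7)


@pytest.fixture(scope="session")
def population(default_config):
    return make_population(default_config)


@pytest.fixture(scope="session")
def metadata(population):
    return population_frame(population)


@pytest.fixture(scope="session")
def twin_features(population, default_config):
    """Statistical-twin feature table: 17 animals x 40 notes."""
    return simulate_note_features(
        population, default_config, default_rng(1234), notes_per_animal=40
    )


@pytest.fixture(scope="session")
def twin_profiles(twin_features):
    return individual_profile(twin_features)


@pytest.fixture(scope="session")
def audio_dataset(tmp_path_factory):
    """A small written-and-refeaturised audio dataset (4 animals, 1 dyad
    each of dominant/subordinate pairs, >= 22 notes per animal)."""
    colony = [
        ("a1", "female", 6, "dominant", "control", 1, 22),
        ("a2", "male", 6, "subordinate", "control", 1, 22),
        ("a3", "female", 12, "dominant", "anti_androgen", 2, 22),
        ("a4", "male", 12, "subordinate", "anti_androgen", 2, 22),
    ]
    cfg = SynthesisConfig(seed=21)
    pop = make_population(cfg, colony=colony)
    root = tmp_path_factory.mktemp("dataset")
    meta, segments = write_dataset(pop, cfg, root)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = extract_dataset_features(root, segments)
    return {
        "root": root,
        "config": cfg,
        "population": pop,
        "metadata": meta,
        "segments": segments,
        "features": features,
    }
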