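import datetime as dt

import numpy as np
import pytest

from murisomnia.io import Hypnogram
from murisomnia.synth import GeneratorConfig

NOON = dt.datetime(2015, 1, 1, 12, 0)
NIGHT = dt.datetime(2015, 1, 1, 21, 0)
EVENING = dt.datetime(2015, 1, 1, 20, 0)


@pytest.fixture
def balanced_config() -> GeneratorConfig:
    """A both-phase config with comfortable kernel margins."""
    return GeneratorConfig(
        group_label="test",
        state_fractions={
            "light": {"W": 0.34, "NR": 0.57, "R": 0.09},
            "dark": {"W": 0.55, "NR": 0.386, "R": 0.064},
        },
        mean_bout_s={
            "light": {"W": 52.6, "NR": 80.5, "R": 72.6},
            "dark": {"W": 162.3, "NR": 100.3, "R": 69.9},
        },
    )


@pytest.fixture
def signal_config(balanced_config) -> GeneratorConfig:
    from dataclasses import replace

    return replace(balanced_config, fidelity="signal")


def make_hypnogram(states, start=NOON, epoch_s=5.0, subject="s1") -> Hypnogram:
    return Hypnogram(states=np.array(states, dtype="U2"), start_time=start,
                     epoch_s=epoch_s, subject_id=subject)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
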