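import numpy as np
import pytest

from ern.io import LabelRecord, RawTrialSet
from ern.synthetic import SynthSpec, generate_deap_like, generate_seed4_like


@pytest.fixture(scope="session")
def deap_like_small() -> RawTrialSet:
    """Eight short DEAP-like trials (7 s: 3 s baseline + 4 s stimulus)."""
    return generate_deap_like(
        SynthSpec(n_trials=8, trial_seconds=7.0, seed=11)
    )


@pytest.fixture(scope="session")
def seed4_like_small() -> RawTrialSet:
    """2 subjects x 3 sessions x 4 clips = 24 one-second clips."""
    return generate_seed4_like(
        SynthSpec(n_subjects=2, n_trials=4, trial_seconds=1.0,
                  baseline_seconds=0.0, seed=12)
    )


@pytest.fixture(scope="session")
def tiny_topo_dataset():
    """A small labelled topographic dataset with a learnable class signal."""
    from ern.topology import assemble_dataset

    trials = generate_seed4_like(
        SynthSpec(n_subjects=2, n_trials=5, trial_seconds=1.0,
                  baseline_seconds=0.0, class_effect=2.0, seed=13)
    )
    return assemble_dataset(trials)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(valence=None, arousal=None, categorical=None) -> LabelRecord:
    return LabelRecord(valence=valence, arousal=arousal, categorical=categorical)
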