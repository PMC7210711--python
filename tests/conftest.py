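import dataclasses

import pytest

from thermotol import SyntheticConfig, compress_time, generate_experiment
from thermotol.pipeline import estimates_from_truth

#: default-noise design with every knock-down time scaled by 1/60 so that
#: full 3 Hz traces stay small; detection fidelity is scale-invariant.
TRACE_SCALE = 1.0 / 60.0


@pytest.fixture(scope="session")
def compressed_config():
    return compress_time(SyntheticConfig(seed=11), TRACE_SCALE)


@pytest.fixture(scope="session")
def traced_experiment(compressed_config):
    """Full 280-subject experiment with simulated velocity traces."""
    return generate_experiment(compressed_config, with_traces=True)


@pytest.fixture(scope="session")
def default_experiment():
    """Full-scale default experiment (no traces) plus error-free estimates."""
    cfg = SyntheticConfig(seed=7)
    runs, subjects, _, truths = generate_experiment(cfg, with_traces=False)
    estimates = estimates_from_truth(subjects, truths)
    return cfg, runs, subjects, estimates, truths


def tiny_config(**overrides):
    """A small, fast experiment: 3 temperatures, 6 runs, 48 subjects."""
    base = dict(
        temperatures=(36.0, 38.0, 40.0),
        runs_per_temperature=(2, 2, 2),
        subjects_per_run=8,
        n_beakers=4,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
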