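"""Shared fixtures.

The two end-to-end training fixtures are session-scoped because a full
scaled protocol takes minutes; every test that needs a trained network reads
from the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from famcirc.runner import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest structurally complete experiment: 2x2 grid x 8 channels."""
    from famcirc.circuit import NetworkConfig

    return ExperimentConfig(
        protocol="familiarity",
        network=NetworkConfig(n_rows=2, n_cols=2, n_channels=8, w_ie=30.0),
        epochs=2,
        probe_interval=1,
        n_targets=3,
        image_side=12,
        dict_patches=200,
        dict_iter=4,
        encode_sparsity=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def familiarity_run():
    """Three replicate scaled-down Hebbian familiarity runs.

    The scaled network has ~8x fewer neurons than the full-scale protocol,
    so a single run retains only ~10-25 responsive neurons; pooling the
    retained populations of three independent stimulus draws restores a
    population size on which the familiarity statistics are meaningful.
    Returns a list of (config, probes) pairs, one per replicate.
    """
    runs = []
    for seed in (1, 2, 3):
        cfg = ExperimentConfig.familiarity_scaled(seed=seed)
        runs.append((cfg, list(run_experiment(cfg))))
    return runs


@pytest.fixture(scope="session")
def association_run():
    """Scaled-down Hebbian association protocol with periodic probes.

    Returns (config, probes, prepared experiment); the probes carry weight
    snapshots so trained networks can be rebuilt for linear analysis.
    """
    from famcirc.runner import _train, prepare_experiment

    cfg = ExperimentConfig.association_scaled(seed=1, store_weights=True)
    exp = prepare_experiment(cfg)
    probes = list(_train(exp))
    return cfg, probes, exp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
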