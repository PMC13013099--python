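"""Shared fixtures.

The expensive fixtures (trained tiny networks) are session-scoped and built
once: the small-object-tracking recovery study on both topologies, the
latent-trajectory classification study, and a directory of ultra-tiny sweep
checkpoints.
"""

import numpy as np
import pytest

GRID_COMBOS = [("perturbed", None), ("context", "threshold")]
GRID_CMAX = [0.0, 1.0 / 3.0, 1.0]
GRID_LEVELS = [0.0, 2.0 / 3.0, 1.0]
GRID_SEEDS = [0, 1]


@pytest.fixture(scope="session")
def recovery_rec():
    """Tiny recurrent SOT recovery study: 3 seeds, both modulation modes."""
    from contextsnn.experiments import RecoveryConfig, recovery_experiment

    return recovery_experiment(RecoveryConfig(topology="recurrent"))


@pytest.fixture(scope="session")
def recovery_ff():
    """The same study on the feedforward topology."""
    from contextsnn.experiments import RecoveryConfig, recovery_experiment

    return recovery_experiment(RecoveryConfig(topology="feedforward"))


@pytest.fixture(scope="session")
def latent_result():
    """Tiny recurrent classification study with latent-trajectory records."""
    from contextsnn.experiments import LatentConfig, latent_experiment

    return latent_experiment(LatentConfig())


@pytest.fixture(scope="session")
def grid_checkpoints(tmp_path_factory):
    """Ultra-tiny trained checkpoints spanning a 2-variant x 3-level x
    2-seed sweep, plus the hold-out evaluation data."""
    from contextsnn.experiments import train_grid_checkpoints

    ckpt_dir = tmp_path_factory.mktemp("grid_ckpts")
    frames, labels = train_grid_checkpoints(
        ckpt_dir, GRID_COMBOS, GRID_CMAX, GRID_SEEDS, epochs=2, base_seed=0,
    )
    return ckpt_dir, frames, labels
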