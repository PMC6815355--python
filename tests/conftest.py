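"""Shared fixtures: small phantoms and trial tables generated at test time."""

import numpy as np
import pandas as pd
import pytest

from dceperf import SynthImagingConfig, SynthTrialConfig, generate_dce_volume, generate_trial


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free phantom with all four classes present (200 in-mask voxels)."""
    cfg = SynthImagingConfig(
        grid_dims=(12, 12, 2), pattern_mix=(0.4, 0.2, 0.2, 0.2), noise_sd=0.0, seed=1
    )
    return cfg, *generate_dce_volume(cfg)


@pytest.fixture(scope="session")
def trial_table():
    """Default-scale synthetic trial (16 ET / 17 CG), with change columns added."""
    cfg = SynthTrialConfig(n_per_arm=16, n_control=17, seed=11)
    table, truth = generate_trial(cfg)
    return table, truth


def add_changes(table: pd.DataFrame, outcomes) -> pd.DataFrame:
    out = table.copy()
    for o in outcomes:
        out[f"{o}_change"] = out[f"{o}_followup"] - out[f"{o}_baseline"]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
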