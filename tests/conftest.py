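import numpy as np
import pytest

import photolick as pl


@pytest.fixture(scope="session")
def default_params() -> pl.BehaviorParams:
    return pl.BehaviorParams()


@pytest.fixture(scope="session")
def default_truth() -> pl.PhotometryGroundTruth:
    return pl.PhotometryGroundTruth()


@pytest.fixture(scope="session")
def whisker_session(default_params):
    """One deterministic whisker-detection behavioral session (30 trials)."""
    cfg = pl.TaskConfig.for_task("whisker_detection")
    events, latent = pl.simulate_behavior(cfg, default_params, 30, seed=1234)
    return cfg, events, latent


@pytest.fixture(scope="session")
def rendered_free_session(default_params):
    """A free-licking session rendered to ideal 1 kHz traces (no satiety)."""
    cfg = pl.TaskConfig.for_task("free_licking")
    params = pl.BehaviorParams(satiety_tau=None)
    truth = pl.PhotometryGroundTruth(bleach_tau_465=600.0, bleach_tau_405=600.0)
    events, latent = pl.simulate_behavior(cfg, params, 60, seed=77)
    traces, gt = pl.render_fluorescence(events, truth, latent, seed=78)
    return cfg, events, latent, truth, traces, gt
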