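import numpy as np
import pytest

from trfaad.evaluate import TRFSettings
from trfaad.pipeline import prepare_session
from trfaad.synth import SimulationConfig, default_ground_truth, synthesize_session
from trfaad.trf import BoostingConfig


def small_sim_config(**overrides) -> SimulationConfig:
    """Reduced-scale simulation: few channels, shortened trials.

    Switch windows are scaled down with the trial duration so the SwitAC
    protocol still fits.
    """
    defaults = dict(
        n_scalp_channels=6,
        n_ceegrid_channels=8,  # smallest grid containing the L4/R4 references
        trial_duration=60.0,
        trial_counts={"SustAC": 2, "SwitAC": 2, "ConvAC": 2},
        switch_window_1=(12.0, 18.0),
        switch_window_2=(35.0, 45.0),
        snr_db=10.0,
        attention_gain=0.5,
        seed=0,
    )
    if "trial_duration" in overrides:
        # keep the switch protocol inside the trial unless windows are given
        scale = overrides["trial_duration"] / defaults["trial_duration"]
        for key in ("switch_window_1", "switch_window_2"):
            if key not in overrides:
                lo, hi = defaults[key]
                defaults[key] = (lo * scale, hi * scale)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def fast_settings(**overrides) -> TRFSettings:
    """Boosting settings sized for unit tests (coarse but quick)."""
    defaults = dict(
        lag_range=(-0.2, 0.6),
        boosting=BoostingConfig(step_size=0.02, partitions=2, patience=10,
                                max_steps=2000),
    )
    defaults.update(overrides)
    return TRFSettings(**defaults)


@pytest.fixture(scope="session")
def mini_session():
    """Raw reduced-scale session shared across tests (read-only)."""
    cfg = small_sim_config()
    return cfg, synthesize_session(cfg, seed=0)


@pytest.fixture(scope="session")
def mini_prepared(mini_session):
    """Preprocessed version of the shared mini session (read-only)."""
    cfg, session = mini_session
    return cfg, prepare_session(session)
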