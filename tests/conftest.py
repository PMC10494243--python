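import numpy as np
import pytest

from isletnet import (
    IsletConfig,
    Protocol,
    Segment,
    StudyConfig,
    generate_islet,
    glucose_control_protocol,
)


@pytest.fixture(scope="session")
def control_protocol():
    """Full-length square-pulse glucose protocol (25 min stimulation)."""
    return glucose_control_protocol()


@pytest.fixture(scope="session")
def fast_protocol():
    """Shortened protocol for smoke tests: 2 min pre, 10 min stim, 4 min post."""
    return Protocol(
        [
            Segment("6mM glucose", 0.0, 120.0),
            Segment("12mM glucose", 120.0, 720.0, True, 0.033, 10.7),
            Segment("6mM washout", 720.0, 960.0),
        ]
    )


@pytest.fixture(scope="session")
def fast_study_config():
    return StudyConfig(settle_s=120.0, interval_len_s=180.0, second_offset_s=60.0)


@pytest.fixture(scope="session")
def fast_islet(fast_protocol):
    """One small noisy islet plus its ground truth (session-cached)."""
    cfg = IsletConfig(n_cells=12, seed=42, deact_delay_median_s=120.0)
    return generate_islet(cfg, fast_protocol)


@pytest.fixture(scope="session")
def quiet_islet(fast_protocol):
    """Noise-free, bleach-free small islet for exact checks."""
    cfg = IsletConfig(
        n_cells=10, seed=7, noise_sd=0.0, bleach_tau_s=np.inf,
        bleach_slope_per_s=0.0, deact_delay_median_s=120.0,
    )
    return generate_islet(cfg, fast_protocol)
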