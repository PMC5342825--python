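import numpy as np
import pytest

from flpstop_pipeline import SimConfig, StimulusSpec


@pytest.fixture
def small_cfg() -> SimConfig:
    """Three genotypes × M5, 2 ROIs each, 6 light flashes — fast but complete."""
    return SimConfig(seed=11, n_rois=2, n_trials=6)


@pytest.fixture
def noiseless_cfg() -> SimConfig:
    """Deterministic signal: no noise, no per-ROI parameter jitter."""
    return SimConfig(
        seed=5, noise_sd=0.0, bleach_jitter_cv=0.0, n_rois=1, n_trials=4,
        conditions=[("no_flp_control", "M5")],
    )


@pytest.fixture
def flash_spec() -> StimulusSpec:
    return StimulusSpec.flash_off_gray()
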