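import numpy as np
import pytest

from meagamma.synth import OscSpec, SimConfig, make_layout, simulate_recording


@pytest.fixture(scope="session")
def layout():
    return make_layout()


@pytest.fixture(scope="session")
def quick_cfg():
    """Small, fast config: 2 kHz sampling, short epochs, immediate onset."""
    return SimConfig(
        seed=7, fs_hz=2000.0, duration_vehicle_s=10.0, duration_drug_s=60.0,
        duration_antagonist_s=10.0,
        osc={"CA1": OscSpec(peak_hz=30.0, bandwidth_hz=10.0, amplitude_uv=20.0),
             "CA3": OscSpec(peak_hz=21.0, bandwidth_hz=16.0, amplitude_uv=25.0)},
        onset_a_per_min=50.0, onset_b_min=0.02, w_within=0.1, w_between=0.04,
        noise_sd_uv=5.0, antagonist_tau_s=5.0)


@pytest.fixture(scope="session")
def quick_recording(quick_cfg, layout):
    return simulate_recording(quick_cfg, layout, slice_id="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
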