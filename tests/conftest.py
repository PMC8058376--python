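import numpy as np
import pytest

from qeeg_mcao import PipelineConfig, analyze_recording
from qeeg_mcao.synthetic_data import generate_recording, phase_presets


@pytest.fixture(scope="session")
def default_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def presets_nojitter():
    return phase_presets(jitter_sigma=0.0)


def session_indices(profile, seed, cfg, duration_s=300.0, rate_hz=1000.0):
    """Generate one synthetic session and push it through the full chain."""
    rec = generate_recording(profile, duration_s=duration_s, rate_hz=rate_hz, seed=seed)
    _, qi, _ = analyze_recording(rec, cfg)
    return qi


@pytest.fixture(scope="session")
def isp_cohort_indices(presets_nojitter, default_cfg):
    """Six jitter-free 5-min sessions from the calibrated ischemic preset."""
    return [session_indices(presets_nojitter["isp"], np.random.SeedSequence([1, k]),
                            default_cfg) for k in range(1, 7)]


@pytest.fixture(scope="session")
def irp_cohort_indices(presets_nojitter, default_cfg):
    """Six jitter-free 5-min sessions from the calibrated reperfusion preset."""
    return [session_indices(presets_nojitter["irp"], np.random.SeedSequence([1, k]),
                            default_cfg) for k in range(1, 7)]
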