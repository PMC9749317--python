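import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vpctrace import (
    WaveformParams,
    default_layout,
    generate_waveform,
    render_ecg_image,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free rendered record with full ground truth."""
    params = WaveformParams()  # noise_sd = 0, no wander
    signals = generate_waveform(params, rng_seed=7)
    return render_ecg_image(signals, record_id="R0", patient_id="P0")


@pytest.fixture(scope="session")
def clean_records_10():
    rng = np.random.default_rng(11)
    out = []
    for i in range(10):
        hr = float(rng.uniform(55, 95))
        label = "VPC" if i % 2 else "NOR"
        params = WaveformParams(heart_rate_bpm=hr, class_label=label)
        signals = generate_waveform(params, rng_seed=int(rng.integers(2**31)))
        out.append(render_ecg_image(signals, record_id=f"R{i}", patient_id=f"P{i}",
                                    label=label))
    return out
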