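import numpy as np
import pytest

from pa_ssid.modal import ModalParameters
from pa_ssid.signal import PASignal
from pa_ssid.synthetic import SimulationConfig, modal_impulse_response


@pytest.fixture
def default_params() -> ModalParameters:
    return ModalParameters(alpha=5e-7, omega_n=3e7, c1=1.0, c2=0.5)


@pytest.fixture
def clean_signal(default_params) -> PASignal:
    """Noise-free second-order trace over the standard 1.2 us / 10 ns window."""
    y = modal_impulse_response(default_params, ts=10e-9, n_points=120)
    return PASignal(samples=y, ts=10e-9, t0=0.0)


@pytest.fixture
def noisy_config() -> SimulationConfig:
    return SimulationConfig(snr_db=30, seed=0)


def series_expm(M: np.ndarray, order: int = 60) -> np.ndarray:
    """Brute-force matrix exponential by truncated Taylor series (test oracle,
    independent of scipy.linalg.expm)."""
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, order + 1):
        term = term @ M / k
        out = out + term
    return out
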