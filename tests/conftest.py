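import warnings

import numpy as np
import pytest

import koopgait as kg

# Every decomposition here is intentional about truncation; rank-clamp
# warnings from degenerate fixtures are expected and not under test.
warnings.filterwarnings("ignore", message=".*clamped")


@pytest.fixture
def rotation_series():
    """y_t = [cos(πt/2), sin(πt/2)]: the 90° rotation linear system."""
    A = np.array([[0.0, -1.0], [1.0, 0.0]])
    return kg.simulate_linear_system(A, [1.0, 0.0], 8, dt=1.0)


@pytest.fixture
def linear_system_3d():
    """Diagonalizable 3-D system: one rotation pair plus a decaying mode."""
    th = 0.3
    A = np.array(
        [
            [np.cos(th), -np.sin(th), 0.0],
            [np.sin(th), np.cos(th), 0.0],
            [0.0, 0.0, 0.9],
        ]
    )
    return A, kg.simulate_linear_system(A, [1.0, 0.5, 1.0], 50, dt=1.0)


@pytest.fixture(scope="session")
def clean_gait():
    """Noise-free 3-channel, 5-harmonic gait signal (f0 = 0.8 Hz, 100 Hz)."""
    return kg.generate_harmonic_gait(kg.GaitGeneratorConfig(duration=30.0))


@pytest.fixture(scope="session")
def noisy_gait():
    """Same signal at 20 dB SNR, seeded."""
    coeff = kg.default_gait_coefficients()
    sd = kg.noise_sd_for_snr(coeff, 20.0)
    return kg.generate_harmonic_gait(
        kg.GaitGeneratorConfig(noise_sd=sd, seed=1, duration=30.0)
    )


@pytest.fixture(scope="session")
def gait_params():
    """Cycle geometry of the gait fixtures: (T frames, f0 Hz, dt s)."""
    return 125, 0.8, 0.01
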