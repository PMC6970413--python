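import numpy as np
import pytest

from mre_ela import simulate_wave_series, waves
from mre_ela.synthetic import WaveSimConfig

# interior window: spectral filtering distorts a band near the image border
# (finite-aperture convolution); comparisons of whole fields use this margin
INTERIOR = (slice(16, 112), slice(16, 112))


def l2(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.abs(a) ** 2)))


def harmonic_field(pos, neg):
    """Phase difference -> unwrap -> temporal first harmonic."""
    return waves.temporal_harmonic(waves.unwrap_phase(waves.phase_difference(pos, neg)))


@pytest.fixture(scope="session")
def lossless_wave():
    """Noise-free lossless bottom-to-top wave plus its ground truth."""
    cfg = WaveSimConfig(
        true_modulus_map=3000 + 0j,
        noise_sd=0.0,
        background_scale=0.0,
        encoding_gain=0.4,
        seed=2,
    )
    pos, neg, truth = simulate_wave_series(cfg, source_edge="bottom")
    return cfg, pos, neg, truth


@pytest.fixture(scope="session")
def viscous_wave():
    """Noise-free attenuating wave (G* = 3000+1000i Pa)."""
    cfg = WaveSimConfig(true_modulus_map=3000 + 1000j, noise_sd=0.0, seed=1)
    pos, neg, truth = simulate_wave_series(cfg, source_edge="bottom")
    return cfg, pos, neg, truth
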