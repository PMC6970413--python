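"""Tests of the phase-processing chain: MSG subtraction, unwrapping,
temporal harmonic extraction and the two spectral filters."""

import numpy as np
import pytest

from mre_ela import simulate_wave_series, waves
from mre_ela.containers import ComplexWaveField, PhaseImageSeries
from mre_ela.synthetic import WaveSimConfig, wrap_phase
from .conftest import INTERIOR, harmonic_field, l2


def series(data, msg_sign=1, wrapped=True, h=0.025 / 128):
    return PhaseImageSeries(
        data=data, msg_sign=msg_sign, drive_frequency=900.0, pixel_spacing=h, wrapped=wrapped
    )


class TestPhaseDifference:
    def test_pure_static_phase_cancels(self):
        bg = np.random.default_rng(0).normal(size=(16, 16, 4)) * 0.3
        out = waves.phase_difference(series(bg, +1), series(bg, -1))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-15)

    def test_antisymmetric_encoding_doubles(self):
        bg = 0.7
        pos = series(np.full((8, 8, 4), 0.3 + bg))
        neg = series(np.full((8, 8, 4), -0.3 + bg), msg_sign=-1)
        out = waves.phase_difference(pos, neg)
        np.testing.assert_allclose(out.data, 0.6, atol=1e-15)

    def test_polynomial_background_removed_exactly(self):
        """Simulator background is static: the ±MSG difference equals twice
        the encoded motion regardless of the background amplitude."""
        kw = dict(true_modulus_map=3000 + 800j, noise_sd=0.0, encoding_gain=0.5, seed=9)
        pos_a, neg_a, truth = simulate_wave_series(WaveSimConfig(background_scale=0.9, **kw))
        pos_b, neg_b, _ = simulate_wave_series(WaveSimConfig(background_scale=0.0, **kw))
        da = waves.phase_difference(pos_a, neg_a)
        db = waves.phase_difference(pos_b, neg_b)
        np.testing.assert_allclose(da.data, db.data, atol=1e-12)
        u0 = np.real(truth.total_field)
        np.testing.assert_allclose(da.data[:, :, 0], 2 * 0.5 * u0, atol=1e-12)

    def test_mismatches_rejected(self):
        pos = series(np.zeros((8, 8, 4)))
        with pytest.raises(ValueError, match="shape"):
            waves.phase_difference(pos, series(np.zeros((8, 10, 4)), -1))
        with pytest.raises(ValueError, match="MSG"):
            waves.phase_difference(pos, series(np.zeros((8, 8, 4)), +1))
        bad_freq = PhaseImageSeries(np.zeros((8, 8, 4)), -1, 450.0, 0.025 / 128)
        with pytest.raises(ValueError, match="frequency"):
            waves.phase_difference(pos, bad_freq)


class TestUnwrap:
    def test_smooth_in_range_is_identity(self):
        rng = np.random.default_rng(1)
        smooth = 0.8 * np.sin(np.linspace(0, 3, 32))[:, None, None] * np.ones((1, 32, 4))
        out = waves.unwrap_phase(series(smooth))
        np.testing.assert_allclose(out.data, smooth, atol=1e-12)
        assert not out.wrapped

    def test_linear_ramp_recovered_modulo_global_offset(self):
        """A noise-free ramp reaching 4*pi is restored up to one global
        2*pi*m constant per frame."""
        ramp = np.linspace(0, 4 * np.pi, 64)[:, None] * np.ones((1, 64))
        frames = np.repeat(wrap_phase(ramp)[:, :, None], 4, axis=2)
        out = waves.unwrap_phase(series(frames))
        for j in range(4):
            resid = out.data[:, :, j] - ramp
            offset = resid.flat[0]
            assert offset / (2 * np.pi) == pytest.approx(round(offset / (2 * np.pi)), abs=1e-9)
            np.testing.assert_allclose(resid, offset, atol=1e-9)

    def test_idempotent_on_unwrapped_range(self):
        data = 0.5 * np.cos(np.linspace(0, 5, 24))[:, None, None] * np.ones((1, 24, 4))
        once = waves.unwrap_phase(series(data))
        twice = waves.unwrap_phase(series(once.data, wrapped=True))
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)


class TestTemporalHarmonic:
    def make(self, tc):  # tc: function of omega*t -> (rows, cols) image
        wt = 2 * np.pi * np.arange(8) / 8
        data = np.stack([tc(w) for w in wt], axis=2)
        return PhaseImageSeries(data, 0, 900.0, 0.025 / 128, wrapped=False)

    def test_cosine_normalisation(self):
        out = waves.temporal_harmonic(self.make(lambda w: np.full((4, 4), 5 * np.cos(w))))
        np.testing.assert_allclose(out.data, 5.0 + 0j, atol=1e-12)

    def test_dc_rejected(self):
        out = waves.temporal_harmonic(self.make(lambda w: np.full((4, 4), 3.7)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_phase_convention(self):
        """3 + 2 cos(wt + pi/3) -> 2 exp(i pi/3), checked against the 8-point
        DFT evaluated directly."""
        out = waves.temporal_harmonic(
            self.make(lambda w: np.full((2, 2), 3 + 2 * np.cos(w + np.pi / 3)))
        )
        np.testing.assert_allclose(out.data, 2 * np.exp(1j * np.pi / 3), atol=1e-12)
        # independent oracle: explicit sum
        wt = 2 * np.pi * np.arange(8) / 8
        sig = 3 + 2 * np.cos(wt + np.pi / 3)
        oracle = (2 / 8) * np.sum(sig * np.exp(-1j * wt))
        np.testing.assert_allclose(out.data[0, 0], oracle, atol=1e-12)

    def test_random_amplitude_phase_machine_precision(self):
        rng = np.random.default_rng(12)
        wt = 2 * np.pi * np.arange(8) / 8
        for _ in range(50):
            A, th = rng.uniform(0.1, 5.0), rng.uniform(-np.pi, np.pi)
            out = waves.temporal_harmonic(
                self.make(lambda w, A=A, th=th: np.full((2, 2), A * np.cos(w + th)))
            )
            np.testing.assert_allclose(out.data, A * np.exp(1j * th), atol=1e-12)

    def test_too_few_dynamics_rejected(self):
        with pytest.raises(ValueError):
            PhaseImageSeries(np.zeros((4, 4, 3)), 0, 900.0, 1e-4)


def plane_field(k_cpm, h=0.025 / 128, n=128):
    """Plane wave along columns with spatial frequency k (cycles/m)."""
    x = np.arange(n) * h
    data = np.exp(-2j * np.pi * k_cpm * x)[None, :] * np.ones((n, 1))
    return ComplexWaveField(data, 900.0, h)


class TestButterworth:
    def test_passband_centre_preserved(self):
        f = plane_field(np.sqrt(50.0 * 800.0))
        out = waves.butterworth_bandpass(f, k_low=50.0, k_high=800.0)
        ratio = l2(out.data[INTERIOR]) / l2(f.data[INTERIOR])
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_dc_zeroed_when_highpass_on(self):
        f = ComplexWaveField(np.full((64, 64), 2.0 + 1.0j), 900.0, 0.025 / 128)
        out = waves.butterworth_bandpass(f, k_low=50.0, k_high=800.0)
        assert l2(out.data) < 1e-12

    def test_half_amplitude_at_k_high(self):
        f = plane_field(800.0)
        out = waves.butterworth_bandpass(f, k_low=50.0, k_high=800.0)
        ratio = l2(out.data[INTERIOR]) / l2(f.data[INTERIOR])
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_never_increases_energy(self, viscous_wave):
        _, pos, neg, _ = viscous_wave
        u = harmonic_field(pos, neg)
        out = waves.butterworth_bandpass(u, k_low=20.0, k_high=1500.0)
        assert np.sum(np.abs(out.data) ** 2) <= np.sum(np.abs(u.data) ** 2) * (1 + 1e-12)

    def test_bad_cutoffs_rejected(self):
        f = plane_field(100.0)
        with pytest.raises(ValueError):
            waves.butterworth_bandpass(f, k_low=500.0, k_high=100.0)
        with pytest.raises(ValueError):
            waves.butterworth_bandpass(f, order=0)


class TestDirectionalFilter:
    def test_forward_wave_passes(self, lossless_wave):
        _, pos, neg, _ = lossless_wave
        u = harmonic_field(pos, neg)
        out = waves.directional_filter(u, "bottom_to_top")
        err = l2(out.data[INTERIOR] - u.data[INTERIOR]) / l2(u.data[INTERIOR])
        assert err <= 0.01

    def test_counter_wave_suppressed(self):
        cfg = WaveSimConfig(
            true_modulus_map=3000 + 0j, noise_sd=0.0, background_scale=0.0,
            encoding_gain=0.4, seed=2,
        )
        pos, neg, _ = simulate_wave_series(cfg, source_edge="top")  # top-to-bottom wave
        u = harmonic_field(pos, neg)
        out = waves.directional_filter(u, "bottom_to_top")
        assert l2(out.data[INTERIOR]) / l2(u.data[INTERIOR]) <= 0.01

    def test_superposition_recovers_forward_component(self):
        """forward + 0.5 reflected -> directional filter isolates the stored
        forward component."""
        cfg = WaveSimConfig(
            true_modulus_map=3000 + 1000j, noise_sd=0.0, background_scale=0.0,
            reflection_coefficient=0.5, seed=3,
        )
        pos, neg, truth = simulate_wave_series(cfg, "bottom")
        u = harmonic_field(pos, neg)
        out = waves.directional_filter(u, "bottom_to_top")
        fwd = 2 * cfg.encoding_gain * truth.forward_field
        err = l2(out.data[INTERIOR] - fwd[INTERIOR]) / l2(fwd[INTERIOR])
        assert err <= 0.05

    def test_linearity(self, viscous_wave):
        _, pos, neg, _ = viscous_wave
        u = harmonic_field(pos, neg)
        a = 2.5 - 1.25j
        scaled = ComplexWaveField(a * u.data, u.drive_frequency, u.pixel_spacing)
        f1 = waves.directional_filter(scaled).data
        f2 = a * waves.directional_filter(u).data
        np.testing.assert_allclose(f1, f2, atol=1e-10 * np.abs(f2).max())

    def test_unknown_direction_rejected(self, lossless_wave):
        _, pos, neg, _ = lossless_wave
        u = harmonic_field(pos, neg)
        with pytest.raises(ValueError):
            waves.directional_filter(u, "diagonal")


class TestProvenance:
    def test_pipeline_order_recorded(self, viscous_wave):
        _, pos, neg, _ = viscous_wave
        u = harmonic_field(pos, neg)
        out = waves.directional_filter(waves.butterworth_bandpass(u))
        assert out.provenance[0] == "temporal_harmonic"
        assert out.provenance[1].startswith("butterworth_bandpass")
        assert out.provenance[2].startswith("directional_filter")
        # append-only: the input field's provenance is untouched
        assert len(u.provenance) == 1
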