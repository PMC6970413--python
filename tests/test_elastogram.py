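"""Tests of the Helmholtz inversion, ROI handling and regional summaries."""

import numpy as np
import pytest

from mre_ela import (
    Elastography,
    helmholtz_invert,
    normalize_to_controls,
    simulate_two_region_phantom,
    simulate_wave_series,
    split_anterior_posterior,
    stencil_bias_factor,
    summarize_roi,
)
from mre_ela.config import FilterConfig, InversionConfig
from mre_ela.containers import ComplexWaveField, ElastogramMaps, ViscoSummary
from mre_ela.synthetic import WaveSimConfig, shear_wavenumber


def uniform_maps(g, n=32, density=1000.0):
    return ElastogramMaps(
        gstar=np.full((n, n), complex(g)),
        valid_mask=np.ones((n, n), bool),
        density=density,
        drive_frequency=900.0,
    )


class TestHelmholtzInversion:
    def test_plane_wave_closed_form(self):
        """U = exp(-ikx) with k = omega sqrt(rho/G) inverts to G = rho w^2/k^2;
        the discrete stencil bias is removed by the correction."""
        G, rho, f = 3000.0, 1000.0, 900.0
        h = 0.025 / 128
        k = shear_wavenumber(G, rho, f)  # real for lossless G
        x = np.arange(128) * h
        u = np.exp(-1j * k * x)[:, None] * np.ones((1, 128))
        field = ComplexWaveField(u, f, h)
        raw = helmholtz_invert(field, rho, stencil_correction=False)
        corr = helmholtz_invert(field, rho, stencil_correction=True)
        bias = abs(stencil_bias_factor(k.real * h))
        g_raw = summarize_roi(raw, np.ones((128, 128), bool)).g_abs
        g_corr = summarize_roi(corr, np.ones((128, 128), bool)).g_abs
        assert g_raw == pytest.approx(G * bias, rel=1e-4)
        assert g_corr == pytest.approx(G, rel=1e-5)

    def test_stencil_bias_factor_at_ten_pixels_per_wavelength(self):
        """(kh)^2/(2-2cos kh) at kh = 2 pi/10 is ~1.033."""
        kh = 2 * np.pi / 10
        oracle = kh**2 / (2 - 2 * np.cos(kh))
        assert stencil_bias_factor(kh) == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(1.033, abs=2e-3)

    def test_scale_invariance_bit_identical(self, viscous_wave):
        from .conftest import harmonic_field
        from mre_ela import waves

        _, pos, neg, _ = viscous_wave
        u = waves.directional_filter(waves.butterworth_bandpass(harmonic_field(pos, neg)))
        u10 = ComplexWaveField(10.0 * u.data, u.drive_frequency, u.pixel_spacing)
        m1 = helmholtz_invert(u, 1000.0)
        m2 = helmholtz_invert(u10, 1000.0)
        assert np.array_equal(m1.valid_mask, m2.valid_mask)
        assert np.array_equal(m1.gstar, m2.gstar)

    def test_zero_field_has_no_invertible_support(self):
        field = ComplexWaveField(np.zeros((16, 16), complex), 900.0, 1e-4)
        with pytest.raises(ValueError, match="support"):
            helmholtz_invert(field, 1000.0)


class TestSummaries:
    def test_uniform_map_summary(self):
        s = summarize_roi(uniform_maps(3000 + 1000j), np.ones((32, 32), bool))
        assert s.g_prime == pytest.approx(3000.0)
        assert s.g_doubleprime == pytest.approx(1000.0)
        assert s.g_abs == pytest.approx(3162.2777, abs=0.01)
        assert s.phi == pytest.approx(0.32175, abs=1e-4)

    def test_elastic_map_has_zero_phi(self):
        s = summarize_roi(uniform_maps(2500 + 0j), np.ones((32, 32), bool))
        assert s.phi == 0.0

    def test_half_and_half_mean(self):
        g = np.full((32, 32), 2000 + 0j)
        g[:, 16:] = 4000 + 0j
        maps = ElastogramMaps(g, np.ones((32, 32), bool), 1000.0, 900.0)
        s = summarize_roi(maps, np.ones((32, 32), bool))
        assert s.g_prime == pytest.approx(3000.0)

    def test_magnitude_averaging_differs_for_mixed_phase(self):
        g = np.full((16, 16), 1000 + 0j)
        g[:, 8:] = -1000 + 0j  # antiphase halves: complex mean 0, |G| mean 1000
        maps = ElastogramMaps(g, np.ones((16, 16), bool), 1000.0, 900.0)
        mag = summarize_roi(maps, np.ones((16, 16), bool), averaging="magnitude", erode=0)
        assert mag.g_abs == pytest.approx(1000.0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_roi(uniform_maps(1000 + 0j), np.zeros((32, 32), bool))

    def test_summary_internal_consistency(self):
        s = ViscoSummary.from_complex(2500 + 700j, 10)
        assert s.g_abs == pytest.approx(np.hypot(s.g_prime, s.g_doubleprime))
        assert s.phi == pytest.approx(np.arctan2(s.g_doubleprime, s.g_prime))


class TestROISplit:
    def test_midline_split_equal_areas(self):
        roi = split_anterior_posterior(np.ones((20, 40), bool), 20)
        assert roi.anterior.sum() == roi.posterior.sum() == 400
        assert not np.any(roi.anterior & roi.posterior)

    def test_moving_junction_conserves_pixels(self):
        mask = np.random.default_rng(0).random((20, 40)) > 0.3
        r1 = split_anterior_posterior(mask, 20)
        r2 = split_anterior_posterior(mask, 21)
        col_count = mask[:, 20].sum()
        assert r2.anterior.sum() - r1.anterior.sum() == col_count
        assert r1.posterior.sum() - r2.posterior.sum() == col_count

    def test_junction_outside_mask_rejected(self):
        with pytest.raises(ValueError):
            split_anterior_posterior(np.ones((8, 8), bool), 8)
        mask = np.zeros((8, 8), bool)
        mask[:, :3] = True  # junction beyond the mask leaves one side empty
        with pytest.raises(ValueError, match="empty"):
            split_anterior_posterior(mask, 5)

    def test_anatomical_boolean_junction(self):
        whole = np.ones((10, 10), bool)
        ant = np.zeros((10, 10), bool)
        ant[:5] = True
        roi = split_anterior_posterior(whole, ant)
        assert np.array_equal(roi.anterior, ant)
        assert np.array_equal(roi.posterior, ~ant)


class TestNormalizeToControls:
    def test_delta_examples(self):
        ctl = [ViscoSummary.from_complex(3000 + 0j, 5), ViscoSummary.from_complex(3200 + 0j, 5)]
        eae = [ViscoSummary.from_complex(2800 + 0j, 5), ViscoSummary.from_complex(3100 + 0j, 5)]
        out = normalize_to_controls(eae, ctl)
        assert out["delta_g_abs"].tolist() == pytest.approx([-300.0, 0.0])
        assert out["delta_g_prime"].tolist() == pytest.approx([-300.0, 0.0])

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_controls([ViscoSummary.from_complex(1 + 0j, 1)], [])

    def test_simulated_softened_cohort_all_negative(self):
        """Noise-free generator: every diseased animal sits below the control
        mean stiffness."""
        from mre_ela import simulate_cohort

        df = simulate_cohort(noise_sd=0.0, seed=2)
        whole = df[df.region == "whole"]
        eae = whole[(whole.group == "EAE")]
        ctl = whole[whole.group == "control"]
        cols = {"g_prime": "gstar_real", "g_doubleprime": "gstar_imag",
                "g_abs": "gstar_abs", "phi": "phi"}
        to_rows = lambda d: [
            {k: r[v] for k, v in cols.items()} for _, r in d.iterrows()
        ]
        out = normalize_to_controls(to_rows(eae), to_rows(ctl))
        assert (out["delta_g_abs"] < 0).all()


class TestEndToEndRecovery:
    def test_homogeneous_round_trip(self, viscous_wave):
        """Noise-free full chain recovers the true modulus: within the
        stencil-bias tolerance uncorrected, tighter with correction."""
        _, pos, neg, _ = viscous_wave
        gt = 3000 + 1000j
        res = Elastography(pos, neg).fit()
        assert res.roi_summaries["whole"].g_abs == pytest.approx(abs(gt), rel=0.05)
        res_c = Elastography(pos, neg, inversion=InversionConfig(stencil_correction=True)).fit()
        assert res_c.roi_summaries["whole"].g_abs == pytest.approx(abs(gt), rel=0.01)

    def test_recovered_magnitude_monotone_in_truth(self):
        """|G*| sweep 1.5-6 kPa at fixed loss angle: recovery preserves order."""
        rec = []
        for g0 in (1500.0, 3000.0, 4500.0, 6000.0):
            cfg = WaveSimConfig(
                true_modulus_map=g0 * np.exp(0.3217j), noise_sd=0.0, seed=4
            )
            pos, neg, _ = simulate_wave_series(cfg, "bottom")
            rec.append(Elastography(pos, neg).fit().roi_summaries["whole"].g_abs)
        assert all(np.diff(rec) > 0)

    def test_two_region_ordering_with_noise(self):
        """Softer posterior recovered softer, under measurement noise."""
        ant, post = 4000 + 1200j, 2800 + 900j
        n, b = 128, 3
        whole = np.ones((n, n), bool)
        whole[:, 64 - b : 64 + b] = False
        for seed in range(5):
            cfg = WaveSimConfig(noise_sd=0.05, seed=seed, junction_col=64)
            pos, neg, _ = simulate_two_region_phantom(ant, post, cfg)
            roi = split_anterior_posterior(whole, 64)
            res = Elastography(pos, neg, roi=roi).fit()
            assert res.roi_summaries["posterior"].g_abs < res.roi_summaries["anterior"].g_abs
            assert res.roi_summaries["anterior"].g_abs == pytest.approx(abs(ant), rel=0.10)
            assert res.roi_summaries["posterior"].g_abs == pytest.approx(abs(post), rel=0.10)
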