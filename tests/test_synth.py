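"""Synthetic M-scan generator: noise spectra, physics scaling, transients."""

import numpy as np
import pytest
from scipy import signal

from ptoct import (
    PhantomLayout,
    SimulationConfig,
    lockin_amplitude,
    pink_noise,
    pt_amplitude_from_physics,
    simulate_phantom_mscan,
    simulate_phase_trace,
)


class TestPinkNoise:
    def test_zero_scale_gives_zero_vector(self):
        assert np.array_equal(pink_noise(1024, 1.0, 0.0, seed=7), np.zeros(1024))

    def test_seed_determinism(self):
        a = pink_noise(1024, 1.0, 0.01, seed=7)
        b = pink_noise(1024, 1.0, 0.01, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, pink_noise(1024, 1.0, 0.01, seed=8))

    def test_zero_mean_and_rms_scale(self):
        v = pink_noise(4096, 1.0, 0.01, seed=3)
        assert abs(v.mean()) < 1e-12
        # expected RMS equals the requested scale
        rms = np.sqrt(
            np.mean([pink_noise(4096, 1.0, 0.01, seed=s).var() for s in range(50)])
        )
        assert rms == pytest.approx(0.01, rel=0.1)

    def test_spectral_slope_is_minus_exponent(self):
        """Mean periodogram slope over (fs/1000, fs/4) must be ~ -1 for 1/f."""
        n = 4096
        psd = np.zeros(n // 2 + 1)
        for s in range(200):
            f, p = signal.periodogram(pink_noise(n, 1.0, 0.01, seed=s))
            psd += p
        psd /= 200
        band = (f > 1 / 1000) & (f < 1 / 4)
        slope = np.polyfit(np.log(f[band]), np.log(psd[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    @pytest.mark.parametrize("n,scale", [(1, 0.01), (0, 0.01), (16, -1.0)])
    def test_invalid_arguments(self, n, scale):
        with pytest.raises(ValueError):
            pink_noise(n, 1.0, scale, seed=0)


class TestAmplitudePhysics:
    def test_zero_power_gives_zero(self):
        cfg = SimulationConfig()
        assert pt_amplitude_from_physics(0.0, 500.0, 60, cfg) == 0.0

    def test_thermal_frequency_falloff(self):
        """With gamma = 1 the amplitude scales as 1/f_m: A(4 kHz)/A(500 Hz) = 1/8."""
        cfg = SimulationConfig(green_exponent=1.0)
        a_hi = pt_amplitude_from_physics(2.0, 4000.0, cfg.focal_depth_px, cfg)
        a_lo = pt_amplitude_from_physics(2.0, 500.0, cfg.focal_depth_px, cfg)
        assert a_hi / a_lo == pytest.approx(0.125, rel=1e-12)

    def test_confocal_half_at_one_rayleigh_range(self):
        cfg = SimulationConfig()
        at_focus = pt_amplitude_from_physics(1.0, 500.0, cfg.focal_depth_px, cfg)
        off = pt_amplitude_from_physics(
            1.0, 500.0, cfg.focal_depth_px + int(cfg.rayleigh_range_px), cfg
        )
        assert off == pytest.approx(at_focus / 2, rel=1e-12)

    def test_monotone_in_power_and_frequency(self):
        cfg = SimulationConfig()
        powers = [pt_amplitude_from_physics(p, 500.0, 60, cfg) for p in (0.5, 1, 2, 4)]
        assert np.all(np.diff(powers) > 0)
        freqs = [pt_amplitude_from_physics(1.0, f, 60, cfg) for f in (250, 500, 1000)]
        assert np.all(np.diff(freqs) < 0)

    def test_invalid_arguments(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            pt_amplitude_from_physics(1.0, -500.0, 60, cfg)
        with pytest.raises(ValueError):
            pt_amplitude_from_physics(-1.0, 500.0, 60, cfg)


class TestPhaseTraceSimulation:
    def test_silent_pixel_is_constant_zero(self, noiseless_config):
        tr = simulate_phase_trace(0.0, 0.0, 1e-7, noiseless_config, seed=0)
        assert np.array_equal(tr.samples_rad, np.zeros(noiseless_config.n_samples))

    def test_instant_transient_recovers_amplitude(self, noiseless_config):
        """tau -> 0 leaves a pure integer-cycle sinusoid: lock-in returns A."""
        cfg = noiseless_config.replace(n_samples=864)
        tr = simulate_phase_trace(0.1, 0.0, 1e-9, cfg, seed=0)
        assert lockin_amplitude(tr, 864) == pytest.approx(0.1, abs=1e-6)

    def test_transient_envelope(self):
        """Noiseless trace starts at 0 and settles to the plateau."""
        cfg = SimulationConfig(
            phase_noise_floor_rad=0.0, pink_noise_scale_rad=0.0, n_samples=1000
        )
        tr = simulate_phase_trace(0.1, 0.5, 0.004, cfg, seed=0)
        assert tr.samples_rad[0] == 0.0
        last_cycle = tr.samples_rad[-43:]
        assert last_cycle.mean() == pytest.approx(0.5, rel=0.02)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            simulate_phase_trace(0.1, 0.0, 0.0, SimulationConfig(), seed=0)


class TestPhantomMScan:
    def test_zero_power_noiseless_cube_is_silent(self, noiseless_config):
        layout = PhantomLayout.bands(
            powers_mw=(0.0, 0.0), n_depth=20, n_lateral=10, surface_row=2
        )
        cube, truth = simulate_phantom_mscan(layout, noiseless_config, seed=0)
        assert np.array_equal(truth.amplitude_rad, np.zeros((20, 10)))
        assert np.allclose(cube.phase_rad, 0.0)

    def test_cube_shape_contract(self, noiseless_cube, small_layout):
        cube, _ = noiseless_cube
        assert cube.shape == (
            small_layout.n_depth,
            small_layout.n_lateral,
            cube.config.n_samples,
        )

    def test_latent_zero_off_absorber(self, noiseless_cube, small_layout):
        _, truth = noiseless_cube
        assert np.all(truth.amplitude_rad[~small_layout.absorber_mask] == 0)

    def test_noiseless_lockin_recovers_latent_amplitude(self, noiseless_cube):
        """Exact-frequency demodulation of noiseless traces is the oracle for
        the generator's hidden amplitudes: agreement within 1% everywhere."""
        from ptoct import reconstruct_image

        cube, truth = noiseless_cube
        img = reconstruct_image(cube, n_use=864)
        sel = img.mask & (truth.amplitude_rad > 0)
        assert sel.sum() > 100
        rel = np.abs(img.amplitude_rad[sel] - truth.amplitude_rad[sel])
        assert np.all(rel / truth.amplitude_rad[sel] < 0.01)

    def test_power_linearity(self, noiseless_config):
        layout1 = PhantomLayout.bands(powers_mw=(0.0, 1.0), n_depth=20, n_lateral=10)
        layout3 = PhantomLayout.bands(powers_mw=(0.0, 3.0), n_depth=20, n_lateral=10)
        _, t1 = simulate_phantom_mscan(layout1, noiseless_config, seed=0)
        _, t3 = simulate_phantom_mscan(layout3, noiseless_config, seed=0)
        assert np.allclose(t3.amplitude_rad, 3.0 * t1.amplitude_rad)

    def test_seed_determinism_bitwise(self, small_layout):
        cfg = SimulationConfig()
        a, _ = simulate_phantom_mscan(small_layout, cfg, seed=5)
        b, _ = simulate_phantom_mscan(small_layout, cfg, seed=5)
        assert np.array_equal(a.phase_rad, b.phase_rad)
        assert np.array_equal(a.oct_intensity_db, b.oct_intensity_db)
        c, _ = simulate_phantom_mscan(small_layout, cfg, seed=6)
        assert not np.array_equal(a.phase_rad, c.phase_rad)

    def test_noise_realism(self):
        """Sample std of zero-amplitude traces ~ sqrt(floor^2 + pink RMS^2)."""
        cfg = SimulationConfig()
        layout = PhantomLayout.bands(
            powers_mw=(0.0,), n_depth=50, n_lateral=25, surface_row=0
        )
        cube, _ = simulate_phantom_mscan(layout, cfg, seed=3)
        stds = cube.phase_rad.std(axis=-1).ravel()  # 1250 traces
        expected = np.hypot(cfg.phase_noise_floor_rad, cfg.pink_noise_scale_rad)
        assert np.mean(stds) == pytest.approx(expected, rel=0.2)

    def test_transient_extinction(self):
        """Long after tau the per-cycle mean sits at the plateau."""
        cfg = SimulationConfig(phase_noise_floor_rad=0, pink_noise_scale_rad=0)
        tr = simulate_phase_trace(0.05, 0.3, 0.004, cfg, seed=0)
        # last full nominal cycle of the 1000-sample record, t ~ 11.5 tau
        assert abs(tr.samples_rad[-44:].mean() - 0.3) / 0.3 < 0.01

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            PhantomLayout(
                n_lateral=4,
                n_depth=4,
                region_labels=np.ones((4, 4), dtype=int),
                region_powers_mw={0: 1.0},  # label 1 has no power entry
                absorber_mask=np.ones((4, 4), dtype=bool),
                surface_row=0,
            )

    def test_nyquist_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(a_line_rate_hz=900.0, mod_freq_hz=500.0)
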