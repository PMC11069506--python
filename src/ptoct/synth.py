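"""Synthetic photothermal OCT M-scan generator.

No public PT-OCT phase dataset exists, so this package ships a physics-based
generator that emulates the statistical structure of experimental M-scans:

* a sinusoidal phase modulation at the pump modulation frequency ``f_m``
  whose amplitude is proportional to pump power, falls off as
  ``(f_ref/f_m)^gamma`` with modulation frequency (a declared stand-in for
  the thermal frequency response), and follows a Lorentzian confocal factor
  with distance from the beam focus;
* a transient bulk-heating ramp ``(1 - exp(-t/tau))`` that multiplies both
  the oscillation and a DC plateau and dies out after a few cycles;
* white Gaussian phase noise at the system phase-stability floor
  (14.6 mrad default) plus a pink (1/f) component;
* a depth-attenuated OCT intensity image with additive dB speckle, used for
  the 20-dB validity mask.

Every operation is bit-reproducible given its seed.  The generator exposes
its hidden per-pixel parameters as :class:`LatentTruth` so reconstruction
accuracy can be scored against the true amplitudes, not merely against
another estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .lockin import PhaseTrace

__all__ = [
    "SimulationConfig",
    "PhantomLayout",
    "LatentTruth",
    "MScanCube",
    "pink_noise",
    "pt_amplitude_from_physics",
    "simulate_phase_trace",
    "simulate_phantom_mscan",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic M-scan forward model.

    Parameters
    ----------
    a_line_rate_hz
        OCT A-line (sampling) rate, Hz.  Default 21 600.
    mod_freq_hz
        Photothermal modulation frequency, Hz.  Default 500.
    n_samples
        Trace length per pixel (number of repeated A-lines).  Default 1000.
    center_wavelength_nm
        OCT source centre wavelength; metadata only.  Default 1315.
    phase_noise_floor_rad
        Std of the white phase noise, rad.  Default 0.0146 (the system
        phase-stability floor).
    pink_noise_scale_rad
        RMS of the pink (1/f) phase-noise component, rad.  Default 0.010.
    pink_exponent
        Spectral exponent of the pink component (PSD ~ 1/f^exponent).
    transient_tau_s
        Time constant of the bulk-heating transient, s.  Default 4 ms
        (about two modulation cycles at 500 Hz).
    responsivity_rad_per_mw
        AC phase amplitude per mW of pump power at the reference modulation
        frequency, in focus.  Default 0.03 rad/mW.
    plateau_rad_per_mw
        Steady-state DC bulk-heating phase per mW.  Default 0.03 rad/mW
        (bulk heating comparable to the modulation amplitude, which keeps
        the two-cycle conventional estimate near one third of the
        long-trace value, as observed on real systems).
    green_exponent
        Exponent gamma of the ``(f_ref/f_m)^gamma`` thermal frequency
        falloff.  Default 1.
    ref_freq_hz
        Reference frequency at which responsivity is specified.  Default 500.
    focal_depth_px, rayleigh_range_px
        Centre and half-width (in depth pixels) of the Lorentzian confocal
        factor ``1 / (1 + ((z - z_f)/z_R)^2)``.
    attenuation_per_px_db
        OCT intensity attenuation per depth pixel below the sample surface.
    oct_noise_floor_db, surface_intensity_db
        Intensity noise floor and intensity at the sample surface, dB.
    intensity_speckle_db
        Std of additive Gaussian speckle on the dB intensity image.
    phase_lag_rad
        Thermal phase lag of the modulation at t = 0.
    snr_dependent_noise
        When true, the per-pixel white-noise std is
        ``max(floor, 10^(-SNR_dB/20))`` with SNR taken as intensity above the
        noise floor; otherwise the floor applies everywhere.
    seed
        Default seed for cube-level simulation.
    """

    a_line_rate_hz: float = 21600.0
    mod_freq_hz: float = 500.0
    n_samples: int = 1000
    center_wavelength_nm: float = 1315.0
    phase_noise_floor_rad: float = 0.0146
    pink_noise_scale_rad: float = 0.010
    pink_exponent: float = 1.0
    transient_tau_s: float = 0.004
    responsivity_rad_per_mw: float = 0.03
    plateau_rad_per_mw: float = 0.03
    green_exponent: float = 1.0
    ref_freq_hz: float = 500.0
    focal_depth_px: int = 60
    rayleigh_range_px: float = 40.0
    attenuation_per_px_db: float = 0.25
    oct_noise_floor_db: float = 0.0
    surface_intensity_db: float = 45.0
    intensity_speckle_db: float = 2.0
    phase_lag_rad: float = 0.0
    snr_dependent_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_line_rate_hz <= 0 or self.mod_freq_hz <= 0 or self.ref_freq_hz <= 0:
            raise ValueError("rates and frequencies must be positive")
        if self.a_line_rate_hz <= 2 * self.mod_freq_hz:
            raise ValueError("A-line rate must exceed twice the modulation frequency")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.phase_noise_floor_rad < 0 or self.pink_noise_scale_rad < 0:
            raise ValueError("noise scales must be non-negative")
        if self.transient_tau_s <= 0:
            raise ValueError("transient_tau_s must be positive")
        if self.responsivity_rad_per_mw <= 0 or self.plateau_rad_per_mw < 0:
            raise ValueError("responsivities must be positive / non-negative")
        if self.green_exponent < 0:
            raise ValueError("green_exponent must be >= 0")
        if self.rayleigh_range_px <= 0:
            raise ValueError("rayleigh_range_px must be positive")
        if self.attenuation_per_px_db < 0 or self.intensity_speckle_db < 0:
            raise ValueError("intensity noise parameters must be non-negative")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @property
    def samples_per_cycle(self) -> float:
        return self.a_line_rate_hz / self.mod_freq_hz


@dataclass
class PhantomLayout:
    """Lateral-band phantom geometry with per-region pump power.

    ``region_labels`` assigns every pixel an integer region id;
    ``region_powers_mw`` maps each id to a pump power (0 allowed: the
    non-absorber region P0).  ``absorber_mask`` marks the pixels that
    actually contain absorber (at and below ``surface_row`` by default).
    """

    n_lateral: int
    n_depth: int
    region_labels: np.ndarray
    region_powers_mw: dict[int, float]
    absorber_mask: np.ndarray
    surface_row: int

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        self.absorber_mask = np.asarray(self.absorber_mask, dtype=bool)
        shape = (self.n_depth, self.n_lateral)
        if self.region_labels.shape != shape or self.absorber_mask.shape != shape:
            raise ValueError("layout matrices must be (n_depth, n_lateral)")
        if not 0 <= self.surface_row < self.n_depth:
            raise ValueError("surface_row out of range")
        labels = set(np.unique(self.region_labels).tolist())
        missing = labels - set(self.region_powers_mw)
        if missing:
            raise ValueError(f"labels without a power entry: {sorted(missing)}")
        if any(p < 0 for p in self.region_powers_mw.values()):
            raise ValueError("region powers must be non-negative")

    @classmethod
    def bands(
        cls,
        powers_mw: tuple[float, ...] = (0.0, 1.0, 2.25, 3.5),
        n_depth: int = 110,
        n_lateral: int = 160,
        surface_row: int = 10,
    ) -> "PhantomLayout":
        """Vertical-band phantom: equal lateral bands, one power per band.

        The default four powers (0, 1, 2.25, 3.5 mW) emulate regions P0-P3
        of increasing absorber response; pass three powers (e.g. 0, 1.6,
        3.2 mW) for the tissue-style P0-P2 variant.
        """
        labels = np.zeros((n_depth, n_lateral), dtype=int)
        edges = np.linspace(0, n_lateral, len(powers_mw) + 1).astype(int)
        for i in range(len(powers_mw)):
            labels[:, edges[i] : edges[i + 1]] = i
        absorber = np.zeros((n_depth, n_lateral), dtype=bool)
        absorber[surface_row:, :] = True
        return cls(
            n_lateral=n_lateral,
            n_depth=n_depth,
            region_labels=labels,
            region_powers_mw={i: float(p) for i, p in enumerate(powers_mw)},
            absorber_mask=absorber,
            surface_row=surface_row,
        )

    def power_image(self) -> np.ndarray:
        """Per-pixel pump power (mW), zero off the absorber."""
        lut = np.zeros(int(self.region_labels.max()) + 1)
        for k, v in self.region_powers_mw.items():
            lut[k] = v
        return np.where(self.absorber_mask, lut[self.region_labels], 0.0)


@dataclass
class LatentTruth:
    """The simulator's hidden per-pixel parameters.

    ``amplitude_rad`` is the steady-state AC modulation amplitude — the
    quantity every reconstruction tries to estimate.  It is zero wherever
    the absorber mask is false or the pump power is zero.
    """

    amplitude_rad: np.ndarray
    transient_plateau_rad: np.ndarray
    transient_tau_s: np.ndarray


@dataclass
class MScanCube:
    """Depth x lateral x time phase cube plus the co-registered OCT image."""

    phase_rad: np.ndarray
    oct_intensity_db: np.ndarray
    config: SimulationConfig
    layout: PhantomLayout | None = None

    def __post_init__(self) -> None:
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        self.oct_intensity_db = np.asarray(self.oct_intensity_db, dtype=float)
        if self.phase_rad.ndim != 3:
            raise ValueError("phase cube must be 3-D (depth, lateral, time)")
        if self.phase_rad.shape[-1] != self.config.n_samples:
            raise ValueError("time axis length must equal config.n_samples")
        if self.oct_intensity_db.shape != self.phase_rad.shape[:2]:
            raise ValueError("intensity image shape mismatch")
        if not np.all(np.isfinite(self.oct_intensity_db)):
            raise ValueError("intensity image must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phase_rad.shape

    def pixel_trace(self, row: int, col: int) -> PhaseTrace:
        return PhaseTrace(
            samples_rad=self.phase_rad[row, col],
            a_line_rate_hz=self.config.a_line_rate_hz,
            mod_freq_hz=self.config.mod_freq_hz,
        )


def _pink_filter(n: int, exponent: float) -> tuple[np.ndarray, float]:
    """Spectral weights w_f ~ f^(-exponent/2) with DC zeroed, plus the
    factor that makes the filtered unit-white-noise output have unit std."""
    w = np.zeros(n // 2 + 1)
    f = np.fft.rfftfreq(n)
    w[1:] = f[1:] ** (-exponent / 2.0)
    # time-domain variance of irfft(rfft(white) * w): mean of |w|^2 over the
    # full (two-sided) spectrum
    full_sq = np.concatenate([w**2, w[1 : (n + 1) // 2][::-1] ** 2])
    std = float(np.sqrt(full_sq.mean()))
    return w, std


def _pink_noise_block(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float, scale_rad: float
) -> np.ndarray:
    """Pink noise with time on the last axis, RMS ``scale_rad``."""
    n = shape[-1]
    if scale_rad == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    w, std = _pink_filter(n, exponent)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * w, n=n, axis=-1)
    return shaped * (scale_rad / std)


def pink_noise(n: int, exponent: float, scale_rad: float, seed: int) -> np.ndarray:
    """Zero-mean 1/f^exponent noise vector of length ``n`` and RMS ``scale_rad``.

    Synthesised by spectral shaping of white Gaussian noise with Hermitian
    symmetry: the DC bin is zeroed (so the sample mean is exactly zero) and
    each positive-frequency bin is weighted by ``f^(-exponent/2)``, giving an
    expected power spectral density proportional to ``1/f^exponent``.  The
    weights are normalised so the expected time-domain std equals
    ``scale_rad``.  Identical seeds give identical vectors.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if scale_rad < 0:
        raise ValueError("scale_rad must be non-negative")
    rng = np.random.default_rng(seed)
    return _pink_noise_block(rng, (n,), exponent, scale_rad)


def confocal_factor(depth_px: np.ndarray | int, config: SimulationConfig) -> np.ndarray:
    """Lorentzian axial falloff ``1 / (1 + ((z - z_f)/z_R)^2)``."""
    z = np.asarray(depth_px, dtype=float)
    return 1.0 / (1.0 + ((z - config.focal_depth_px) / config.rayleigh_range_px) ** 2)


def pt_amplitude_from_physics(
    power_mw: float,
    mod_freq_hz: float,
    depth_px: int,
    config: SimulationConfig,
) -> float:
    """Steady-state photothermal phase amplitude of one pixel, radians.

    Declared forward model::

        A = responsivity * P * (f_ref / f_m)^gamma * confocal(z)

    monotone increasing in pump power, monotone decreasing in modulation
    frequency for ``gamma > 0`` (the thermal response falls off with
    frequency), and maximal at the focal plane.
    """
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    if mod_freq_hz <= 0:
        raise ValueError("modulation frequency must be positive")
    return float(
        config.responsivity_rad_per_mw
        * power_mw
        * (config.ref_freq_hz / mod_freq_hz) ** config.green_exponent
        * confocal_factor(depth_px, config)
    )


def _noiseless_trace(
    amplitude_rad: np.ndarray,
    plateau_rad: np.ndarray,
    tau_s: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Deterministic part of the phase trace, broadcast over leading axes."""
    t = np.arange(config.n_samples) / config.a_line_rate_hz
    envelope = 1.0 - np.exp(-t / tau_s)
    carrier = np.sin(2 * np.pi * config.mod_freq_hz * t + config.phase_lag_rad)
    a = np.asarray(amplitude_rad, dtype=float)[..., None]
    p = np.asarray(plateau_rad, dtype=float)[..., None]
    return a * envelope * carrier + p * envelope


def simulate_phase_trace(
    amplitude_rad: float,
    plateau_rad: float,
    tau_s: float,
    config: SimulationConfig,
    seed: int,
) -> PhaseTrace:
    """Simulate one pixel's phase time series.

    ``phi[k] = A (1 - e^{-t_k/tau}) sin(2 pi f_m t_k + psi)
    + plateau (1 - e^{-t_k/tau}) + white[k] + pink[k]`` with
    ``t_k = k / fs``.  The noiseless part is zero at ``t = 0`` (the trace is
    referenced to its start).  Both the AC modulation and the DC bulk-heating
    plateau grow in with the same thermal time constant; the transient dies
    out after a few modulation cycles.
    """
    if amplitude_rad < 0:
        raise ValueError("amplitude must be non-negative")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rng = np.random.default_rng(seed)
    clean = _noiseless_trace(
        np.asarray(amplitude_rad), np.asarray(plateau_rad), tau_s, config
    )
    white = rng.normal(0.0, config.phase_noise_floor_rad, config.n_samples) \
        if config.phase_noise_floor_rad > 0 else 0.0
    pink = _pink_noise_block(
        rng, (config.n_samples,), config.pink_exponent, config.pink_noise_scale_rad
    )
    return PhaseTrace(
        samples_rad=clean + white + pink,
        a_line_rate_hz=config.a_line_rate_hz,
        mod_freq_hz=config.mod_freq_hz,
    )


def _intensity_image(
    layout: PhantomLayout, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Depth-attenuated OCT intensity in dB with additive dB speckle."""
    depth = np.arange(layout.n_depth)[:, None]
    below = depth - layout.surface_row
    intensity = np.where(
        below >= 0,
        config.surface_intensity_db - config.attenuation_per_px_db * below,
        config.oct_noise_floor_db,
    )
    intensity = np.broadcast_to(intensity, (layout.n_depth, layout.n_lateral)).copy()
    if config.intensity_speckle_db > 0:
        intensity += rng.normal(
            0.0, config.intensity_speckle_db, intensity.shape
        )
    return intensity


def simulate_phantom_mscan(
    layout: PhantomLayout,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[MScanCube, LatentTruth]:
    """Simulate a full phantom M-scan cube and return it with its latent truth.

    Per-pixel steady-state amplitude comes from
    :func:`pt_amplitude_from_physics` applied to the pixel's region power and
    depth; the DC plateau scales the same way with
    ``plateau_rad_per_mw``.  The OCT intensity image is the surface level
    minus ``attenuation_per_px_db`` per pixel below the surface (noise floor
    above the surface) plus dB speckle.  Deterministic for a fixed seed
    (``config.seed`` when ``seed`` is None).
    """
    if layout.region_labels.shape != (layout.n_depth, layout.n_lateral):
        raise ValueError("inconsistent layout dimensions")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    power = layout.power_image()
    depth = np.arange(layout.n_depth)[:, None]
    scale = (
        (config.ref_freq_hz / config.mod_freq_hz) ** config.green_exponent
        * confocal_factor(depth, config)
    )
    amplitude = config.responsivity_rad_per_mw * power * scale
    plateau = config.plateau_rad_per_mw * power * scale
    clean = _noiseless_trace(amplitude, plateau, config.transient_tau_s, config)

    intensity = _intensity_image(layout, config, rng)

    shape = (layout.n_depth, layout.n_lateral, config.n_samples)
    if config.snr_dependent_noise:
        snr_db = intensity - config.oct_noise_floor_db
        sigma = np.maximum(
            config.phase_noise_floor_rad, 10.0 ** (-snr_db / 20.0)
        )[..., None]
    else:
        sigma = config.phase_noise_floor_rad
    phase = clean
    if np.any(np.asarray(sigma) > 0):
        phase = phase + rng.standard_normal(shape) * sigma
    if config.pink_noise_scale_rad > 0:
        phase = phase + _pink_noise_block(
            rng, shape, config.pink_exponent, config.pink_noise_scale_rad
        )

    cube = MScanCube(
        phase_rad=phase, oct_intensity_db=intensity, config=config, layout=layout
    )
    truth = LatentTruth(
        amplitude_rad=amplitude,
        transient_plateau_rad=plateau,
        transient_tau_s=np.full_like(amplitude, config.transient_tau_s),
    )
    return cube, truth
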