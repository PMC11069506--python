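"""Conventional PT-OCT reconstruction by single-frequency lock-in demodulation.

A photothermal pump modulated at ``f_m`` imprints a sinusoidal oscillation on
the OCT phase of every pixel above an absorber.  The conventional estimate of
the photothermal amplitude is the magnitude of the phase time series at the
known modulation frequency — a single-bin discrete Fourier transform, i.e. a
software lock-in.  This module implements that demodulation for single traces
and whole M-scan cubes, the OCT-intensity validity mask, and the extraction of
(short-trace, long-trace-amplitude) training pairs for the network.

Two demodulation modes are provided:

``exact_freq``
    Correlate against a complex tone at exactly ``f_m`` over the first ``N``
    samples: ``(2/N) |sum_k x[k] exp(-i 2 pi f_m k / fs)|``.  Immune to FFT
    scalloping when ``N`` does not span an integer number of cycles.
``fft_bin``
    Magnitude of the DFT bin nearest ``N f_m / fs`` (times ``2/N``), matching
    FFT-based processing pipelines.

Both return the true amplitude for a pure sinusoid spanning an integer number
of modulation cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synth import MScanCube

__all__ = [
    "PhaseTrace",
    "PTImage",
    "TrainingPairs",
    "reference_trace",
    "lockin_amplitude",
    "lockin_amplitude_array",
    "intensity_mask",
    "reconstruct_image",
    "extract_training_pairs",
]

#: Number of phase samples in the conventional short trace (~2 cycles at
#: 500 Hz modulation and 21.6 kHz A-line rate).
N_SHORT_DEFAULT = 88
#: Number of phase samples in the conventional long (ground-truth) trace
#: (~20 cycles).
N_GT_DEFAULT = 864


@dataclass
class PhaseTrace:
    """One pixel's OCT phase time series with its acquisition metadata.

    Parameters
    ----------
    samples_rad
        Phase samples in radians, one per A-line.
    a_line_rate_hz
        Sampling rate of the M-scan (A-line rate), Hz.
    mod_freq_hz
        Photothermal modulation frequency, Hz.
    """

    samples_rad: np.ndarray
    a_line_rate_hz: float
    mod_freq_hz: float

    def __post_init__(self) -> None:
        self.samples_rad = np.asarray(self.samples_rad, dtype=float)
        if self.samples_rad.ndim != 1 or self.samples_rad.size < 2:
            raise ValueError("trace must be a 1-D vector with >= 2 samples")
        if not np.all(np.isfinite(self.samples_rad)):
            raise ValueError("trace contains non-finite samples")
        if self.a_line_rate_hz <= 0 or self.mod_freq_hz <= 0:
            raise ValueError("rates must be positive")

    def __len__(self) -> int:
        return self.samples_rad.size


@dataclass
class PTImage:
    """Per-pixel photothermal amplitude image with a validity mask.

    ``amplitude_rad`` is finite on masked-true pixels; masked-false pixels
    carry NaN and are excluded from every metric.  ``kind`` records how the
    image was produced: ``"GT"`` (long-trace lock-in), ``"ST"`` (short-trace
    lock-in) or ``"NET"`` (network prediction).
    """

    amplitude_rad: np.ndarray
    mask: np.ndarray
    kind: str
    n_samples_used: int

    def __post_init__(self) -> None:
        self.amplitude_rad = np.asarray(self.amplitude_rad, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.amplitude_rad.shape != self.mask.shape:
            raise ValueError("amplitude and mask shapes differ")
        if self.kind not in ("GT", "ST", "NET"):
            raise ValueError(f"unknown image kind {self.kind!r}")
        if self.n_samples_used < 1:
            raise ValueError("n_samples_used must be positive")
        if not np.all(np.isfinite(self.amplitude_rad[self.mask])):
            raise ValueError("non-finite amplitude on masked-true pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude_rad.shape


@dataclass
class TrainingPairs:
    """Dataset of (short-trace input, long-trace amplitude label) pairs.

    One pair per masked-true pixel, in row-major pixel order.  Inputs are
    referenced to their first sample (first sample subtracted) so every
    vector starts at zero.
    """

    inputs: np.ndarray  # (n_pairs, n_short)
    labels: np.ndarray  # (n_pairs,)
    pixel_rows: np.ndarray = field(repr=False, default=None)
    pixel_cols: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.labels.size


def reference_trace(x: np.ndarray) -> np.ndarray:
    """Subtract the first sample along the last axis.

    OCT phase is relative; referencing each trace to its own start puts every
    input on a common origin while preserving the bulk-heating ramp shape.
    """
    x = np.asarray(x, dtype=float)
    return x - x[..., :1]


def _check_demod_args(n_use: int, fs: float, fm: float) -> None:
    if n_use < 2:
        raise ValueError("n_use must be >= 2")
    if fm >= fs / 2:
        raise ValueError("modulation frequency must be below Nyquist (fs/2)")


def lockin_amplitude_array(
    x: np.ndarray,
    a_line_rate_hz: float,
    mod_freq_hz: float,
    n_use: int,
    mode: str = "exact_freq",
) -> np.ndarray:
    """Vectorised lock-in amplitude over the first ``n_use`` samples.

    ``x`` has time on the last axis; returns an array with that axis removed.
    """
    x = np.asarray(x, dtype=float)
    _check_demod_args(n_use, a_line_rate_hz, mod_freq_hz)
    if n_use > x.shape[-1]:
        raise ValueError(f"n_use={n_use} exceeds trace length {x.shape[-1]}")
    seg = x[..., :n_use]
    if mode == "exact_freq":
        k = np.arange(n_use)
        tone = np.exp(-2j * np.pi * mod_freq_hz * k / a_line_rate_hz)
        return (2.0 / n_use) * np.abs(seg @ tone)
    if mode == "fft_bin":
        target = n_use * mod_freq_hz / a_line_rate_hz
        b = int(round(target))
        b = min(max(b, 0), n_use // 2)
        spec = np.fft.rfft(seg, axis=-1)
        return (2.0 / n_use) * np.abs(spec[..., b])
    raise ValueError(f"unknown demodulation mode {mode!r}")


def lockin_amplitude(trace: PhaseTrace, n_use: int, mode: str = "exact_freq") -> float:
    """Photothermal amplitude of one trace at the modulation frequency.

    Returns ``(2/N) |sum_{k<N} x[k] e^{-i 2 pi f_m k / fs}|`` (``exact_freq``)
    or the nearest-bin DFT magnitude (``fft_bin``) over the first ``n_use``
    samples.  For a pure sinusoid of amplitude ``A`` spanning an integer
    number of cycles both modes return ``A``; a constant (DC) offset is
    rejected because it is orthogonal to the demodulation tone.
    """
    return float(
        lockin_amplitude_array(
            trace.samples_rad, trace.a_line_rate_hz, trace.mod_freq_hz, n_use, mode
        )
    )


def intensity_mask(
    intensity_db: np.ndarray, noise_floor_db: float, threshold_db: float = 20.0
) -> np.ndarray:
    """Validity mask: true where OCT intensity is >= floor + threshold.

    Pixels without meaningful OCT signal have no usable phase; the
    conventional protocol masks everything below 20 dB above the noise floor.
    The boundary is inclusive.
    """
    intensity_db = np.asarray(intensity_db, dtype=float)
    if not np.all(np.isfinite(intensity_db)):
        raise ValueError("intensity image contains non-finite values")
    if threshold_db < 0:
        raise ValueError("threshold must be non-negative")
    return intensity_db >= noise_floor_db + threshold_db


def reconstruct_image(
    cube: "MScanCube", n_use: int, mode: str = "exact_freq"
) -> PTImage:
    """Lock-in reconstruction of a full M-scan cube.

    Applies :func:`lockin_amplitude` to the first ``n_use`` samples of every
    pixel (each trace referenced to its first sample), attaches the
    20-dB-above-floor intensity mask, and records ``n_samples_used``.  The
    image kind is ``"GT"`` when ``n_use`` spans at least 10 modulation cycles,
    else ``"ST"``.
    """
    cfg = cube.config
    if n_use > cfg.n_samples:
        raise ValueError(f"n_use={n_use} exceeds cube n_samples={cfg.n_samples}")
    phase = reference_trace(cube.phase_rad)
    amp = lockin_amplitude_array(phase, cfg.a_line_rate_hz, cfg.mod_freq_hz, n_use, mode)
    mask = intensity_mask(cube.oct_intensity_db, cfg.oct_noise_floor_db)
    amp = np.where(mask, amp, np.nan)
    cycles = n_use * cfg.mod_freq_hz / cfg.a_line_rate_hz
    kind = "GT" if cycles >= 10 else "ST"
    return PTImage(amplitude_rad=amp, mask=mask, kind=kind, n_samples_used=n_use)


def extract_training_pairs(
    cube: "MScanCube",
    n_short: int = N_SHORT_DEFAULT,
    n_gt: int = N_GT_DEFAULT,
    mode: str = "exact_freq",
    lateral_slice: slice | np.ndarray | None = None,
) -> TrainingPairs:
    """Build the network training set from an M-scan cube.

    One pair per masked-true pixel in row-major order: the input is the
    pixel's first ``n_short`` phase samples referenced to the first sample,
    the label is the lock-in amplitude over the first ``n_gt`` samples (the
    conventional long-trace ground truth).  ``lateral_slice`` optionally
    restricts extraction to a lateral column range (train/test splits).
    """
    if n_short >= n_gt:
        raise ValueError("n_short must be < n_gt")
    cfg = cube.config
    if n_gt > cfg.n_samples:
        raise ValueError("n_gt exceeds cube n_samples")
    phase = cube.phase_rad
    intensity = cube.oct_intensity_db
    if lateral_slice is not None:
        phase = phase[:, lateral_slice, :]
        intensity = intensity[:, lateral_slice]
    mask = intensity_mask(intensity, cfg.oct_noise_floor_db)
    rows, cols = np.nonzero(mask)
    traces = reference_trace(phase[rows, cols, :])
    labels = lockin_amplitude_array(
        traces, cfg.a_line_rate_hz, cfg.mod_freq_hz, n_gt, mode
    )
    return TrainingPairs(
        inputs=traces[:, :n_short].copy(),
        labels=labels,
        pixel_rows=rows,
        pixel_cols=cols,
    )
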