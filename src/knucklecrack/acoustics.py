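"""Radiated acoustic pressure of the oscillating bubble.

A bubble whose volume ``V(t)`` changes in time radiates (monopole,
incompressible near field, no retardation)

    P_a(t) = rho_m / (4 pi r) * d^2 V / d t^2

at distance ``r`` in a medium of density ``rho_m``.  From the radiated
waveform this module computes the peak sound pressure level (re 20 uPa), the
amplitude spectrum of the uniformly resampled and zero-padded signal, the
dominant (largest non-DC) frequency, and 16-bit PCM WAV exports.

A 0.01 s record has an intrinsic resolution of 100 Hz; zero-padding to 1 s
(the default) refines the spectral grid to 1 Hz so that a dominant frequency
of order 100 Hz is representable.
"""

from __future__ import annotations

import logging
import wave as _wave
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .bubble import BubbleTrajectory
from .errors import DomainError, SignalError

__all__ = [
    "AcousticParams",
    "AcousticWaveform",
    "Spectrum",
    "volume_second_derivative",
    "acoustic_pressure",
    "peak_spl_db",
    "normalize",
    "amplitude_spectrum",
    "export_wav",
]

log = logging.getLogger(__name__)

SPL_REFERENCE = 20e-6  # Pa, airborne-acoustics convention


@dataclass(frozen=True)
class AcousticParams:
    """Observation model: medium density, distance, SPL reference."""

    rho_m: float = 1015.0
    distance: float = 0.01
    p_ref: float = SPL_REFERENCE

    def __post_init__(self) -> None:
        if self.rho_m <= 0.0 or self.distance <= 0.0 or self.p_ref <= 0.0:
            raise DomainError("acoustic parameters must be positive")


@dataclass
class AcousticWaveform:
    """Acoustic pressure versus time; ``normalized`` marks unit peak."""

    t: np.ndarray
    pa: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pa = np.asarray(self.pa, dtype=float)
        if self.t.shape != self.pa.shape or self.t.ndim != 1:
            raise DomainError("waveform arrays must be matching 1-D series")
        if len(self.t) < 2 or not np.all(np.diff(self.t) > 0.0):
            raise DomainError("time grid must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "pa_pa": self.pa})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Spectrum:
    """One-sided amplitude spectrum and its dominant frequency."""

    f: np.ndarray
    amplitude: np.ndarray
    f_dominant: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"f_hz": self.f, "amplitude": self.amplitude})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def volume_second_derivative(
    r: np.ndarray, rdot: np.ndarray, rddot: np.ndarray
) -> np.ndarray:
    """``d^2V/dt^2 = 4 pi (2 R Rdot^2 + R^2 Rddot)`` for a sphere."""
    r = np.asarray(r, dtype=float)
    rdot = np.asarray(rdot, dtype=float)
    rddot = np.asarray(rddot, dtype=float)
    if not (r.shape == rdot.shape == rddot.shape):
        raise DomainError("series lengths do not match")
    return 4.0 * np.pi * (2.0 * r * rdot**2 + r**2 * rddot)


def acoustic_pressure(
    traj: BubbleTrajectory, params: AcousticParams = AcousticParams()
) -> AcousticWaveform:
    """Radiated pressure waveform of a bubble trajectory.

    The trajectory must carry a wall acceleration (see
    :func:`knucklecrack.bubble.wall_acceleration`).
    """
    if traj.rddot is None:
        raise DomainError("trajectory has no wall acceleration; "
                          "run wall_acceleration() first")
    d2v = volume_second_derivative(traj.r, traj.rdot, traj.rddot)
    pa = params.rho_m / (4.0 * np.pi * params.distance) * d2v
    return AcousticWaveform(t=traj.t.copy(), pa=pa)


def peak_spl_db(wave: AcousticWaveform, p_ref: float = SPL_REFERENCE) -> float:
    """Peak sound pressure level ``20 log10(max|P_a| / p_ref)`` in dB."""
    if wave.normalized:
        raise SignalError("SPL of a normalized waveform is meaningless")
    peak = float(np.max(np.abs(wave.pa)))
    if peak == 0.0:
        raise SignalError("SPL undefined for an all-zero waveform")
    return float(20.0 * np.log10(peak / p_ref))


def normalize(wave: AcousticWaveform) -> AcousticWaveform:
    """Scale the waveform by its maximum absolute amplitude (idempotent)."""
    peak = float(np.max(np.abs(wave.pa)))
    if peak == 0.0:
        raise SignalError("cannot normalize an all-zero waveform")
    return AcousticWaveform(t=wave.t.copy(), pa=wave.pa / peak, normalized=True)


def _resample(wave: AcousticWaveform, fs: float) -> np.ndarray:
    t0 = wave.t[0]
    n = int(np.floor(wave.duration * fs)) + 1
    tu = t0 + np.arange(n) / fs
    return np.interp(tu, wave.t, wave.pa)


def amplitude_spectrum(
    wave: AcousticWaveform,
    resample_hz: float = 44000.0,
    pad_to_s: float = 1.0,
    window: Optional[str] = None,
) -> Spectrum:
    """Amplitude spectrum after uniform resampling and zero-padding.

    The waveform is linearly resampled at ``resample_hz`` (default 44 kHz,
    the audio recording rate), optionally tapered (``window="hann"``;
    rectangular by default), zero-padded to ``pad_to_s`` seconds and
    transformed with a real FFT.  The dominant frequency is the argmax of the
    magnitude over ``f > 0`` (DC excluded).
    """
    if wave.duration <= 0.0:
        raise DomainError("waveform duration must be positive")
    if resample_hz <= 0.0 or pad_to_s <= 0.0:
        raise DomainError("resample rate and pad length must be positive")
    x = _resample(wave, resample_hz)
    if window is not None:
        if window.lower() != "hann":
            raise DomainError(f"unknown window {window!r}")
        x = x * np.hanning(len(x))
    n_fft = max(int(round(pad_to_s * resample_hz)), len(x))
    if n_fft < len(x):
        log.warning("pad_to_s shorter than the signal; no padding applied")
    amp = np.abs(np.fft.rfft(x, n_fft))
    f = np.fft.rfftfreq(n_fft, 1.0 / resample_hz)
    i_dom = 1 + int(np.argmax(amp[1:]))
    return Spectrum(f=f, amplitude=amp, f_dominant=float(f[i_dom]))


def export_wav(
    wave: AcousticWaveform, path, sample_rate: int = 44100
) -> None:
    """Write the waveform as 16-bit PCM mono WAV, scaled to 0.9 full scale.

    The signal is uniformly resampled at ``sample_rate``; an all-zero
    waveform is written as silence.
    """
    if sample_rate <= 0:
        raise DomainError("sample rate must be positive")
    x = _resample(wave, float(sample_rate))
    peak = np.max(np.abs(x))
    if peak > 0.0:
        x = x / peak * 0.9
    samples = np.round(x * 32767.0).astype("<i2")
    with _wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(int(sample_rate))
        fh.writeframes(samples.tobytes())


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a 16-bit PCM mono WAV back as ``(sample_rate, samples)``."""
    with _wave.open(str(path), "rb") as fh:
        if fh.getsampwidth() != 2 or fh.getnchannels() != 1:
            raise DomainError("expected 16-bit mono PCM")
        rate = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    return rate, np.frombuffer(raw, dtype="<i2")
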