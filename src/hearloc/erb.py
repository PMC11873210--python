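"""ERB-scale filterbank and per-channel log-magnitude spectra.

The auditory periphery is modelled as a bank of independent frequency
channels whose centre frequencies are equally spaced on the ERB-number
(equivalent rectangular bandwidth) scale of Glasberg & Moore:

    E(f) = 21.4 * log10(0.00437 * f + 1)        [f in Hz]

A channel's magnitude is the signal power integrated over a band one ERB
wide around its centre frequency, expressed in dB.  With 1-ERB spacing the
band from 300 Hz to 12 kHz yields 30 channels, the standard configuration
used throughout this package.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

__all__ = [
    "erb_number",
    "erb_to_hz",
    "erb_bandwidth",
    "ErbFilterbank",
    "ChannelSpectrum",
    "make_filterbank",
    "frame_logmag",
    "read_wav_mono",
    "chop_corpus",
]

log = logging.getLogger(__name__)

#: Glasberg-Moore ERB-number scale constants.
_ERB_A = 21.4
_ERB_B = 0.00437

#: Channel values are clamped at this floor (dB re full scale) so that a
#: silent frame produces finite numbers rather than -inf.
LOG_FLOOR_DB = -120.0

#: Frames whose RMS falls below this level (dB re full scale) are treated as
#: silence and discarded when pooling corpus statistics.
FRAME_RMS_FLOOR_DBFS = -60.0

#: All corpus audio is resampled to this rate before framing.
CORPUS_SAMPLE_RATE = 44100


def erb_number(f: np.ndarray | float) -> np.ndarray | float:
    """Map frequency in Hz to ERB-number (Glasberg-Moore scale).

    Strictly increasing, with ``erb_number(0) == 0``.  Raises ``ValueError``
    for negative frequencies.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = _ERB_A * np.log10(_ERB_B * f + 1.0)
    return float(out) if out.ndim == 0 else out


def erb_to_hz(e: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`erb_number`."""
    e = np.asarray(e, dtype=float)
    out = (10.0 ** (e / _ERB_A) - 1.0) / _ERB_B
    return float(out) if out.ndim == 0 else out


def erb_bandwidth(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth (Hz) at frequency ``f`` (Hz)."""
    f = np.asarray(f, dtype=float)
    # df/dE = ln(10)/(A*B) * (B f + 1): the width of a 1-ERB step in Hz
    out = np.log(10.0) / (_ERB_A * _ERB_B) * (_ERB_B * f + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ErbFilterbank:
    """A bank of 1-ERB-wide channels on an ERB-spaced frequency axis.

    Attributes
    ----------
    centre_frequencies_hz
        Strictly increasing channel centre frequencies.
    spacing_erb
        Spacing of consecutive centres on the ERB-number scale.
    """

    centre_frequencies_hz: np.ndarray
    spacing_erb: float

    def __post_init__(self) -> None:
        cf = np.asarray(self.centre_frequencies_hz, dtype=float)
        object.__setattr__(self, "centre_frequencies_hz", cf)
        if cf.ndim != 1 or cf.size == 0:
            raise ValueError("centre frequencies must be a non-empty 1-D array")
        if np.any(np.diff(cf) <= 0):
            raise ValueError("centre frequencies must be strictly increasing")
        e = erb_number(cf)
        if cf.size > 1 and not np.allclose(np.diff(e), self.spacing_erb, atol=1e-9):
            raise ValueError("centre frequencies not uniformly ERB-spaced")

    @property
    def n_channels(self) -> int:
        return int(self.centre_frequencies_hz.size)

    def band_edges_hz(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper edges of the 1-ERB-wide integration band per channel."""
        e = erb_number(self.centre_frequencies_hz)
        return erb_to_hz(e - 0.5), erb_to_hz(e + 0.5)

    def to_dict(self) -> dict:
        lo, hi = self.band_edges_hz()
        return {
            "centre_frequencies_hz": self.centre_frequencies_hz.tolist(),
            "spacing_erb": self.spacing_erb,
            "band_edges_lo_hz": lo.tolist(),
            "band_edges_hi_hz": hi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErbFilterbank":
        return cls(np.asarray(d["centre_frequencies_hz"], float), float(d["spacing_erb"]))


@dataclass
class ChannelSpectrum:
    """Per-channel log-magnitudes (dB) on a filterbank's frequency axis."""

    values_db: np.ndarray
    filterbank: ErbFilterbank

    def __post_init__(self) -> None:
        v = np.asarray(self.values_db, dtype=float)
        if v.shape != (self.filterbank.n_channels,):
            raise ValueError(
                f"expected {self.filterbank.n_channels} channel values, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("channel values must be finite")
        self.values_db = v


def make_filterbank(f_lo: float, f_hi: float, spacing: float = 1.0) -> ErbFilterbank:
    """Build a filterbank spanning ``[f_lo, f_hi]`` at ``spacing`` ERB.

    The first centre frequency is ``f_lo``; further centres are placed every
    ``spacing`` ERB until ``f_hi`` is exceeded.  ``(300, 12000, 1.0)`` yields
    the standard 30-channel configuration.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    e_lo, e_hi = erb_number(f_lo), erb_number(f_hi)
    n = int(np.floor((e_hi - e_lo) / spacing + 1e-12)) + 1
    centres = erb_to_hz(e_lo + spacing * np.arange(n))
    centres[0] = f_lo  # exact, avoids round-trip error
    return ErbFilterbank(centres, spacing)


def frame_logmag(
    frame: np.ndarray,
    sample_rate: float,
    fb: ErbFilterbank,
    *,
    window: str = "hann",
    floor_db: float = LOG_FLOOR_DB,
) -> ChannelSpectrum:
    """Per-channel band power of one audio frame, in dB.

    The frame's periodogram (windowed, by default Hann) is integrated over
    each channel's 1-ERB-wide rectangular band; the band power is converted
    to dB and clamped at ``floor_db``.  Deterministic for a fixed frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if sample_rate <= 2 * fb.centre_frequencies_hz[-1]:
        raise ValueError("sample rate must exceed twice the highest centre frequency")
    n = frame.size
    w = get_window(window, n, fftbins=True)
    # window power normalization keeps a full-scale sinusoid at ~0 dB re FS
    spec = np.fft.rfft(frame * w)
    psd = (np.abs(spec) ** 2) * (2.0 / (np.sum(w**2) * sample_rate))
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    df = freqs[1] - freqs[0] if freqs.size > 1 else sample_rate / n

    lo, hi = fb.band_edges_hz()
    power = np.empty(fb.n_channels)
    for i in range(fb.n_channels):
        sel = (freqs >= lo[i]) & (freqs < hi[i])
        power[i] = np.sum(psd[sel]) * df
    with np.errstate(divide="ignore"):
        values = 10.0 * np.log10(power)
    values = np.maximum(values, floor_db)
    return ChannelSpectrum(values, fb)


def read_wav_mono(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read a WAV file (PCM or float), average channels to mono, scale to [-1, 1]."""
    rate, data = wavfile.read(os.fspath(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, int(rate)


def chop_corpus(
    paths: Iterable[str | os.PathLike],
    frame_length_s: float = 0.2,
    *,
    target_rate: int = CORPUS_SAMPLE_RATE,
    rms_floor_dbfs: float = FRAME_RMS_FLOOR_DBFS,
) -> Iterator[tuple[np.ndarray, int]]:
    """Chop WAV files into non-overlapping frames of ``frame_length_s``.

    Files are resampled to ``target_rate``; the trailing remainder of each
    file is discarded, as are near-silent frames (RMS below
    ``rms_floor_dbfs`` dB re full scale).  Unreadable files are logged and
    skipped.  Yields ``(frame_samples, sample_rate)`` pairs.
    """
    if frame_length_s <= 0:
        raise ValueError("frame length must be positive")
    rms_floor = 10.0 ** (rms_floor_dbfs / 20.0)
    for path in paths:
        try:
            data, rate = read_wav_mono(path)
        except Exception as exc:  # unreadable file: skip, do not abort the pool
            log.warning("skipping unreadable audio file %s: %s", path, exc)
            continue
        if rate != target_rate:
            g = np.gcd(rate, target_rate)
            data = resample_poly(data, target_rate // g, rate // g)
            rate = target_rate
        n_frame = int(round(frame_length_s * rate))
        n_full = data.size // n_frame
        for k in range(n_full):
            frame = data[k * n_frame : (k + 1) * n_frame]
            if np.sqrt(np.mean(frame**2)) < rms_floor:
                continue
            yield frame, rate
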