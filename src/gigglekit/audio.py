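"""Waveform container and RIFF PCM WAV I/O.

All audio in the package is mono PCM at a single sample rate (44.1 kHz by
default). Files are written as 16-bit integer RIFF WAV so that a written
dataset round-trips sample-exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

_INT16_FULL_SCALE = 32767.0


@dataclass
class Waveform:
    """Mono audio signal.

    samples are float64 in [-1, 1]; sample_rate in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires a 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def normalized(self, peak: float = 0.9) -> "Waveform":
        """Scale so the absolute peak equals ``peak`` (no-op on silence)."""
        m = np.max(np.abs(self.samples))
        if m == 0:
            return Waveform(self.samples.copy(), self.sample_rate)
        return Waveform(self.samples * (peak / m), self.sample_rate)

    def slice(self, start_s: float, end_s: float) -> "Waveform":
        i = int(round(start_s * self.sample_rate))
        j = int(round(end_s * self.sample_rate))
        return Waveform(self.samples[i:j], self.sample_rate)


def write_wav(path: str | Path, wave: Waveform) -> None:
    """Write 16-bit mono PCM. Samples are clipped to [-1, 1] first."""
    x = np.clip(wave.samples, -1.0, 1.0)
    data = np.round(x * _INT16_FULL_SCALE).astype(np.int16)
    wavfile.write(str(path), int(wave.sample_rate), data)


def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, int(rate))
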