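"""Mono waveforms and WAV round-tripping (PCM16 / float32 via scipy)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = ["Waveform", "read_wav", "write_wav"]


@dataclass
class Waveform:
    """Mono audio: samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def read_wav(path, downmix: bool = False) -> Waveform:
    """Read a WAV file into a mono :class:`Waveform`.

    Integer PCM is rescaled to [-1, 1].  Multi-channel input raises unless
    ``downmix=True``, in which case channels are averaged.
    """
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        if not downmix:
            raise ValueError(
                f"{path}: {data.shape[1]}-channel audio; mono required "
                "(pass downmix=True to average channels)"
            )
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        # divide by the positive full-scale value (matching the encoder),
        # then clip the single most-negative code into range
        info = np.iinfo(data.dtype)
        data = np.clip(data.astype(float) / info.max, -1.0, 1.0)
    else:
        data = data.astype(float)
    return Waveform(data, int(rate))


def write_wav(path, w: Waveform, subtype: str = "float32") -> None:
    """Write a waveform as WAV; ``subtype`` is ``"float32"`` or ``"pcm16"``."""
    x = np.clip(w.samples, -1.0, 1.0)
    if subtype == "float32":
        wavfile.write(path, w.sample_rate, x.astype(np.float32))
    elif subtype == "pcm16":
        wavfile.write(path, w.sample_rate, np.round(x * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")
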