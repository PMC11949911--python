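"""Audio containers and WAV file I/O.

The whole DSP layer operates on :class:`AudioBuffer`: a float array of
dimensionless amplitudes in [-1, 1] with an explicit sample rate.  Samples are
stored channel-major, shape ``(channels, n_samples)``, so every filter can be
written once and broadcast over channels.  Mono input may be given as a 1-D
array and is stored as a single row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioBuffer", "read_wav", "write_wav"]

DEFAULT_SAMPLE_RATE = 44_100


@dataclass
class AudioBuffer:
    """A sampled waveform.

    Parameters
    ----------
    samples
        Amplitudes in ``[-1, 1]``, shape ``(n_samples,)`` (mono) or
        ``(channels, n_samples)`` with 1 or 2 channels.
    sample_rate
        Sampling frequency in Hz (default 44,100).
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim == 1:
            s = s[np.newaxis, :]
        if s.ndim != 2 or s.shape[0] not in (1, 2):
            raise ValueError(
                f"samples must be (n,) or (1|2, n); got shape {np.shape(self.samples)}"
            )
        if not np.all(np.isfinite(s)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = s

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds (``n_samples / sample_rate``)."""
        return self.n_samples / self.sample_rate

    # -- convenience ----------------------------------------------------
    def mono(self) -> np.ndarray:
        """Channel-averaged 1-D view of the signal."""
        return self.samples.mean(axis=0)

    def rms(self) -> float:
        """Root-mean-square amplitude over all channels."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def copy_with(self, samples: np.ndarray) -> "AudioBuffer":
        return AudioBuffer(samples, self.sample_rate)

    def clipped(self) -> "AudioBuffer":
        """Hard-clip to [-1, 1]."""
        return self.copy_with(np.clip(self.samples, -1.0, 1.0))

    def to_duration(self, seconds: float) -> "AudioBuffer":
        """Loop-pad or trim to an exact duration.

        Mirrors the stimulus preparation convention: clips longer than the
        target are truncated, shorter ones are looped until they exceed the
        target and then truncated.
        """
        n_target = int(round(seconds * self.sample_rate))
        s = self.samples
        if s.shape[1] == 0:
            raise ValueError("cannot extend an empty buffer")
        if s.shape[1] < n_target:
            reps = int(np.ceil(n_target / s.shape[1]))
            s = np.tile(s, (1, reps))
        return self.copy_with(s[:, :n_target])


def read_wav(path) -> AudioBuffer:
    """Read a PCM (16/24/32-bit) or float32 WAV file into an AudioBuffer."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 1:
        data = data[:, np.newaxis]
    if data.dtype == np.int16:
        scaled = data / 32768.0
    elif data.dtype == np.int32:
        scaled = data / 2147483648.0
    elif data.dtype == np.uint8:
        scaled = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64
        scaled = data.astype(np.float64)
    return AudioBuffer(np.clip(scaled.T, -1.0, 1.0), rate)


def write_wav(path, audio: AudioBuffer, dtype: str = "float32") -> None:
    """Write an AudioBuffer as WAV (``dtype``: 'float32' or 'int16')."""
    s = np.clip(audio.samples, -1.0, 1.0).T
    if s.shape[1] == 1:
        s = s[:, 0]
    if dtype == "int16":
        out = np.round(s * 32767.0).astype(np.int16)
    elif dtype == "float32":
        out = s.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    wavfile.write(path, audio.sample_rate, out)
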