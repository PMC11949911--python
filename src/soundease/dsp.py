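"""Low-level DSP primitives used by the filter engine.

All functions act on a channel-major float array ``x`` of shape
``(channels, n)`` and return an array of identical shape — length preservation
is a hard contract for every primitive here, including the pitch shifter.

Design notes
------------
* The peaking (peak/notch) equalizer is the RBJ-cookbook second-order
  parametric biquad, parameterized by center frequency, bandwidth in Hz
  (Q = f0/BW) and a *linear* peak gain (1.0 = identity; internally converted
  to dB for the coefficient formulas).
* Band filters are Butterworth IIR of second order: ``scipy.signal.butter``
  with N=2 for low/high-pass and N=1 for band-pass/band-stop (a band design of
  order N has 2N poles, so N=1 is the second-order band filter).
* The reverb is a classic Schroeder network (four parallel feedback combs into
  two series allpasses) with fixed internal constants; the exposed control is
  the dry/wet mix only.
* The flanger adds a delayed copy whose delay is sinusoidally modulated
  (base 5 ms, depth 2 ms) at the given LFO frequency, mixed by a dry/wet
  "power" control.
* Pitch shifting is a phase vocoder: time-stretch by the semitone ratio, then
  resample back to the original length, so duration is preserved exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "fader",
    "peaking_eq",
    "butter_lowpass",
    "butter_highpass",
    "butter_bandpass",
    "butter_bandstop",
    "add_white_noise",
    "add_sine",
    "schroeder_reverb_mix",
    "flanger",
    "pitch_shift",
]


def fader(x: np.ndarray, gain: float) -> np.ndarray:
    """Stereo fader: multiply all channels by a linear gain."""
    return x * float(gain)


# ---------------------------------------------------------------------------
# Biquad peaking EQ (RBJ audio-EQ cookbook)
# ---------------------------------------------------------------------------

def _peaking_coeffs(f0: float, bw: float, gain: float, fs: float):
    nyq = fs / 2.0
    f0 = min(max(f0, 1.0), nyq * 0.999)
    # Q from bandwidth in Hz; guard very narrow bands
    q = f0 / max(bw, 1e-6)
    a_amp = np.sqrt(max(gain, 1e-9))  # amplitude gain at peak = gain
    w0 = 2.0 * np.pi * f0 / fs
    alpha = np.sin(w0) / (2.0 * q)
    cosw = np.cos(w0)
    b = np.array([1.0 + alpha * a_amp, -2.0 * cosw, 1.0 - alpha * a_amp])
    a = np.array([1.0 + alpha / a_amp, -2.0 * cosw, 1.0 - alpha / a_amp])
    return b / a[0], a / a[0]


def peaking_eq(x: np.ndarray, fs: float, center: float, bandwidth: float, gain: float) -> np.ndarray:
    """Second-order parametric peak/notch filter.

    ``gain`` is the linear amplitude ratio at the center frequency: >1 boosts,
    <1 cuts, exactly 1 bypasses.
    """
    if gain == 1.0:
        return x
    b, a = _peaking_coeffs(center, bandwidth, gain, fs)
    return signal.lfilter(b, a, x, axis=-1)


# ---------------------------------------------------------------------------
# Butterworth second-order filters
# ---------------------------------------------------------------------------

def _clip_edge(f: float, fs: float) -> float:
    return min(max(f, 1.0), fs / 2.0 * 0.999)


def butter_lowpass(x: np.ndarray, fs: float, cutoff: float, zero_phase: bool = False) -> np.ndarray:
    b, a = signal.butter(2, _clip_edge(cutoff, fs), btype="lowpass", fs=fs)
    filt = signal.filtfilt if zero_phase else signal.lfilter
    return filt(b, a, x, axis=-1)


def butter_highpass(x: np.ndarray, fs: float, cutoff: float, zero_phase: bool = False) -> np.ndarray:
    b, a = signal.butter(2, _clip_edge(cutoff, fs), btype="highpass", fs=fs)
    filt = signal.filtfilt if zero_phase else signal.lfilter
    return filt(b, a, x, axis=-1)


def _band_edges(center: float, width: float, fs: float):
    # geometric centering: lo*hi = center^2 and hi-lo = width, so the band
    # design's center (the notch zero / passband peak) lands on `center`
    hi = (width + np.sqrt(width**2 + 4.0 * center**2)) / 2.0
    lo = _clip_edge(hi - width, fs)
    hi = _clip_edge(hi, fs)
    if hi <= lo:
        hi = min(lo + 1.0, fs / 2.0 * 0.9999)
    return lo, hi


def butter_bandpass(x: np.ndarray, fs: float, center: float, width: float, zero_phase: bool = False) -> np.ndarray:
    lo, hi = _band_edges(center, width, fs)
    b, a = signal.butter(1, [lo, hi], btype="bandpass", fs=fs)
    filt = signal.filtfilt if zero_phase else signal.lfilter
    return filt(b, a, x, axis=-1)


def butter_bandstop(x: np.ndarray, fs: float, center: float, width: float) -> np.ndarray:
    """Second-order Butterworth band-reject (notch) filter.

    Widths below 1 Hz bypass: such a notch is both inaudible and numerically
    marginal (poles essentially on the unit circle), and the registry default
    width of 0.1 Hz is treated as "filter untouched".
    """
    if width < 1.0:
        return x
    lo, hi = _band_edges(center, width, fs)
    b, a = signal.butter(1, [lo, hi], btype="bandstop", fs=fs)
    return signal.lfilter(b, a, x, axis=-1)


# ---------------------------------------------------------------------------
# Additive sources
# ---------------------------------------------------------------------------

def add_white_noise(x: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Add uniform white noise with the given peak amplitude (same per channel)."""
    if amplitude == 0.0:
        return x
    noise = rng.uniform(-amplitude, amplitude, size=x.shape[1])
    return x + noise[np.newaxis, :]


def add_sine(x: np.ndarray, fs: float, amplitude: float, frequency: float) -> np.ndarray:
    """Add a steady sine tone (tinnitus simulation)."""
    if amplitude == 0.0:
        return x
    t = np.arange(x.shape[1]) / fs
    return x + amplitude * np.sin(2.0 * np.pi * frequency * t)[np.newaxis, :]


# ---------------------------------------------------------------------------
# Schroeder reverb
# ---------------------------------------------------------------------------

_COMB_DELAYS_44K = (1557, 1617, 1491, 1422)
_COMB_FEEDBACK = 0.84
_ALLPASS_DELAYS_44K = (225, 556)
_ALLPASS_G = 0.5


def _comb(x1d: np.ndarray, delay: int, g: float) -> np.ndarray:
    b = np.zeros(delay + 1)
    b[delay] = 1.0
    a = np.zeros(delay + 1)
    a[0] = 1.0
    a[delay] = -g
    return signal.lfilter(b, a, x1d)


def _allpass(x1d: np.ndarray, delay: int, g: float) -> np.ndarray:
    b = np.zeros(delay + 1)
    b[0] = -g
    b[delay] = 1.0
    a = np.zeros(delay + 1)
    a[0] = 1.0
    a[delay] = -g
    return signal.lfilter(b, a, x1d)


def schroeder_reverb_mix(x: np.ndarray, fs: float, dry_wet: float) -> np.ndarray:
    """Echo-chamber reverb mixed with the dry signal.

    ``dry_wet`` 0 bypasses entirely; 1 is fully wet.
    """
    if dry_wet == 0.0:
        return x
    scale = fs / 44_100.0
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        wet = np.zeros(x.shape[1])
        for d in _COMB_DELAYS_44K:
            wet += _comb(x[c], max(1, int(round(d * scale))), _COMB_FEEDBACK)
        wet *= 0.25
        for d in _ALLPASS_DELAYS_44K:
            wet = _allpass(wet, max(1, int(round(d * scale))), _ALLPASS_G)
        out[c] = (1.0 - dry_wet) * x[c] + dry_wet * wet
    return out


# ---------------------------------------------------------------------------
# Flanger
# ---------------------------------------------------------------------------

_FLANGER_BASE_S = 0.005
_FLANGER_DEPTH_S = 0.002


def flanger(x: np.ndarray, fs: float, power: float, frequency: float) -> np.ndarray:
    """Mix in a copy delayed by 5 ms +/- 2 ms, modulated at ``frequency`` Hz."""
    if power == 0.0:
        return x
    n = x.shape[1]
    t = np.arange(n) / fs
    delay_s = _FLANGER_BASE_S + _FLANGER_DEPTH_S * np.sin(2.0 * np.pi * frequency * t)
    src = t - delay_s
    idx = np.clip(src * fs, 0.0, n - 1.0)
    i0 = np.floor(idx).astype(np.intp)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = idx - i0
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        delayed = (1.0 - frac) * x[c, i0] + frac * x[c, i1]
        out[c] = (1.0 - power) * x[c] + power * delayed
    return out


# ---------------------------------------------------------------------------
# Phase-vocoder pitch shift (duration preserving)
# ---------------------------------------------------------------------------

_PV_NFFT = 2048
_PV_HOP = 512


def _stft_frames(x1d: np.ndarray, nfft: int, hop: int) -> np.ndarray:
    win = np.hanning(nfft)
    n_frames = 1 + max(0, (len(x1d) - nfft)) // hop
    idx = np.arange(nfft)[np.newaxis, :] + hop * np.arange(n_frames)[:, np.newaxis]
    return np.fft.rfft(x1d[idx] * win, axis=1)


def _time_stretch(x1d: np.ndarray, rate: float) -> np.ndarray:
    """Phase-vocoder time stretch by ``rate`` (>1 = longer output)."""
    nfft, hop = _PV_NFFT, _PV_HOP
    spec = _stft_frames(np.pad(x1d, (0, nfft)), nfft, hop)
    n_frames = spec.shape[0]
    # fractional read positions into the analysis frames
    steps = np.arange(0, n_frames - 1, 1.0 / rate)
    omega = 2.0 * np.pi * hop * np.arange(nfft // 2 + 1) / nfft
    phase = np.angle(spec[0])
    win = np.hanning(nfft)
    out = np.zeros(int(len(steps) * hop + nfft))
    pos = 0
    for s in steps:
        i = int(s)
        frac = s - i
        mag = (1.0 - frac) * np.abs(spec[i]) + frac * np.abs(spec[i + 1])
        out[pos : pos + nfft] += win * np.fft.irfft(mag * np.exp(1j * phase), n=nfft)
        dphi = np.angle(spec[i + 1]) - np.angle(spec[i]) - omega
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase = phase + omega + dphi
        pos += hop
    # COLA normalization for the Hann window at this hop
    out /= (nfft / hop) * 0.5
    return out


def pitch_shift(x: np.ndarray, fs: float, semitones: float) -> np.ndarray:
    """Shift pitch by ``semitones`` while preserving signal length exactly."""
    if semitones == 0.0:
        return x
    ratio = 2.0 ** (semitones / 12.0)
    n = x.shape[1]
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        stretched = _time_stretch(x[c], ratio)
        # resample the stretched signal back onto n samples -> pitch * ratio
        src = np.arange(n) * ratio
        src = np.clip(src, 0, len(stretched) - 1.000001)
        i0 = np.floor(src).astype(np.intp)
        frac = src - i0
        out[c] = (1.0 - frac) * stretched[i0] + frac * stretched[i0 + 1]
    return out
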