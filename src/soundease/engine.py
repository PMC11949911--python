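"""The auditory filter engine: single filters, dynamic suppression, chains.

The engine realizes the two task chains:

* **Recollection**: base-volume correction, then (in palette order)
  Amplify(All) -> Amplify(Low/Medium/High) -> Noise -> Tinnitus ->
  Band reject -> Echo -> Flanger -> Water effect.
* **Easing**: base-volume correction, then the three-band volume crossover ->
  Pitch shift -> Change suppression -> Volume change (All) -> Noise ->
  Tinnitus -> Band reject -> Echo -> Flanger -> Water effect.

Every filter at its registry default is an identity stage (the tinnitus tone
is only silent at amplitude 0 — its clamped default is audible by design).
The chain clips to [-1, 1] once, at the output; intermediate stages are left
unclipped so gain staging composes linearly.
"""

from __future__ import annotations

import warnings
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from . import dsp
from .audio import AudioBuffer
from .specs import FilterSettings, task_specs

__all__ = [
    "volume_correction_db",
    "base_volume_adjust",
    "apply_static_filter",
    "change_suppression",
    "change_suppression_gain",
    "apply_chain",
    "SUPPRESSION_FRAME",
    "SUPPRESSION_WINDOW_FRAMES",
]

#: Analysis frame length (samples) for the change-suppression loudness tracker.
SUPPRESSION_FRAME = 1024
#: Number of frame-to-frame differences averaged by the trigger.
SUPPRESSION_WINDOW_FRAMES = 16

#: Water effect: fixed two-band EQ, boost at 260 Hz (bw 240), cut at 4,400 Hz
#: (bw 3,600), both scaled by one 0-1 control.  At control 1 the boost is
#: +12 dB and the cut -12 dB (fixed internal constants).
_WATER_BOOST = (260.0, 240.0)
_WATER_CUT = (4400.0, 3600.0)
_WATER_MAX_DB = 12.0

# Amplify band parameters: (center Hz, bandwidth Hz)
_AMPLIFY_BANDS = {
    "amplify_low": (100.0, 100.0),
    "amplify_medium": (1100.0, 900.0),
    "amplify_high": (11100.0, 9000.0),
}

# Easing crossover
_XOVER_LOW_CUT = 200.0
_XOVER_HIGH_CUT = 2000.0
_XOVER_BAND = (1100.0, 900.0)  # center, bandwidth


def volume_correction_db(o: float) -> float:
    """Base-volume correction A (dB) from the device volume setting ``o``.

    A = 2.0 * (0.5 - o) / 0.0625 = 32 * (0.5 - o): zero at the reference
    setting 0.5, +16 dB at o = 0 and -16 dB at o = 1, matching the
    [-16, 16] span used for covariate normalization.
    """
    if not (0.0 <= o <= 1.0):
        raise ValueError(f"volume setting o must be in [0, 1], got {o}")
    return 32.0 * (0.5 - o)


def base_volume_adjust(audio: AudioBuffer, o: float) -> AudioBuffer:
    """Scale the signal by 10^(A/20) for A = 32*(0.5-o); clip to [-1, 1]."""
    a_db = volume_correction_db(o)
    if a_db == 0.0:
        return audio
    return audio.copy_with(np.clip(audio.samples * 10.0 ** (a_db / 20.0), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Static (time-invariant) filter dispatch
# ---------------------------------------------------------------------------

def _amplify_all(x, fs, p, rng):
    return dsp.fader(x, p["gain"])


def _amplify_band(name):
    center, bw = _AMPLIFY_BANDS[name]

    def run(x, fs, p, rng):
        return dsp.peaking_eq(x, fs, center, bw, p["gain"])

    return run


def _noise(x, fs, p, rng):
    return dsp.add_white_noise(x, p["amplitude"], rng)


def _tinnitus(x, fs, p, rng):
    return dsp.add_sine(x, fs, p["amplitude"], p["frequency"])


def _band_reject(x, fs, p, rng):
    return dsp.butter_bandstop(x, fs, p["center"], p["width"])


def _echo(x, fs, p, rng):
    return dsp.schroeder_reverb_mix(x, fs, p["dry_wet"])


def _flanger(x, fs, p, rng):
    return dsp.flanger(x, fs, p["power"], p["frequency"])


def _water(x, fs, p, rng):
    g = p["gain"]
    if g == 0.0:
        return x
    boost = 10.0 ** (_WATER_MAX_DB * g / 20.0)
    cut = 10.0 ** (-_WATER_MAX_DB * g / 20.0)
    x = dsp.peaking_eq(x, fs, *_WATER_BOOST, boost)
    return dsp.peaking_eq(x, fs, *_WATER_CUT, cut)


def _volume_all(x, fs, p, rng):
    return dsp.fader(x, p["gain"])


def _pitch_shift(x, fs, p, rng):
    return dsp.pitch_shift(x, fs, p["semitones"])


_DISPATCH: Dict[str, Callable] = {
    "amplify_all": _amplify_all,
    "amplify_low": _amplify_band("amplify_low"),
    "amplify_medium": _amplify_band("amplify_medium"),
    "amplify_high": _amplify_band("amplify_high"),
    "noise": _noise,
    "tinnitus": _tinnitus,
    "band_reject": _band_reject,
    "echo": _echo,
    "flanger": _flanger,
    "water": _water,
    "volume_all": _volume_all,
    "pitch_shift": _pitch_shift,
}


def apply_static_filter(
    audio: AudioBuffer,
    filter_name: str,
    params: Dict[str, float],
    noise_seed: int = 0,
) -> AudioBuffer:
    """Apply one named time-invariant filter with the given parameters.

    Output has the same length as the input and is clipped to [-1, 1].
    The three Easing band-volume filters form one crossover stage and are
    applied via :func:`apply_chain`; ``change_suppression`` is the dynamic
    stage with its own entry point.
    """
    if audio.n_samples == 0:
        raise ValueError("audio is empty")
    try:
        fn = _DISPATCH[filter_name]
    except KeyError:
        raise KeyError(f"unknown filter {filter_name!r}") from None
    rng = np.random.default_rng(noise_seed)
    y = fn(audio.samples, audio.sample_rate, params, rng)
    return audio.copy_with(np.clip(y, -1.0, 1.0))


def _volume_crossover(x: np.ndarray, fs: float, g_low: float, g_med: float, g_high: float) -> np.ndarray:
    """Easing three-band volume stage.

    Implemented as a delta crossover, ``y = x + (gL-1) LP(x) + (gM-1) BP(x)
    + (gH-1) HP(x)``, so unity gains are an exact identity and each gain
    rescales its Butterworth band.  The band extractions run zero-phase
    (forward-backward), which keeps the subtraction phase-true: at gain 0 the
    band is removed rather than phase-smeared.
    """
    y = x
    if g_low != 1.0:
        y = y + (g_low - 1.0) * dsp.butter_lowpass(x, fs, _XOVER_LOW_CUT, zero_phase=True)
    if g_med != 1.0:
        y = y + (g_med - 1.0) * dsp.butter_bandpass(x, fs, *_XOVER_BAND, zero_phase=True)
    if g_high != 1.0:
        y = y + (g_high - 1.0) * dsp.butter_highpass(x, fs, _XOVER_HIGH_CUT, zero_phase=True)
    return y


# ---------------------------------------------------------------------------
# Change suppression (dynamic gain ducker)
# ---------------------------------------------------------------------------

def change_suppression_gain(
    audio: AudioBuffer,
    threshold: float,
    suppression: float,
    back_time: float,
    mode: str = "mean_abs",
) -> np.ndarray:
    """Per-sample gain trajectory of the change-suppression filter.

    The signal is analyzed in consecutive 1,024-sample frames; each frame's
    amplitude is its mean absolute value (``mode="mean_abs"``, default) or its
    RMS (``mode="rms"``).  For every new frame the mean of the last 16
    frame-to-frame amplitude differences (signed: a rise detector) is
    compared against ``threshold``; when it exceeds the threshold the gain
    drops to ``suppression`` for that frame and then relaxes linearly back to
    1.0 over ``back_time`` seconds.  A re-trigger restarts the relaxation.

    Returns a gain array of length ``n_samples`` in (0, 1]; never exceeds 1.
    """
    frame = SUPPRESSION_FRAME
    window = SUPPRESSION_WINDOW_FRAMES
    mono = np.abs(audio.mono())
    n = len(mono)
    n_frames = n // frame
    if n_frames < window + 1:
        warnings.warn(
            f"audio shorter than {window + 1} analysis frames; change suppression bypassed",
            stacklevel=2,
        )
        return np.ones(n)
    frames = mono[: n_frames * frame].reshape(n_frames, frame)
    if mode == "mean_abs":
        amp = frames.mean(axis=1)
    elif mode == "rms":
        amp = np.sqrt(np.square(frames).mean(axis=1))
    else:
        raise ValueError(f"unknown amplitude mode {mode!r}")
    diffs = np.diff(amp)
    # mean of the last `window` differences, available from frame `window`
    means = np.convolve(diffs, np.ones(window) / window, mode="valid")
    triggered = np.zeros(n_frames, dtype=bool)
    triggered[window:] = means > threshold

    fs = audio.sample_rate
    gain = np.ones(n)
    last_trigger_end: Optional[int] = None  # sample index where relaxation starts
    for f in range(n_frames):
        start, stop = f * frame, (f + 1) * frame
        if triggered[f]:
            gain[start:stop] = suppression
            last_trigger_end = stop
        elif last_trigger_end is not None:
            t = (np.arange(start, stop) - last_trigger_end) / fs
            g = suppression + (1.0 - suppression) * np.clip(t / back_time, 0.0, 1.0)
            gain[start:stop] = g
    if last_trigger_end is not None and n_frames * frame < n:
        t = (np.arange(n_frames * frame, n) - last_trigger_end) / fs
        gain[n_frames * frame :] = suppression + (1.0 - suppression) * np.clip(
            t / back_time, 0.0, 1.0
        )
    return gain


def change_suppression(
    audio: AudioBuffer,
    threshold: float,
    suppression: float,
    back_time: float,
    mode: str = "mean_abs",
) -> AudioBuffer:
    """Duck sudden loudness increases (see :func:`change_suppression_gain`)."""
    gain = change_suppression_gain(audio, threshold, suppression, back_time, mode)
    return audio.copy_with(audio.samples * gain[np.newaxis, :])


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

#: Recollection chain order (after base-volume adjustment).
RECOLLECTION_CHAIN: Tuple[str, ...] = (
    "amplify_all",
    "amplify_low",
    "amplify_medium",
    "amplify_high",
    "noise",
    "tinnitus",
    "band_reject",
    "echo",
    "flanger",
    "water",
)

#: Easing chain order (after base-volume adjustment).  ``volume_bands`` is the
#: three-band crossover stage; ``change_suppression`` the dynamic ducker.
EASING_CHAIN: Tuple[str, ...] = (
    "volume_bands",
    "pitch_shift",
    "change_suppression",
    "volume_all",
    "noise",
    "tinnitus",
    "band_reject",
    "echo",
    "flanger",
    "water",
)


def chain_order(task: str) -> Tuple[str, ...]:
    task = task.lower()
    if task == "recollection":
        return RECOLLECTION_CHAIN
    if task == "easing":
        return EASING_CHAIN
    raise KeyError(f"unknown task {task!r}")


def apply_chain(
    audio: AudioBuffer,
    settings: FilterSettings,
    o: float = 0.5,
    noise_seed: int = 0,
    order: Optional[Tuple[str, ...]] = None,
) -> AudioBuffer:
    """Run the full task chain for ``settings.task`` over the audio.

    Base-volume correction is applied first; stages whose parameters sit at
    their defaults are identities.  Deterministic for a fixed ``noise_seed``.
    The output is hard-clipped to [-1, 1]; intermediate stages are not.
    """
    fs = audio.sample_rate
    x = base_volume_adjust(audio, o).samples
    rng = np.random.default_rng(noise_seed)
    stages = order if order is not None else chain_order(settings.task)
    for stage in stages:
        try:
            if stage == "volume_bands":
                x = _volume_crossover(
                    x,
                    fs,
                    settings["volume_low.gain"],
                    settings["volume_medium.gain"],
                    settings["volume_high.gain"],
                )
            elif stage == "change_suppression":
                p = settings.filter_params("change_suppression")
                gain = change_suppression_gain(
                    audio.copy_with(x), p["threshold"], p["suppression"], p["back_time"]
                )
                x = x * gain[np.newaxis, :]
            else:
                p = settings.filter_params(stage)
                x = _DISPATCH[stage](x, fs, p, rng)
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(f"filter chain failed at stage {stage!r}: {exc}") from exc
    return audio.copy_with(np.clip(x, -1.0, 1.0))
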