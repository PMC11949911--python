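"""Model input construction: audio embeddings and normalized covariates.

Audio frontend
--------------
A 20-second stimulus is resampled to 16 kHz and embedded as 41 feature frames
of 1,024 features each.  Two frontends share that exact output geometry:

* ``"pretrained"`` — the published YAMNet embedding.  Its weights are not
  bundled with this package and are not downloaded automatically; selecting it
  without weights raises an error that names the fallback.
* ``"fallback"`` (default) — a deterministic log-mel frontend with YAMNet's
  framing: 64 mel bins (125-7,500 Hz, HTK scale), 25 ms windows, 10 ms hop,
  grouped into 0.96-s patches hopped by 0.48 s, each flattened patch projected
  to 1,024 dimensions through a fixed, seeded Gaussian matrix.  The waveform
  is right-padded by one patch hop (0.48 s) so a 20-s clip yields exactly 41
  patches.

Covariates
----------
Session state, participant characteristics and the environment are min-max
scaled to [0, 1] with fixed bounds (sleep 0-1,440 min; fatigue 1-7; age 20-64;
AQ 0-50; AASP quadrants 15-75; AASP auditory total 11-55; volume correction
-16 to +16 dB) and one-hot encodings for sex and the Bluetooth profile.  The
component order is fixed and published as :data:`COVARIATE_SCHEMA`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import resample_poly

from .audio import AudioBuffer
from .specs import FilterSettings, normalize_ratings, normalize_settings

__all__ = [
    "N_FRAMES",
    "N_FEATURES",
    "embed_audio",
    "ParticipantProfile",
    "SessionState",
    "build_covariates",
    "build_easing_inputs",
    "COVARIATE_SCHEMA",
]

N_FRAMES = 41
N_FEATURES = 1024

_TARGET_SR = 16_000
_CLIP_SECONDS = 20.0
_N_MELS = 64
_MEL_FMIN, _MEL_FMAX = 125.0, 7500.0
_WIN = 400  # 25 ms at 16 kHz
_HOP = 160  # 10 ms
_NFFT = 512
_PATCH_FRAMES = 96  # 0.96 s
_PATCH_HOP = 48  # 0.48 s
_PAD_SAMPLES = _PATCH_HOP * _HOP  # right-pad one patch hop (0.48 s)
_LOG_FLOOR = 1e-3
_PROJECTION_SEED = 909


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank() -> np.ndarray:
    edges = _mel_to_hz(np.linspace(_hz_to_mel(_MEL_FMIN), _hz_to_mel(_MEL_FMAX), _N_MELS + 2))
    bins = np.fft.rfftfreq(_NFFT, d=1.0 / _TARGET_SR)
    fb = np.zeros((_N_MELS, len(bins)))
    for i in range(_N_MELS):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


_FB_CACHE: Dict[str, np.ndarray] = {}


def _projection_matrix(seed: int) -> np.ndarray:
    key = f"proj{seed}"
    if key not in _FB_CACHE:
        rng = np.random.default_rng(seed)
        d_in = _PATCH_FRAMES * _N_MELS
        _FB_CACHE[key] = rng.standard_normal((d_in, N_FEATURES)) / np.sqrt(d_in)
    return _FB_CACHE[key]


def _log_mel(x16k: np.ndarray) -> np.ndarray:
    if "fb" not in _FB_CACHE:
        _FB_CACHE["fb"] = _mel_filterbank()
    fb = _FB_CACHE["fb"]
    n_frames = 1 + (len(x16k) - _WIN) // _HOP
    idx = np.arange(_WIN)[np.newaxis, :] + _HOP * np.arange(n_frames)[:, np.newaxis]
    frames = x16k[idx] * np.hanning(_WIN)
    spec = np.abs(np.fft.rfft(frames, n=_NFFT, axis=1)) ** 2
    return np.log(spec @ fb.T + _LOG_FLOOR)


def embed_audio(
    audio: AudioBuffer, frontend: str = "fallback", projection_seed: int = _PROJECTION_SEED
) -> np.ndarray:
    """Embed a stimulus as a ``(41, 1024)`` feature matrix.

    Inputs that are not exactly 20 s are loop-padded or trimmed first,
    mirroring the stimulus-preparation convention.
    """
    if frontend == "pretrained":
        raise RuntimeError(
            "the pretrained YAMNet frontend requires downloaded weights, which are "
            "not bundled; use frontend='fallback' for the deterministic log-mel "
            "frontend with identical 41x1024 output geometry"
        )
    if frontend != "fallback":
        raise ValueError(f"unknown frontend {frontend!r}")
    clip = audio.to_duration(_CLIP_SECONDS)
    x = clip.mono()
    x16 = resample_poly(x, _TARGET_SR, clip.sample_rate) if clip.sample_rate != _TARGET_SR else x
    x16 = np.pad(x16, (0, _PAD_SAMPLES))
    logmel = _log_mel(x16)
    n_patches = 1 + (logmel.shape[0] - _PATCH_FRAMES) // _PATCH_HOP
    starts = _PATCH_HOP * np.arange(n_patches)
    patches = np.stack([logmel[s : s + _PATCH_FRAMES].ravel() for s in starts])
    out = patches @ _projection_matrix(projection_seed)
    if out.shape != (N_FRAMES, N_FEATURES):
        raise AssertionError(f"frontend produced {out.shape}, expected {(N_FRAMES, N_FEATURES)}")
    return out


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

#: Fixed min-max bounds; ``None`` marks one-hot components.
COVARIATE_SCHEMA: Tuple[Tuple[str, object], ...] = (
    ("sleep_minutes", (0.0, 1440.0)),
    ("fatigue_physical", (1.0, 7.0)),
    ("fatigue_mental", (1.0, 7.0)),
    ("age", (20.0, 64.0)),
    ("sex_female", None),
    ("sex_male", None),
    ("aq", (0.0, 50.0)),
    ("aasp_low_registration", (15.0, 75.0)),
    ("aasp_sensation_seeking", (15.0, 75.0)),
    ("aasp_sensory_sensitivity", (15.0, 75.0)),
    ("aasp_sensation_avoiding", (15.0, 75.0)),
    ("aasp_auditory_total", (11.0, 55.0)),
    ("volume_correction_db", (-16.0, 16.0)),
    ("bluetooth_a2dp", None),
    ("bluetooth_hfp", None),
)

N_COVARIATES = len(COVARIATE_SCHEMA)


@dataclass(frozen=True)
class ParticipantProfile:
    """Stable listener characteristics consumed as plain numbers."""

    group: str  # "DD" | "TD"
    age: float
    sex: str  # "female" | "male"
    aq: float
    aasp_low_registration: float
    aasp_sensation_seeking: float
    aasp_sensory_sensitivity: float
    aasp_sensation_avoiding: float
    aasp_auditory_total: float

    def __post_init__(self):
        if self.group not in ("DD", "TD"):
            raise ValueError(f"group must be 'DD' or 'TD', got {self.group!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class SessionState:
    """Per-session condition and environment."""

    sleep_minutes: float
    fatigue_physical: float
    fatigue_mental: float
    volume_o: float = 0.5
    bluetooth_profile: str = "A2DP"

    def __post_init__(self):
        if self.bluetooth_profile not in ("A2DP", "HFP"):
            raise ValueError("bluetooth_profile must be 'A2DP' or 'HFP'")


def _scaled(name: str, value: float, lo: float, hi: float) -> float:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} = {value} outside [{lo}, {hi}]")
    return (value - lo) / (hi - lo)


def build_covariates(
    profile: ParticipantProfile, state: SessionState, volume_correction_db: float
) -> np.ndarray:
    """Unit-scaled covariate vector in :data:`COVARIATE_SCHEMA` order."""
    raw = {
        "sleep_minutes": state.sleep_minutes,
        "fatigue_physical": state.fatigue_physical,
        "fatigue_mental": state.fatigue_mental,
        "age": profile.age,
        "aq": profile.aq,
        "aasp_low_registration": profile.aasp_low_registration,
        "aasp_sensation_seeking": profile.aasp_sensation_seeking,
        "aasp_sensory_sensitivity": profile.aasp_sensory_sensitivity,
        "aasp_sensation_avoiding": profile.aasp_sensation_avoiding,
        "aasp_auditory_total": profile.aasp_auditory_total,
        "volume_correction_db": volume_correction_db,
        "sex_female": 1.0 if profile.sex == "female" else 0.0,
        "sex_male": 1.0 if profile.sex == "male" else 0.0,
        "bluetooth_a2dp": 1.0 if state.bluetooth_profile == "A2DP" else 0.0,
        "bluetooth_hfp": 1.0 if state.bluetooth_profile == "HFP" else 0.0,
    }
    out = np.empty(N_COVARIATES)
    for i, (name, bounds) in enumerate(COVARIATE_SCHEMA):
        out[i] = raw[name] if bounds is None else _scaled(name, raw[name], *bounds)
    return out


def build_easing_inputs(
    covariates: np.ndarray,
    recollection_settings: FilterSettings,
    recollection_ratings: Sequence[float],
) -> np.ndarray:
    """Extend the covariates with the Recollection outcome.

    Appends the 13 min-max normalized Recollection filter parameters and the
    five stress ratings scaled from 1-7 onto [0, 1].
    """
    if recollection_settings.task != "recollection":
        raise ValueError("recollection_settings must be for the Recollection task")
    ratings = np.asarray(recollection_ratings, dtype=float)
    if ratings.shape != (5,):
        raise ValueError("expected five stress ratings")
    return np.concatenate(
        [covariates, normalize_settings(recollection_settings), normalize_ratings(ratings)]
    )
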