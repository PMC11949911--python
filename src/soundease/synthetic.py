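"""Synthetic experiment generator: stimuli, listeners, and trial responses.

No participant data from the original study are published, so this module
fabricates the entire experiment at desk scale from a known ground truth:

* **Stimuli** — 62 clips of 20 s at 44.1 kHz (30 Training, 10
  Training-reserve, 12 Test, 10 Test-reserve), synthesized from parametric
  primitives covering the four stress-inducing sound characters (sudden
  sounds, steady interfering noise, multi-source environments, strong sounds)
  plus low-stress fillers.  Per-clip acoustic descriptors (RMS, band-energy
  shares, onset count) are recorded and drive the response model.
* **Listeners** — 28 DD and 29 TD profiles with trait scores drawn from
  truncated normals inside instrument bounds; DD means are shifted upward on
  AQ, low registration, sensory sensitivity, sensation avoiding and the
  auditory total, with zero shift on sensation seeking.
* **Trials** — for every listener x stimulus x task, a latent stress
  ``L = aversiveness(stimulus) * sensitivity(listener) + noise`` generates
  ratings (discretized to 1-7) and filter settings: each filter is "touched"
  through a noisy threshold link, and touched parameters follow monotone
  functions of ``L``.  Easing ratings subtract a planted easing effect.
  Skips replace Training/Test stimuli with reserves, three repeated stimuli
  probe reproducibility, and a missing-data event removes one Training and
  one Test trial of one listener.

With ``noise_sd = 0`` every link becomes deterministic, so the generative
mapping is exactly recoverable — the basis of the model-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .audio import AudioBuffer
from .specs import param_keys, task_bounds, default_settings, RATING_ITEMS

__all__ = [
    "ExperimentDesign",
    "ResponseModel",
    "Stimulus",
    "generate_stimuli",
    "generate_participants",
    "generate_trials",
    "generate_experiment",
]

SAMPLE_RATE = 44_100
CLIP_SECONDS = 20.0
SOUND_TYPES = ("sudden", "steady", "multiple", "strong", "calm")


@dataclass
class ExperimentDesign:
    """Counts and probabilities defining the experiment layout."""

    n_dd: int = 28
    n_td: int = 29
    n_training: int = 30
    n_training_reserve: int = 10
    n_test: int = 12
    n_test_reserve: int = 10
    n_repeats: int = 3
    skip_probability: float = 31.0 / 2394.0
    # one listener loses one Training and one Test trial (both tasks)
    missing_participant: Optional[int] = 0

    @property
    def n_participants(self) -> int:
        return self.n_dd + self.n_td

    @property
    def n_scored_trials(self) -> int:
        return self.n_training + self.n_test

    @property
    def n_stimuli(self) -> int:
        return self.n_training + self.n_training_reserve + self.n_test + self.n_test_reserve


# ---------------------------------------------------------------------------
# Response model (the recoverable ground truth)
# ---------------------------------------------------------------------------

# Per-filter usage anchors: probability that a filter is touched at average
# stress, chosen to mirror realistic usage frequencies (main volume filters
# around one-half, texture filters like flanger/tinnitus rare).
_USAGE_RECOLLECTION = {
    "amplify_all": 0.57, "amplify_low": 0.45, "amplify_medium": 0.45,
    "amplify_high": 0.49, "noise": 0.26, "tinnitus": 0.13, "band_reject": 0.34,
    "echo": 0.27, "flanger": 0.10, "water": 0.11,
}
_USAGE_EASING = {
    "volume_low": 0.56, "volume_medium": 0.51, "volume_high": 0.66,
    "pitch_shift": 0.33, "change_suppression": 0.35, "volume_all": 0.58,
    "noise": 0.08, "tinnitus": 0.08, "band_reject": 0.33, "echo": 0.08,
    "flanger": 0.03, "water": 0.12,
}

# Setting links: unit value = intercept + slope * L when the filter is touched
# (clipped to [0, 1]).  Recollection links grow with stress (the remembered
# sound felt louder/harsher); Easing volume links shrink (the listener turns
# the sound down to ease it).
_LINKS_RECOLLECTION = {
    "amplify_all.gain": (0.05, 0.35), "amplify_low.gain": (0.05, 0.25),
    "amplify_medium.gain": (0.05, 0.30), "amplify_high.gain": (0.05, 0.30),
    "noise.amplitude": (0.10, 0.20), "tinnitus.amplitude": (0.20, 0.20),
    "tinnitus.frequency": (0.30, 0.15), "band_reject.width": (0.10, 0.25),
    "band_reject.center": (0.25, 0.10), "echo.dry_wet": (0.10, 0.15),
    "flanger.power": (0.10, 0.15), "flanger.frequency": (0.20, 0.10),
    "water.gain": (0.10, 0.15),
}
_LINKS_EASING = {
    "volume_low.gain": (0.55, -0.18), "volume_medium.gain": (0.50, -0.15),
    "volume_high.gain": (0.45, -0.15), "pitch_shift.semitones": (0.50, -0.12),
    "change_suppression.threshold": (0.35, -0.10),
    "change_suppression.suppression": (0.80, -0.25),
    "change_suppression.back_time": (0.05, 0.05),
    "volume_all.gain": (0.45, -0.15), "noise.amplitude": (0.05, 0.10),
    "tinnitus.amplitude": (0.20, 0.20), "tinnitus.frequency": (0.30, 0.15),
    "band_reject.width": (0.10, 0.25), "band_reject.center": (0.25, 0.10),
    "echo.dry_wet": (0.05, 0.10), "flanger.power": (0.10, 0.15),
    "flanger.frequency": (0.20, 0.10), "water.gain": (0.10, 0.15),
}

_RATING_WEIGHTS = {
    "overall": 1.00, "painful": 0.90, "distracting": 1.05,
    "anxious": 0.85, "impeditive": 0.95,
}


@dataclass
class ResponseModel:
    """Ground-truth mapping from (stimulus, listener) to responses.

    ``noise_sd`` scales every stochastic element: latent jitter, usage-link
    noise and setting noise.  At 0 the whole mapping is deterministic.
    ``easing_effect`` is the planted mean rating reduction (rating points)
    in the Easing task.
    """

    easing_effect: float = 1.5
    noise_sd: float = 0.6
    rating_scale: float = 2.4  # rating latent = 1 + rating_scale * L
    usage_slope: float = 0.8
    usage_noise_per_sd: float = 3.0  # usage score sd = this * noise_sd
    setting_noise_per_sd: float = 0.13
    repeat_correlation: float = 0.0  # shared usage noise across presentations

    def __post_init__(self):
        if self.easing_effect < 0 or self.noise_sd < 0:
            raise ValueError("easing_effect and noise_sd must be non-negative")

    def usage_table(self, task: str) -> Dict[str, float]:
        return _USAGE_RECOLLECTION if task == "recollection" else _USAGE_EASING

    def links(self, task: str) -> Dict[str, Tuple[float, float]]:
        return _LINKS_RECOLLECTION if task == "recollection" else _LINKS_EASING

    def usage_intercept(self, task: str, filter_name: str) -> float:
        p = self.usage_table(task)[filter_name]
        return self.usage_noise_per_sd * 0.6 * stats.norm.ppf(p)

    def noiseless_unit_setting(self, task: str, key: str, latent: float) -> float:
        c0, c1 = self.links(task)[key]
        return float(np.clip(c0 + c1 * latent, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class Stimulus:
    stimulus_id: str
    category: str  # training | training_reserve | test | test_reserve
    sound_type: str
    descriptors: Dict[str, float]
    audio: Optional[AudioBuffer] = None

    @property
    def aversiveness(self) -> float:
        return self.descriptors["aversiveness"]


def _tone_complex(t, rng, n_partials, f_lo, f_hi, amp):
    x = np.zeros_like(t)
    for _ in range(n_partials):
        f = rng.uniform(f_lo, f_hi)
        x += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return amp * x / max(n_partials, 1)

def _synthesize(sound_type: str, rng: np.random.Generator) -> np.ndarray:
    n = int(CLIP_SECONDS * SAMPLE_RATE)
    t = np.arange(n) / SAMPLE_RATE
    if sound_type == "calm":
        x = _tone_complex(t, rng, 3, 180, 900, rng.uniform(0.03, 0.08))
        x += rng.uniform(0.004, 0.01) * rng.standard_normal(n)
    elif sound_type == "steady":
        x = rng.uniform(0.15, 0.35) * rng.standard_normal(n)
    elif sound_type == "strong":
        x = _tone_complex(t, rng, 4, 300, 4000, rng.uniform(0.35, 0.55))
        x += rng.uniform(0.2, 0.35) * rng.standard_normal(n)
    elif sound_type == "sudden":
        x = rng.uniform(0.02, 0.05) * rng.standard_normal(n)
        for _ in range(rng.integers(3, 8)):
            start = rng.integers(SAMPLE_RATE, n - SAMPLE_RATE)
            dur = rng.integers(int(0.2 * SAMPLE_RATE), int(0.6 * SAMPLE_RATE))
            burst = rng.uniform(0.4, 0.85) * rng.standard_normal(dur)
            burst *= np.exp(-np.linspace(0, 4, dur))  # sharp onset, decay
            x[start : start + dur] += burst
    elif sound_type == "multiple":
        x = _tone_complex(t, rng, 3, 150, 1200, rng.uniform(0.08, 0.15))
        x += _tone_complex(t, rng, 3, 1500, 6000, rng.uniform(0.05, 0.12))
        x += rng.uniform(0.05, 0.12) * rng.standard_normal(n)
        for _ in range(rng.integers(1, 4)):
            start = rng.integers(0, n - SAMPLE_RATE // 2)
            dur = SAMPLE_RATE // 4
            x[start : start + dur] += rng.uniform(0.15, 0.3) * rng.standard_normal(dur)
    else:
        raise ValueError(f"unknown sound type {sound_type!r}")
    return np.clip(x, -1.0, 1.0)


_ONSET_FRAME = 1024
_ONSET_JUMP = 0.02


def describe_waveform(x: np.ndarray) -> Dict[str, float]:
    """Acoustic descriptors driving the response model."""
    rms = float(np.sqrt(np.mean(x**2)))
    rms_db = 20.0 * np.log10(rms + 1e-9)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / SAMPLE_RATE)
    total = spec.sum() + 1e-12
    low = float(spec[freqs < 200].sum() / total)
    high = float(spec[freqs > 2000].sum() / total)
    n_frames = len(x) // _ONSET_FRAME
    frames = x[: n_frames * _ONSET_FRAME].reshape(n_frames, _ONSET_FRAME)
    frame_rms = np.sqrt((frames**2).mean(axis=1))
    onsets = int(np.sum(np.diff(frame_rms) > _ONSET_JUMP))
    loudness = float(np.clip((rms_db + 35.0) / 32.0, 0.0, 1.0))
    aversiveness = float(
        np.clip(1.8 * loudness + 0.35 * min(onsets, 6) / 6.0 + 0.45 * high, 0.0, 2.5)
    )
    return {
        "rms": rms, "rms_db": rms_db, "low_share": low, "mid_share": 1.0 - low - high,
        "high_share": high, "onset_count": onsets, "loudness": loudness,
        "aversiveness": aversiveness,
    }


def generate_stimuli(
    design: ExperimentDesign = ExperimentDesign(),
    seed: int = 0,
    keep_audio: bool = True,
) -> List[Stimulus]:
    """Synthesize the full labelled stimulus set (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    out: List[Stimulus] = []
    plan = [
        ("training", design.n_training),
        ("training_reserve", design.n_training_reserve),
        ("test", design.n_test),
        ("test_reserve", design.n_test_reserve),
    ]
    k = 0
    for category, count in plan:
        for j in range(count):
            sound_type = SOUND_TYPES[j % len(SOUND_TYPES)]
            x = _synthesize(sound_type, np.random.default_rng(rng.integers(2**31)))
            stim = Stimulus(
                stimulus_id=f"S{k:03d}",
                category=category,
                sound_type=sound_type,
                descriptors=describe_waveform(x),
                audio=AudioBuffer(x, SAMPLE_RATE) if keep_audio else None,
            )
            out.append(stim)
            k += 1
    return out


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

# trait -> (td_mean, dd_mean, sd, lo, hi)
TRAIT_PARAMS = {
    "aq": (17.0, 31.0, 7.0, 0.0, 50.0),
    "aasp_low_registration": (30.0, 42.0, 8.0, 15.0, 75.0),
    "aasp_sensation_seeking": (40.0, 40.0, 8.0, 15.0, 75.0),
    "aasp_sensory_sensitivity": (32.0, 45.0, 8.0, 15.0, 75.0),
    "aasp_sensation_avoiding": (33.0, 44.0, 8.0, 15.0, 75.0),
    "aasp_auditory_total": (25.0, 36.0, 6.0, 11.0, 55.0),
}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def participant_sensitivity(df: pd.DataFrame) -> np.ndarray:
    """Latent auditory sensitivity from trait scores (higher traits -> higher).

    A fixed linear read-out of AQ, sensory sensitivity and the auditory
    total, squashed into (0.4, 1.6).
    """
    z = (
        (df["aq"] - 24.0) / 10.0
        + (df["aasp_sensory_sensitivity"] - 38.0) / 10.0
        + (df["aasp_auditory_total"] - 30.0) / 8.0
    ) / 3.0
    return 0.4 + 1.2 / (1.0 + np.exp(-1.5 * z))


def generate_participants(
    design: ExperimentDesign = ExperimentDesign(), seed: int = 0
) -> pd.DataFrame:
    """Draw listener profiles and session states for both groups."""
    if design.n_dd < 1 or design.n_td < 1:
        raise ValueError("both groups need at least one participant")
    rng = np.random.default_rng(seed + 1)
    n = design.n_participants
    groups = ["DD"] * design.n_dd + ["TD"] * design.n_td
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:02d}" for i in range(n)],
            "group": groups,
            "age": rng.integers(20, 65, size=n),
            "sex": rng.choice(["female", "male"], size=n),
        }
    )
    is_dd = (df["group"] == "DD").to_numpy()
    for trait, (td_m, dd_m, sd, lo, hi) in TRAIT_PARAMS.items():
        vals = np.empty(n)
        vals[is_dd] = _truncated_normal(rng, dd_m, sd, lo, hi, int(is_dd.sum()))
        vals[~is_dd] = _truncated_normal(rng, td_m, sd, lo, hi, int((~is_dd).sum()))
        df[trait] = np.round(vals)
    df["sleep_minutes"] = np.clip(np.round(rng.normal(420, 80, size=n)), 120, 720)
    df["fatigue_physical"] = np.clip(np.round(rng.normal(3.2, 1.3, size=n)), 1, 7)
    df["fatigue_mental"] = np.clip(np.round(rng.normal(3.2, 1.3, size=n)), 1, 7)
    df["volume_o"] = np.round(rng.uniform(0.40, 0.60, size=n), 3)
    df["bluetooth_profile"] = rng.choice(["A2DP", "HFP"], size=n, p=[0.9, 0.1])
    df["sensitivity"] = participant_sensitivity(df)
    return df


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def _setting_columns() -> List[str]:
    keys = sorted(set(param_keys("recollection")) | set(param_keys("easing")))
    return keys


_TASK_CACHE: Dict[str, Tuple] = {}


def _task_tables(task: str):
    """Cached (filter -> param keys, unit defaults) tables per task."""
    if task not in _TASK_CACHE:
        from .specs import task_specs

        lo, hi = task_bounds(task)
        keys = param_keys(task)
        defaults = default_settings(task).values
        defaults_unit = {
            k: (defaults[k] - l) / (h - l) for k, l, h in zip(keys, lo, hi)
        }
        filters = [(f.name, [f"{f.name}.{p.name}" for p in f.params]) for f in task_specs(task)]
        _TASK_CACHE[task] = (filters, defaults_unit)
    return _TASK_CACHE[task]


def _draw_settings(
    task: str,
    latent: float,
    response: ResponseModel,
    rng: np.random.Generator,
    shared_usage_eps: Optional[Dict[str, float]] = None,
    intercepts: Optional[Dict[str, float]] = None,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Unit-scale settings for one trial; returns (unit values, usage eps)."""
    filters, defaults_unit = _task_tables(task)
    links = response.links(task)
    unit: Dict[str, float] = {}
    usage_eps: Dict[str, float] = {}
    for fname, fkeys in filters:
        eps_new = rng.standard_normal()
        if shared_usage_eps is not None:
            rho = response.repeat_correlation
            eps = rho * shared_usage_eps[fname] + np.sqrt(1 - rho**2) * eps_new
        else:
            eps = eps_new
        usage_eps[fname] = eps
        alpha = (
            intercepts[fname] if intercepts is not None else response.usage_intercept(task, fname)
        )
        score = (
            alpha
            + response.usage_slope * (latent - 1.0)
            + response.usage_noise_per_sd * response.noise_sd * eps
        )
        used = score > 0.0
        for key in fkeys:
            if used:
                c0, c1 = links[key]
                u = c0 + c1 * latent
                u += response.setting_noise_per_sd * response.noise_sd * rng.standard_normal()
                unit[key] = float(np.clip(u, 0.0, 1.0))
            else:
                unit[key] = defaults_unit[key]
    return unit, usage_eps


def _discretize(latent_rating: float) -> int:
    return int(np.clip(np.round(latent_rating), 1, 7))


def generate_trials(
    stimuli: Sequence[Stimulus],
    participants: pd.DataFrame,
    response: ResponseModel = ResponseModel(),
    seed: int = 0,
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """Simulate both tasks for every listener; returns a tidy trial table.

    One row per (participant, stimulus, task, presentation).  Scored trials
    carry ``is_repeat = False``; the three reproducibility re-presentations
    carry ``is_repeat = True`` and are excluded from model datasets.  Setting
    columns are unit-scale parameters prefixed ``u_``; native-scale values
    can be recovered through :func:`soundease.specs.denormalize_settings`.
    """
    by_cat: Dict[str, List[Stimulus]] = {}
    for s in stimuli:
        by_cat.setdefault(s.category, []).append(s)
    for cat in ("training", "training_reserve", "test", "test_reserve"):
        if cat not in by_cat:
            raise ValueError(f"stimulus set has no {cat!r} stimuli")

    rng = np.random.default_rng(seed + 2)
    rows: List[Dict] = []
    rec_latents: Dict[Tuple[str, str], float] = {}
    intercepts = {
        task: {f: response.usage_intercept(task, f) for f in response.usage_table(task)}
        for task in ("recollection", "easing")
    }

    for _, part in participants.iterrows():
        pid = part["participant_id"]
        sens = part["sensitivity"]
        # --- presented stimulus list with skip replacement ---------------
        presented: List[Stimulus] = []
        reserves = {
            "training": list(by_cat["training_reserve"]),
            "test": list(by_cat["test_reserve"]),
        }
        for cat in ("training", "test"):
            for stim in by_cat[cat]:
                if rng.uniform() < design.skip_probability and reserves[cat]:
                    stim = reserves[cat].pop(int(rng.integers(len(reserves[cat]))))
                presented.append(stim)
        skip_flags = [s.category.endswith("_reserve") for s in presented]

        repeat_stims = [s for s in presented if s.category == "training"][: design.n_repeats]

        def emit(stim: Stimulus, presentation: int, is_repeat: bool, skip_replaced: bool):
            a = stim.aversiveness
            for task in ("recollection", "easing"):
                latent = a * sens + response.noise_sd * rng.standard_normal()
                latent = max(latent, 0.0)
                if task == "recollection":
                    rec_latents[(pid, stim.stimulus_id)] = latent
                key = (pid, stim.stimulus_id)
                base_latent = rec_latents.get(key, latent)
                shared = None
                if is_repeat:
                    shared = usage_memory.get((pid, stim.stimulus_id, task))
                unit, usage_eps = _draw_settings(
                    task, latent, response, rng, shared, intercepts[task]
                )
                if not is_repeat:
                    usage_memory[(pid, stim.stimulus_id, task)] = usage_eps
                row = {
                    "participant_id": pid,
                    "group": part["group"],
                    "task": task,
                    "stimulus_id": stim.stimulus_id,
                    "stimulus_category": stim.category,
                    "sound_type": stim.sound_type,
                    "presentation": presentation,
                    "is_repeat": is_repeat,
                    "skip_replaced": skip_replaced,
                    "aversiveness": a,
                    "sensitivity": sens,
                    "latent_stress": latent,
                }
                for item in RATING_ITEMS:
                    w = _RATING_WEIGHTS[item]
                    r_lat = 1.0 + response.rating_scale * w * base_latent
                    r_lat += response.noise_sd * 0.5 * rng.standard_normal()
                    if task == "easing":
                        r_lat -= response.easing_effect
                    row[f"rating_{item}"] = _discretize(r_lat)
                for k in param_keys(task):
                    row[f"u_{k}"] = unit[k]
                rows.append(row)

        usage_memory: Dict[Tuple[str, str, str], Dict[str, float]] = {}
        for stim, skipped in zip(presented, skip_flags):
            emit(stim, presentation=1, is_repeat=False, skip_replaced=skipped)
        for stim in repeat_stims:
            emit(stim, presentation=2, is_repeat=True, skip_replaced=False)

    df = pd.DataFrame(rows)
    # missing-data event: one Training and one Test trial of one listener
    if design.missing_participant is not None and len(participants) > design.missing_participant:
        pid = participants.iloc[design.missing_participant]["participant_id"]
        for cat_set in (("training", "training_reserve"), ("test", "test_reserve")):
            mask = (
                (df["participant_id"] == pid)
                & (~df["is_repeat"])
                & (df["stimulus_category"].isin(cat_set))
            )
            if mask.any():
                victim = df.loc[mask, "stimulus_id"].iloc[0]
                df = df[~((df["participant_id"] == pid) & (df["stimulus_id"] == victim) & (~df["is_repeat"]))]
    return df.reset_index(drop=True)


def generate_experiment(
    design: ExperimentDesign = ExperimentDesign(),
    response: ResponseModel = ResponseModel(),
    seed: int = 0,
    keep_audio: bool = False,
) -> Tuple[List[Stimulus], pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: stimuli, participants and trials from one seed."""
    stimuli = generate_stimuli(design, seed, keep_audio=keep_audio)
    participants = generate_participants(design, seed)
    trials = generate_trials(stimuli, participants, response, seed, design)
    return stimuli, participants, trials
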