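"""Filter engine contracts: identities, spectral behavior, dynamics, chains.

Spectral assertions use a steady-state tone-level oracle (projection of the
second half of the signal onto a complex exponential), independent of the
IIR implementations under test.
"""

import numpy as np
import pytest

import soundease as se
from soundease import dsp, engine
from soundease.specs import param_keys, task_specs

FS = 44_100


def tone(freq, seconds=2.0, amp=0.3):
    t = np.arange(int(FS * seconds)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def level_db(x, freq):
    """Steady-state amplitude (dB) of a tone component at ``freq``."""
    n = len(x)
    seg = x[n // 2 :]
    t = np.arange(n // 2, n) / FS
    c = np.abs(np.vdot(np.exp(-2j * np.pi * freq * t), seg)) / len(seg) * 2
    return 20 * np.log10(c + 1e-12)


# ---------------------------------------------------------------------------
# Base volume correction
# ---------------------------------------------------------------------------

def test_volume_correction_endpoints():
    assert engine.volume_correction_db(0.5) == 0.0
    assert engine.volume_correction_db(0.0) == 16.0
    assert engine.volume_correction_db(1.0) == -16.0
    with pytest.raises(ValueError):
        engine.volume_correction_db(1.2)


def test_base_volume_adjust_scales_and_clips():
    audio = se.AudioBuffer(tone(440, amp=0.05), FS)
    mid = engine.base_volume_adjust(audio, 0.5)
    np.testing.assert_array_equal(mid.samples, audio.samples)
    loud = engine.base_volume_adjust(audio, 0.0)
    np.testing.assert_allclose(loud.samples, audio.samples * 10 ** (16 / 20), rtol=1e-12)
    quiet = engine.base_volume_adjust(audio, 1.0)
    np.testing.assert_allclose(quiet.samples, audio.samples * 10 ** (-16 / 20), rtol=1e-12)
    hot = se.AudioBuffer(tone(440, amp=0.9), FS)
    assert np.abs(engine.base_volume_adjust(hot, 0.0).samples).max() == 1.0


# ---------------------------------------------------------------------------
# Identity at registry defaults
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("task", ["recollection", "easing"])
def test_every_filter_default_is_identity(task, short_tone):
    """Each static filter at its registry default passes audio unchanged.

    The tinnitus tone is the documented exception (its clamped default
    amplitude is audible); identity is asserted at amplitude 0 instead.
    """
    defaults = se.default_settings(task)
    for spec in task_specs(task):
        params = defaults.filter_params(spec.name)
        if spec.name == "tinnitus":
            assert params["amplitude"] == 0.05  # documented (clamped) default
            params = dict(params, amplitude=0.0)
        if spec.name in ("volume_low", "volume_medium", "volume_high"):
            continue  # crossover stage covered via the chain test
        if spec.name == "change_suppression":
            out = engine.change_suppression(short_tone, **params)
        else:
            out = se.apply_static_filter(short_tone, spec.name, params)
        np.testing.assert_array_equal(out.samples, short_tone.samples), spec.name


@pytest.mark.parametrize("task", ["recollection", "easing"])
def test_chain_at_defaults_is_identity(task, short_tone):
    settings = se.default_settings(task).replace(tinnitus__amplitude=0.0)
    out = se.apply_chain(short_tone, settings, o=0.5)
    np.testing.assert_array_equal(out.samples, short_tone.samples)


def test_unknown_filter_and_out_of_range_param():
    audio = se.AudioBuffer(tone(440), FS)
    with pytest.raises(KeyError):
        se.apply_static_filter(audio, "chorus", {"gain": 1.0})
    with pytest.raises(ValueError):
        se.FilterSettings("recollection", {"amplify_all.gain": 9.0})
    with pytest.raises(KeyError):
        se.FilterSettings("recollection", {"pitch_shift.semitones": 2.0})


# ---------------------------------------------------------------------------
# Spectral contracts (FFT oracle)
# ---------------------------------------------------------------------------

def test_peaking_amplifiers_monotone_in_band_and_flat_far_out():
    cases = {  # filter -> (in-band probe Hz, far-out probe Hz)
        "amplify_low": (100, 2000),
        "amplify_medium": (1100, 10_000),
        "amplify_high": (11_100, 100),
    }
    for name, (f_in, f_out) in cases.items():
        audio_in = se.AudioBuffer(tone(f_in), FS)
        ref_in = level_db(audio_in.samples[0], f_in)
        levels = []
        for g in (1.0, 2.0, 3.0, 5.0):
            y = se.apply_static_filter(audio_in, name, {"gain": g})
            levels.append(level_db(y.samples[0], f_in) - ref_in)
        assert levels[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(levels) > 0.5), f"{name} not monotone in gain: {levels}"
        audio_out = se.AudioBuffer(tone(f_out), FS)
        y = se.apply_static_filter(audio_out, name, {"gain": 5.0})
        delta = level_db(y.samples[0], f_out) - level_db(audio_out.samples[0], f_out)
        assert abs(delta) < 1.0, f"{name} leaks {delta:.2f} dB far out of band"


def test_band_reject_deep_at_center_and_monotone_in_width():
    center_tone = se.AudioBuffer(tone(1000), FS)
    pass_tone = se.AudioBuffer(tone(100), FS)
    y_c = se.apply_static_filter(center_tone, "band_reject", {"center": 1000, "width": 500})
    y_p = se.apply_static_filter(pass_tone, "band_reject", {"center": 1000, "width": 500})
    atten_center = level_db(y_c.samples[0], 1000) - level_db(center_tone.samples[0], 1000)
    atten_pass = level_db(y_p.samples[0], 100) - level_db(pass_tone.samples[0], 100)
    assert atten_center < -20.0  # tone at the notch center is strongly removed
    assert abs(atten_pass) < 1.0
    # widening the notch attenuates an off-center tone ever more strongly
    off = se.AudioBuffer(tone(1300), FS)
    ref = level_db(off.samples[0], 1300)
    attens = []
    for w in (200.0, 500.0, 1000.0, 2000.0, 4000.0):
        y = se.apply_static_filter(off, "band_reject", {"center": 1000, "width": w})
        attens.append(level_db(y.samples[0], 1300) - ref)
    assert np.all(np.diff(attens) < 0), attens


def test_noise_and_tinnitus_additivity():
    audio = se.AudioBuffer(tone(440, seconds=1.0), FS)
    noisy = se.apply_static_filter(audio, "noise", {"amplitude": 0.01}, noise_seed=3)
    resid = noisy.samples - audio.samples
    assert 0 < np.abs(resid).max() <= 0.01 + 1e-12
    noisy2 = se.apply_static_filter(audio, "noise", {"amplitude": 0.01}, noise_seed=3)
    np.testing.assert_array_equal(noisy.samples, noisy2.samples)  # seeded determinism
    ringing = se.apply_static_filter(audio, "tinnitus", {"amplitude": 0.05, "frequency": 2000})
    boost = level_db(ringing.samples[0], 2000) - level_db(audio.samples[0], 2000)
    assert boost > 20  # tone added where there was none


def test_pitch_shift_preserves_length_and_moves_frequency():
    audio = se.AudioBuffer(tone(440), FS)
    up = se.apply_static_filter(audio, "pitch_shift", {"semitones": 12.0})
    assert up.n_samples == audio.n_samples
    assert level_db(up.samples[0], 880) > level_db(up.samples[0], 440) + 10
    down = se.apply_static_filter(audio, "pitch_shift", {"semitones": -12.0})
    assert down.n_samples == audio.n_samples
    assert level_db(down.samples[0], 220) > level_db(down.samples[0], 440) + 10


def test_echo_flanger_water_alter_signal_but_preserve_shape():
    audio = se.AudioBuffer(tone(440), FS)
    for name, params in [
        ("echo", {"dry_wet": 0.5}),
        ("flanger", {"power": 0.5, "frequency": 1.0}),
        ("water", {"gain": 1.0}),
    ]:
        y = se.apply_static_filter(audio, name, params)
        assert y.samples.shape == audio.samples.shape
        assert np.abs(y.samples - audio.samples).max() > 1e-4
        assert np.abs(y.samples).max() <= 1.0


def test_water_effect_boosts_low_and_cuts_high():
    low = se.AudioBuffer(tone(260), FS)
    high = se.AudioBuffer(tone(4400), FS)
    y_low = se.apply_static_filter(low, "water", {"gain": 1.0})
    y_high = se.apply_static_filter(high, "water", {"gain": 1.0})
    assert level_db(y_low.samples[0], 260) - level_db(low.samples[0], 260) > 3.0
    assert level_db(y_high.samples[0], 4400) - level_db(high.samples[0], 4400) < -3.0


# ---------------------------------------------------------------------------
# Change suppression
# ---------------------------------------------------------------------------

def test_change_suppression_never_triggers_on_steady_tone(short_tone):
    out = engine.change_suppression(short_tone, 0.0015, 0.2, 0.05)
    np.testing.assert_array_equal(out.samples, short_tone.samples)


def test_change_suppression_trigger_and_relaxation():
    fs = FS
    rng = np.random.default_rng(0)
    # half a second of silence, then a loud step that stays constant (sine)
    x = np.concatenate([np.zeros(fs // 2), 0.8 * np.sin(2 * np.pi * 300 * np.arange(fs) / fs)])
    audio = se.AudioBuffer(x, fs)
    gain = engine.change_suppression_gain(audio, 0.0015, 0.2, 0.05)
    step = fs // 2
    frame = engine.SUPPRESSION_FRAME
    assert gain.min() == pytest.approx(0.2)
    assert gain[step + 2 * frame] == pytest.approx(0.2)  # active within a frame of the step
    # ... and back to 1.0 within back_time + one frame after the last trigger
    last_active = np.max(np.nonzero(gain < 1.0 - 1e-6))
    assert np.all(gain[int(last_active + 1) :] >= 1.0 - 1e-6)
    recovered = np.nonzero(gain == 1.0)[0]
    post = recovered[recovered > step]
    assert len(post) > 0
    # gain is piecewise monotone: drops then recovers, never exceeds 1
    assert gain.max() <= 1.0
    out = engine.change_suppression(audio, 0.0015, 0.2, 0.05)
    np.testing.assert_allclose(out.samples[0], x * gain)


def test_change_suppression_short_audio_warns_and_passes_through():
    audio = se.AudioBuffer(np.ones(engine.SUPPRESSION_FRAME * 4) * 0.1, FS)
    with pytest.warns(UserWarning):
        out = engine.change_suppression(audio, 0.0015, 0.5, 0.05)
    np.testing.assert_array_equal(out.samples, audio.samples)


def test_change_suppression_window_duration():
    window_ms = (
        engine.SUPPRESSION_WINDOW_FRAMES * engine.SUPPRESSION_FRAME / FS * 1000.0
    )
    assert round(window_ms) == 372


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def test_chain_single_active_fader(short_tone):
    quiet = se.AudioBuffer(short_tone.samples * 0.5, FS)
    settings = se.default_settings("recollection").replace(
        tinnitus__amplitude=0.0, amplify_all__gain=2.0
    )
    out = se.apply_chain(quiet, settings, o=0.5)
    np.testing.assert_allclose(out.samples, np.clip(2.0 * quiet.samples, -1, 1), atol=1e-12)


def test_chain_deterministic_under_seed(short_tone):
    settings = se.default_settings("easing").replace(
        noise__amplitude=0.02, volume_high__gain=3.0, pitch_shift__semitones=3.0
    )
    a = se.apply_chain(short_tone, settings, o=0.4, noise_seed=7)
    b = se.apply_chain(short_tone, settings, o=0.4, noise_seed=7)
    np.testing.assert_array_equal(a.samples, b.samples)
    c = se.apply_chain(short_tone, settings, o=0.4, noise_seed=8)
    assert np.abs(a.samples - c.samples).max() > 0


def test_easing_volume_all_zero_silences(short_tone):
    settings = se.default_settings("easing").replace(
        tinnitus__amplitude=0.0, volume_all__gain=0.0
    )
    out = se.apply_chain(short_tone, settings, o=0.5)
    assert np.abs(out.samples).max() == 0.0


def test_easing_crossover_band_gains(short_tone):
    low = se.AudioBuffer(tone(100, amp=0.2), FS)
    settings = se.default_settings("easing").replace(
        tinnitus__amplitude=0.0, volume_low__gain=0.0
    )
    out = se.apply_chain(low, settings, o=0.5)
    drop = level_db(out.samples[0], 100) - level_db(low.samples[0], 100)
    assert drop < -10  # low band strongly reduced at gain 0
    high = se.AudioBuffer(tone(8000, amp=0.2), FS)
    out_h = se.apply_chain(high, settings, o=0.5)
    leak = level_db(out_h.samples[0], 8000) - level_db(high.samples[0], 8000)
    assert abs(leak) < 1.0  # high band untouched by the low-gain change


def test_chain_output_always_bounded(short_tone):
    settings = se.default_settings("recollection").replace(
        amplify_all__gain=5.0, noise__amplitude=0.05
    )
    out = se.apply_chain(short_tone, settings, o=0.0)
    assert np.abs(out.samples).max() <= 1.0
    assert out.n_samples == short_tone.n_samples
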