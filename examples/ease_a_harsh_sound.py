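"""Apply the Easing filter chain to a synthetic harsh sound.

Builds a 20-s clip with sudden loud noise bursts, then runs an Easing
configuration that turns the overall and high-band volume down and enables
the change-suppression ducker.  Printed numbers: RMS before/after (overall
energy reduction) and the minimum suppression gain (how hard the ducker
reacted to the bursts).
"""

import numpy as np

import soundease as se
from soundease.engine import change_suppression_gain

fs = 44_100
rng = np.random.default_rng(0)
t = np.arange(fs * 20) / fs
x = 0.05 * rng.standard_normal(len(t))  # quiet background
for start_s in (3.0, 8.0, 14.0):  # three sudden loud bursts
    i = int(start_s * fs)
    x[i : i + fs // 2] += 0.7 * rng.standard_normal(fs // 2) * np.exp(-np.linspace(0, 4, fs // 2))
harsh = se.AudioBuffer(np.clip(x, -1, 1), fs)

settings = se.default_settings("easing").replace(
    tinnitus__amplitude=0.0,          # keep the (audible) tinnitus default off
    volume_all__gain=0.6,             # global volume down
    volume_high__gain=0.4,            # high band further down
    change_suppression__suppression=0.3,  # duck hard on sudden loudness rises
    change_suppression__back_time=0.8,
)
eased = se.apply_chain(harsh, settings, o=0.5)
gain = change_suppression_gain(harsh, threshold=0.0015, suppression=0.3, back_time=0.8)

print(f"input RMS   : {harsh.rms():.4f}")
print(f"eased RMS   : {eased.rms():.4f}  (lower = less acoustic energy reaching the ear)")
print(f"ducker floor: {gain.min():.2f}   (gain applied during the loudness bursts)")
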