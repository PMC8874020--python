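"""Run the per-modality feature extractors on constructed signals.

Each extractor is exercised on a signal with a known answer: band power
of a pure sinusoid (Parseval), heart rate of a pulse train, a pupil
trace with a blink artifact, and the VRS labeling rule.
"""

import numpy as np

from painfusion import (
    BAND_DEFINITIONS,
    band_power,
    heart_rate_from_bvp,
    label_from_vrs,
    pupil_velocity_filter,
)

fs = 500.0
t = np.arange(int(20 * fs)) / fs
alpha_wave = np.sin(2 * np.pi * 10 * t)  # unit 10 Hz sinusoid, variance 1/2
p = band_power(alpha_wave, fs, BAND_DEFINITIONS["alpha"])
print(f"alpha power of unit 10 Hz sinusoid: {p:.4f} (closed form: 0.5)")

fs_bvp = 2048.0
t = np.arange(int(20 * fs_bvp)) / fs_bvp
pulse = np.sin(2 * np.pi * t / 0.8333)  # one beat every 0.8333 s
print(f"heart rate from pulse train: {heart_rate_from_bvp(pulse, fs_bvp):.1f} bpm "
      "(constructed: 72)")

pupil = np.full(200, 4.0)
pupil[100] = 0.5  # blink collapses the measured diameter
cleaned = pupil_velocity_filter(pupil, fs=50.0)
print(f"blink sample 0.5 mm restored to {cleaned[100]:.2f} mm by the "
      "velocity filter")

ratings = [None, 2, 5, 6, 10]
labels = [label_from_vrs("baseline")] + [
    label_from_vrs("session", r) for r in ratings[1:]
]
print(f"ratings {ratings} -> labels {labels}  (1-5 low pain, 6-10 high pain)")
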