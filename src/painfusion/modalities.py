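"""Shared constants for the nine sensing modalities.

Defines modality identifiers, published sampling rates, the facial action
unit inventory, EEG montages with scalp-region groupings, and the canonical
EEG frequency bands.
"""

from __future__ import annotations

from enum import Enum


class Modality(str, Enum):
    """The nine sensing modalities."""

    FE = "fe"      # facial expression (action-unit probabilities)
    EEG = "eeg"    # electroencephalography
    EM = "em"      # eye movement (pupil diameter)
    SC = "sc"      # skin conductance
    BVP = "bvp"    # blood volume pulse
    EMG = "emg"    # electromyography
    RR = "rr"      # respiration
    ST = "st"      # skin temperature
    BP = "bp"      # blood pressure (cuff, pre/post)


#: Canonical ordering used for fusion weight vectors.
MODALITY_ORDER: tuple[str, ...] = (
    "fe", "eeg", "em", "sc", "bvp", "emg", "rr", "st", "bp",
)

#: Sampling rate in Hz per modality; BP has no rate (two cuff readings).
SAMPLING_RATES: dict[str, float | None] = {
    "fe": 30.0,
    "eeg": 500.0,
    "em": 50.0,
    "sc": 2048.0,
    "bvp": 2048.0,
    "emg": 2048.0,
    "rr": 2048.0,
    "st": 2048.0,
    "bp": None,
}

#: The 17 facial action units emitted by AU-probability extractors, in
#: canonical order (AU45, blink, last).
AU_NAMES: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26",
    "AU45",
)

#: Action units with the strongest pain response (brow lowerer, nose
#: wrinkle, upper lip raiser); AU45 (blink) carries none.
PAIN_RESPONSIVE_AUS: frozenset[str] = frozenset({"AU04", "AU09", "AU10"})

#: EEG frequency bands, half-open [lo, hi) in Hz.  Note the deliberate gap
#: at [3, 4): delta stops at 3 and theta starts at 4, mirroring the printed
#: band definitions; frequencies in the gap belong to no band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Default desk-scale 10-20 montage (8 channels).
DEFAULT_EEG_CHANNELS: tuple[str, ...] = (
    "Fz", "Cz", "C3", "C4", "Pz", "P3", "P4", "Oz",
)

#: Scalp-region grouping for the default montage.  The 8-channel montage
#: has no CP electrodes, so C3/C4 stand proxy for the centro-parietal
#: region in which band power decreases under pain; the 32-channel montage
#: below maps true CP sites.
DEFAULT_EEG_REGIONS: dict[str, str] = {
    "Fz": "Other",
    "Cz": "Central",
    "C3": "CentralParietal",
    "C4": "CentralParietal",
    "Pz": "Parietal",
    "P3": "Parietal",
    "P4": "Parietal",
    "Oz": "Other",
}

#: Full 32-channel 10-20 montage (configurable alternative).
EEG_CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2", "AF3", "AF4",
)

EEG_REGIONS_32: dict[str, str] = {
    **{ch: "Other" for ch in EEG_CHANNELS_32},
    "C3": "Central", "Cz": "Central", "C4": "Central",
    "CP5": "CentralParietal", "CP1": "CentralParietal",
    "CP2": "CentralParietal", "CP6": "CentralParietal",
    "P7": "Parietal", "P3": "Parietal", "Pz": "Parietal",
    "P4": "Parietal", "P8": "Parietal",
}

#: Pain-state class labels: baseline, low pain (VRS 1-5), high pain
#: (VRS 6-10).
PAIN_LABELS: tuple[str, ...] = ("B", "LP", "HP")

#: Numeric class codes shared by the cascade scores and the fusion layer.
LABEL_CODES: dict[str, int] = {"B": 0, "LP": 1, "HP": 2}
CODE_LABELS: dict[int, str] = {0: "B", 1: "LP", 2: "HP"}

#: Duration of every analysis window in seconds (one baseline window, then
#: one window per immersion session).
WINDOW_SECONDS: float = 20.0
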