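"""Synthetic multimodal cold-pressor cohort generation.

Emulates the statistical structure of a cold-pressor pain study: each
subject contributes three repeated days; each day starts with a relaxed
20-s baseline recording followed by up to ten 20-s iced-water immersion
sessions, with a 0-10 verbal pain rating (VRS) after every session and the
option to withdraw early once the rating exceeds the subject's tolerance.

The generator has two layers:

1. A *latent window model*: every 20-s window has per-modality feature
   targets equal to a subject baseline plus a configured effect size (in
   standardized, noise-scaled units) times the pain-level code (0 baseline,
   1 for VRS 1-5, 2 for VRS 6-10), plus Gaussian window noise.  This layer
   is sampled directly by :func:`simulate_features` for cohort-scale
   Monte-Carlo work.
2. A *signal renderer*: :func:`synthesize_recording` realizes each window
   as a raw time series at the published sampling rates (AU probabilities
   at 30 Hz, EEG as band-limited noise at 500 Hz, pupil at 50 Hz,
   electrodermal/cardiorespiratory channels at 2048 Hz, and exactly two
   blood-pressure cuff readings per day), constructed so that the feature
   extractors recover the latent targets.

Default effect directions follow the study findings the generator is meant
to emulate: skin conductance, pupil diameter, systolic blood pressure and
parietal EEG power respond positively, skin temperature and
centro-parietal alpha/beta/gamma power respond negatively, facial action
units AU4/AU9/AU10 and EEG carry the largest effects, and heart rate, EMG
and respiration rate are null.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .modalities import (
    AU_NAMES,
    BANDS,
    BAND_NAMES,
    DEFAULT_EEG_CHANNELS,
    DEFAULT_EEG_REGIONS,
    MODALITY_ORDER,
    PAIN_RESPONSIVE_AUS,
    SAMPLING_RATES,
    WINDOW_SECONDS,
)
from .features import label_from_vrs

SeedLike = "int | np.random.SeedSequence"

#: Population baseline means (physical units).
POP_BASELINES: dict[str, float] = {
    "em.pupil_mean": 4.0,    # mm
    "sc.mean": 5.0,          # uS
    "bvp.hr": 72.0,          # bpm
    "emg.rms": 2.0,          # uV
    "rr.rate": 14.0,         # breaths/min
    "st.mean": 31.5,         # degC
    "bp.sys": 115.0,         # mmHg
    "bp.dia": 72.0,          # mmHg
}

#: Population baseline log band power (log variance units) per EEG band.
EEG_BAND_BASE_LOGPOWER: dict[str, float] = {
    "delta": 2.0, "theta": 1.5, "alpha": 1.8, "beta": 1.2, "gamma": 0.8,
}

#: Baseline AU probabilities (blink AU45 higher than expressive units).
AU_BASELINE: dict[str, float] = {
    **{au: 0.12 for au in AU_NAMES}, "AU45": 0.30,
}

#: Lower clips keeping subject baselines physiologically plausible.
_BASELINE_FLOORS: dict[str, float] = {
    "em.pupil_mean": 1.5, "sc.mean": 0.5, "bvp.hr": 45.0, "emg.rms": 0.3,
    "rr.rate": 6.0, "st.mean": 28.0, "bp.sys": 90.0, "bp.dia": 50.0,
}


def _default_effect_sizes() -> dict[str, float]:
    return {
        "sc": 0.6, "pupil": 0.6, "st": -0.4, "hr": 0.0, "emg": 0.0,
        "rr": 0.0, "fe": 0.8, "bp_sys": 1.2, "bp_dia": 0.0,
    }


def _default_eeg_region_effects() -> dict[str, dict[str, float]]:
    return {
        "Parietal": {b: 0.8 for b in BAND_NAMES},
        "CentralParietal": {"alpha": -0.5, "beta": -0.5, "gamma": -0.5},
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "sc": 0.8, "pupil": 0.4, "st": 0.4, "hr": 5.0, "emg": 0.5,
        "rr": 1.5, "fe": 0.08, "eeg": 0.35, "bp": 6.0,
    }


def _default_random_effect_sd() -> dict[str, float]:
    return {
        "sc": 1.2, "pupil": 0.6, "st": 0.6, "hr": 7.0, "emg": 0.8,
        "rr": 2.0, "fe": 0.10, "eeg": 0.3, "eeg_cell": 0.4, "bp": 8.0,
        "bp_delta": 2.0,
    }


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic cohort.

    ``effect_sizes`` are signed standardized shifts per pain-level code
    step (the mean shift in physical units is ``effect * noise_sd``);
    ``eeg_region_effects`` does the same per scalp region and band on the
    log-power scale.  ``seed`` fully determines every generated dataset.
    """

    n_subjects: int = 26
    n_days: int = 3
    seed: int = 0
    effect_sizes: dict[str, float] = field(default_factory=_default_effect_sizes)
    eeg_region_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_eeg_region_effects
    )
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    random_effect_sd: dict[str, float] = field(
        default_factory=_default_random_effect_sd
    )
    # VRS trajectory
    sensitivity_log_sd: float = 0.3
    tolerance_range: tuple[float, float] = (7.0, 10.0)
    growth_rate: float = 0.25
    rating_noise_log_sd: float = 0.15
    day1_rating_shift: float = 1.0
    withdrawal_scale: float = 1.0
    max_sessions: int = 10
    # montage / enabled modalities
    eeg_channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS
    eeg_regions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EEG_REGIONS)
    )
    modalities: tuple[str, ...] = MODALITY_ORDER

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("n_subjects and n_days must be positive")
        if not 1 <= self.max_sessions <= 10:
            raise ValueError("max_sessions must be in [1, 10]")
        for d in (self.effect_sizes, self.noise_sd, self.random_effect_sd):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite config parameter {k}")
        for k, v in self.noise_sd.items():
            if v <= 0:
                raise ValueError(f"noise_sd[{k}] must be positive")
        unknown = set(self.modalities) - set(MODALITY_ORDER)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        """Build a config from a (possibly partial) plain mapping.

        Dict-valued fields are merged over the defaults rather than
        replaced, so a YAML file can override a single effect size.
        """
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, Mapping):
                merged = dict(current)
                for k, v in value.items():
                    if isinstance(v, Mapping) and isinstance(merged.get(k), dict):
                        merged[k] = {**merged[k], **v}
                    else:
                        merged[k] = v
                setattr(cfg, key, merged)
            elif isinstance(current, tuple):
                setattr(cfg, key, tuple(value))
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject parameters driving signal generation.

    ``sensitivity`` multiplies the VRS growth rate; ``tolerance`` is the
    rating above which early withdrawal becomes likely; ``baseline_means``
    hold resting physiology (including per-channel, per-band EEG
    log-power); ``response_offsets`` carry subject-level shifts of derived
    responses (blood-pressure deltas).
    """

    subject_id: str
    sensitivity: float
    tolerance: float
    baseline_means: dict[str, float]
    response_offsets: dict[str, float]
    random_effect_sd: dict[str, float]

    def __post_init__(self) -> None:
        if not self.sensitivity >= 0:
            raise ValueError("sensitivity must be >= 0")
        if not 1.0 <= self.tolerance <= 10.0:
            raise ValueError("tolerance must lie in [1, 10]")


@dataclass(frozen=True)
class StimulusTimeline:
    """One day's protocol: baseline window then up to ten rated sessions."""

    day: int
    vrs: tuple[int, ...]
    withdrew_early: bool

    @property
    def n_sessions(self) -> int:
        return len(self.vrs)

    @property
    def baseline_window(self) -> tuple[float, float]:
        return (0.0, WINDOW_SECONDS)

    @property
    def session_windows(self) -> list[tuple[float, float]]:
        return [
            ((k + 1) * WINDOW_SECONDS, (k + 2) * WINDOW_SECONDS)
            for k in range(self.n_sessions)
        ]

    @property
    def duration_s(self) -> float:
        return (self.n_sessions + 1) * WINDOW_SECONDS


@dataclass(frozen=True)
class ModalityRecording:
    """A raw recording of one modality over a full day timeline."""

    modality: str
    sampling_rate: float | None
    channels: tuple[str, ...]
    samples: np.ndarray  # (n_samples, n_channels); BP: (2, 2) pre/post


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_subject(
    seed, config: GeneratorConfig, subject_id: str | None = None
) -> SubjectProfile:
    """Draw one subject's latent parameters.

    Sensitivity is lognormal (median 1) and tolerance uniform on the
    configured range; baselines are population means plus Gaussian subject
    random effects, floored at physiological minima.  The EEG random
    effect is a single scalar offset applied to every channel and band,
    giving strongly subject-correlated spectra.
    """
    config.validate()
    rng = _rng(seed)
    re = config.random_effect_sd
    sensitivity = float(rng.lognormal(0.0, config.sensitivity_log_sd))
    tolerance = float(rng.uniform(*config.tolerance_range))

    base: dict[str, float] = {}
    for key, sd_key in [
        ("em.pupil_mean", "pupil"), ("sc.mean", "sc"), ("bvp.hr", "hr"),
        ("emg.rms", "emg"), ("rr.rate", "rr"), ("st.mean", "st"),
        ("bp.sys", "bp"), ("bp.dia", "bp"),
    ]:
        v = POP_BASELINES[key] + rng.normal(0.0, re[sd_key])
        base[key] = max(v, _BASELINE_FLOORS[key])
    for au in AU_NAMES:
        v = AU_BASELINE[au] + rng.normal(0.0, re["fe"])
        base[f"fe.{au}"] = float(np.clip(v, 0.02, 0.9))
    # EEG subject effect: a global spectral offset shared by all channels
    # plus independent per-channel-band deviations, so cross-subject
    # generalization degrades in many directions at once.
    eeg_offset = rng.normal(0.0, re["eeg"])
    cell_sd = re.get("eeg_cell", 0.0)
    for ch in config.eeg_channels:
        for b in BAND_NAMES:
            base[f"eeg.{ch}.{b}"] = (
                EEG_BAND_BASE_LOGPOWER[b] + eeg_offset
                + rng.normal(0.0, cell_sd)
            )

    offsets = {
        "bp.sys_delta": float(rng.normal(0.0, re["bp_delta"])),
        "bp.dia_delta": float(rng.normal(0.0, re["bp_delta"])),
    }
    sid = subject_id if subject_id is not None else f"subj{seed}"
    return SubjectProfile(
        subject_id=sid,
        sensitivity=sensitivity,
        tolerance=tolerance,
        baseline_means=base,
        response_offsets=offsets,
        random_effect_sd=dict(re),
    )


def generate_timeline(
    profile: SubjectProfile, day: int, config: GeneratorConfig, seed
) -> StimulusTimeline:
    """Simulate one day's VRS trajectory and early-withdrawal decision.

    The latent pain state grows as a saturating exponential toward 10 with
    rate proportional to the subject's sensitivity, perturbed by lognormal
    multiplicative noise (so zero sensitivity gives exactly zero ratings);
    day 1 ratings are shifted up by ``day1_rating_shift`` before rounding
    and clipping.  After each rating above tolerance, the subject
    withdraws with logistic probability in (vrs - tolerance).
    """
    if day not in range(1, config.n_days + 1):
        raise ValueError(f"day {day} outside 1..{config.n_days}")
    rng = _rng(seed)
    vrs: list[int] = []
    withdrew = False
    for k in range(1, config.max_sessions + 1):
        growth = 10.0 * (1.0 - np.exp(-config.growth_rate * profile.sensitivity * k))
        latent = growth * np.exp(rng.normal(0.0, config.rating_noise_log_sd))
        if day == 1:
            latent += config.day1_rating_shift
        v = int(np.clip(np.round(latent), 0, 10))
        vrs.append(v)
        if v > profile.tolerance:
            p_stop = expit((v - profile.tolerance) / config.withdrawal_scale)
            if rng.uniform() < p_stop:
                withdrew = True
                break
    return StimulusTimeline(day=day, vrs=tuple(vrs), withdrew_early=withdrew)


def pain_code(window_kind: str, rating: int | None = None) -> int:
    """Pain-level code of a window: B -> 0, LP -> 1, HP -> 2."""
    return {"B": 0, "LP": 1, "HP": 2}[label_from_vrs(window_kind, rating)]


# ---------------------------------------------------------------------------
# Latent window model (fast path)
# ---------------------------------------------------------------------------

def window_latent_features(
    profile: SubjectProfile,
    code: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw one window's latent feature targets given its pain code.

    Target = subject baseline + effect_size * code * noise_sd + Gaussian
    window noise; AU probabilities are clipped to (0.01, 0.99) and
    positive-valued physiology floored above zero.
    """
    eff, sd = config.effect_sizes, config.noise_sd
    f: dict[str, float] = {}
    for au in AU_NAMES:
        e = eff["fe"] if au in PAIN_RESPONSIVE_AUS else 0.0
        v = (profile.baseline_means[f"fe.{au}"] + e * sd["fe"] * code
             + rng.normal(0.0, sd["fe"]))
        f[f"fe.{au}"] = float(np.clip(v, 0.01, 0.99))
    for ch in config.eeg_channels:
        region = config.eeg_regions.get(ch, "Other")
        for b in BAND_NAMES:
            e = config.eeg_region_effects.get(region, {}).get(b, 0.0)
            f[f"eeg.{ch}.{b}"] = float(
                profile.baseline_means[f"eeg.{ch}.{b}"]
                + e * sd["eeg"] * code + rng.normal(0.0, sd["eeg"])
            )
    f["em.pupil_mean"] = float(max(
        profile.baseline_means["em.pupil_mean"]
        + eff["pupil"] * sd["pupil"] * code + rng.normal(0.0, sd["pupil"]),
        0.5,
    ))
    f["em.pupil_sd"] = float(abs(rng.normal(0.15, 0.05)) + 0.02)
    f["sc.mean"] = float(max(
        profile.baseline_means["sc.mean"]
        + eff["sc"] * sd["sc"] * code + rng.normal(0.0, sd["sc"]), 0.05,
    ))
    f["sc.slope"] = float(rng.normal(0.0, 0.01))
    f["bvp.hr"] = float(np.clip(
        profile.baseline_means["bvp.hr"]
        + eff["hr"] * sd["hr"] * code + rng.normal(0.0, sd["hr"]), 40, 180,
    ))
    f["emg.rms"] = float(max(
        profile.baseline_means["emg.rms"]
        + eff["emg"] * sd["emg"] * code + rng.normal(0.0, sd["emg"]), 0.05,
    ))
    f["rr.rate"] = float(np.clip(
        profile.baseline_means["rr.rate"]
        + eff["rr"] * sd["rr"] * code + rng.normal(0.0, sd["rr"]), 5, 35,
    ))
    f["st.mean"] = float(
        profile.baseline_means["st.mean"]
        + eff["st"] * sd["st"] * code + rng.normal(0.0, sd["st"])
    )
    f["st.slope"] = float(rng.normal(0.0, 0.005))
    return f


def day_bp_deltas(
    profile: SubjectProfile, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Post-minus-pre cuff deltas (mmHg) for one day.

    The systolic response to the cold-pressor day is a configured
    standardized effect plus subject offset plus day noise; the immersion
    itself (not the per-session rating) drives the change, so the delta
    does not depend on individual session codes.
    """
    eff, sd = config.effect_sizes, config.noise_sd["bp"]
    sys_d = (eff["bp_sys"] * sd + profile.response_offsets["bp.sys_delta"]
             + rng.normal(0.0, sd))
    dia_d = (eff["bp_dia"] * sd + profile.response_offsets["bp.dia_delta"]
             + rng.normal(0.0, sd))
    return float(sys_d), float(dia_d)


def simulate_features(
    config: GeneratorConfig | None = None, seed=None
) -> pd.DataFrame:
    """Sample a full cohort at the latent feature level (no raw signals).

    One row per 20-s window with identification columns and the same
    namespaced features that :func:`painfusion.features.assemble_session_features`
    extracts from rendered datasets.  Statistically equivalent to
    rendering plus extraction up to the (negligible) extraction error of
    averaging tens of thousands of raw samples per window.
    """
    config = config or GeneratorConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    root_ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for i, subj_ss in enumerate(root_ss.spawn(config.n_subjects)):
        prof_ss, *day_ss = subj_ss.spawn(config.n_days + 1)
        profile = generate_subject(prof_ss, config, subject_id=f"S{i + 1:02d}")
        for d, dss in enumerate(day_ss, start=1):
            t_ss, f_ss = dss.spawn(2)
            timeline = generate_timeline(profile, d, config, t_ss)
            rng = _rng(f_ss)
            bp_sys, bp_dia = day_bp_deltas(profile, config, rng)
            for k in range(timeline.n_sessions + 1):
                if k == 0:
                    code, rating, label = 0, np.nan, "B"
                else:
                    rating = timeline.vrs[k - 1]
                    label = label_from_vrs("session", rating)
                    code = pain_code("session", rating)
                feats = window_latent_features(profile, code, config, rng)
                feats["bp.sys_delta"] = bp_sys
                feats["bp.dia_delta"] = bp_dia
                rows.append({
                    "subject": profile.subject_id, "day": d, "window": k,
                    "vrs": rating, "label": label, **feats,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Raw-signal renderer
# ---------------------------------------------------------------------------

_EEG_SOS_CACHE: dict[tuple[float, float, float], np.ndarray] = {}


def _band_sos(lo: float, hi: float, fs: float) -> np.ndarray:
    key = (lo, hi, fs)
    if key not in _EEG_SOS_CACHE:
        _EEG_SOS_CACHE[key] = sps.butter(
            4, [lo, hi], btype="bandpass", fs=fs, output="sos"
        )
    return _EEG_SOS_CACHE[key]


def _band_sos_lowpass(cutoff: float, fs: float) -> np.ndarray:
    key = (0.0, cutoff, fs)
    if key not in _EEG_SOS_CACHE:
        _EEG_SOS_CACHE[key] = sps.butter(
            4, cutoff, btype="lowpass", fs=fs, output="sos"
        )
    return _EEG_SOS_CACHE[key]


def render_window(
    modality: str,
    latent: Mapping[str, float],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one 20-s window of raw samples from its latent targets.

    Returns an (n_samples, n_channels) array.  EEG is a sum of
    band-limited noise components rescaled so each band's variance equals
    the latent (exp of log) power; BVP and respiration are quasi-periodic
    waveforms whose peak rate equals the latent rate; scalar channels are
    target mean plus small measurement noise, with slopes centered on the
    window midpoint so the window mean equals the latent mean.
    """
    fs = SAMPLING_RATES[modality]
    if modality == "bp":
        raise ValueError("BP emits cuff readings, not sampled windows")
    n = int(WINDOW_SECONDS * fs)
    t = np.arange(n) / fs
    if modality == "fe":
        out = np.empty((n, len(AU_NAMES)))
        for j, au in enumerate(AU_NAMES):
            out[:, j] = np.clip(
                latent[f"fe.{au}"] + rng.normal(0.0, 0.05, n), 0.0, 1.0
            )
        return out
    if modality == "eeg":
        chans = config.eeg_channels
        out = np.zeros((n, len(chans)))
        for j, ch in enumerate(chans):
            for b, (lo, hi) in BANDS.items():
                comp = sps.sosfiltfilt(
                    _band_sos(lo, hi, fs), rng.standard_normal(n)
                )
                target_var = np.exp(latent[f"eeg.{ch}.{b}"])
                comp *= np.sqrt(target_var) / max(comp.std(), 1e-12)
                out[:, j] += comp
        return out
    if modality == "em":
        # pupil diameter drifts slowly: low-pass the noise (<= 2 Hz) so
        # sample-to-sample velocity stays physiological, then rescale to
        # the latent window SD
        sos = _band_sos_lowpass(2.0, fs)
        drift = sps.sosfiltfilt(sos, rng.standard_normal(n))
        drift *= latent["em.pupil_sd"] / max(drift.std(), 1e-12)
        return (latent["em.pupil_mean"] + drift)[:, None]
    if modality == "sc":
        x = (latent["sc.mean"] + latent["sc.slope"] * (t - WINDOW_SECONDS / 2)
             + rng.normal(0.0, 0.05, n))
        return x[:, None]
    if modality == "st":
        x = (latent["st.mean"] + latent["st.slope"] * (t - WINDOW_SECONDS / 2)
             + rng.normal(0.0, 0.02, n))
        return x[:, None]
    if modality == "emg":
        return rng.normal(0.0, max(latent["emg.rms"], 1e-6), n)[:, None]
    if modality == "bvp":
        f = latent["bvp.hr"] / 60.0
        x = np.sin(2 * np.pi * f * t) + rng.normal(0.0, 0.05, n)
        return x[:, None]
    if modality == "rr":
        f = latent["rr.rate"] / 60.0
        x = 0.5 * np.sin(2 * np.pi * f * t) + rng.normal(0.0, 0.02, n)
        return x[:, None]
    raise ValueError(f"unknown modality {modality!r}")


def synthesize_recording(
    profile: SubjectProfile,
    timeline: StimulusTimeline,
    modality: str,
    config: GeneratorConfig,
    seed,
) -> ModalityRecording:
    """Render one modality's raw recording for a whole day timeline.

    Concatenates the baseline window and each session window; BP instead
    returns exactly two (systolic, diastolic) cuff readings, pre and post.
    """
    if modality not in MODALITY_ORDER:
        raise ValueError(f"unknown modality {modality!r}")
    rng = _rng(seed)
    if modality == "bp":
        sys_d, dia_d = day_bp_deltas(profile, config, rng)
        pre = np.array([
            profile.baseline_means["bp.sys"] + rng.normal(0.0, 2.0),
            profile.baseline_means["bp.dia"] + rng.normal(0.0, 2.0),
        ])
        post = pre + np.array([sys_d, dia_d])
        return ModalityRecording(
            "bp", None, ("systolic", "diastolic"), np.vstack([pre, post])
        )
    codes = [0] + [pain_code("session", v) for v in timeline.vrs]
    segments = []
    for code in codes:
        latent = window_latent_features(profile, code, config, rng)
        segments.append(render_window(modality, latent, config, rng))
    samples = np.vstack(segments)
    if modality == "fe":
        channels = AU_NAMES
    elif modality == "eeg":
        channels = tuple(config.eeg_channels)
    else:
        channels = (modality,)
    return ModalityRecording(modality, SAMPLING_RATES[modality], tuple(channels), samples)


# ---------------------------------------------------------------------------
# On-disk datasets
# ---------------------------------------------------------------------------

def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.5f", lineterminator="\n")


def generate_dataset(
    config: GeneratorConfig | None = None,
    out_dir: str | Path = ".",
    seed=None,
) -> dict:
    """Write a full cohort to disk and return the manifest.

    Layout: ``<root>/subject_<id>/day_<d>/{eeg.csv, em.csv, fe.csv,
    physio.csv, bp.csv, ratings.csv}`` plus a top-level ``manifest.json``
    recording the config, seed and schema version.  Identical (config,
    seed) produce byte-identical trees.
    """
    config = config or GeneratorConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    enabled = set(config.modalities)
    physio_mods = [m for m in ("sc", "bvp", "emg", "st", "rr") if m in enabled]

    recordings = []
    root_ss = np.random.SeedSequence(seed)
    for i, subj_ss in enumerate(root_ss.spawn(config.n_subjects)):
        prof_ss, *day_ss = subj_ss.spawn(config.n_days + 1)
        sid = f"S{i + 1:02d}"
        profile = generate_subject(prof_ss, config, subject_id=sid)
        for d, dss in enumerate(day_ss, start=1):
            t_ss, *mod_ss = dss.spawn(1 + len(MODALITY_ORDER))
            timeline = generate_timeline(profile, d, config, t_ss)
            day_dir = root / f"subject_{sid}" / f"day_{d}"
            day_dir.mkdir(parents=True, exist_ok=True)
            mod_seed = dict(zip(MODALITY_ORDER, mod_ss))

            _write_csv(day_dir / "ratings.csv", pd.DataFrame({
                "session": np.arange(1, timeline.n_sessions + 1),
                "vrs": list(timeline.vrs),
            }))
            if "eeg" in enabled:
                rec = synthesize_recording(profile, timeline, "eeg", config, mod_seed["eeg"])
                df = pd.DataFrame(rec.samples, columns=list(rec.channels))
                df.insert(0, "time_s", np.arange(len(df)) / rec.sampling_rate)
                _write_csv(day_dir / "eeg.csv", df)
            if "em" in enabled:
                rec = synthesize_recording(profile, timeline, "em", config, mod_seed["em"])
                df = pd.DataFrame({"time_s": np.arange(len(rec.samples)) / rec.sampling_rate,
                                   "pupil_mm": rec.samples[:, 0]})
                _write_csv(day_dir / "em.csv", df)
            if "fe" in enabled:
                rec = synthesize_recording(profile, timeline, "fe", config, mod_seed["fe"])
                df = pd.DataFrame(rec.samples, columns=list(rec.channels))
                df.insert(0, "time_s", np.arange(len(df)) / rec.sampling_rate)
                _write_csv(day_dir / "fe.csv", df)
            if physio_mods:
                cols = {}
                for m in physio_mods:
                    rec = synthesize_recording(profile, timeline, m, config, mod_seed[m])
                    cols[m] = rec.samples[:, 0]
                n = len(next(iter(cols.values())))
                df = pd.DataFrame({"time_s": np.arange(n) / SAMPLING_RATES["sc"], **{
                    m: cols[m] for m in ("sc", "bvp", "emg", "st", "rr") if m in cols
                }})
                _write_csv(day_dir / "physio.csv", df)
            if "bp" in enabled:
                rec = synthesize_recording(profile, timeline, "bp", config, mod_seed["bp"])
                df = pd.DataFrame({
                    "phase": ["pre", "post"],
                    "systolic": rec.samples[:, 0],
                    "diastolic": rec.samples[:, 1],
                })
                _write_csv(day_dir / "bp.csv", df)
            recordings.append({
                "subject": sid, "day": d,
                "path": f"subject_{sid}/day_{d}",
                "n_sessions": timeline.n_sessions,
                "withdrew_early": timeline.withdrew_early,
            })

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["eeg_channels"] = list(config.eeg_channels)
    cfg_dict["modalities"] = list(config.modalities)
    cfg_dict["tolerance_range"] = list(config.tolerance_range)
    manifest = {
        "schema_version": 1,
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
        "config": cfg_dict,
        "recordings": recordings,
    }
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
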